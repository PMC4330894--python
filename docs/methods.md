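# Methods

## Overview

`munet` implements a sensor-space analysis of band-limited functional
networks over the sensorimotor cortex. Its input is a multichannel recording
with movement-onset events and a per-subject individual mu peak frequency
(IMPF); its output is a per-subject pair of thresholded connectivity
networks (rest and prehension), five scalar network measures per network,
and group-level statistics. Because infant MEG recordings of this kind are
not publicly available, the package ships a synthetic cohort generator with
known ground truth; every stage is validated against that generator and
against closed-form or brute-force oracles.

## Synthetic data generator

Each simulated channel is the sum of a unit-variance narrowband "mu"
component and broadband white noise of standard deviation `noise_sd`
(default 0.3). The mu component is Gaussian narrowband noise obtained by
forward–reverse Butterworth band-passing white noise at IMPF ± 1 Hz.
Pairwise coupling is imposed by Cholesky mixing of independent narrowband
sources: given a symmetric coupling matrix `c` with zero diagonal (validated
so that `c + I` is positive semidefinite), the mixed channels have mu-band
correlation exactly `c[k, q]` in expectation. Event-related
desynchronization is emulated by multiplying the mu component by the factor
`suppression` during the 3 s following each movement onset. Movement onsets
occupy the second half of each record at a 6-s pitch (with ±0.3 s jitter),
leaving the first half as uninterrupted rest; this guarantees that both
conditions yield complete 4-s epochs. All randomness flows from a single
integer seed per subject, so identical specs reproduce bit-identical data.

Sensor positions are laid out by a Fibonacci lattice on a spherical cap
(sphere radius 75 mm), sized by hexagonal-packing arithmetic for the target
nearest-neighbor pitch (default 13 mm for the default 76 channels) and
rescaled so the median nearest-neighbor distance equals the pitch exactly.

What the generator does **not** emulate: forward-model MEG physics and field
spread (channels are statistically, not physically, mixed), 1/f background
spectra, artifacts (motion, chewing, cardiac), head-position variability,
or heteroscedastic channel noise. Passing tests therefore demonstrate the
correctness and sensitivity of the estimator chain — not robustness to
real-world MEG contaminants, which the upstream IC-selection step is
expected to remove.

## Preprocessing

Recordings are band-pass filtered at 0.5–40 Hz with a third-order
forward–reverse (zero-phase) Butterworth filter, then again inside the
individual mu band, IMPF ± 2 Hz, with the same design; the band's low edge
is clamped to 0.5 Hz so infant bands never extend below the wideband floor.
Filtering always precedes epoch cutting so filter transients never sit at
epoch boundaries. Prehension epochs are 4 s starting 1 s before each onset
(non-overlapping; edge-truncated epochs are discarded). Rest epochs tile
every stretch of the record whose samples all lie at least 5 s from every
onset — the 5-s margin operationalizes "far from movements" and is
configurable. An externally computed ICA decomposition can be re-projected
through `reproject_ics` (mixing matrix × retained source rows); component
selection is deliberately out of scope because it is a visual,
topography-based judgement.

## Synchronization likelihood

SL is computed per epoch per channel pair from time-delay embeddings. For an
analysis band (low, high) at sampling rate fs the embedding parameters follow
a band-based scheme: lag `l = round(fs / (3·high))`, dimension
`m = ceil(3·high / low) + 1`, Theiler window `w1 = 2·l·(m − 1)`, and outer
window `w2 = min(w1 + round(90 / p_ref), n_emb − 1)` where `n_emb` is the
number of embedded vectors. The target recurrence fraction `p_ref` defaults
to 0.01. For each reference time `i` the critical distance ε(i) is the
k-th smallest Euclidean distance to the admissible comparison times
(`w1 < |i − j| < w2`, two-sided), with `k = ceil(p_ref · N_w(i))`; ties at
ε are counted as recurrences. The pairwise SL is the joint-recurrence count
normalized by the realized recurrence fraction `k/N_w`:

    SL_kq = mean_i [ hits_i · p_ref · N_w(i) / k_i² ]

clipped to [0, 1]. When `p_ref · N_w` is an integer this equals the
textbook normalization `hits / (p_ref · N_w)`; using the realized fraction
removes the order-statistic discretization bias, so independent signals
average to `p_ref` exactly and identical signals reach 1 within
`1/(p_ref · N_w)`. Epoch SL matrices are averaged per condition. A
`ref_stride` option subsamples reference times (never comparison times) for
speed; at stride 2 the estimate changes by well under the epoch-to-epoch
standard deviation. Constant channels produce ε = 0 with a warning rather
than an error.

## Thresholding and quality control

Each average SL matrix is reduced to a network by keeping values strictly
greater than Median + 1·MAD of its own upper-triangle off-diagonal value
distribution (each symmetric pair counted once; a zero MAD or an empty
result raises). SL_MEAN is the mean of the surviving values. Two conditions
decide subject inclusion: (1) the squared Pearson correlation between the
thresholded matrix (zeros included) and the Euclidean inter-sensor distance
matrix must be below 0.1 for both conditions, rejecting networks whose
structure follows sensor proximity; and (2) the rest and prehension networks
must have exactly equal edge counts, so their graph metrics are compared at
a fixed average degree. Zero-valued (sub-threshold) pairs are included in
the r² because proximity bias manifests precisely as short-distance pairs
surviving and long-distance pairs vanishing. Degree equality is exact
integer equality; it can be disabled (`require_equal_degree=False`) for
synthetic experiments, where edge counts are stochastic and the filter would
thin cohorts without serving its purpose of making real recordings
comparable.

## Graph measures

On the thresholded network with weights `w ∈ (0, 1]`:

* **Clustering coefficient C** — mean over nodes of
  `c_i = 2 t_i / (k_i (k_i − 1))`, `t_i = ½ Σ_{j,h} (w_ij w_ih w_jh)^{1/3}`;
  nodes of degree < 2 contribute 0.
* **Local efficiency E_loc** — mean over nodes of the neighborhood
  efficiency `e_i = Σ_{j≠h ∈ N_i} (w_ij w_ih / d_jh(N_i))^{1/3} /
  (k_i (k_i − 1))`, with `d_jh(N_i)` the shortest path between neighbors
  restricted to the neighborhood subgraph.
* **Characteristic path length L** — mean of finite shortest-path distances
  over ordered node pairs with edge length `1/w`; the fraction of
  unreachable pairs is reported separately instead of being folded into the
  mean.
* **Global efficiency E_glob** — mean inverse shortest-path distance with
  `1/∞ = 0`.

C and E_loc are computed on max-normalized weights (`w / max w`), which
makes them exactly invariant to a common rescaling of the SL values and
matches the convention of standard weighted clustering implementations.
L and E_glob are computed on the raw SL weights: the magnitude of SL is
itself the quantity of interest for integration (strong synchronization =
short functional distance), SL ≤ 1 already guarantees E_glob ∈ [0, 1], and
max-normalizing would erase the connectivity-strength differences these
measures are meant to reflect. Shortest paths use Dijkstra's algorithm
(scipy's csgraph); equivalence with Floyd–Warshall enumeration is asserted
in the tests to 1e-9 on hundreds of random graphs, and the closed-form cases
(complete graph, star, chains, disjoint edges) are asserted exactly.

The printed formula for local efficiency in the source literature is
ambiguous about its normalization (it lacks an explicit averaging term and
describes weighted distances as link counts); the implementation fixes the
normalization so that a complete unit-weight graph has E_loc = 1 and a star
has E_loc = 0, and uses the inverse-weight length consistently.

## Group statistics

Each measure is analyzed with a mixed ANOVA — age group between subjects,
condition (rest/prehension) within subjects — with partial eta squared
`η²_p = SS_effect / (SS_effect + SS_error)` per effect, at α = 0.05.
The implementation delegates to `pingouin.mixed_anova`; the test suite
verifies it against a hand-computed split-plot sums-of-squares decomposition
(exact to 1e-9 on balanced designs, including the completeness of the
decomposition). Post-hoc group comparisons are two-sample t tests on
condition-averaged subject means, Bonferroni-corrected by the number of
pairs (×10 for five groups, capped at 1). Regressions of each measure on
age and mu peak frequency report the OLS r². Observed power is not
computed. Under null cohorts the group-effect rejection rate calibrates to
≈ 0.05 (checked over 200 replicates).

## Problem sizes and numerical choices

The validation experiments run at deliberately modest sizes chosen so a
full cohort analysis completes in well under a minute per cohort on one
core: 12 channels, 64-s recordings, 3 prehension events (≈ 7 rest + 3
prehension epochs), fs = 500 Hz, 4-s epochs, `ref_stride = 2`. The
developmental-contrast experiment opposes a "mature" group (two 4-channel
modules coupled at 0.75) to an "immature" group (uniform weak coupling
0.12), six subjects each; its expected signature — higher SL_MEAN, C,
E_loc, E_glob and lower L in the modular group — is recovered with a
significant group effect in ≥ 8 of 10 cohort replicates. Distances inside
the SL kernel are computed in float32 (the thresholding and metrics stages
are float64 throughout); Dijkstra distances and the MAD threshold are exact.
Ties at the recurrence quantile are included; degenerate inputs (constant
channels, all-equal SL distributions, empty networks, disconnected graphs)
raise typed errors or warnings rather than propagating NaNs.

## Known limitations

* SL magnitudes depend on the embedding-parameter scheme; the band-based
  scheme used here is a standard heuristic, and absolute SL values are not
  comparable across different schemes (relative contrasts are).
* The generator's linear Gaussian coupling cannot produce the nonlinear
  generalized synchronization SL was designed to detect; SL is validated
  here on its limits, monotonicity and independence calibration, not on
  chaotic-oscillator recovery.
* The distance-bias QC uses a fixed shared sensor layout per cohort; with
  per-subject layouts the r² threshold may need recalibration.
* With few epochs, Median+MAD thresholding of noisy SL matrices yields
  stochastic edge counts, which is why the exact degree-equality filter is
  optional for synthetic cohorts.
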