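"""Synchronization likelihood (SL) between multichannel time series.

SL is a recurrence-based, normalized estimate of generalized synchronization.
Each channel is time-delay embedded; for every reference time i a critical
distance eps_k(i) is chosen so that a fixed fraction p_ref of the comparison
times j inside a two-sided window (Theiler exclusion w1 < |i - j| < outer
bound w2) are recurrences of v_k(i).  The SL between channels k and q is the
probability of *simultaneous* recurrence, normalized by p_ref:

    SL_kq = mean_i  #{j : recur_k(i,j) and recur_q(i,j)} / (p_ref * N_w(i))

so SL ~ p_ref for independent signals and ~ 1 for identical signals.
Because eps is an order statistic (the k-th smallest distance with
k = ceil(p_ref * N_w)), the realized recurrence fraction p_hat = k / N_w
slightly exceeds p_ref whenever p_ref * N_w is not an integer; the counts
are therefore normalized by the realized fraction,

    SL_kq = mean_i  hits_i * p_ref * N_w(i) / k_i**2

which reduces to the expression above when p_ref * N_w is an integer, is
exactly unbiased at p_ref under independence, and deviates from 1 by at most
1/(p_ref * N_w) in the identical-signal limit.

Embedding parameters follow a frequency-band heuristic: for an analysis band
(low, high) at sampling rate fs, lag l = round(fs / (3 * high)), dimension
m = ceil(3 * high / low) + 1, Theiler window w1 = 2 * l * (m - 1) and outer
window w2 = w1 + round(90 / p_ref) capped at the embedded length - 1 (the
cap keeps the recurrence fraction attainable in short epochs).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import EpochTooShortError, WindowConfigError

__all__ = [
    "SLParams",
    "SLMatrix",
    "choose_sl_params",
    "embed",
    "critical_distances",
    "sl_pairwise",
    "sl_average",
    "sl_condition",
]

_POPCOUNT_AVAILABLE = hasattr(np, "bitwise_count")


@dataclass(frozen=True)
class SLParams:
    """Embedding and recurrence parameters of the SL estimator."""

    p_ref: float = 0.01     # target recurrence fraction
    lag: int = 10           # embedding lag l, samples
    dim: int = 5            # embedding dimension m
    w1: int = 80            # Theiler window, samples
    w2: int = 400           # outer window, samples

    def __post_init__(self):
        if not 0.0 < self.p_ref < 1.0:
            raise ValueError("p_ref must lie in (0, 1)")
        if self.lag < 1 or self.dim < 1:
            raise ValueError("lag >= 1 and dim >= 1 required")
        if not 0 < self.w1 < self.w2:
            raise ValueError("need 0 < w1 < w2")


@dataclass
class SLMatrix:
    """Symmetric channels x channels SL matrix, diagonal fixed to 0."""

    values: np.ndarray
    n_epochs: int = 1

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def choose_sl_params(band, fs: float, epoch_samples: int,
                     p_ref: float = 0.01) -> SLParams:
    """Band-based SL parameter scheme (see module docstring)."""
    lag = max(1, round(fs / (3.0 * band.high)))
    dim = math.ceil(3.0 * band.high / band.low) + 1
    w1 = 2 * lag * (dim - 1)
    n_emb = epoch_samples - (dim - 1) * lag
    if n_emb <= w1 + 1:
        raise EpochTooShortError(
            f"epoch of {epoch_samples} samples leaves {n_emb} embedded "
            f"vectors, too few for Theiler window w1={w1}")
    w2 = min(w1 + round(90.0 / p_ref), n_emb - 1)
    return SLParams(p_ref=p_ref, lag=lag, dim=dim, w1=w1, w2=w2)


def embed(signal: np.ndarray, m: int, l: int) -> np.ndarray:
    """Time-delay embedding: row i = (x_i, x_{i+l}, ..., x_{i+(m-1)l})."""
    signal = np.asarray(signal)
    span = (m - 1) * l
    if signal.shape[-1] <= span:
        raise EpochTooShortError(
            f"signal of length {signal.shape[-1]} too short for m={m}, l={l}")
    if m == 1:
        return signal.reshape(-1, 1)
    view = np.lib.stride_tricks.sliding_window_view(signal, span + 1)
    return view[..., ::l]


def _window_counts(n_emb: int, w1: int, w2: int,
                   ref_idx: np.ndarray) -> np.ndarray:
    """N_w(i): number of admissible j with w1 < |i - j| < w2, per reference i."""
    lo = np.minimum(ref_idx, w2 - 1) - w1          # admissible j < i
    hi = np.minimum(n_emb - 1 - ref_idx, w2 - 1) - w1  # admissible j > i
    return np.maximum(lo, 0) + np.maximum(hi, 0)


def _admissible_mask(n_emb: int, w1: int, w2: int,
                     ref_idx: np.ndarray) -> np.ndarray:
    offs = np.abs(ref_idx[:, None] - np.arange(n_emb)[None, :])
    return (offs > w1) & (offs < w2)


def critical_distances(embedded: np.ndarray, params: SLParams,
                       ref_idx: np.ndarray | None = None,
                       dist_rows: np.ndarray | None = None,
                       adm: np.ndarray | None = None) -> np.ndarray:
    """Per-reference-time critical distance eps(i).

    eps(i) is the empirical p_ref quantile (k-th order statistic,
    k = ceil(p_ref * N_w(i))) of the distances between v(i) and the
    admissible v(j); the realized in-window recurrence fraction therefore
    equals p_ref within 1/N_w(i) up to ties.
    """
    n_emb = embedded.shape[0]
    if ref_idx is None:
        ref_idx = np.arange(n_emb)
    nw = _window_counts(n_emb, params.w1, params.w2, ref_idx)
    if np.any(nw == 0):
        raise WindowConfigError("some reference times have no admissible "
                                "comparison time; reduce w1 or grow the epoch")
    if dist_rows is None:
        dist_rows = cdist(embedded[ref_idx], embedded).astype(np.float32)
    if adm is None:
        adm = _admissible_mask(n_emb, params.w1, params.w2, ref_idx)
    masked = np.where(adm, dist_rows, np.float32(np.inf))
    k = np.ceil(params.p_ref * nw).astype(int)
    k = np.maximum(k, 1)
    kmax = int(k.max())
    part = np.partition(masked, kmax - 1, axis=1)[:, :kmax]
    part.sort(axis=1)
    eps = part[np.arange(len(ref_idx)), k - 1]
    if np.all(eps == 0):
        warnings.warn("constant signal: all in-window distances are zero",
                      stacklevel=2)
    return eps.astype(np.float32)


def _recurrence_bits(embedded: np.ndarray, params: SLParams,
                     ref_idx: np.ndarray, adm: np.ndarray) -> np.ndarray:
    dist_rows = cdist(embedded[ref_idx], embedded).astype(np.float32)
    eps = critical_distances(embedded, params, ref_idx=ref_idx,
                             dist_rows=dist_rows, adm=adm)
    recur = (dist_rows <= eps[:, None]) & adm
    return np.packbits(recur, axis=1)


def _pair_counts(pk: np.ndarray, pq: np.ndarray) -> np.ndarray:
    both = np.bitwise_and(pk, pq)
    if _POPCOUNT_AVAILABLE:
        return np.bitwise_count(both).sum(axis=1)
    return np.unpackbits(both, axis=1).sum(axis=1)


def sl_pairwise(epoch: np.ndarray, params: SLParams,
                ref_stride: int = 1) -> SLMatrix:
    """Pairwise SL matrix of one epoch (channels x samples).

    ``ref_stride`` subsamples the reference times i (every comparison time j
    is still used), trading a little estimator variance for speed.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] < 2:
        raise ValueError("epoch must be (n_channels >= 2, n_samples)")
    n_ch = epoch.shape[0]
    emb0 = embed(epoch[0], params.dim, params.lag)
    n_emb = emb0.shape[0]
    if n_emb <= params.w1 + 1:
        raise EpochTooShortError("embedded length does not exceed w1")
    ref_idx = np.arange(0, n_emb, ref_stride)
    nw = _window_counts(n_emb, params.w1, params.w2, ref_idx)
    if np.any(nw == 0):
        raise WindowConfigError("reference time with empty window")
    adm = _admissible_mask(n_emb, params.w1, params.w2, ref_idx)

    packed = []
    for ch in range(n_ch):
        emb = emb0 if ch == 0 else embed(epoch[ch], params.dim, params.lag)
        packed.append(_recurrence_bits(emb, params, ref_idx, adm))

    k = np.maximum(np.ceil(params.p_ref * nw).astype(int), 1)
    inv_norm = params.p_ref * nw / k.astype(float) ** 2
    values = np.zeros((n_ch, n_ch))
    for k in range(n_ch):
        for q in range(k + 1, n_ch):
            hits = _pair_counts(packed[k], packed[q])
            values[k, q] = values[q, k] = float(np.mean(hits * inv_norm))
    np.clip(values, 0.0, 1.0, out=values)
    np.fill_diagonal(values, 0.0)
    return SLMatrix(values=values, n_epochs=1)


def sl_average(mats: list[SLMatrix]) -> SLMatrix:
    """Element-wise arithmetic mean of per-epoch SL matrices."""
    if not mats:
        raise ValueError("need at least one SL matrix")
    shape = mats[0].values.shape
    if any(m.values.shape != shape for m in mats):
        raise ValueError("all SL matrices must share one shape")
    values = np.mean([m.values for m in mats], axis=0)
    return SLMatrix(values=values, n_epochs=sum(m.n_epochs for m in mats))


def sl_condition(epochs: np.ndarray, params: SLParams,
                 ref_stride: int = 1) -> SLMatrix:
    """Average SL matrix over the epochs (n_epochs, n_channels, n_samples)."""
    mats = [sl_pairwise(ep, params, ref_stride=ref_stride) for ep in epochs]
    return sl_average(mats)
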