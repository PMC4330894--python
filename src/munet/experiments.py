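"""Ready-made synthetic experiments exercising the whole pipeline.

These are the study designs used for validation and in the worked examples:

* a two-group developmental contrast — a "mature" group with strong modular
  mu-band coupling against an "immature" group with weak diffuse coupling —
  whose expected signature is higher SL_MEAN, C, E_loc and E_glob and lower
  L in the modular group;
* a null cohort (no group or condition effect) for type-I calibration of the
  mixed ANOVA;
* a distance-bias simulation checking that the r^2 QC rejects networks whose
  connectivity follows inter-sensor distance and passes distance-independent
  ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import AnalysisParams, CohortNetworkModel
from .simulate import (SimSpec, make_sensor_array, modular_coupling,
                       uniform_coupling)
from .sl import SLMatrix
from .stats import MEASURES, mixed_anova
from .threshold import distance_bias_r2, mad_threshold

__all__ = ["contrast_specs", "run_contrast", "contrast_success",
           "null_metric_table", "anova_rejection_rate", "qc_bias_rates"]

#: problem size of the contrast experiment (kept modest so a cohort runs in
#: well under a minute on one core; see the methods note)
N_CHANNELS = 12
N_PER_GROUP = 6
DURATION = 64.0
N_EVENTS = 3


def contrast_specs(seed: int) -> list[tuple[str, SimSpec]]:
    """Cohort specs: modular high-coupling group vs random low-coupling group.

    The modular group couples two 4-channel modules at 0.75; the random group
    couples every pair weakly at 0.12 so its suprathreshold topology is
    estimation-noise driven.  Edge counts after Median+MAD thresholding come
    out comparable by construction (the threshold adapts to each matrix).
    """
    mod = modular_coupling(N_CHANNELS, n_modules=2, module_size=4,
                           within=0.75)
    uni = uniform_coupling(N_CHANNELS, 0.12)
    specs = []
    for i in range(N_PER_GROUP):
        specs.append(("modular", SimSpec(
            n_channels=N_CHANNELS, duration=DURATION, n_events=N_EVENTS,
            impf=9.0, coupling=mod, suppression=0.7, age=25.0,
            seed=(seed * 1009 + i) % 2**31)))
        specs.append(("random", SimSpec(
            n_channels=N_CHANNELS, duration=DURATION, n_events=N_EVENTS,
            impf=9.0, coupling=uni, suppression=0.7, age=0.5,
            seed=(seed * 1009 + 500 + i) % 2**31)))
    return specs


def run_contrast(seed: int, ref_stride: int = 2):
    """Fit the developmental-contrast cohort; returns the results object.

    The degree-equality QC is disabled: it is a data-quality filter for real
    recordings, and on synthetic cohorts with stochastic edge counts it would
    thin both groups without bearing on the contrast.
    """
    params = AnalysisParams(require_equal_degree=False, ref_stride=ref_stride)
    model = CohortNetworkModel.from_simulation(contrast_specs(seed),
                                               layout_seed=seed,
                                               params=params)
    return model.fit()


def contrast_success(results) -> dict:
    """Direction checks and the SL_MEAN group effect for one fitted cohort."""
    means = results.metrics.groupby("group")[MEASURES].mean()
    directions = {
        m: bool(means.loc["modular", m] > means.loc["random", m])
        for m in ("SL_MEAN", "C", "E_loc", "E_glob")}
    directions["L"] = bool(means.loc["modular", "L"]
                           < means.loc["random", "L"])
    p_group = next(r.p for r in results.anova("SL_MEAN")
                   if r.effect == "group")
    return {"directions": directions,
            "all_directions": all(directions.values()),
            "p_group_sl_mean": float(p_group),
            "significant": bool(p_group < 0.05)}


def null_metric_table(rng: np.random.Generator, n_groups: int = 5,
                      per_group: int = 6) -> pd.DataFrame:
    """Cohort metrics table with no group or condition effect."""
    rows = []
    sid = 0
    for g in range(n_groups):
        for _ in range(per_group):
            sid += 1
            for cond in ("rest", "prehension"):
                rows.append({"subject_id": f"s{sid}", "group": f"G{g + 1}",
                             "condition": cond, "y": rng.normal()})
    return pd.DataFrame(rows)


def anova_rejection_rate(n_replicates: int, seed: int,
                         alpha: float = 0.05) -> float:
    """Type-I rate of the mixed-ANOVA group effect under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        res = mixed_anova(null_metric_table(rng), "y")
        p = next(r.p for r in res if r.effect == "group")
        rejections += p < alpha
    return rejections / n_replicates


def _symmetrize(upper: np.ndarray, n: int) -> np.ndarray:
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = upper
    return m + m.T


def qc_bias_rates(n_seeds: int, seed: int, n_channels: int = 76,
                  r2_max: float = 0.1) -> tuple[float, float]:
    """(rejection rate of distance-driven nets, pass rate of independent nets).

    Distance-driven matrices follow 1/M_Eu plus noise (short-distance
    inflation as produced by volume conduction / field spread); independent
    matrices draw every pair uniformly.  Both are Median+MAD thresholded
    before the r^2 check, as in the pipeline.
    """
    arr = make_sensor_array(n_channels, 13.0, seed=seed)
    n_pairs = n_channels * (n_channels - 1) // 2
    iu = np.triu_indices(n_channels, k=1)
    inv_d = 13.0 / arr.m_eu[iu]
    rng = np.random.default_rng(seed)
    rejected = passed = 0
    for _ in range(n_seeds):
        biased = np.clip(0.3 * inv_d + 0.02 * rng.standard_normal(n_pairs),
                         1e-4, 0.999)
        t = mad_threshold(SLMatrix(values=_symmetrize(biased, n_channels)))
        rejected += distance_bias_r2(t, arr) >= r2_max

        indep = rng.uniform(1e-3, 0.5, size=n_pairs)
        t = mad_threshold(SLMatrix(values=_symmetrize(indep, n_channels)))
        passed += distance_bias_r2(t, arr) < r2_max
    return rejected / n_seeds, passed / n_seeds
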