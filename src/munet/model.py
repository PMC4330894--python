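"""Cohort-level model and results objects.

`CohortNetworkModel` holds a cohort of recordings plus the analysis
parameters; `fit()` runs the full chain per subject — wideband filtering,
individual mu-band filtering, 4-s epoch extraction, per-epoch SL, epoch
averaging, Median+MAD thresholding, QC, graph metrics — and returns a
`CohortNetworkResults` carrying the connectivity matrices, the QC table, the
long-format metrics table, and group statistics behind `anova()`,
`posthoc()`, `regressions()` and `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import graphs, preprocess, simulate, sl, threshold
from .errors import EmptyEpochsError
from .stats import MEASURES, bonferroni_posthoc, mixed_anova, regression_table

__all__ = ["AnalysisParams", "CohortNetworkModel", "CohortNetworkResults",
           "SubjectResult"]


@dataclass(frozen=True)
class AnalysisParams:
    """Every tunable constant of the analysis chain, with study defaults."""

    wide_low: float = 0.5        # Hz, wideband high-pass edge
    wide_high: float = 40.0      # Hz, wideband low-pass edge
    filter_order: int = 3        # Butterworth order (applied forward-reverse)
    band_offset: float = 2.0     # mu band = impf +/- band_offset, Hz
    epoch_s: float = 4.0         # epoch length, s
    pre_onset_s: float = 1.0     # prehension epochs start this before onset, s
    rest_margin_s: float = 5.0   # rest epochs keep this distance from onsets, s
    p_ref: float = 0.01          # SL recurrence fraction
    ref_stride: int = 1          # SL reference-time subsampling
    r2_max: float = 0.1          # distance-bias QC bound
    require_equal_degree: bool = True
    alpha: float = 0.05


@dataclass
class SubjectResult:
    meta: simulate.SubjectMeta
    sl_rest: sl.SLMatrix
    sl_prehension: sl.SLMatrix
    thr_rest: threshold.ThresholdedSL
    thr_prehension: threshold.ThresholdedSL
    qc: threshold.SubjectQC
    metrics_rest: graphs.NetworkMetrics | None
    metrics_prehension: graphs.NetworkMetrics | None
    n_epochs_rest: int
    n_epochs_prehension: int


class CohortNetworkModel:
    """Sensor-space mu-band functional-network model of a cohort."""

    def __init__(self, subjects, sensor_array: simulate.SensorArray,
                 params: AnalysisParams | None = None):
        self.subjects = list(subjects)  # (SubjectMeta, Recording, EventTable)
        self.sensor_array = sensor_array
        self.params = params or AnalysisParams()

    @classmethod
    def from_simulation(cls, specs: list[tuple[str, simulate.SimSpec]],
                        layout_seed: int = 0,
                        params: AnalysisParams | None = None,
                        ) -> "CohortNetworkModel":
        """Simulate a cohort and build the model over one shared layout."""
        subjects = simulate.simulate_cohort(specs)
        n_channels = subjects[0][1].n_channels
        spec0 = specs[0][1]
        arr = simulate.make_sensor_array(n_channels, spec0.spacing,
                                         seed=layout_seed)
        return cls(subjects, arr, params=params)

    def _analyze_subject(self, meta, rec, events) -> SubjectResult:
        p = self.params
        rec_wide = preprocess.bandpass(rec, p.wide_low, p.wide_high,
                                       order=p.filter_order)
        band = preprocess.select_band(meta.impf, offset=p.band_offset,
                                      floor=p.wide_low)
        rec_mu = preprocess.bandpass(rec_wide, band.low, band.high,
                                     order=p.filter_order)
        epoch_samples = round(p.epoch_s * rec.fs)
        params_sl = sl.choose_sl_params(band, rec.fs, epoch_samples,
                                        p_ref=p.p_ref)
        per_condition = {}
        n_epochs = {}
        for condition in ("rest", "prehension"):
            eps = preprocess.extract_epochs(
                rec_mu, events, condition, epoch_s=p.epoch_s,
                pre_onset_s=p.pre_onset_s, rest_margin_s=p.rest_margin_s)
            per_condition[condition] = sl.sl_condition(
                eps.epochs, params_sl, ref_stride=p.ref_stride)
            n_epochs[condition] = eps.n_epochs

        thr_rest = threshold.mad_threshold(per_condition["rest"])
        thr_preh = threshold.mad_threshold(per_condition["prehension"])
        qc = threshold.subject_qc(
            thr_rest, thr_preh, self.sensor_array,
            subject_id=meta.subject_id, r2_max=p.r2_max,
            require_equal_degree=p.require_equal_degree)
        metrics_rest = metrics_preh = None
        if qc.included:
            metrics_rest, metrics_preh = graphs.compute_all(thr_rest, thr_preh)
        return SubjectResult(
            meta=meta, sl_rest=per_condition["rest"],
            sl_prehension=per_condition["prehension"],
            thr_rest=thr_rest, thr_prehension=thr_preh, qc=qc,
            metrics_rest=metrics_rest, metrics_prehension=metrics_preh,
            n_epochs_rest=n_epochs["rest"],
            n_epochs_prehension=n_epochs["prehension"])

    def fit(self, verbose: bool = False) -> "CohortNetworkResults":
        results = []
        for meta, rec, events in self.subjects:
            res = self._analyze_subject(meta, rec, events)
            if verbose:
                print(f"{meta.subject_id}: r2=({res.qc.r2_rest:.3f}, "
                      f"{res.qc.r2_prehension:.3f}) edges=({res.qc.degree_rest}, "
                      f"{res.qc.degree_prehension}) included={res.qc.included}")
            results.append(res)
        return CohortNetworkResults(self, results)


class CohortNetworkResults:
    """Fitted cohort results: matrices, QC, metrics table, group statistics."""

    def __init__(self, model: CohortNetworkModel,
                 subject_results: list[SubjectResult]):
        self.model = model
        self.subject_results = subject_results

    @property
    def qc_table(self) -> pd.DataFrame:
        rows = []
        for r in self.subject_results:
            rows.append({"subject_id": r.meta.subject_id,
                         "group": r.meta.group,
                         "r2_rest": r.qc.r2_rest,
                         "r2_prehension": r.qc.r2_prehension,
                         "edges_rest": r.qc.degree_rest,
                         "edges_prehension": r.qc.degree_prehension,
                         "included": r.qc.included})
        return pd.DataFrame(rows)

    @property
    def metrics(self) -> pd.DataFrame:
        """Long-format cohort table: one row per included subject x condition."""
        rows = []
        for r in self.subject_results:
            if not r.qc.included:
                continue
            for condition, m in (("rest", r.metrics_rest),
                                 ("prehension", r.metrics_prehension)):
                rows.append({"subject_id": r.meta.subject_id,
                             "group": r.meta.group, "age": r.meta.age,
                             "impf": r.meta.impf, "condition": condition,
                             **m.as_dict()})
        return pd.DataFrame(rows)

    @property
    def n_included(self) -> int:
        return sum(r.qc.included for r in self.subject_results)

    def anova(self, measure: str):
        return mixed_anova(self.metrics, measure)

    def anova_table(self) -> pd.DataFrame:
        rows = []
        for m in MEASURES:
            for res in self.anova(m):
                rows.append({"measure": m, "effect": res.effect, "F": res.F,
                             "df_num": res.df_num, "df_den": res.df_den,
                             "p": res.p, "eta_p2": res.eta_p2})
        return pd.DataFrame(rows)

    def posthoc(self, measure: str) -> pd.DataFrame:
        return bonferroni_posthoc(self.metrics, measure)

    def regressions(self) -> pd.DataFrame:
        return regression_table(self.metrics)

    def group_means(self) -> pd.DataFrame:
        return (self.metrics
                .groupby(["group", "condition"], observed=True)[MEASURES]
                .agg(["mean", "std"]))

    def summary(self) -> str:
        lines = ["Sensorimotor mu-band functional network analysis",
                 "=" * 50,
                 f"subjects analyzed : {len(self.subject_results)}",
                 f"subjects included : {self.n_included}",
                 "", "Group means (mean +/- SD over subjects)", "-" * 50]
        gm = self.metrics.groupby(["group", "condition"],
                                  observed=True)[MEASURES]
        for (group, condition), sub in gm:
            cells = "  ".join(f"{m}={sub[m].mean():.3f}+/-{sub[m].std():.3f}"
                              for m in MEASURES)
            lines.append(f"{group:>6} {condition:<11} {cells}")
        lines += ["", "Mixed ANOVA group (between) x condition (within)",
                  "-" * 50]
        for m in MEASURES:
            for res in self.anova(m):
                star = "*" if res.p < self.model.params.alpha else " "
                lines.append(
                    f"{m:<8} {res.effect:<18} F({res.df_num},{res.df_den})="
                    f"{res.F:7.3f}  p={res.p:.4f}{star}  eta_p2={res.eta_p2:.3f}")
        return "\n".join(lines)
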