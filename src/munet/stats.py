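"""Group-level statistics on the cohort metrics table.

The cohort table is long format: one row per subject x condition with the
five network measures plus group, age and individual mu peak frequency.
Each measure is analyzed with a mixed 5 (age group, between subjects) x
2 (condition rest/prehension, within subjects) ANOVA with partial eta
squared effect sizes, Bonferroni-corrected pairwise group comparisons on
condition-averaged subject means, and ordinary least-squares regressions of
the measures on age and mu peak frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidDesignError, UndefinedR2Error

__all__ = [
    "AnovaResult",
    "MEASURES",
    "regress_r2",
    "mixed_anova",
    "bonferroni_posthoc",
    "regression_table",
]

MEASURES = ["SL_MEAN", "C", "E_loc", "L", "E_glob"]
ALPHA = 0.05


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta_p2: float


def regress_r2(x: np.ndarray, y: np.ndarray) -> float:
    """OLS coefficient of determination of y on a single predictor x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise UndefinedR2Error("predictor has zero variance")
    res = sps.linregress(x, y)
    return float(res.rvalue ** 2)


def _validate_table(tbl: pd.DataFrame, measure: str) -> None:
    for col in ("subject_id", "group", "condition", measure):
        if col not in tbl.columns:
            raise InvalidDesignError(f"missing column {col!r}")
    counts = tbl.groupby("subject_id")["condition"].nunique()
    if (counts != 2).any():
        raise InvalidDesignError("every subject needs both conditions")
    per_group = tbl.groupby("group")["subject_id"].nunique()
    if (per_group < 2).any():
        raise InvalidDesignError("every group needs >= 2 subjects")


def mixed_anova(tbl: pd.DataFrame, measure: str) -> list[AnovaResult]:
    """Mixed ANOVA: group (between) x condition (within) for one measure."""
    _validate_table(tbl, measure)
    import pingouin as pg
    aov = pg.mixed_anova(data=tbl, dv=measure, within="condition",
                         between="group", subject="subject_id")
    name_map = {"group": "group", "condition": "condition",
                "Interaction": "group x condition"}
    out = []
    for _, row in aov.iterrows():
        out.append(AnovaResult(
            effect=name_map.get(row["Source"], row["Source"]),
            F=float(row["F"]),
            df_num=int(row["DF1"]),
            df_den=int(row["DF2"]),
            p=float(row["p_unc"]),
            eta_p2=float(row["np2"]),
        ))
    return out


def bonferroni_posthoc(tbl: pd.DataFrame, measure: str) -> pd.DataFrame:
    """All pairwise group comparisons, Bonferroni-corrected.

    Comparisons use condition-averaged subject means and two-sample t tests;
    raw p values are multiplied by the number of pairs and capped at 1.
    """
    _validate_table(tbl, measure)
    means = (tbl.groupby(["subject_id", "group"], observed=True)[measure]
             .mean().reset_index())
    groups = sorted(means["group"].unique())
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    n_pairs = len(pairs)
    rows = []
    for a, b in pairs:
        xa = means.loc[means["group"] == a, measure].to_numpy()
        xb = means.loc[means["group"] == b, measure].to_numpy()
        if xa.size < 2 or xb.size < 2:
            raise InvalidDesignError("each group needs >= 2 subjects")
        t, p = sps.ttest_ind(xa, xb)
        rows.append({"group_a": a, "group_b": b,
                     "mean_a": xa.mean(), "mean_b": xb.mean(),
                     "t": float(t), "p_unc": float(p),
                     "p_bonf": float(min(1.0, p * n_pairs))})
    return pd.DataFrame(rows)


def regression_table(tbl: pd.DataFrame,
                     predictors: tuple[str, ...] = ("age", "impf"),
                     measures: list[str] | None = None) -> pd.DataFrame:
    """r^2 of each measure (condition-averaged subject means) vs predictors."""
    measures = measures or MEASURES
    means = (tbl.groupby("subject_id", observed=True)
             .agg({m: "mean" for m in measures}
                  | {p: "first" for p in predictors}).reset_index())
    rows = []
    for pred in predictors:
        for m in measures:
            sub = means[[pred, m]].dropna()
            if sub[pred].nunique() < 2 or len(sub) < 3:
                r2 = float("nan")
            else:
                r2 = regress_r2(sub[pred].to_numpy(), sub[m].to_numpy())
            rows.append({"predictor": pred, "measure": m, "r2": r2})
    return pd.DataFrame(rows)
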