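"""Median + MAD thresholding of SL matrices, SL_MEAN, and subject-level QC.

An average SL matrix is reduced to a sparse functional network by keeping
only values strictly above Median + 1 * MAD of its own off-diagonal value
distribution (SL value distributions are heavily skewed, so a robust
location/scale rule is used instead of mean/SD).  Two quality conditions
decide subject inclusion: the thresholded networks must be independent of
inter-sensor Euclidean distance (r^2 < 0.1 against M_Eu, guarding against
spatial-proximity/volume-conduction bias), and the rest and prehension
networks must carry the same number of edges so their graph metrics are
comparable at fixed average degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (DegenerateDistributionError, EmptyNetworkError,
                     UndefinedR2Error)
from .simulate import SensorArray
from .sl import SLMatrix

__all__ = [
    "ThresholdedSL",
    "SubjectQC",
    "mad_threshold",
    "sl_mean",
    "distance_bias_r2",
    "subject_qc",
]

#: maximum r^2 between SL_MAD and M_Eu for a subject to be retained
R2_MAX = 0.1


@dataclass
class ThresholdedSL:
    """SL matrix after Median + 1*MAD thresholding (SL_MAD)."""

    values: np.ndarray      # symmetric, zero diagonal, subthreshold -> 0
    threshold: float        # Median + 1*MAD of the source distribution
    n_retained: int         # nonzero entries over the full matrix (Eq. N)
    edge_count: int         # nonzero entries over the upper triangle

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class SubjectQC:
    """Inclusion record for one subject."""

    subject_id: str
    r2_rest: float
    r2_prehension: float
    degree_rest: int
    degree_prehension: int
    included: bool


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mad_threshold(sl: SLMatrix) -> ThresholdedSL:
    """Keep SL values strictly above Median + 1*MAD of the distribution.

    The distribution is the upper-triangle off-diagonal values (each
    symmetric pair counted once, structural zero diagonal excluded).
    """
    vals = sl.values
    upper = _upper(vals)
    if np.unique(upper).size < 2:
        raise DegenerateDistributionError(
            "need at least two distinct off-diagonal SL values")
    med = float(np.median(upper))
    mad = float(np.median(np.abs(upper - med)))
    if mad == 0.0:
        raise DegenerateDistributionError("MAD of the SL distribution is zero")
    thr = med + mad
    kept = np.where(vals > thr, vals, 0.0)
    np.fill_diagonal(kept, 0.0)
    edge_count = int(np.count_nonzero(_upper(kept)))
    if edge_count == 0:
        raise EmptyNetworkError("no SL value exceeds Median + 1*MAD")
    return ThresholdedSL(values=kept, threshold=thr,
                         n_retained=2 * edge_count, edge_count=edge_count)


def sl_mean(t: ThresholdedSL) -> float:
    """Mean of the nonzero SL_MAD values (overall connection likelihood)."""
    nz = _upper(t.values)
    nz = nz[nz != 0]
    if nz.size == 0:
        raise EmptyNetworkError("SL_MEAN undefined on an empty network")
    return float(nz.mean())


def distance_bias_r2(t: ThresholdedSL, arr: SensorArray) -> float:
    """r^2 between the SL_MAD entries and Euclidean inter-sensor distances.

    Computed over all upper-triangle channel pairs with sub-threshold (zeroed)
    entries included, so short-distance inflation of suprathreshold SL shows
    up as distance dependence of the full network pattern.
    """
    if t.values.shape[0] != arr.n_channels:
        raise ValueError("SL matrix and sensor array dimensions differ")
    x = _upper(arr.m_eu)
    y = _upper(t.values)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedR2Error("zero variance makes r^2 undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


def subject_qc(rest: ThresholdedSL, preh: ThresholdedSL, arr: SensorArray,
               subject_id: str = "", r2_max: float = R2_MAX,
               require_equal_degree: bool = True) -> SubjectQC:
    """Apply the two inclusion conditions to one subject.

    Included iff both r^2 values are below ``r2_max`` and (when
    ``require_equal_degree``) the rest and prehension edge counts are equal.
    """
    if rest.values.shape != preh.values.shape:
        raise ValueError("rest and prehension matrices differ in shape")
    r2_rest = distance_bias_r2(rest, arr)
    r2_preh = distance_bias_r2(preh, arr)
    included = r2_rest < r2_max and r2_preh < r2_max
    if require_equal_degree:
        included = included and (rest.edge_count == preh.edge_count)
    return SubjectQC(subject_id=subject_id, r2_rest=r2_rest,
                     r2_prehension=r2_preh, degree_rest=rest.edge_count,
                     degree_prehension=preh.edge_count, included=included)
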