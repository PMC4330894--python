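"""Filtering, IC re-projection, individual mu-band selection and epoching.

All filtering is zero-phase (forward-reverse) Butterworth applied to the
continuous record; epochs are always cut *after* filtering so filter
transients never sit at epoch edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import EmptyEpochsError

__all__ = [
    "BandSpec",
    "EpochSet",
    "bandpass_array",
    "bandpass",
    "select_band",
    "reproject_ics",
    "extract_epochs",
]

#: wideband pre-filter applied to raw recordings, Hz
WIDEBAND = (0.5, 40.0)
#: number of independent components budgeted in the (external) decomposition
N_ICS = 20


@dataclass(frozen=True)
class BandSpec:
    """Individual mu band: impf - 2 Hz to impf + 2 Hz, low edge clamped."""

    impf: float
    low: float
    high: float


@dataclass
class EpochSet:
    """Band-limited fixed-length signal segments for one condition."""

    condition: str
    epochs: np.ndarray          # (n_epochs, n_channels, n_samples)
    starts: np.ndarray          # sample index of each epoch start

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def bandpass_array(data: np.ndarray, fs: float, low: float, high: float,
                   order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    if not 0.0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= fs / 2.0:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {fs / 2} Hz")
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, data, axis=-1)


def bandpass(rec, low: float = WIDEBAND[0], high: float = WIDEBAND[1],
             order: int = 3):
    """Zero-phase Butterworth band-pass of a Recording (default 0.5-40 Hz)."""
    from .simulate import Recording
    data = bandpass_array(rec.data, rec.fs, low, high, order=order)
    return Recording(subject_id=rec.subject_id, fs=rec.fs, data=data,
                     channel_mask=rec.channel_mask.copy())


def select_band(impf: float, offset: float = 2.0,
                floor: float = WIDEBAND[0]) -> BandSpec:
    """Individual mu band (impf - offset, impf + offset), low edge clamped.

    The clamp keeps infant bands (impf as low as ~2.75 Hz) from extending
    below the wideband filter floor.
    """
    if impf <= 0:
        raise ValueError("impf must be > 0")
    low = max(impf - offset, floor)
    high = impf + offset
    return BandSpec(impf=impf, low=low, high=high)


def reproject_ics(mixing: np.ndarray, sources: np.ndarray,
                  retained: list[int], fs: float,
                  subject_id: str = "reprojected"):
    """Reconstruct sensor signals from a subset of independent components.

    ``mixing`` is channels x ICs, ``sources`` ICs x samples; only the
    ``retained`` component indices contribute.  Component selection itself
    (topography and spectral inspection) happens outside the pipeline.
    """
    from .simulate import Recording
    mixing = np.asarray(mixing, dtype=float)
    sources = np.asarray(sources, dtype=float)
    if mixing.shape[1] != sources.shape[0]:
        raise ValueError("mixing columns must match source rows")
    retained = list(retained)
    if not retained:
        raise ValueError("retained IC list must not be empty")
    if min(retained) < 0 or max(retained) >= mixing.shape[1]:
        raise ValueError("retained IC index out of range")
    data = mixing[:, retained] @ sources[retained, :]
    return Recording(subject_id=subject_id, fs=fs, data=data)


def _rest_intervals(n_samples: int, fs: float, onsets: np.ndarray,
                    margin_s: float) -> list[tuple[int, int]]:
    """Sample intervals in which every sample is >= margin_s from all onsets."""
    if onsets.size == 0:
        return [(0, n_samples)]
    keep: list[tuple[int, int]] = []
    cursor = 0
    for onset in np.sort(onsets):
        a = int(np.ceil((onset - margin_s) * fs))
        b = int(np.floor((onset + margin_s) * fs)) + 1
        if a > cursor:
            keep.append((cursor, min(a, n_samples)))
        cursor = max(cursor, b)
    if cursor < n_samples:
        keep.append((cursor, n_samples))
    return [(a, b) for a, b in keep if b > a]


def extract_epochs(rec, events, condition: str, epoch_s: float = 4.0,
                   pre_onset_s: float = 1.0,
                   rest_margin_s: float = 5.0) -> EpochSet:
    """Cut fixed-length epochs for one condition.

    prehension: one epoch per onset, spanning [onset - pre_onset_s,
    onset - pre_onset_s + epoch_s); epochs overlapping a previous one or the
    record edges are discarded.

    rest: non-overlapping epochs tiled over every stretch of the record whose
    samples all lie at least ``rest_margin_s`` from every movement onset.
    """
    n_len = round(epoch_s * rec.fs)
    n_samples = rec.n_samples
    starts: list[int] = []
    if condition == "prehension":
        last_end = -1
        for onset in events.onset:
            a = round((onset - pre_onset_s) * rec.fs)
            if a < 0 or a + n_len > n_samples or a < last_end:
                continue
            starts.append(a)
            last_end = a + n_len
    elif condition == "rest":
        for a, b in _rest_intervals(n_samples, rec.fs, events.onset,
                                    rest_margin_s):
            s = a
            while s + n_len <= b:
                starts.append(s)
                s += n_len
    else:
        raise ValueError(f"unknown condition {condition!r}")

    if not starts:
        raise EmptyEpochsError(
            f"no complete {condition} epoch in {rec.subject_id}")
    starts_arr = np.asarray(starts, dtype=int)
    epochs = np.stack([rec.data[:, s:s + n_len] for s in starts_arr])
    return EpochSet(condition=condition, epochs=epochs, starts=starts_arr)
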