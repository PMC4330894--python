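"""Synthetic multichannel MEG-like cohort generator.

Emulates hemispheric sensor-array recordings of the sensorimotor cortex:
narrowband mu-like oscillations with a controllable pairwise coupling
structure, broadband noise, and event-locked mu-amplitude suppression
(event-related desynchronization) around movement onsets.  Every downstream
stage of the pipeline is testable against these signals because the coupling
structure, band content and suppression factor are known exactly.

The oscillation model: each channel's mu component is a unit-variance
narrowband Gaussian process (white noise band-passed at impf +/- 1 Hz).
Pairwise coupling is realized by Cholesky mixing of independent narrowband
sources so that the mu-band correlation between channels k and q equals
``coupling[k, q]`` exactly in expectation.  Broadband white noise of scale
``noise_sd`` is added on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .preprocess import bandpass_array

__all__ = [
    "SensorArray",
    "SimSpec",
    "Recording",
    "EventTable",
    "SubjectMeta",
    "make_sensor_array",
    "simulate_subject",
    "simulate_cohort",
    "modular_coupling",
    "uniform_coupling",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class SensorArray:
    """Sensor labels, 3-D positions (mm) and inter-sensor distance matrix."""

    sensor_id: list[str]
    position: np.ndarray        # (n, 3) mm
    m_eu: np.ndarray            # (n, n) symmetric Euclidean distances, mm

    @property
    def n_channels(self) -> int:
        return len(self.sensor_id)

    @classmethod
    def from_positions(cls, position: np.ndarray,
                       sensor_id: list[str] | None = None) -> "SensorArray":
        position = np.asarray(position, dtype=float)
        if sensor_id is None:
            sensor_id = [f"MEG{i:03d}" for i in range(len(position))]
        m_eu = squareform(pdist(position))
        return cls(sensor_id=list(sensor_id), position=position, m_eu=m_eu)


@dataclass
class SimSpec:
    """Parameters of one simulated subject recording."""

    n_channels: int = 76
    spacing: float = 13.0       # mm, target nearest-neighbor pitch
    fs: float = 500.0           # Hz
    duration: float = 120.0     # s
    impf: float = 9.5           # Hz, individual mu peak frequency
    coupling: np.ndarray | None = None   # (n, n) in [0, 1), zero diagonal
    suppression: float = 1.0    # multiplicative mu amplitude factor in events
    noise_sd: float = 0.3       # broadband noise scale (mu component has sd 1)
    n_events: int = 5
    seed: int = 0
    subject_id: str | None = None
    age: float = float("nan")   # nominal age, unit chosen by the caller

    def validate(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.fs <= 0 or self.duration <= 0 or self.n_events < 0:
            raise ValueError("fs, duration must be > 0 and n_events >= 0")
        if not 0.0 <= self.suppression <= 1.0:
            raise ValueError("suppression must lie in [0, 1]")
        if self.impf <= 1.0:
            raise ValueError("impf must exceed 1 Hz (band is impf +/- 1 Hz)")
        if self.coupling is not None:
            c = np.asarray(self.coupling, dtype=float)
            if c.shape != (self.n_channels, self.n_channels):
                raise ValueError("coupling shape must be (n_channels, n_channels)")
            if not np.allclose(c, c.T):
                raise ValueError("coupling must be symmetric")
            if np.any(np.diag(c) != 0):
                raise ValueError("coupling diagonal must be zero")
            if np.any(c < 0) or np.any(c >= 1):
                raise ValueError("coupling entries must lie in [0, 1)")
            if np.linalg.eigvalsh(c + np.eye(self.n_channels)).min() < -1e-10:
                raise ValueError("coupling + I must be positive semidefinite")


@dataclass
class Recording:
    """One subject's multichannel recording (field units, arbitrary scale)."""

    subject_id: str
    fs: float
    data: np.ndarray            # (n_channels, n_samples)
    channel_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.channel_mask is None:
            self.channel_mask = np.ones(self.data.shape[0], dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EventTable:
    """Movement-onset times (s) with condition labels."""

    onset: np.ndarray           # strictly increasing, seconds
    condition: list[str]

    def __post_init__(self):
        self.onset = np.asarray(self.onset, dtype=float)
        if self.onset.size and np.any(np.diff(self.onset) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if len(self.condition) != self.onset.size:
            raise ValueError("condition label per onset required")


@dataclass
class SubjectMeta:
    subject_id: str
    group: str
    age: float
    impf: float
    seed: int


def make_sensor_array(n_channels: int = 76, spacing: float = 13.0,
                      seed: int = 0, cap_radius: float = 75.0) -> SensorArray:
    """Lay sensors on a spherical-cap patch with a target center-to-center pitch.

    Positions come from a Fibonacci lattice on a cap of a ``cap_radius`` mm
    sphere, sized so hexagonal packing of ``n_channels`` sensors yields the
    requested ``spacing``; a small seeded tangential jitter breaks the exact
    lattice symmetry and the whole patch is rescaled so the median
    nearest-neighbor distance equals ``spacing`` exactly.
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    rng = np.random.default_rng(seed)
    if n_channels == 2:
        position = np.array([[0.0, 0.0, cap_radius],
                             [spacing, 0.0, cap_radius]])
        return SensorArray.from_positions(position)

    # hexagonal packing: area per sensor = (sqrt(3)/2) d^2 on the cap surface
    cos_theta = 1.0 - n_channels * np.sqrt(3.0) * spacing**2 / (4.0 * np.pi * cap_radius**2)
    cos_theta = max(cos_theta, 0.0)      # never below the equator
    frac = np.arange(n_channels, dtype=float) + 0.5
    z = cap_radius * (1.0 - (1.0 - cos_theta) * frac / n_channels)
    rho = np.sqrt(np.maximum(cap_radius**2 - z**2, 0.0))
    phi = _GOLDEN_ANGLE * np.arange(n_channels)
    position = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    position += rng.normal(scale=0.02 * spacing, size=position.shape)

    d = squareform(pdist(position))
    np.fill_diagonal(d, np.inf)
    median_nn = np.median(d.min(axis=1))
    position *= spacing / median_nn
    return SensorArray.from_positions(position)


def _narrowband(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, impf: float) -> np.ndarray:
    """Independent unit-variance narrowband Gaussian processes at impf +/- 1 Hz."""
    low = max(impf - 1.0, 0.1)
    x = bandpass_array(rng.standard_normal((n_channels, n_samples)),
                       fs, low, impf + 1.0, order=3)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def event_onsets(spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    """Deterministic prehension-onset layout: rest block first, events after.

    Onsets occupy the second half of the record, 6 s apart (prehension epochs
    span [onset - 1 s, onset + 3 s), so 6 s guarantees non-overlap), leaving
    the first half as uninterrupted rest from which rest epochs are tiled.
    """
    if spec.n_events == 0:
        return np.empty(0)
    t0 = spec.duration / 2.0
    needed = t0 + 6.0 * spec.n_events + 4.0
    if needed > spec.duration:
        raise ValueError(
            f"{spec.n_events} events at 6 s pitch do not fit in "
            f"{spec.duration} s (need >= {needed:.0f} s)")
    onsets = t0 + 6.0 * np.arange(spec.n_events) + 2.0
    onsets = onsets + rng.uniform(-0.3, 0.3, size=spec.n_events)
    return onsets


def simulate_subject(spec: SimSpec) -> tuple[Recording, EventTable]:
    """Generate one subject: coupled narrowband mu + noise + event-locked ERD.

    The mu-band amplitude of every channel is multiplied by
    ``spec.suppression`` during the 3 s following each movement onset,
    emulating movement-related mu desynchronization.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_samples = round(spec.fs * spec.duration)

    onsets = event_onsets(spec, rng)

    mu = _narrowband(rng, spec.n_channels, n_samples, spec.fs, spec.impf)
    if spec.coupling is not None:
        chol = np.linalg.cholesky(
            np.asarray(spec.coupling, dtype=float) + np.eye(spec.n_channels))
        mu = chol @ mu
        # re-standardize so every channel's mu component has unit variance
        mu /= np.sqrt(np.maximum(np.diag(chol @ chol.T), 1e-12))[:, None]

    for onset in onsets:
        a = round(onset * spec.fs)
        b = min(round((onset + 3.0) * spec.fs), n_samples)
        mu[:, a:b] *= spec.suppression

    data = mu + spec.noise_sd * rng.standard_normal((spec.n_channels, n_samples))
    subject_id = spec.subject_id or f"sub-{spec.seed}"
    rec = Recording(subject_id=subject_id, fs=spec.fs, data=data)
    events = EventTable(onset=onsets, condition=["prehension"] * len(onsets))
    return rec, events


def simulate_cohort(
    specs: list[tuple[str, SimSpec]],
) -> list[tuple[SubjectMeta, Recording, EventTable]]:
    """Simulate one subject per (group label, SimSpec) pair.

    Seeds must be distinct across specs so subjects are independent; subject
    ids default to ``<group>-<index within group>``.
    """
    if not specs:
        raise ValueError("at least one (group, SimSpec) pair is required")
    seeds = [s.seed for _, s in specs]
    if len(set(seeds)) != len(seeds):
        raise ValueError("specs must carry distinct seeds")

    out = []
    seen_ids: set[str] = set()
    per_group_count: dict[str, int] = {}
    for group, spec in specs:
        if spec.subject_id is None:
            k = per_group_count.get(group, 0) + 1
            per_group_count[group] = k
            spec.subject_id = f"{group}-{k:02d}"
        if spec.subject_id in seen_ids:
            raise ValueError(f"duplicate subject_id {spec.subject_id!r}")
        seen_ids.add(spec.subject_id)
        rec, events = simulate_subject(spec)
        meta = SubjectMeta(subject_id=spec.subject_id, group=group,
                           age=spec.age, impf=spec.impf, seed=spec.seed)
        out.append((meta, rec, events))
    return out


def uniform_coupling(n_channels: int, strength: float) -> np.ndarray:
    """Equicorrelated coupling: every channel pair shares fraction ``strength``."""
    c = np.full((n_channels, n_channels), float(strength))
    np.fill_diagonal(c, 0.0)
    return c


def modular_coupling(n_channels: int, n_modules: int, module_size: int,
                     within: float, between: float = 0.0) -> np.ndarray:
    """Block-modular coupling: ``n_modules`` contiguous blocks of
    ``module_size`` channels coupled at ``within``; all other pairs at
    ``between``; leftover channels stay at ``between``."""
    if n_modules * module_size > n_channels:
        raise ValueError("modules do not fit in n_channels")
    c = np.full((n_channels, n_channels), float(between))
    for m in range(n_modules):
        a, b = m * module_size, (m + 1) * module_size
        c[a:b, a:b] = within
    np.fill_diagonal(c, 0.0)
    eig_min = np.linalg.eigvalsh(c + np.eye(n_channels)).min()
    if eig_min < -1e-10:
        warnings.warn("modular coupling is not PSD; reduce strengths")
    return c
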