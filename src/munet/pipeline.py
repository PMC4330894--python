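"""Stage orchestration: simulate -> preprocess -> connectivity -> netmap ->
metrics -> group-stats, driven by one config, with deterministic seeding.

Each stage reads its predecessor's artifacts from the output directory and
writes its own, so stages can be re-run individually (and are exposed as CLI
verbs); `run_all` chains them and writes a manifest.  Re-running with the
same config reproduces every artifact byte-identically: all randomness flows
from the global seed through per-subject seeds, and no artifact embeds
timestamps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .model import AnalysisParams
from .preprocess import extract_epochs, bandpass, select_band
from .simulate import (EventTable, Recording, SimSpec, SubjectMeta,
                       make_sensor_array, modular_coupling, simulate_cohort,
                       uniform_coupling)
from .sl import choose_sl_params, sl_condition, SLMatrix
from .threshold import mad_threshold, sl_mean, subject_qc, ThresholdedSL
from .graphs import compute_all
from .stats import MEASURES, bonferroni_posthoc, mixed_anova, regression_table

__all__ = ["GroupSpec", "PipelineConfig", "run_all",
           "stage_simulate", "stage_preprocess", "stage_connectivity",
           "stage_netmap", "stage_metrics", "stage_group_stats"]


@dataclass
class GroupSpec:
    """One age group of the simulated cohort."""

    name: str
    n_subjects: int
    impf: float                 # Hz, individual mu peak frequency
    age: float = float("nan")
    suppression: float = 0.7    # mu amplitude factor during prehension
    coupling: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_channels: int = 76
    spacing: float = 13.0       # mm
    fs: float = 500.0           # Hz
    duration: float = 120.0     # s
    n_events: int = 5
    noise_sd: float = 0.3
    groups: list[GroupSpec] = field(default_factory=list)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        groups = [GroupSpec(**g) for g in raw.pop("groups", [])]
        analysis = AnalysisParams(**raw.pop("analysis", {}))
        return cls(groups=groups, analysis=analysis, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        with open(path, "w") as f:
            yaml.safe_dump(raw, f, sort_keys=False)


def build_coupling(spec: dict, n_channels: int) -> np.ndarray | None:
    """Coupling matrix from a config mapping: kind none|uniform|modular."""
    kind = spec.get("kind", "none")
    if kind == "none":
        return None
    if kind == "uniform":
        return uniform_coupling(n_channels, spec["strength"])
    if kind == "modular":
        return modular_coupling(n_channels, spec["n_modules"],
                                spec["module_size"], spec["within"],
                                spec.get("between", 0.0))
    raise ValueError(f"unknown coupling kind {kind!r}")


def subject_seed(global_seed: int, index: int) -> int:
    """Per-subject seed derived from the global seed, kept below 2**31."""
    return (global_seed * 100003 + 7919 * index + 1) % (2**31)


def cohort_specs(cfg: PipelineConfig) -> list[tuple[str, SimSpec]]:
    specs = []
    idx = 0
    for g in cfg.groups:
        coupling = build_coupling(g.coupling, cfg.n_channels)
        for _ in range(g.n_subjects):
            specs.append((g.name, SimSpec(
                n_channels=cfg.n_channels, spacing=cfg.spacing, fs=cfg.fs,
                duration=cfg.duration, impf=g.impf, coupling=coupling,
                suppression=g.suppression, noise_sd=cfg.noise_sd,
                n_events=cfg.n_events, seed=subject_seed(cfg.seed, idx),
                age=g.age)))
            idx += 1
    return specs


# ---------------------------------------------------------------- stages

def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    subjects = simulate_cohort(cohort_specs(cfg))
    arr = make_sensor_array(cfg.n_channels, cfg.spacing, seed=cfg.seed)
    mio.save_layout(arr, out / "layout.csv")
    mio.save_cohort_meta([m for m, _, _ in subjects], out / "cohort.csv")
    mio.save_events({m.subject_id: ev for m, _, ev in subjects},
                    out / "events.csv")
    mio.save_recordings([rec for _, rec, _ in subjects],
                        out / "recordings.h5")


def stage_preprocess(cfg: PipelineConfig, out: Path) -> None:
    """Wideband + individual mu-band filtering and 4-s epoch extraction."""
    import h5py
    p = cfg.analysis
    meta = mio.load_cohort_meta(out / "cohort.csv").set_index("subject_id")
    events = mio.load_events(out / "events.csv")
    recordings = mio.load_recordings(out / "recordings.h5")
    with h5py.File(out / "epochs.h5", "w") as f:
        for sid in meta.index:
            rec = recordings[sid]
            rec = bandpass(rec, p.wide_low, p.wide_high, order=p.filter_order)
            band = select_band(meta.loc[sid, "impf"], offset=p.band_offset,
                               floor=p.wide_low)
            rec = bandpass(rec, band.low, band.high, order=p.filter_order)
            ev = events.get(sid, EventTable(onset=np.empty(0), condition=[]))
            g = f.create_group(sid)
            g.attrs["fs"] = rec.fs
            for condition in ("rest", "prehension"):
                eps = extract_epochs(rec, ev, condition, epoch_s=p.epoch_s,
                                     pre_onset_s=p.pre_onset_s,
                                     rest_margin_s=p.rest_margin_s)
                g.create_dataset(condition, data=eps.epochs,
                                 compression="gzip")


def stage_connectivity(cfg: PipelineConfig, out: Path) -> None:
    """Per-epoch SL within the individual mu band, averaged per condition."""
    import h5py
    p = cfg.analysis
    meta = mio.load_cohort_meta(out / "cohort.csv").set_index("subject_id")
    layout = mio.load_layout(out / "layout.csv")
    sl_dir = out / "sl"
    sl_dir.mkdir(exist_ok=True)
    with h5py.File(out / "epochs.h5", "r") as f:
        for sid in meta.index:
            fs = float(f[sid].attrs["fs"])
            band = select_band(meta.loc[sid, "impf"], offset=p.band_offset,
                               floor=p.wide_low)
            for condition in ("rest", "prehension"):
                epochs = f[sid][condition][()]
                params = choose_sl_params(band, fs, epochs.shape[-1],
                                          p_ref=p.p_ref)
                mat = sl_condition(epochs, params, ref_stride=p.ref_stride)
                mio.save_matrix(mat.values, layout.sensor_id,
                                sl_dir / f"{sid}_{condition}.csv")


def stage_netmap(cfg: PipelineConfig, out: Path) -> None:
    """Median+MAD thresholding, distance-bias r^2 and degree QC."""
    p = cfg.analysis
    meta = mio.load_cohort_meta(out / "cohort.csv")
    layout = mio.load_layout(out / "layout.csv")
    mad_dir = out / "slmad"
    mad_dir.mkdir(exist_ok=True)
    rows = []
    for sid in meta["subject_id"]:
        thr = {}
        for condition in ("rest", "prehension"):
            values, ids = mio.load_matrix(out / "sl" / f"{sid}_{condition}.csv")
            thr[condition] = mad_threshold(SLMatrix(values=values))
            mio.save_matrix(thr[condition].values, ids,
                            mad_dir / f"{sid}_{condition}.csv")
        qc = subject_qc(thr["rest"], thr["prehension"], layout,
                        subject_id=sid, r2_max=p.r2_max,
                        require_equal_degree=p.require_equal_degree)
        rows.append({"subject_id": sid, "r2_rest": qc.r2_rest,
                     "r2_prehension": qc.r2_prehension,
                     "edges_rest": qc.degree_rest,
                     "edges_prehension": qc.degree_prehension,
                     "included": qc.included})
    pd.DataFrame(rows).to_csv(out / "qc.csv", index=False)


def stage_metrics(cfg: PipelineConfig, out: Path) -> None:
    """Segregation/integration measures for every included subject."""
    meta = mio.load_cohort_meta(out / "cohort.csv").set_index("subject_id")
    qc = pd.read_csv(out / "qc.csv", dtype={"subject_id": str})
    rows = []
    for _, q in qc.iterrows():
        if not q["included"]:
            continue
        sid = q["subject_id"]
        rest, _ = mio.load_matrix(out / "slmad" / f"{sid}_rest.csv")
        preh, _ = mio.load_matrix(out / "slmad" / f"{sid}_prehension.csv")
        m_rest, m_preh = compute_all(
            _as_thresholded(rest), _as_thresholded(preh))
        for condition, m in (("rest", m_rest), ("prehension", m_preh)):
            rows.append({"subject_id": sid, "group": meta.loc[sid, "group"],
                         "age": meta.loc[sid, "age"],
                         "impf": meta.loc[sid, "impf"],
                         "condition": condition, **m.as_dict()})
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)


def _as_thresholded(values: np.ndarray) -> ThresholdedSL:
    iu = np.triu_indices(values.shape[0], k=1)
    edge_count = int(np.count_nonzero(values[iu]))
    nz = values[iu][values[iu] > 0]
    thr = float(nz.min()) if nz.size else 0.0
    return ThresholdedSL(values=values, threshold=thr,
                         n_retained=2 * edge_count, edge_count=edge_count)


def stage_group_stats(cfg: PipelineConfig, out: Path) -> None:
    """Mixed ANOVA, Bonferroni post-hoc and age/impf regressions per measure."""
    tbl = pd.read_csv(out / "metrics.csv", dtype={"subject_id": str,
                                                  "group": str})
    anova_rows, posthoc_frames = [], []
    for m in MEASURES:
        for res in mixed_anova(tbl, m):
            anova_rows.append({"measure": m, "effect": res.effect,
                               "F": res.F, "df_num": res.df_num,
                               "df_den": res.df_den, "p": res.p,
                               "eta_p2": res.eta_p2})
        ph = bonferroni_posthoc(tbl, m)
        ph.insert(0, "measure", m)
        posthoc_frames.append(ph)
    pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)
    pd.concat(posthoc_frames).to_csv(out / "posthoc.csv", index=False)
    regression_table(tbl).to_csv(out / "regression.csv", index=False)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: PipelineConfig, out: str | Path) -> Path:
    """Run every stage and write a run manifest; returns the output dir."""
    out = Path(out)
    stage_simulate(cfg, out)
    stage_preprocess(cfg, out)
    stage_connectivity(cfg, out)
    stage_netmap(cfg, out)
    stage_metrics(cfg, out)
    stage_group_stats(cfg, out)

    qc = pd.read_csv(out / "qc.csv")
    manifest = {
        "seed": cfg.seed,
        "n_subjects_simulated": int(len(qc)),
        "n_subjects_included": int(qc["included"].sum()),
        "analysis": asdict(cfg.analysis),
        "metrics_sha256": _file_hash(out / "metrics.csv"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
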