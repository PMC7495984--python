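"""Orchestration: simulate -> preprocess -> GC/coherence -> trajectories ->
selection, with a round-trippable config, a manifest, and summary reports.

A run directory contains the config echo, a manifest with seeds, exclusion
accounting and output checksums (re-running with the same config and seed
reproduces all numeric outputs bit-for-bit), the aligned group curves (HDF5),
tidy TSV exports and, from :func:`report`, median/IQR tables and basic plots.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .coherence import coherence_over_session
from .granger import DEFAULT_FREQS, DEFAULT_ORDER, gc_over_session
from .preprocessing import preprocess
from .recording import Recording
from .selection import select_coherence_pairs, select_gc_pairs
from .synthetic import default_session_plan, simulate_session
from .trajectories import (BANDS, align_logmean, median_iqr_at,
                           subject_band_trajectories)

__all__ = ["RunConfig", "run_pipeline", "report", "load_config"]

logger = logging.getLogger(__name__)

EVENTS = ("LOBR", "ROBR")


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the analysis' stated values."""

    n_subjects: int = 16
    session_duration: str = "short"      # 'short' (20 min) or 'full' (2 h)
    seed: int = 0
    sample_rate: float = 250.0           # simulator native rate
    target_rate: float = 125.0
    model_order: int = DEFAULT_ORDER
    freqs: tuple = tuple(DEFAULT_FREQS.tolist())
    bands: tuple = tuple(BANDS)
    smoothing_bandwidth_s: float = 50.0
    normalization_scope: str = "pair"    # 'pair' or 'subject'
    selection_quantile: float = 0.05
    min_common_categories: int = 3
    window_seconds: float = 900.0
    compute_coherence: bool = True
    coupling_weight: float = 0.45
    artifact_rate: float = 0.5
    save_tensors: bool = False
    write_sessions: bool = False
    input_sessions: tuple = ()           # optional: paths to real sessions
    out_dir: str = "eeggc_run"

    def __post_init__(self):
        unknown = set(self.bands) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown band names: {sorted(unknown)}")
        if self.normalization_scope not in ("pair", "subject"):
            raise ValueError("normalization_scope must be 'pair' or 'subject'")
        if not 0 < self.selection_quantile < 0.5:
            raise ValueError("selection_quantile must be in (0, 0.5)")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("freqs", "bands", "input_sessions"):
            if key in data and data[key] is not None:
                data[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in data[key]
                )
        return cls(**data)


def load_config(path) -> RunConfig:
    return RunConfig.from_yaml(path)


@dataclass
class SubjectResult:
    subject: str
    events: dict
    truth: dict
    gc_trajectories: dict
    coh_trajectories: dict
    stats: dict
    gc_tensor: object = None
    coh_tensor: object = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def process_subject(recording: Recording, config: RunConfig,
                    truth: dict | None = None) -> SubjectResult:
    """Preprocess one recording and compute its band trajectories."""
    filtered, grid = preprocess(recording, target_rate=config.target_rate)
    freqs = np.asarray(config.freqs, dtype=float)
    gc = gc_over_session(grid, order=config.model_order, freqs=freqs)
    ev = recording.events
    gc_trajs = subject_band_trajectories(
        gc, recording.subject, "gc", infusion_start=ev.infusion_start,
        bands=config.bands, bandwidth=config.smoothing_bandwidth_s,
        normalization_scope=config.normalization_scope,
        events=ev.to_dict(),
    )
    coh_trajs = {}
    coh = None
    if config.compute_coherence:
        coh = coherence_over_session(filtered, freqs=freqs)
        coh_trajs = subject_band_trajectories(
            coh, recording.subject, "coherence", bands=config.bands,
            bandwidth=config.smoothing_bandwidth_s, events=ev.to_dict(),
        )
    stats = {
        "n_segments": int(grid.n_segments),
        "n_rejected_blocks": int((~grid.valid).sum()),
        **{k: v for k, v in gc.stats.items()},
    }
    return SubjectResult(
        subject=recording.subject, events=ev.to_dict(), truth=truth or {},
        gc_trajectories=gc_trajs, coh_trajectories=coh_trajs, stats=stats,
        gc_tensor=gc if config.save_tensors else None,
        coh_tensor=coh if config.save_tensors else None,
    )


def _simulated_recordings(config: RunConfig, plan_factory=None):
    root = np.random.SeedSequence(config.seed)
    for i, child in enumerate(root.spawn(config.n_subjects)):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        if plan_factory is None:
            plan = default_session_plan(
                seed=sub_seed, duration=config.session_duration,
                coupling_weight=config.coupling_weight,
                artifact_rate=config.artifact_rate,
                sample_rate=config.sample_rate,
            )
        else:
            plan = plan_factory(sub_seed)
        rec, truth = simulate_session(plan)
        rec.subject = f"S{i:02d}"
        yield rec, truth


def aligned_groups(results: list[SubjectResult], metric: str, config: RunConfig
                   ) -> dict[tuple[str, str], object]:
    """Aligned log-mean group curves for every (band, event) combination."""
    groups = {}
    attr = "gc_trajectories" if metric == "gc" else "coh_trajectories"
    for band in config.bands:
        trajs = [getattr(r, attr)[band] for r in results if getattr(r, attr)]
        for event in EVENTS:
            key = event.lower()
            times = [r.events.get(key) for r in results if getattr(r, attr)]
            if not trajs or all(t is None for t in times):
                continue
            groups[(band, event)] = align_logmean(
                trajs, times, event, window_seconds=config.window_seconds,
            )
    return groups


def run_group_study(config: RunConfig, plan_factory=None) -> dict:
    """Simulate and analyze a multi-subject study entirely in memory.

    Returns subject results, the aligned group curves per metric, the pair
    selections, and the per-subject ground truth — the programmatic
    counterpart of :func:`run_pipeline` for benchmarking and testing.
    ``plan_factory`` (seed -> SessionPlan) overrides the default study design.
    """
    results = []
    truths = []
    for rec, truth in _simulated_recordings(config, plan_factory):
        results.append(process_subject(rec, config, truth))
        truths.append(truth)
    gc_groups = aligned_groups(results, "gc", config)
    coh_groups = (aligned_groups(results, "coherence", config)
                  if config.compute_coherence else {})
    selections = {}
    needed = (("delta", "LOBR"), ("delta", "ROBR"),
              ("alpha", "LOBR"), ("alpha", "ROBR"))
    if all(k in gc_groups for k in needed):
        top, bottom = select_gc_pairs(
            gc_groups, quantile=config.selection_quantile,
            min_common=config.min_common_categories,
        )
        selections["gc_top"] = top
        selections["gc_bottom"] = bottom
    for band in config.bands:
        if (band, "LOBR") in coh_groups and (band, "ROBR") in coh_groups:
            inc, dec = select_coherence_pairs(
                coh_groups, band, quantile=config.selection_quantile,
            )
            selections[f"coh_{band}_increase"] = inc
            selections[f"coh_{band}_decrease"] = dec
    return {"results": results, "truths": truths, "gc_groups": gc_groups,
            "coh_groups": coh_groups, "selections": selections}


def run_pipeline(config: RunConfig, out_dir=None) -> Path:
    """Run every stage and write a self-describing run directory."""
    t_start = time.time()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"stages": {}, "subjects": {}, "seed": config.seed}

    results: list[SubjectResult] = []
    failed_stage = None
    try:
        t0 = time.time()
        if config.input_sessions:
            recordings = list(_load_input_sessions(config))
        else:
            recordings = list(_simulated_recordings(config))
        manifest["stages"]["simulate_or_load"] = round(time.time() - t0, 2)

        if config.write_sessions:
            sess_dir = out / "subjects"
            for rec, truth in recordings:
                d = sess_dir / rec.subject
                d.mkdir(parents=True, exist_ok=True)
                eio.write_recording_csv(rec, d / "session.csv")
                eio.write_events_json(rec.events, d / "events.json")
                eio.write_ground_truth_json(truth, d / "truth.json")
                rec.montage.to_csv(d / "montage.csv")

        t0 = time.time()
        for rec, truth in recordings:
            res = process_subject(rec, config, truth)
            manifest["subjects"][rec.subject] = res.stats
            if config.save_tensors:
                d = out / "subjects" / rec.subject
                d.mkdir(parents=True, exist_ok=True)
                eio.save_tensor_hdf5(res.gc_tensor, d / "gc.h5")
                if res.coh_tensor is not None:
                    eio.save_tensor_hdf5(res.coh_tensor, d / "coherence.h5")
                res.gc_tensor = res.coh_tensor = None
            results.append(res)
        manifest["stages"]["connectivity"] = round(time.time() - t0, 2)

        t0 = time.time()
        gc_groups = aligned_groups(results, "gc", config)
        coh_groups = (aligned_groups(results, "coherence", config)
                      if config.compute_coherence else {})
        _save_groups(out / "group_curves.h5", gc_groups, coh_groups)
        manifest["stages"]["trajectories"] = round(time.time() - t0, 2)

        t0 = time.time()
        selections = []
        if all((b, e) in gc_groups for b, e in
               (("delta", "LOBR"), ("delta", "ROBR"),
                ("alpha", "LOBR"), ("alpha", "ROBR"))):
            top, bottom = select_gc_pairs(
                gc_groups, quantile=config.selection_quantile,
                min_common=config.min_common_categories,
            )
            selections += [top, bottom]
        for band in config.bands:
            if (band, "LOBR") in coh_groups and (band, "ROBR") in coh_groups:
                inc, dec = select_coherence_pairs(
                    coh_groups, band, quantile=config.selection_quantile,
                )
                selections += [inc, dec]
        eio.selections_tsv(selections, out / "selections.tsv")
        _save_selection_summary(selections, out / "selections.json")
        manifest["stages"]["selection"] = round(time.time() - t0, 2)

        gc_trajs = [t for r in results for t in r.gc_trajectories.values()]
        eio.trajectories_tsv(gc_trajs, out / "trajectories_gc.tsv")
    except Exception as err:  # partial outputs stay; manifest records failure
        failed_stage = f"{type(err).__name__}: {err}"
        raise
    finally:
        manifest["failed"] = failed_stage
        manifest["runtime_s"] = round(time.time() - t_start, 2)
        data_files = sorted(
            p for p in out.rglob("*")
            if p.is_file() and p.suffix in (".tsv", ".json", ".h5", ".csv", ".yaml")
            and p.name != "manifest.json"
        )
        manifest["checksums"] = {
            str(p.relative_to(out)): _sha256(p) for p in data_files
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _load_input_sessions(config: RunConfig):
    from .montage import Montage

    for entry in config.input_sessions:
        entry = dict(entry) if not isinstance(entry, dict) else entry
        montage = Montage.from_csv(entry["montage"])
        events = eio.read_events_json(entry["events"])
        path = entry["session"]
        subject = entry.get("subject", Path(path).stem)
        if str(path).endswith(".edf"):
            rec = eio.read_recording_edf(path, montage, events, subject)
        else:
            rec = eio.read_recording_csv(path, montage,
                                         float(entry["sample_rate"]),
                                         events, subject)
        yield rec, {}


def _save_groups(path, gc_groups, coh_groups) -> None:
    with h5py.File(path, "w") as fh:
        for metric, groups in (("gc", gc_groups), ("coherence", coh_groups)):
            for (band, event), g in groups.items():
                grp = fh.create_group(f"{metric}/{band}/{event}")
                grp.create_dataset("offsets", data=g.offsets)
                grp.create_dataset("curve", data=g.curve)
                grp.create_dataset("n_subjects", data=g.n_subjects)
                grp.attrs["floor_events"] = g.floor_events
                grp.create_dataset(
                    "pairs", data=np.array([[a, b] for a, b in g.pairs], dtype="S16"),
                )


def load_groups(path) -> dict:
    """Read back the aligned group curves written by :func:`run_pipeline`."""
    from .trajectories import AlignedGroupTrajectory

    out: dict = {"gc": {}, "coherence": {}}
    with h5py.File(path, "r") as fh:
        for metric in out:
            if metric not in fh:
                continue
            for band in fh[metric]:
                for event in fh[metric][band]:
                    grp = fh[metric][band][event]
                    pairs = tuple((a.decode(), b.decode())
                                  for a, b in grp["pairs"][()])
                    out[metric][(band, event)] = AlignedGroupTrajectory(
                        event=event, band=band, metric=metric,
                        offsets=grp["offsets"][()], curve=grp["curve"][()],
                        n_subjects=grp["n_subjects"][()], pairs=pairs,
                        floor_events=int(grp.attrs["floor_events"]),
                    )
    return out


def _save_selection_summary(selections, path) -> None:
    summary = [{
        "metric": s.metric, "rule": s.rule, "band": s.band,
        "n_pairs": len(s.pairs),
        "variance_explained": s.variance_explained,
        "categories": list(s.categories_used),
    } for s in selections]
    Path(path).write_text(json.dumps(summary, indent=2))


def report(run_dir, offsets=(-900.0, -120.0, 0.0, 120.0, 900.0),
           make_plots: bool = True) -> pd.DataFrame:
    """Median/IQR tables over pair means at key offsets, plus basic figures.

    Returns (and writes) a tidy table: metric, band, event, offset, median,
    IQR, n_subjects.  Events without data (e.g. a run with no ROBR) are
    simply absent and noted in the report JSON.
    """
    run_dir = Path(run_dir)
    groups_path = run_dir / "group_curves.h5"
    if not groups_path.exists():
        raise FileNotFoundError(f"missing stage output: {groups_path}")
    groups = load_groups(groups_path)
    rows = []
    missing = []
    for metric, gset in groups.items():
        for (band, event), g in gset.items():
            for off in offsets:
                if abs(off) > g.offsets.max():
                    continue
                med, iqr = median_iqr_at(g.curve, g.offsets, off)
                idx = int(np.argmin(np.abs(g.offsets - off)))
                rows.append({"metric": metric, "band": band, "event": event,
                             "offset_s": off, "median": med, "iqr": iqr,
                             "n_subjects": int(g.n_subjects[idx])})
    for metric in ("gc", "coherence"):
        for event in EVENTS:
            if not any(k[1] == event for k in groups.get(metric, {})):
                missing.append(f"{metric}:{event}")
    table = pd.DataFrame(rows)
    table.to_csv(run_dir / "median_iqr.tsv", sep="\t", index=False)
    (run_dir / "report.json").write_text(json.dumps({
        "missing_events": missing, "n_rows": len(table),
    }, indent=2))
    if make_plots and not table.empty:
        _plot_groups(run_dir, groups)
    return table


def _plot_groups(run_dir: Path, groups: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gset = groups.get("gc", {})
    if not gset:
        return
    bands = sorted({b for b, _ in gset})
    fig, axes = plt.subplots(len(EVENTS), len(bands),
                             figsize=(4 * len(bands), 6), squeeze=False)
    for i, event in enumerate(EVENTS):
        for j, band in enumerate(bands):
            ax = axes[i][j]
            g = gset.get((band, event))
            if g is None:
                ax.axis("off")
                continue
            ax.plot(g.offsets / 60, g.curve, color="gray", alpha=0.1, lw=0.5)
            ax.set_yscale("log")
            ax.axvline(0, color="k", ls="--", lw=1)
            ax.set_title(f"{band} {event}")
            ax.set_xlabel("min from event")
            if j == 0:
                ax.set_ylabel("normalized GC")
    fig.tight_layout()
    fig.savefig(run_dir / "gc_trajectories.png", dpi=110)
    plt.close(fig)
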