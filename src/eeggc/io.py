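"""Readers and writers for sessions, events, tensors and exports.

Sessions travel as EDF or as plain CSV (one column per channel, header row of
channel names); events and ground truth as JSON; montages as CSV; connectivity
tensors as HDF5 with TSV band-mean exports.  EDF reading goes through MNE; a
minimal 16-bit EDF writer is provided here.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .coherence import CoherenceTensor
from .granger import GCTensor
from .montage import Montage
from .recording import EventTimeline, Recording
from .trajectories import BANDS, BandTrajectory, band_average

__all__ = [
    "write_recording_csv", "read_recording_csv", "write_recording_edf",
    "read_recording_edf", "write_events_json", "read_events_json",
    "write_ground_truth_json", "read_ground_truth_json",
    "save_tensor_hdf5", "load_tensor_hdf5", "band_means_tsv",
    "trajectories_tsv", "selections_tsv",
]


# ---------------------------------------------------------------------------
# CSV sessions
# ---------------------------------------------------------------------------

def write_recording_csv(recording: Recording, path) -> None:
    df = pd.DataFrame(recording.signal.T, columns=list(recording.montage.names))
    df.to_csv(path, index=False, float_format="%.4f")


def read_recording_csv(path, montage: Montage, sample_rate: float,
                       events: EventTimeline | None = None,
                       subject: str = "S00") -> Recording:
    df = pd.read_csv(path)
    missing = set(montage.names) - set(df.columns)
    if missing:
        raise ValueError(f"CSV lacks montage channels: {sorted(missing)}")
    signal = df[list(montage.names)].to_numpy(float).T
    return Recording(signal=signal, sample_rate=sample_rate, montage=montage,
                     events=events or EventTimeline(), subject=subject)


# ---------------------------------------------------------------------------
# EDF sessions
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(recording: Recording, path) -> None:
    """Write a minimal EDF file (16-bit, 1-s data records).

    The sampling rate must be an integer; the signal is truncated to whole
    1-s records.  Physical scaling is symmetric around zero per channel.
    """
    fs = recording.sample_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    m = recording.n_channels
    n_rec = recording.n_samples // spr
    x = recording.signal[:, : n_rec * spr]
    phys_max = np.maximum(np.abs(x).max(axis=1), 1.0)
    dig_max = 32767
    header = b"".join([
        _edf_field(0, 8),
        _edf_field(recording.subject, 80),
        _edf_field("eeggc synthetic session", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + m), 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field(1, 8),
        _edf_field(m, 4),
    ])
    labels = b"".join(_edf_field(name, 16) for name in recording.montage.names)
    transducer = b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(m))
    dim = b"".join(_edf_field("uV", 8) for _ in range(m))
    pmin = b"".join(_edf_field(f"{-v:.6g}"[:8], 8) for v in phys_max)
    pmax = b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in phys_max)
    dmin = b"".join(_edf_field(-dig_max, 8) for _ in range(m))
    dmax = b"".join(_edf_field(dig_max, 8) for _ in range(m))
    prefilter = b"".join(_edf_field("", 80) for _ in range(m))
    nsamp = b"".join(_edf_field(spr, 8) for _ in range(m))
    reserved = b"".join(_edf_field("", 32) for _ in range(m))
    scale = dig_max / phys_max
    digital = np.round(x * scale[:, None]).astype("<i2")
    records = digital.reshape(m, n_rec, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + dim + pmin + pmax + dmin
                 + dmax + prefilter + nsamp + reserved)
        fh.write(records.tobytes())


def read_recording_edf(path, montage: Montage | None = None,
                       events: EventTimeline | None = None,
                       subject: str = "S00") -> Recording:
    """Read an EDF session via MNE; channel order follows the montage if given."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts
    names = list(raw.ch_names)
    if montage is None:
        coords = np.zeros((len(names), 2))
        montage = Montage(tuple(names), coords) if len(names) >= 4 else None
        if montage is None:
            raise ValueError("montage required for recordings with < 4 channels")
    else:
        order = [names.index(c) for c in montage.names]
        data = data[order]
    return Recording(signal=data, sample_rate=float(raw.info["sfreq"]),
                     montage=montage, events=events or EventTimeline(),
                     subject=subject)


# ---------------------------------------------------------------------------
# JSON sidecars
# ---------------------------------------------------------------------------

def write_events_json(events: EventTimeline, path) -> None:
    Path(path).write_text(json.dumps(events.to_dict(), indent=2))


def read_events_json(path) -> EventTimeline:
    return EventTimeline.from_dict(json.loads(Path(path).read_text()))


def write_ground_truth_json(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=list))


def read_ground_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# HDF5 tensors
# ---------------------------------------------------------------------------

def save_tensor_hdf5(tensor, path) -> None:
    kind = "gc" if isinstance(tensor, GCTensor) else "coherence"
    with h5py.File(path, "w") as fh:
        fh.attrs["kind"] = kind
        fh.attrs["stats"] = json.dumps(tensor.stats)
        fh.create_dataset("values", data=tensor.values, compression="gzip")
        fh.create_dataset("freqs", data=tensor.freqs)
        fh.create_dataset("times", data=tensor.times)
        pairs = np.array([[a, b] for a, b in tensor.pairs], dtype="S16")
        fh.create_dataset("pairs", data=pairs)
        if kind == "gc":
            fh.create_dataset("validity", data=tensor.validity)


def load_tensor_hdf5(path):
    with h5py.File(path, "r") as fh:
        kind = fh.attrs["kind"]
        stats = json.loads(fh.attrs["stats"])
        values = fh["values"][()]
        freqs = fh["freqs"][()]
        times = fh["times"][()]
        pairs = tuple((a.decode(), b.decode()) for a, b in fh["pairs"][()])
        if kind == "gc":
            return GCTensor(values=values, freqs=freqs, pairs=pairs,
                            validity=fh["validity"][()], times=times, stats=stats)
        return CoherenceTensor(values=values, freqs=freqs, pairs=pairs,
                               times=times, stats=stats)


# ---------------------------------------------------------------------------
# TSV exports
# ---------------------------------------------------------------------------

def band_means_tsv(tensor, path) -> None:
    """Tidy per-segment band means: time, band, source, target, value."""
    frames = []
    n_pairs = len(tensor.pairs)
    n_seg = tensor.values.shape[0]
    src = np.array([a for a, _ in tensor.pairs])
    tgt = np.array([b for _, b in tensor.pairs])
    for band in BANDS:
        bv = band_average(tensor, band)
        frames.append(pd.DataFrame({
            "time_s": np.repeat(tensor.times, n_pairs),
            "band": band,
            "source": np.tile(src, n_seg),
            "target": np.tile(tgt, n_seg),
            "value": bv.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def trajectories_tsv(trajs: list[BandTrajectory], path,
                     event_times: dict | None = None) -> None:
    """Tidy trajectories: subject, pair, band, time (or offset), value."""
    rows = []
    for traj in trajs:
        for pi, (src, tgt) in enumerate(traj.pairs):
            rows.append(pd.DataFrame({
                "subject": traj.subject, "band": traj.band, "metric": traj.metric,
                "source": src, "target": tgt, "time_s": traj.times,
                "value": traj.values[:, pi],
            }))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def selections_tsv(selections, path) -> None:
    rows = []
    for sel in selections:
        for src, tgt in sorted(sel.pairs):
            rows.append({"metric": sel.metric, "rule": sel.rule,
                         "band": sel.band or "", "source": src, "target": tgt})
    pd.DataFrame(rows, columns=["metric", "rule", "band", "source", "target"]
                 ).to_csv(path, sep="\t", index=False)
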