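"""Band-averaged, smoothed, baseline-normalized connectivity trajectories.

Per-segment tensors are reduced to delta/alpha/beta band means, smoothed over
time by Nadaraya-Watson kernel regression (Gaussian kernel, 50-s bandwidth),
normalized — for Granger causality only — to the 95th centile of the first
2 min of propofol infusion, and aligned across subjects at the loss/recovery
of behavioral response, where the group curve per electrode pair is the
log-mean (geometric mean) over subjects, suited to the positively skewed GC
distribution.  A normalized GC above 1 means "larger than at the start of the
infusion".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BANDS", "BandTrajectory", "AlignedGroupTrajectory",
    "kernel_smooth", "band_average", "normalize_gc", "subject_band_trajectories",
    "align_logmean", "median_iqr_at", "SMOOTH_BANDWIDTH_S",
]

logger = logging.getLogger(__name__)

#: Band definitions (inclusive frequency ranges, Hz).
BANDS = {"delta": (0.5, 1.0), "alpha": (8.0, 14.0), "beta": (21.0, 30.0)}

SMOOTH_BANDWIDTH_S = 50.0
BASELINE_SECONDS = 120.0
BASELINE_PERCENTILE = 95.0
LOG_FLOOR = 1e-12


@dataclass
class BandTrajectory:
    """Per-subject, per-band connectivity time courses for many pairs."""

    subject: str
    band: str
    metric: str                      # "gc" or "coherence"
    times: np.ndarray                # (T,) segment centers, s
    values: np.ndarray               # (T, n_pairs)
    pairs: tuple[tuple[str, str], ...]
    normalized: bool = False
    divisors: np.ndarray | None = None
    events: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class AlignedGroupTrajectory:
    """Group (log-mean over subjects) curves on a common event-relative grid."""

    event: str                       # "LOBR" or "ROBR"
    band: str
    metric: str
    offsets: np.ndarray              # (O,) s relative to the event
    curve: np.ndarray                # (O, n_pairs) geometric-mean values
    n_subjects: np.ndarray           # (O,) subjects contributing
    pairs: tuple[tuple[str, str], ...]
    floor_events: int = 0

    def at_offset(self, offset: float) -> np.ndarray:
        return self.curve[int(np.argmin(np.abs(self.offsets - offset)))]


def kernel_smooth(times: np.ndarray, values: np.ndarray,
                  bandwidth: float = SMOOTH_BANDWIDTH_S,
                  eval_times: np.ndarray | None = None) -> np.ndarray:
    """Nadaraya-Watson kernel regression with a Gaussian kernel.

    Missing values are excluded from both numerator and denominator, so gaps
    are interpolated from neighboring segments.  The estimate is a convex
    combination of observed values: constants are preserved exactly and the
    output is bounded by the input range.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 1
    v = values[:, None] if squeeze else values
    if v.shape[0] != times.size:
        raise ValueError("times/values length mismatch")
    te = times if eval_times is None else np.asarray(eval_times, dtype=float)
    w = np.exp(-0.5 * ((te[:, None] - times[None, :]) / bandwidth) ** 2)
    mask = np.isfinite(v)
    num = w @ np.where(mask, v, 0.0)
    den = w @ mask.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out[:, 0] if squeeze else out


def band_average(tensor, band: str) -> np.ndarray:
    """Unweighted mean over the band's frequency bins: (n_seg, n_pairs).

    Delta averages the 0.5 and 1 Hz bins, alpha 8-14 Hz inclusive, beta
    21-30 Hz inclusive.  Missing values propagate as missing.
    """
    if band not in BANDS:
        raise KeyError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    lo, hi = BANDS[band]
    sel = (tensor.freqs >= lo - 1e-9) & (tensor.freqs <= hi + 1e-9)
    if not sel.any():
        raise ValueError(f"tensor frequency grid has no bins in band {band!r}")
    return tensor.values[:, sel, :].mean(axis=1)


def normalize_gc(values: np.ndarray, times: np.ndarray, infusion_start: float,
                 baseline_seconds: float = BASELINE_SECONDS,
                 percentile: float = BASELINE_PERCENTILE,
                 scope: str = "pair",
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Divide each pair's series by the subject's baseline percentile.

    The baseline is the ``percentile`` (linear interpolation between order
    statistics) of the series within the first ``baseline_seconds`` of the
    propofol infusion.  With ``scope='pair'`` (default) each pair is divided
    by its own baseline percentile, which makes "normalized GC > 1" meaningful
    pair-wise and every trajectory scale-free; ``scope='subject'`` divides all
    pairs by one subject-global baseline percentile.  Returns (normalized,
    divisors, flagged) where flagged marks pairs whose baseline is zero or
    undefined; their series are set to NaN and excluded from group summaries.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if infusion_start is None:
        raise ValueError("infusion_start is required for GC normalization")
    window = (times >= infusion_start) & (times < infusion_start + baseline_seconds)
    if times.max() < infusion_start + baseline_seconds:
        raise ValueError("need at least the full baseline window after infusion start")
    base = values[window]
    with np.errstate(all="ignore"):
        if scope == "pair":
            div = np.nanpercentile(base, percentile, axis=0)
        elif scope == "subject":
            div = np.full(values.shape[1], np.nanpercentile(base, percentile))
        else:
            raise ValueError("scope must be 'pair' or 'subject'")
    flagged = ~np.isfinite(div) | (div <= 0)
    if flagged.any():
        logger.warning("%d pairs have zero/undefined baseline; excluded",
                       int(flagged.sum()))
    safe = np.where(flagged, 1.0, div)
    out = values / safe
    out[:, flagged] = np.nan
    return out, div, flagged


def subject_band_trajectories(tensor, subject: str, metric: str,
                              infusion_start: float | None = None,
                              bands=tuple(BANDS),
                              bandwidth: float = SMOOTH_BANDWIDTH_S,
                              normalize: bool | None = None,
                              normalization_scope: str = "pair",
                              events: dict | None = None,
                              ) -> dict[str, BandTrajectory]:
    """Band-average, smooth and (for GC) baseline-normalize one subject.

    ``normalize`` defaults to True for the GC metric and False for coherence
    (coherence values are already on a common [0, 1] scale across subjects).
    """
    if normalize is None:
        normalize = metric == "gc"
    out = {}
    for band in bands:
        bv = band_average(tensor, band)
        sm = kernel_smooth(tensor.times, bv, bandwidth)
        div = None
        if normalize:
            sm, div, _ = normalize_gc(sm, tensor.times, infusion_start,
                                      scope=normalization_scope)
        out[band] = BandTrajectory(
            subject=subject, band=band, metric=metric, times=tensor.times.copy(),
            values=sm, pairs=tensor.pairs, normalized=normalize, divisors=div,
            events=dict(events or {}),
        )
    return out


def align_logmean(trajectories: list[BandTrajectory], event_times: list[float],
                  event: str, window_seconds: float = 900.0,
                  step_seconds: float = 4.0, log_floor: float = LOG_FLOOR,
                  ) -> AlignedGroupTrajectory:
    """Event-aligned geometric-mean group curve.

    Each subject's series is sampled on a common offset grid by
    nearest-segment lookup; offsets outside a subject's recording contribute
    nothing (the window is truncated, not padded, for subjects with short
    post-event coverage).  Values are floored at ``log_floor`` before the
    logarithm (floor events are counted); the group curve is
    exp(mean over subjects of ln value), with per-offset subject counts.
    """
    if not trajectories:
        raise ValueError("need at least one subject")
    if len(trajectories) != len(event_times):
        raise ValueError("one event time per subject required")
    pairs = trajectories[0].pairs
    band = trajectories[0].band
    metric = trajectories[0].metric
    offsets = np.arange(-window_seconds, window_seconds + step_seconds / 2,
                        step_seconds)
    stack = np.full((len(trajectories), offsets.size, len(pairs)), np.nan)
    floor_events = 0
    for si, (traj, t_event) in enumerate(zip(trajectories, event_times)):
        if traj.pairs != pairs or traj.band != band:
            raise ValueError("subjects must share pair index and band")
        if t_event is None:
            continue
        targets = t_event + offsets
        pos = np.searchsorted(traj.times, targets)
        pos = np.clip(pos, 1, traj.times.size - 1)
        left = traj.times[pos - 1]
        right = traj.times[pos]
        nearest = np.where(targets - left <= right - targets, pos - 1, pos)
        dist = np.abs(traj.times[nearest] - targets)
        inside = dist <= step_seconds
        vals = traj.values[nearest]
        vals[~inside] = np.nan
        floor_events += int((vals < log_floor).sum())
        stack[si] = np.maximum(vals, log_floor)
    import warnings as _warnings

    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN offsets
        logs = np.log(stack)
        curve = np.exp(np.nanmean(logs, axis=0))
    n_subjects = np.isfinite(logs).any(axis=2).sum(axis=0)
    return AlignedGroupTrajectory(
        event=event, band=band, metric=metric, offsets=offsets, curve=curve,
        n_subjects=n_subjects, pairs=pairs, floor_events=floor_events,
    )


def median_iqr_at(curve: np.ndarray, offsets: np.ndarray,
                  offset: float) -> tuple[float, float]:
    """Median and interquartile range across pair means at a time offset."""
    row = np.asarray(curve)[int(np.argmin(np.abs(np.asarray(offsets) - offset)))]
    row = row[np.isfinite(row)]
    if row.size < 2:
        raise ValueError("need at least 2 pairs")
    q25, q50, q75 = np.percentile(row, [25.0, 50.0, 75.0])
    return float(q50), float(q75 - q25)
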