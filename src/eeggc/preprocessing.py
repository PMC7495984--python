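"""Scalp-EEG preprocessing: average reference, decimation, Hjorth spatial
filter, artifact rejection and 4-s segmentation.

The pipeline order is fixed: re-reference -> downsample -> Hjorth filter ->
segment/reject -> per-segment z-normalization.  Decimation is performed
without an anti-alias filter by default: temporal filtering distorts the time
ordering that autoregressive modeling relies on, so only the spatial (Hjorth)
filter is applied.  An optional anti-alias flag exists for sensitivity
analyses; the aliasing risk of the default is documented in the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import decimate

from .montage import Montage, build_neighbor_map  # re-export  # noqa: F401
from .recording import EventTimeline, Recording  # re-export  # noqa: F401

__all__ = [
    "Montage", "Recording", "EventTimeline", "SegmentGrid",
    "build_neighbor_map", "average_rereference", "downsample",
    "hjorth_filter", "segment_and_reject", "preprocess",
    "AMPLITUDE_THRESHOLD_UV", "SEGMENT_SECONDS", "TARGET_RATE",
]

logger = logging.getLogger(__name__)

AMPLITUDE_THRESHOLD_UV = 200.0
SEGMENT_SECONDS = 4.0
TARGET_RATE = 125.0


@dataclass
class SegmentGrid:
    """Non-overlapping, contiguous 4-s blocks with per-channel validity.

    ``blocks`` is (n_segments, n_channels, samples_per_segment); when
    ``z_normalized`` each valid block has zero mean and unit SD.  Invalid
    blocks (amplitude above threshold, or zero variance) are left un-normalized
    and masked out in ``valid``.
    """

    blocks: np.ndarray        # (n_seg, n_ch, n_per_seg)
    valid: np.ndarray         # (n_seg, n_ch) bool
    times: np.ndarray         # (n_seg,) segment-center times, s
    sample_rate: float
    channel_names: tuple[str, ...]
    z_normalized: bool = False

    @property
    def n_segments(self) -> int:
        return self.blocks.shape[0]

    @property
    def n_channels(self) -> int:
        return self.blocks.shape[1]

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "channel": self.channel_names,
            "n_segments": self.n_segments,
            "n_valid": self.valid.sum(axis=0),
            "n_rejected": (~self.valid).sum(axis=0),
        })


def average_rereference(signal: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean over channels from every channel."""
    signal = np.asarray(signal, dtype=float)
    if signal.shape[0] < 2:
        raise ValueError("average reference needs at least 2 channels")
    return signal - signal.mean(axis=0, keepdims=True)


def downsample(signal: np.ndarray, from_rate: float, to_rate: float = TARGET_RATE,
               anti_alias: bool = False) -> np.ndarray:
    """Decimate to ``to_rate`` by keeping every k-th sample.

    ``from_rate`` must be an integer multiple of ``to_rate``.  By default no
    anti-alias filter is applied (see module docstring); ``anti_alias=True``
    switches to a zero-phase FIR decimator.
    """
    factor = from_rate / to_rate
    k = int(round(factor))
    if abs(factor - k) > 1e-9 or k < 1:
        raise ValueError(
            f"sampling rate {from_rate} is not an integer multiple of {to_rate}"
        )
    signal = np.asarray(signal, dtype=float)
    if k == 1:
        return signal.copy()
    if anti_alias:
        return decimate(signal, k, ftype="fir", zero_phase=True, axis=-1)
    return signal[..., ::k].copy()


def hjorth_filter(signal: np.ndarray, montage: Montage) -> np.ndarray:
    """Hjorth-type local spatial filter: each channel minus the mean of its
    three nearest neighbors, all computed from the unfiltered input.

    Suppresses volume-conducted common-mode activity: adding any signal that
    is identical on all channels leaves the output unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape[0] != len(montage):
        raise ValueError("signal/montage channel count mismatch")
    idx = {c: i for i, c in enumerate(montage.names)}
    out = np.empty_like(signal)
    for c in montage.names:
        if c not in montage.neighbor_map:
            raise KeyError(f"channel {c} missing from neighbor map")
        nb = [idx[n] for n in montage.neighbor_map[c]]
        out[idx[c]] = signal[idx[c]] - signal[nb].mean(axis=0)
    return out


def segment_and_reject(
    recording: Recording,
    segment_seconds: float = SEGMENT_SECONDS,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD_UV,
    reject_whole_segment: bool = False,
    z_normalize: bool = True,
) -> SegmentGrid:
    """Cut into non-overlapping 4-s segments, reject artifacts, z-normalize.

    A segment x channel block is invalid when its maximum absolute amplitude
    exceeds ``amplitude_threshold`` (strictly above; a block peaking exactly
    at the threshold is kept).  Rejection scope is per channel by default,
    which maximizes data retention; ``reject_whole_segment=True`` drops the
    entire segment when any channel trips the threshold.  Zero-variance
    blocks cannot be z-normalized and are marked invalid.  A trailing partial
    segment is dropped.
    """
    fs = recording.sample_rate
    n_per = int(round(segment_seconds * fs))
    if recording.n_samples < n_per:
        raise ValueError("recording shorter than one segment")
    n_seg = recording.n_samples // n_per
    m = recording.n_channels
    blocks = (
        recording.signal[:, : n_seg * n_per]
        .reshape(m, n_seg, n_per)
        .transpose(1, 0, 2)
        .copy()
    )
    valid = np.abs(blocks).max(axis=2) <= amplitude_threshold
    if reject_whole_segment:
        valid &= valid.all(axis=1, keepdims=True)
    sd = blocks.std(axis=2)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d zero-variance channel blocks marked invalid",
                       int(degenerate.sum()))
        valid &= ~degenerate
    if z_normalize:
        mu = blocks.mean(axis=2, keepdims=True)
        blocks = (blocks - mu) / np.where(sd[..., None] == 0, 1.0, sd[..., None])
    times = (np.arange(n_seg) + 0.5) * segment_seconds
    return SegmentGrid(
        blocks=blocks, valid=valid, times=times, sample_rate=fs,
        channel_names=tuple(recording.montage.names), z_normalized=z_normalize,
    )


def preprocess(
    recording: Recording,
    target_rate: float = TARGET_RATE,
    anti_alias: bool = False,
    reject_whole_segment: bool = False,
) -> tuple[Recording, SegmentGrid]:
    """Full preprocessing chain; returns the spatially filtered recording
    (input to the coherence analysis) and the z-normalized segment grid
    (input to the Granger analysis)."""
    x = average_rereference(recording.signal)
    x = downsample(x, recording.sample_rate, target_rate, anti_alias=anti_alias)
    filtered = recording.copy_with(
        hjorth_filter(x, recording.montage), sample_rate=target_rate
    )
    grid = segment_and_reject(filtered, reject_whole_segment=reject_whole_segment)
    return filtered, grid
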