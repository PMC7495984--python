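"""Power-weighted Hilbert-phase coherence between channel pairs.

For each analysis frequency f0 the spatially filtered signal is narrowband
filtered (third-order Butterworth high-pass at f0-0.8 Hz and low-pass at
f0+0.8 Hz, applied forward-backward so phases are not lag-distorted), the
analytic signal is taken, and per 4-s segment the coherence of a pair is the
amplitude-product-weighted phase-locking value

    C = | sum_t a_x a_y e^{i(phi_x - phi_y)} | / sum_t a_x a_y
      = | sum_t z_x conj(z_y) | / sum_t |z_x||z_y|,

which is 1 for a constant phase relation, falls toward the small-sample floor
for inconsistent phases, lies in [0, 1], is symmetric in its arguments and
invariant under positive rescaling of either channel.  Coherence is
nondirectional; it is computed for every unordered pair with no exclusions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, hilbert

from .granger import DEFAULT_FREQS
from .preprocessing import SEGMENT_SECONDS, Recording

__all__ = [
    "CoherenceTensor", "narrowband", "phase_amplitude", "weighted_coherence",
    "coherence_over_session", "HALF_WIDTH_HZ",
]

logger = logging.getLogger(__name__)

HALF_WIDTH_HZ = 0.8
MIN_EDGE_HZ = 0.05


def narrowband(signal: np.ndarray, f0: float, sample_rate: float,
               half_width: float = HALF_WIDTH_HZ, order: int = 3) -> np.ndarray:
    """Zero-phase band isolation around f0 (high-pass then low-pass).

    For f0 at the bottom of the grid (0.5 Hz) the lower edge would be
    non-positive; it is clamped to a small positive cutoff and logged.
    """
    nyq = sample_rate / 2.0
    lo = f0 - half_width
    hi = f0 + half_width
    if hi >= nyq:
        raise ValueError(f"upper band edge {hi} Hz at or above Nyquist {nyq} Hz")
    if lo <= 0:
        logger.info("band edge %.2f Hz <= 0 at f0=%.2f Hz; clamped to %.2f Hz",
                    lo, f0, MIN_EDGE_HZ)
        lo = MIN_EDGE_HZ
    bh, ah = butter(order, lo / nyq, btype="highpass")
    bl, al = butter(order, hi / nyq, btype="lowpass")
    y = filtfilt(bh, ah, np.asarray(signal, dtype=float), axis=-1)
    return filtfilt(bl, al, y, axis=-1)


def phase_amplitude(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase in (-pi, pi] and envelope amplitude (>= 0).

    The input is expected to be narrowband; the analytic signal is formed by
    the Hilbert transform along the last axis.
    """
    z = hilbert(np.asarray(signal, dtype=float), axis=-1)
    return np.angle(z), np.abs(z)


def weighted_coherence(x_block: np.ndarray, y_block: np.ndarray,
                       f0: float, sample_rate: float) -> float:
    """Amplitude-weighted phase locking of two same-segment raw blocks at f0.

    Returns NaN (and logs) when the total amplitude weight vanishes (flat
    signal).
    """
    zx = hilbert(narrowband(x_block, f0, sample_rate))
    zy = hilbert(narrowband(y_block, f0, sample_rate))
    weight = float(np.sum(np.abs(zx) * np.abs(zy)))
    if weight == 0.0:
        logger.warning("zero amplitude weight at f0=%.2f Hz; coherence undefined", f0)
        return float("nan")
    return float(np.abs(np.sum(zx * np.conj(zy))) / weight)


@dataclass
class CoherenceTensor:
    """segment x frequency x unordered-pair coherence values in [0, 1]."""

    values: np.ndarray       # (n_seg, n_freq, n_pairs)
    freqs: np.ndarray
    pairs: tuple[tuple[str, str], ...]
    times: np.ndarray
    stats: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_index(self, a: str, b: str) -> int:
        try:
            return self.pairs.index((a, b))
        except ValueError:
            return self.pairs.index((b, a))


def coherence_over_session(recording: Recording, freqs=DEFAULT_FREQS,
                           segment_seconds: float = SEGMENT_SECONDS
                           ) -> CoherenceTensor:
    """Coherence for all unordered pairs on the same 4-s segment grid as GC.

    Operates on the spatially filtered (Hjorth) recording; amplitude weights
    are taken from the un-normalized signal.  The narrowband filter runs over
    the continuous recording (segment boundaries would otherwise distort
    phase estimates through edge transients), and the analytic signal is then
    cut into the segment grid.
    """
    freqs = np.asarray(freqs, dtype=float)
    fs = recording.sample_rate
    m = recording.n_channels
    n_per = int(round(segment_seconds * fs))
    n_seg = recording.n_samples // n_per
    iu = np.triu_indices(m, 1)
    n_pairs = iu[0].size
    values = np.empty((n_seg, len(freqs), n_pairs))
    for fi, f0 in enumerate(freqs):
        z = hilbert(narrowband(recording.signal, float(f0), fs), axis=-1)
        z = z[:, : n_seg * n_per].reshape(m, n_seg, n_per)
        for s in range(n_seg):
            zs = z[:, s, :]
            num = np.abs(zs @ np.conj(zs.T))
            amp = np.abs(zs)
            den = amp @ amp.T
            with np.errstate(invalid="ignore", divide="ignore"):
                c = np.where(den > 0, num / den, np.nan)
            values[s, fi] = c[iu]
    names = recording.montage.names
    pairs = tuple((names[i], names[j]) for i, j in zip(*iu))
    times = (np.arange(n_seg) + 0.5) * segment_seconds
    n_undef = int(np.isnan(values).sum())
    if n_undef:
        logger.warning("%d undefined coherence values (zero weight)", n_undef)
    return CoherenceTensor(values=values, freqs=freqs, pairs=pairs, times=times,
                           stats={"n_undefined": n_undef})
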