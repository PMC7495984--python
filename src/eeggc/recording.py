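"""Recording and event-timeline containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .montage import Montage

__all__ = ["EventTimeline", "Recording"]


@dataclass(frozen=True)
class EventTimeline:
    """Per-subject behavioral events, in seconds from recording start.

    ``lobr``/``robr`` are the times of loss and recovery of behavioral
    response (failure and return of button presses to the auditory task);
    ``eye_closed_intervals`` lists (start, stop) stretches with eyes closed.
    """

    infusion_start: float | None = None
    lobr: float | None = None
    robr: float | None = None
    eye_closed_intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if (
            self.lobr is not None
            and self.robr is not None
            and not self.lobr < self.robr
        ):
            raise ValueError("lobr must precede robr")
        if (
            self.infusion_start is not None
            and self.lobr is not None
            and not self.infusion_start < self.lobr
        ):
            raise ValueError("infusion_start must precede lobr")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EventTimeline":
        d = dict(d)
        d["eye_closed_intervals"] = tuple(
            tuple(iv) for iv in d.get("eye_closed_intervals", ())
        )
        return cls(**d)


@dataclass
class Recording:
    """Multichannel EEG: channel x sample signal in microvolts."""

    signal: np.ndarray  # (n_channels, n_samples), µV
    sample_rate: float  # Hz
    montage: Montage
    events: EventTimeline = field(default_factory=EventTimeline)
    subject: str = "S00"

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.montage):
            raise ValueError(
                "signal must be (n_channels, n_samples) matching the montage"
            )
        dur = self.duration
        for t in (self.events.infusion_start, self.events.lobr, self.events.robr):
            if t is not None and not 0 <= t <= dur:
                raise ValueError(f"event time {t} s outside recording (0..{dur} s)")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def copy_with(self, signal: np.ndarray, sample_rate: float | None = None) -> "Recording":
        return Recording(
            signal=signal,
            sample_rate=self.sample_rate if sample_rate is None else sample_rate,
            montage=self.montage,
            events=self.events,
            subject=self.subject,
        )
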