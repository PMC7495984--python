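"""Electrode montages and the Hjorth neighbor geometry.

A montage is an ordered list of channel names with schematic 2-D scalp
coordinates (head seen from above, nose up, unit head radius).  The spatial
filter used throughout the pipeline subtracts, from each channel, the mean of
its three nearest neighbors, so the montage also carries a neighbor map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Montage", "build_neighbor_map", "standard_montage_31"]

N_NEIGHBORS = 3

#: Schematic 10-20 / 10-10 positions for the default 31-channel cap.
_COORDS_31 = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "AFz": (0.0, 0.72),
    "F7": (-0.81, 0.59), "F3": (-0.42, 0.52), "Fz": (0.0, 0.50),
    "F4": (0.42, 0.52), "F8": (0.81, 0.59),
    "FC5": (-0.69, 0.28), "FC1": (-0.25, 0.28), "FCz": (0.0, 0.25),
    "FC2": (0.25, 0.28), "FC6": (0.69, 0.28),
    "T7": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.69, -0.28), "CP1": (-0.25, -0.28), "CP2": (0.25, -0.28),
    "CP6": (0.69, -0.28),
    "P7": (-0.81, -0.59), "P3": (-0.42, -0.52), "Pz": (0.0, -0.50),
    "P4": (0.42, -0.52), "P8": (0.81, -0.59),
    "POz": (0.0, -0.75),
    "O1": (-0.31, -0.95), "Oz": (0.0, -0.99), "O2": (0.31, -0.95),
}


def build_neighbor_map(
    names: list[str], coords: np.ndarray, n_neighbors: int = N_NEIGHBORS
) -> dict[str, list[str]]:
    """For each channel, its ``n_neighbors`` nearest other channels.

    Distances are Euclidean in the 2-D scalp plane.  Ties are broken
    deterministically by channel name order; exactly duplicated coordinates
    are geometrically ambiguous and raise a warning (the tie-break still
    applies).
    """
    coords = np.asarray(coords, dtype=float)
    if len(names) < n_neighbors + 1:
        raise ValueError(
            f"need at least {n_neighbors + 1} channels, got {len(names)}"
        )
    if not np.isfinite(coords).all():
        raise ValueError("montage coordinates must be finite")
    if len({tuple(c) for c in coords.tolist()}) < len(names):
        warnings.warn(
            "duplicate electrode coordinates; neighbor assignment resolved "
            "by name order",
            stacklevel=2,
        )
    out: dict[str, list[str]] = {}
    for i, name in enumerate(names):
        d = np.hypot(*(coords - coords[i]).T)
        ranked = sorted(
            (d[j], names[j]) for j in range(len(names)) if j != i
        )
        out[name] = [n for _, n in ranked[:n_neighbors]]
    return out


@dataclass(frozen=True)
class Montage:
    """Ordered channel names, 2-D coordinates and the 3-nearest-neighbor map."""

    names: tuple[str, ...]
    coords: np.ndarray  # (n_channels, 2)
    neighbor_map: dict[str, list[str]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(self.names), 2):
            raise ValueError("coords must be (n_channels, 2)")
        object.__setattr__(self, "coords", coords)
        if self.neighbor_map is None:
            object.__setattr__(
                self,
                "neighbor_map",
                build_neighbor_map(list(self.names), coords),
            )
        for ch, nbs in self.neighbor_map.items():
            if len(nbs) != N_NEIGHBORS or ch in nbs or len(set(nbs)) != N_NEIGHBORS:
                raise ValueError(f"invalid neighbor set for {ch}: {nbs}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.names, "x": self.coords[:, 0], "y": self.coords[:, 1]}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Montage":
        df = pd.read_csv(path)
        return cls(tuple(df["name"]), df[["x", "y"]].to_numpy(float))


def standard_montage_31() -> Montage:
    """The default 31-channel 10-20-style cap used by the simulator."""
    names = tuple(_COORDS_31)
    coords = np.array([_COORDS_31[n] for n in names])
    return Montage(names, coords)
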