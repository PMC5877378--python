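"""Electrode layout handling for the 62-channel 10-20 montage.

The recording montage has 62 scalp electrodes placed by the extended
international 10-20 system; Fz serves as the reference, leaving 61
effective channels.  2D positions are an azimuthal-equidistant projection
of the standard spherical coordinates (+y anterior, +x right, vertex at
the origin, preauricular ring at radius 1), shipped as package data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

REFERENCE_CHANNEL = "Fz"

#: channels repeatedly implicated in emotion discrimination (bilateral
#: temporal, prefrontal and occipital sites); used as simulation defaults
DEFAULT_EFFECT_CHANNELS = ("T7", "T8", "TP8", "AF7", "O1")


@dataclass(frozen=True)
class ChannelLayout:
    """An ordered set of named electrodes with 2D scalp positions."""

    names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2), unit head disc

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("channel names must be unique")
        if self.positions.shape != (len(self.names), 2):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.names)} channel names"
            )

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in layout") from None

    def indices(self, names) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    def subset(self, names) -> "ChannelLayout":
        idx = self.indices(names)
        return ChannelLayout(tuple(names), self.positions[idx])


def _load_montage() -> tuple[tuple[str, ...], np.ndarray]:
    ref = resources.files("emoeeg.data").joinpath("layout_62.csv")
    names, xy = [], []
    with ref.open("r") as fh:
        for row in csv.DictReader(fh):
            names.append(row["name"])
            xy.append((float(row["x"]), float(row["y"])))
    return tuple(names), np.asarray(xy)


def standard_layout(n_channels: int = 61) -> ChannelLayout:
    """The standard 61-channel effective layout (62-channel cap minus Fz).

    ``n_channels`` < 61 returns the first n channels of the effective
    layout — a reduced montage for fast tests, not a physiological choice.
    """
    names, xy = _load_montage()
    keep = [i for i, n in enumerate(names) if n != REFERENCE_CHANNEL]
    if not 1 <= n_channels <= len(keep):
        raise ValueError(f"n_channels must be in [1, {len(keep)}], got {n_channels}")
    keep = keep[:n_channels]
    return ChannelLayout(tuple(names[i] for i in keep), xy[keep])
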