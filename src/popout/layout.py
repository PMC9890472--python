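"""64-channel EEG montage: names, 3-D positions, and mastoid identifiers.

The packaged template is a standard 10-10 arrangement (EasyCap-style 64-channel
subset) scaled to an 85 mm head sphere; positions are in meters.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import StructuralError

MASTOIDS = ("TP9", "TP10")


@dataclass(frozen=True)
class ChannelLayout:
    names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3) in meters
    mastoids: tuple[str, str] = MASTOIDS

    def __post_init__(self) -> None:
        if len(self.names) != self.positions.shape[0]:
            raise StructuralError("channel names and positions disagree in length")
        d = self.distance_matrix()
        if np.any(d[~np.eye(len(self.names), dtype=bool)] <= 0):
            raise StructuralError("layout contains coincident electrodes")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise StructuralError(f"channel {name!r} not in layout") from None

    def distance_matrix(self) -> np.ndarray:
        p = self.positions
        return np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)

    @classmethod
    def load_default(cls) -> "ChannelLayout":
        """Load the packaged 64-channel template (name, x, y, z TSV)."""
        with resources.files("popout.data").joinpath("layout_64ch.tsv").open() as f:
            tab = pd.read_csv(f, sep="\t")
        return cls(names=tuple(tab["name"]),
                   positions=tab[["x", "y", "z"]].to_numpy(float))

    @classmethod
    def from_tsv(cls, path) -> "ChannelLayout":
        tab = pd.read_csv(path, sep="\t")
        return cls(names=tuple(tab["name"]),
                   positions=tab[["x", "y", "z"]].to_numpy(float))

    def to_tsv(self, path) -> None:
        pd.DataFrame({"name": self.names,
                      "x": self.positions[:, 0],
                      "y": self.positions[:, 1],
                      "z": self.positions[:, 2]}).to_csv(path, sep="\t", index=False)
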