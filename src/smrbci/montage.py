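"""Electrode montage: the 31-channel 10–20 cap and its motor-strip subset.

Positions are taken from the standard 10–20 template shipped with MNE,
sphere-fitted and flattened with an azimuthal-equidistant projection so that
spatial profiles, scalp maps and interpolation all work in a common 2-D
head-schematic coordinate frame (vertex at the origin, left ear at negative x).
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field

import numpy as np

#: The full cap: 31 Ag/AgCl electrodes in 10–20 layout.
CHANNELS_31: tuple[str, ...] = (
    "FP1", "FZ", "F3", "F7", "FT9", "FC5", "FC1", "C3", "T7", "TP9",
    "CP5", "CP1", "PZ", "P3", "P7", "O1", "O2", "P4", "P8", "TP10",
    "CP6", "CP2", "CZ", "C4", "T8", "FT10", "FC6", "FC2", "F4", "F8", "FP2",
)

#: Motor-strip subset used for the reduced-channel decoder.
CHANNELS_7: tuple[str, ...] = ("FC1", "FC2", "C3", "CZ", "C4", "CP1", "CP2")


def _fit_sphere(xyz: np.ndarray) -> np.ndarray:
    """Least-squares sphere centre of a point cloud (linearised fit)."""
    A = np.c_[2.0 * xyz, np.ones(len(xyz))]
    b = (xyz**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


@functools.lru_cache(maxsize=1)
def _standard_positions_2d() -> dict[str, tuple[float, float]]:
    """2-D azimuthal-equidistant positions for the 31 cap labels.

    Radius equals the inclination angle from the vertex in radians, so the
    ear-level ring (T7/T8) sits near pi/2 and CZ at the origin.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1020")
    ch_pos = {k.upper(): np.asarray(v) for k, v in std.get_positions()["ch_pos"].items()}
    xyz = np.array([ch_pos[label] for label in CHANNELS_31])
    xyz = xyz - _fit_sphere(xyz)
    out: dict[str, tuple[float, float]] = {}
    for label, p in zip(CHANNELS_31, xyz):
        r = np.linalg.norm(p)
        incl = np.arccos(np.clip(p[2] / r, -1.0, 1.0))
        horiz = np.hypot(p[0], p[1])
        if horiz < 1e-12:
            out[label] = (0.0, 0.0)
        else:
            out[label] = (float(incl * p[0] / horiz), float(incl * p[1] / horiz))
    return out


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels plus projected 2-D scalp positions."""

    labels: tuple[str, ...]
    positions: dict[str, tuple[float, float]] = field(repr=False)

    def __post_init__(self) -> None:
        missing = [l for l in self.labels if l not in self.positions]
        if missing:
            raise ValueError(f"montage positions missing for channels: {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def position_array(self) -> np.ndarray:
        """(n_channels, 2) array of projected positions, in label order."""
        return np.array([self.positions[l] for l in self.labels])

    def spacing(self) -> float:
        """Median nearest-neighbour distance — one 'inter-electrode spacing'."""
        pos = self.position_array()
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        return float(np.median(d.min(axis=1)))

    def subset(self, labels: tuple[str, ...] | list[str]) -> "Montage":
        return Montage(tuple(labels), {l: self.positions[l] for l in labels})


def default_montage() -> Montage:
    """The 31-channel cap with standard 10–20 template positions."""
    return Montage(CHANNELS_31, _standard_positions_2d())


def motor_subset_montage() -> Montage:
    return default_montage().subset(CHANNELS_7)


def mirror_channel(label: str) -> str:
    """Homologous electrode in the opposite hemisphere (C3 <-> C4, ...)."""
    if label.endswith("Z"):
        return label
    head = label.rstrip("0123456789")
    digits = label[len(head):]
    if not digits:
        raise ValueError(f"cannot mirror channel {label!r}")
    d = int(digits)
    return f"{head}{d + 1 if d % 2 else d - 1}"
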