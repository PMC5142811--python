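"""Shared domain containers for the imaging and behavior pipelines.

Axis convention used throughout the package: image stacks are indexed
``(t, z, y, x, c)`` with 0-based indices and voxel centers at integer
coordinates.  The first channel is the calcium indicator ("G"), the second
the activity-independent reference fluorophore ("R"); the G/R ratio cancels
motion and expression artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: The four scored behavioral states, plus the sentinel for unscored frames.
BEHAVIORS = ("forward", "reversal", "turn", "pause")
UNKNOWN = "unknown"
LABEL_VOCABULARY = BEHAVIORS + (UNKNOWN,)

#: Synonyms accepted when reading ethogram files.
LABEL_SYNONYMS = {
    "reverse": "reversal",
    "omega turn": "turn",
    "omega_turn": "turn",
}


def canonical_label(label: str) -> str:
    """Map a raw behavior label to the canonical vocabulary.

    Raises ``ValueError`` for labels outside the vocabulary.
    """
    lab = str(label).strip().lower()
    lab = LABEL_SYNONYMS.get(lab, lab)
    if lab not in LABEL_VOCABULARY:
        raise ValueError(f"unknown behavior label: {label!r}")
    return lab


@dataclass
class ImageStack:
    """Two-channel volumetric time-lapse recording.

    Parameters
    ----------
    data
        Voxel grid indexed ``(t, z, y, x, c)``, non-negative.
    voxel_size
        Physical voxel extents ``(dz, dy, dx)`` in micrometres.
    frame_interval
        Time between volumes, seconds.
    channel_names
        Ordered channel labels; ``("G", "R")`` for ratiometric recordings.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_interval: float = 0.5
    channel_names: tuple[str, ...] = ("G", "R")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"stack data must be 5-dimensional (t, z, y, x, c); got {self.data.ndim}"
            )
        if any(s < 1 for s in self.data.shape):
            raise ValueError("every axis must have length >= 1")
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise ValueError("voxel intensities must be non-negative")
        if len(self.channel_names) != self.data.shape[4]:
            raise ValueError("channel_names length must match the c axis")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.frame_interval = float(self.frame_interval)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each volume, seconds."""
        return np.arange(self.n_frames) * self.frame_interval

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            return self.channel_names.index(channel)
        return int(channel)

    def volume(self, t: int, channel: int | str) -> np.ndarray:
        """3D volume at frame ``t`` for one channel."""
        return self.data[t, :, :, :, self.channel_index(channel)]


@dataclass
class StimulusProtocol:
    """Timed thermal stimulation protocol.

    The canonical plate/laser protocol records a pre-stimulus baseline, then
    ``repeats`` cycles of a heat pulse (``stim_duration``) followed by an
    interstimulus interval (``isi``).  ``cultivation_temp`` is the rearing
    temperature T_C on which thermosensory responses depend.
    """

    pre_duration: float = 50.0
    stim_duration: float = 20.0
    isi: float = 30.0
    repeats: int = 5
    base_temp: float = 23.0
    stim_temp: float = 33.0
    ramp_time: float = 0.0
    cultivation_temp: float = 23.0

    def __post_init__(self) -> None:
        for name in ("pre_duration", "stim_duration", "isi", "ramp_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.repeats < 0:
            raise ValueError("repeats must be >= 0")
        if self.stim_temp < self.base_temp:
            raise ValueError("stim_temp must be >= base_temp for a heating protocol")

    @property
    def total_duration(self) -> float:
        """Protocol length in seconds."""
        return self.pre_duration + self.repeats * (self.stim_duration + self.isi)

    def heat_windows(self) -> list[tuple[float, float]]:
        """``(start, end)`` of every heating pulse, seconds."""
        out = []
        t = self.pre_duration
        for _ in range(self.repeats):
            out.append((t, t + self.stim_duration))
            t += self.stim_duration + self.isi
        return out

    def to_dict(self) -> dict:
        return {
            "pre_duration": self.pre_duration,
            "stim_duration": self.stim_duration,
            "isi": self.isi,
            "repeats": self.repeats,
            "base_temp": self.base_temp,
            "stim_temp": self.stim_temp,
            "ramp_time": self.ramp_time,
            "cultivation_temp": self.cultivation_temp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class Ethogram:
    """Per-frame behavior labels for a single worm at a fixed frame rate."""

    worm_id: str
    labels: Sequence[str]
    fps: float = 20.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        self.labels = np.asarray([canonical_label(l) for l in self.labels], dtype=object)

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    def frame_times(self) -> np.ndarray:
        """Start time of each frame, seconds."""
        return np.arange(self.n_frames) / self.fps
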