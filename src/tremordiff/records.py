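"""Core record types shared across the pipeline.

A :class:`TremorRecording` is one subject/posture 3-axis acceleration stream;
a :class:`Segment` is a single-channel, preprocessed window ready for feature
extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

GROUPS = ("PD", "ET")
STAGES = ("S1", "S2")
POSTURES = ("P1", "P2")

#: Subgroup labels: group crossed with disease stage.
SUBGROUPS = ("PD1", "PD2", "ET1", "ET2")


def subgroup_label(group: str, stage: str) -> str:
    """Map (group, stage) to the compact subgroup label, e.g. (PD, S1) -> PD1."""
    return f"{group}{1 if stage == 'S1' else 2}"


@dataclass
class TremorRecording:
    """One subject/posture 3-axis acceleration stream with metadata.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    group : {"PD", "ET"}
    stage : {"S1", "S2"}
        Incipient (S1) or progressed (S2) disease stage.
    posture : {"P1", "P2"}
        Arm-stretching (P1) or arm-rested (P2) posture.
    sampling_rate : float
        Sampling rate in Hz.
    axes : ndarray, shape (3, N)
        Acceleration samples in m/s^2, one row per axis.
    trial_bounds : list of (int, int)
        Half-open [start, end) sample index ranges of the trials making up
        the recording, ordered and non-overlapping.
    """

    subject_id: str
    group: str
    stage: str
    posture: str
    sampling_rate: float
    axes: np.ndarray
    trial_bounds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axes = np.asarray(self.axes, dtype=float)
        if self.axes.ndim != 2 or self.axes.shape[0] != 3:
            raise ValueError(f"axes must have shape (3, N), got {self.axes.shape}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.posture not in POSTURES:
            raise ValueError(
                f"posture must be one of {POSTURES}, got {self.posture!r}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n = self.axes.shape[1]
        if not self.trial_bounds:
            self.trial_bounds = [(0, n)] if n else []
        prev_end = 0
        for start, end in self.trial_bounds:
            if not (0 <= start < end <= n):
                raise ValueError(f"trial bounds ({start}, {end}) outside [0, {n})")
            if start < prev_end:
                raise ValueError("trial bounds overlap or are out of order")
            prev_end = end

    @property
    def n_samples(self) -> int:
        return self.axes.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def subgroup(self) -> str:
        return subgroup_label(self.group, self.stage)


@dataclass(frozen=True)
class SegmentProvenance:
    """Where a segment came from, carried through feature extraction."""

    subject_id: str
    group: str
    stage: str
    posture: str
    segment_index: int
    trial_index: int = 0
    flags: tuple[str, ...] = ()

    def with_flag(self, flag: str) -> "SegmentProvenance":
        return replace(self, flags=self.flags + (flag,))


@dataclass
class RawSegment:
    """A fixed-length 3-axis window cut from a recording, prior to filtering."""

    axes: np.ndarray  # (3, M)
    sampling_rate: float
    provenance: SegmentProvenance

    def __post_init__(self) -> None:
        self.axes = np.asarray(self.axes, dtype=float)
        if self.axes.ndim != 2 or self.axes.shape[0] != 3:
            raise ValueError(f"axes must have shape (3, M), got {self.axes.shape}")

    @property
    def n_samples(self) -> int:
        return self.axes.shape[1]


@dataclass
class Segment:
    """A single-channel, preprocessed, fixed-length acceleration window."""

    samples: np.ndarray  # (M,)
    sampling_rate: float
    provenance: SegmentProvenance

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValueError(f"non-finite sample at index {bad}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def length_s(self) -> float:
        return self.n_samples / self.sampling_rate
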