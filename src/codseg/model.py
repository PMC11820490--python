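"""Shared data model for COD segmentation.

A *trial* is one recorded V-cut run: per-frame trunk velocity components in
the capture system's global horizontal plane plus four binary foot-contact
channels (heel and toe point per foot).  A *COD event* is one detected change
of direction: the velocity minimum that anchors it, the initial frame (IF,
heel strike of the penultimate foot contact of the non-cutting foot) and the
final frame (FF, toe off of the final foot contact of the cutting foot).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Any, Mapping

import numpy as np

__all__ = [
    "TestType",
    "Side",
    "EventStatus",
    "ContactChannels",
    "MotionTrial",
    "LabelEvent",
    "ManualLabels",
    "DetectionParams",
    "CODEvent",
    "SegmentationResult",
]


class TestType(str, Enum):
    """V-cut variants: the plain agility sprint and the dribbling version."""

    VCUT = "VCUT"
    VCUT_BK = "VCUT_BK"


class Side(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"

    @property
    def other(self) -> "Side":
        return Side.RIGHT if self is Side.LEFT else Side.LEFT


class EventStatus(str, Enum):
    COMPLETE = "COMPLETE"
    IF_MISSING = "IF_MISSING"
    FF_MISSING = "FF_MISSING"
    BOTH_MISSING = "BOTH_MISSING"


def _as_binary(name: str, values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        bad = np.flatnonzero(~np.isin(arr, (0, 1)))[0]
        raise ValueError(
            f"contact channel {name!r} must be binary; value {arr[bad]!r} at frame {bad}"
        )
    return arr.astype(np.int8)


@dataclass
class ContactChannels:
    """Four per-frame binary stance indicators (1 = point on the ground)."""

    left_heel: np.ndarray
    left_toe: np.ndarray
    right_heel: np.ndarray
    right_toe: np.ndarray

    def __post_init__(self) -> None:
        for name in ("left_heel", "left_toe", "right_heel", "right_toe"):
            setattr(self, name, _as_binary(name, getattr(self, name)))
        lengths = {len(getattr(self, n)) for n in self.channel_names()}
        if len(lengths) != 1:
            raise ValueError(f"contact channels have unequal lengths: {lengths}")

    @staticmethod
    def channel_names() -> tuple[str, str, str, str]:
        return ("left_heel", "left_toe", "right_heel", "right_toe")

    def __len__(self) -> int:
        return len(self.left_heel)

    def heel(self, side: Side) -> np.ndarray:
        return self.left_heel if side is Side.LEFT else self.right_heel

    def toe(self, side: Side) -> np.ndarray:
        return self.left_toe if side is Side.LEFT else self.right_toe

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContactChannels):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, n), getattr(other, n))
            for n in self.channel_names()
        )


@dataclass
class MotionTrial:
    """One recorded trial in the common in-memory form.

    ``trunk_vx``/``trunk_vy`` are the trunk segment's velocity components
    (m/s) along the global x and y axes; the detector only ever consumes
    their Euclidean norm (horizontal speed).
    """

    trial_id: str
    frame_rate: float
    trunk_vx: np.ndarray
    trunk_vy: np.ndarray
    contacts: ContactChannels
    test_type: TestType = TestType.VCUT
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trunk_vx = np.asarray(self.trunk_vx, dtype=float)
        self.trunk_vy = np.asarray(self.trunk_vy, dtype=float)
        if isinstance(self.test_type, str):
            self.test_type = TestType(self.test_type)
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        n = len(self.trunk_vx)
        if len(self.trunk_vy) != n or len(self.contacts) != n:
            raise ValueError(
                "per-frame series disagree in length: "
                f"vx={len(self.trunk_vx)} vy={len(self.trunk_vy)} contacts={len(self.contacts)}"
            )
        if n < 2:
            raise ValueError(f"trial needs at least 2 frames, got {n}")

    @property
    def n_frames(self) -> int:
        return len(self.trunk_vx)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MotionTrial):
            return NotImplemented
        return (
            self.trial_id == other.trial_id
            and self.test_type == other.test_type
            and self.frame_rate == other.frame_rate
            and np.array_equal(self.trunk_vx, other.trunk_vx)
            and np.array_equal(self.trunk_vy, other.trunk_vy)
            and self.contacts == other.contacts
            and self.meta == other.meta
        )


@dataclass(frozen=True)
class LabelEvent:
    """Manually annotated ground truth for one COD."""

    cod_index: int
    if_frame: int
    ff_frame: int

    def __post_init__(self) -> None:
        if self.if_frame >= self.ff_frame:
            raise ValueError(
                f"COD {self.cod_index}: if_frame {self.if_frame} must precede "
                f"ff_frame {self.ff_frame}"
            )


@dataclass
class ManualLabels:
    trial_id: str
    events: list[LabelEvent]

    def __post_init__(self) -> None:
        idx = [e.cod_index for e in self.events]
        if len(set(idx)) != len(idx):
            raise ValueError(f"duplicate cod_index in labels for {self.trial_id!r}")
        self.events = sorted(self.events, key=lambda e: e.if_frame)


@dataclass(frozen=True)
class DetectionParams:
    """Filter and search-region configuration.

    ``region_before``/``region_after`` are expressed in frames at
    ``reference_rate`` and rescaled proportionally for trials recorded at a
    different rate, so the temporal window stays physically constant.
    """

    prominence: float = 1.5  # m/s depth qualifying a braking trough
    region_before: int = 40  # frames at reference_rate
    region_after: int = 25
    cutoff: float = 1.5  # Hz, low-pass cut-off
    filter_order: int = 4  # per pass; applied forward and backward
    reference_rate: float = 60.0  # Hz
    pad_method: str = "odd"  # filtfilt edge padding

    def __post_init__(self) -> None:
        if self.prominence <= 0:
            raise ValueError("prominence must be positive")
        if self.region_before <= 0 or self.region_after <= 0:
            raise ValueError("search-region bounds must be positive")

    @property
    def region_width(self) -> int:
        return self.region_before + self.region_after

    def to_dict(self) -> dict[str, Any]:
        return {
            "prominence": self.prominence,
            "region_before": self.region_before,
            "region_after": self.region_after,
            "cutoff": self.cutoff,
            "filter_order": self.filter_order,
            "reference_rate": self.reference_rate,
            "pad_method": self.pad_method,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DetectionParams":
        return cls(**dict(d))


@dataclass(frozen=True)
class CODEvent:
    """One detected change of direction.

    ``if_frame``/``ff_frame`` are ``None`` when the corresponding contact
    transition was not found inside the search region; ``status`` records
    which parts are missing.
    """

    cod_index: int
    minimum_frame: int
    if_frame: int | None
    ff_frame: int | None
    pfc_side: Side | None
    ffc_side: Side | None
    status: EventStatus

    def to_dict(self) -> dict[str, Any]:
        return {
            "cod_index": self.cod_index,
            "minimum_frame": self.minimum_frame,
            "if_frame": self.if_frame,
            "ff_frame": self.ff_frame,
            "pfc_side": self.pfc_side.value if self.pfc_side else None,
            "ffc_side": self.ffc_side.value if self.ffc_side else None,
            "status": self.status.value,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CODEvent":
        return cls(
            cod_index=int(d["cod_index"]),
            minimum_frame=int(d["minimum_frame"]),
            if_frame=None if d["if_frame"] is None else int(d["if_frame"]),
            ff_frame=None if d["ff_frame"] is None else int(d["ff_frame"]),
            pfc_side=None if d["pfc_side"] is None else Side(d["pfc_side"]),
            ffc_side=None if d["ffc_side"] is None else Side(d["ffc_side"]),
            status=EventStatus(d["status"]),
        )


@dataclass
class SegmentationResult:
    trial_id: str
    params_used: DetectionParams
    events: list[CODEvent]
    frame_rate: float = 60.0
    test_type: TestType = TestType.VCUT

    def __post_init__(self) -> None:
        frames = [e.minimum_frame for e in self.events]
        if sorted(frames) != frames or len(set(frames)) != len(frames):
            raise ValueError("events must be ordered by distinct minimum frames")

    def complete_events(self) -> list[CODEvent]:
        return [e for e in self.events if e.status is EventStatus.COMPLETE]


def rescale_params(params: DetectionParams, frame_rate: float) -> tuple[int, int]:
    """Region bounds in frames at ``frame_rate`` (rounded from the reference)."""
    scale = frame_rate / params.reference_rate
    return (
        int(round(params.region_before * scale)),
        int(round(params.region_after * scale)),
    )


__all__.append("rescale_params")
__all__.append("replace")
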