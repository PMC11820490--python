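"""COD event assembly from velocity minima and foot-contact transitions.

Around each prominence-qualified trough of the filtered trunk speed, a
search region of ``region_before`` frames back and ``region_after`` frames
forward (at the 60 Hz reference rate, rescaled for other rates) is scanned:

* IF — the *latest* rising edge (0→1) of the penultimate-foot-contact
  (non-cutting) heel channel at or before the minimum: the heel strike of
  the braking step nearest the trough.
* FF — the *earliest* falling edge (1→0) of the final-foot-contact
  (cutting) toe channel at or after the minimum: the toe off that ends the
  cut.

The cutting foot is inferred as the side whose toe-off falls earliest after
the minimum; a per-COD schedule can override the inference when the cut
sequence is known (the V-cut alternates right/left by design).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .kinematics import find_velocity_minima, velocity_trace
from .model import (
    CODEvent,
    ContactChannels,
    DetectionParams,
    EventStatus,
    MotionTrial,
    SegmentationResult,
    Side,
    rescale_params,
)

__all__ = [
    "build_search_region",
    "detect_if",
    "detect_ff",
    "assign_foot_sides",
    "detect_cods",
]


def build_search_region(
    minimum_frame: int,
    params: DetectionParams,
    frame_rate: float,
    n_frames: int,
) -> tuple[int, int]:
    """Inclusive frame interval scanned around one velocity minimum."""
    before, after = rescale_params(params, frame_rate)
    lo = max(0, minimum_frame - before)
    hi = min(n_frames - 1, minimum_frame + after)
    return lo, hi


def _rising_edges(channel: np.ndarray) -> np.ndarray:
    """Frames t with c[t]=1 and c[t]-c[t-1]=1 (t=0 can never qualify)."""
    d = np.diff(channel.astype(np.int8))
    return np.flatnonzero(d == 1) + 1


def _falling_edges(channel: np.ndarray) -> np.ndarray:
    """Frames t with c[t]=0 and |c[t]-c[t-1]|=1, i.e. the first airborne frame."""
    d = np.diff(channel.astype(np.int8))
    return np.flatnonzero(d == -1) + 1


def detect_if(
    contacts: ContactChannels,
    region: tuple[int, int],
    minimum_frame: int,
    pfc_side: Side,
) -> int | None:
    """Latest heel strike of the non-cutting foot at or before the minimum."""
    lo, _hi = region
    edges = _rising_edges(contacts.heel(pfc_side))
    edges = edges[(edges >= lo) & (edges <= minimum_frame)]
    return int(edges[-1]) if len(edges) else None


def detect_ff(
    contacts: ContactChannels,
    region: tuple[int, int],
    minimum_frame: int,
    ffc_side: Side,
) -> int | None:
    """Earliest toe off of the cutting foot at or after the minimum."""
    _lo, hi = region
    edges = _falling_edges(contacts.toe(ffc_side))
    edges = edges[(edges >= minimum_frame) & (edges <= hi)]
    return int(edges[0]) if len(edges) else None


def assign_foot_sides(
    contacts: ContactChannels,
    region: tuple[int, int],
    minimum_frame: int,
) -> tuple[Side | None, Side | None]:
    """Infer (pfc_side, ffc_side) from the earliest post-minimum toe off.

    Ties (both feet lifting on the same frame, physically implausible) break
    to LEFT for determinism.
    """
    _lo, hi = region
    best: tuple[int, Side] | None = None
    for side in (Side.LEFT, Side.RIGHT):
        edges = _falling_edges(contacts.toe(side))
        edges = edges[(edges >= minimum_frame) & (edges <= hi)]
        if len(edges):
            cand = (int(edges[0]), side)
            if best is None or cand[0] < best[0]:
                best = cand
    if best is None:
        return None, None
    ffc = best[1]
    return ffc.other, ffc


def detect_cods(
    trial: MotionTrial,
    params: DetectionParams = DetectionParams(),
    sides: Sequence[Side] | None = None,
    filtered: np.ndarray | None = None,
) -> SegmentationResult:
    """Run the full detection pipeline on one trial.

    Parameters
    ----------
    trial
        Input trial.
    params
        Filter and search-region configuration.
    sides
        Optional known cutting-foot schedule, one FFC side per COD in order;
        entries beyond the detected minima are ignored.  When omitted, sides
        are inferred from contact transitions.
    filtered
        Pre-filtered speed trace, to avoid refiltering when only prominence
        or region bounds change across calls (used by the tuner).
    """
    if filtered is None:
        filtered = velocity_trace(
            trial, params.cutoff, params.filter_order, params.pad_method
        ).filtered
    minima = find_velocity_minima(filtered, params.prominence)
    events: list[CODEvent] = []
    for k, m in enumerate(minima):
        region = build_search_region(m.frame, params, trial.frame_rate, trial.n_frames)
        if sides is not None and k < len(sides):
            ffc: Side | None = sides[k]
            pfc: Side | None = ffc.other
        else:
            pfc, ffc = assign_foot_sides(trial.contacts, region, m.frame)
        if_frame = (
            detect_if(trial.contacts, region, m.frame, pfc) if pfc is not None else None
        )
        ff_frame = (
            detect_ff(trial.contacts, region, m.frame, ffc) if ffc is not None else None
        )
        if if_frame is not None and ff_frame is not None:
            status = EventStatus.COMPLETE
        elif if_frame is not None:
            status = EventStatus.FF_MISSING
        elif ff_frame is not None:
            status = EventStatus.IF_MISSING
        else:
            status = EventStatus.BOTH_MISSING
        events.append(
            CODEvent(
                cod_index=k + 1,
                minimum_frame=m.frame,
                if_frame=if_frame,
                ff_frame=ff_frame,
                pfc_side=pfc,
                ffc_side=ffc,
                status=status,
            )
        )
    return SegmentationResult(
        trial_id=trial.trial_id,
        params_used=params,
        events=events,
        frame_rate=trial.frame_rate,
        test_type=trial.test_type,
    )
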