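"""Synthetic V-cut trials with known ground-truth IF/FF.

The study's cohort recordings are not public, so every downstream module is
exercised on generated trials that emulate the test's kinematic signature:

* trunk horizontal speed cruising near 4 m/s with one raised-cosine braking
  trough per COD (default four, alternating cut sides right/left);
* velocity components consistent with a 45° internal-angle (135° cut) path,
  heading switching smoothly across each trough;
* alternating-foot stance trains (heel + toe contact points per foot) at a
  sprint-like cadence, with the penultimate-foot-contact heel strike
  anchored a known number of frames before each trough and the cutting
  foot's toe off a known number of frames after;
* optional additive Gaussian velocity noise and integer jitter on the
  anchored contact edges.

Ground truth records the *realized* (post-jitter) edges, so zero-error
recovery by the detector is a meaningful end-to-end oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import (
    ContactChannels,
    LabelEvent,
    ManualLabels,
    MotionTrial,
    Side,
    TestType,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticTrial",
    "FailureMode",
    "generate_trial",
    "generate_dataset",
    "make_failure_fixture",
]


class FailureMode(str, Enum):
    """The two documented misdetection scenarios."""

    MIN_TOO_LATE = "MIN_TOO_LATE"  # trough displaced past the true toe off
    IF_OUTSIDE_REGION = "IF_OUTSIDE_REGION"  # true heel strike before the region


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one generated trial.

    Offsets are in frames at ``frame_rate``; defaults keep the true contact
    edges well inside the default −40/+25 search region.
    """

    n_cods: int = 4
    frame_rate: float = 60.0
    cruise_speed: float = 4.0  # m/s between cuts
    trough_speed: float = 0.8  # m/s at the braking minimum
    segment_duration: float = 1.2  # s between consecutive troughs (5 m legs)
    step_rate: float = 3.5  # steps/s at cruise
    duty_factor: float = 0.35  # stance fraction of the step cycle
    if_offset: int = 18  # PFC heel strike, frames before the trough
    ff_offset: int = 10  # FFC toe off, frames after the trough
    velocity_noise_sd: float = 0.1  # m/s additive Gaussian noise
    jitter_sd: float = 0.0  # frames, integer jitter on anchored edges
    seed: int = 0
    trial_id: str = "synthetic-000"
    test_type: TestType = TestType.VCUT
    lead_in: float = 1.5  # s before the first trough
    lead_out: float = 1.5  # s after the last trough

    def __post_init__(self) -> None:
        if not self.trough_speed < self.cruise_speed:
            raise ValueError("trough_speed must be below cruise_speed")
        if not 0 < self.duty_factor < 1:
            raise ValueError("duty_factor must lie in (0, 1)")
        seg_frames = self.segment_duration * self.frame_rate
        if self.if_offset + self.ff_offset >= seg_frames:
            raise ValueError(
                "IF/FF offsets exceed the inter-COD spacing "
                f"({self.if_offset}+{self.ff_offset} >= {seg_frames:.0f} frames)"
            )


@dataclass
class SyntheticTrial:
    trial: MotionTrial
    truth: ManualLabels
    cut_schedule: list[Side]


@dataclass(frozen=True)
class _Step:
    foot: Side
    strike: int  # first contact frame (heel rising edge)
    edge: int  # first airborne frame (toe falling edge)


def _cut_schedule(n_cods: int) -> list[Side]:
    # V-cut convention: two cuts on each leg, alternating, starting right
    return [Side.RIGHT if i % 2 == 0 else Side.LEFT for i in range(n_cods)]


def _speed_profile(
    n: int,
    centers: Sequence[int],
    spec: SyntheticSpec,
    half_width: int,
) -> np.ndarray:
    speed = np.full(n, spec.cruise_speed)
    depth = spec.cruise_speed - spec.trough_speed
    t = np.arange(n)
    for c in centers:
        mask = np.abs(t - c) <= half_width
        speed[mask] -= depth * 0.5 * (1 + np.cos(np.pi * (t[mask] - c) / half_width))
    # sprint start/stop ramps (half-cosine), monotone so no spurious minima
    ramp = int(round(0.9 * spec.frame_rate))
    ramp = min(ramp, max(1, centers[0] - half_width), max(1, n - centers[-1] - half_width))
    if ramp > 1:
        up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        speed[:ramp] *= up
        speed[n - ramp :] *= up[::-1]
    return speed


def _heading_profile(
    n: int, centers: Sequence[int], half_width: int
) -> np.ndarray:
    """Heading in radians, alternating ±67.5° with smooth switches at troughs."""
    ang = math.radians(67.5)
    heading = np.full(n, -ang)
    t = np.arange(n)
    for i, c in enumerate(centers):
        before = -ang if i % 2 == 0 else ang
        after = -before
        s = np.clip((t - (c - half_width)) / (2 * half_width), 0.0, 1.0)
        blend = 0.5 * (1 - np.cos(np.pi * s))
        heading = np.where(t <= c - half_width, heading, before + (after - before) * blend)
    return heading


def _fill_steps(
    prev: _Step, nxt: _Step, period: float, stance: int
) -> list[_Step]:
    """Filler steps between two anchored steps, feet alternating end-to-end.

    The filler count's parity is chosen so the foot sequence alternates from
    ``prev`` to ``nxt`` whenever the gap allows; spacing stays as close to
    the nominal step period as the parity constraint permits.
    """
    gap = nxt.strike - prev.strike
    if gap <= stance + 2:
        return []
    need_odd = prev.foot == nxt.foot
    k0 = max(0, round(gap / period) - 1)
    candidates = [k for k in (k0 - 1, k0, k0 + 1, k0 + 2) if k >= 0 and (k % 2 == 1) == need_odd]
    if not candidates:
        return []
    k = min(candidates, key=lambda k: abs(gap / (k + 1) - period))
    if k == 0:
        return []
    out = []
    foot = prev.foot
    for j in range(1, k + 1):
        foot = foot.other
        strike = prev.strike + int(round(gap * j / (k + 1)))
        edge = min(strike + stance, nxt.strike - 1)
        if strike >= prev.edge and edge > strike:
            out.append(_Step(foot, strike, edge))
    return out


def _generate(
    spec: SyntheticSpec,
    dip_shifts: Mapping[int, int] | None = None,
    if_offset_overrides: Mapping[int, int] | None = None,
) -> SyntheticTrial:
    """Build one trial; the override hooks exist for the failure fixtures."""
    dip_shifts = dict(dip_shifts or {})
    if_offset_overrides = dict(if_offset_overrides or {})
    rng = np.random.default_rng(spec.seed)
    fr = spec.frame_rate
    seg = int(round(spec.segment_duration * fr))
    lead = int(round(spec.lead_in * fr))
    n = lead + (spec.n_cods - 1) * seg + int(round(spec.lead_out * fr))
    contact_centers = [lead + i * seg for i in range(spec.n_cods)]
    dip_centers = [c + dip_shifts.get(i, 0) for i, c in enumerate(contact_centers)]

    half_width = int(round(0.4 * seg))
    speed = _speed_profile(n, dip_centers, spec, half_width)
    heading = _heading_profile(n, dip_centers, half_width)
    if spec.velocity_noise_sd > 0:
        speed = speed + rng.normal(0.0, spec.velocity_noise_sd, n)
    speed = np.clip(speed, 0.0, None)
    vx = speed * np.cos(heading)
    vy = speed * np.sin(heading)

    schedule = _cut_schedule(spec.n_cods)
    stance = max(2, int(round(spec.duty_factor / spec.step_rate * fr)))
    period = fr / spec.step_rate

    def jit() -> int:
        if spec.jitter_sd <= 0:
            return 0
        return int(round(rng.normal(0.0, spec.jitter_sd)))

    anchors: list[_Step] = []
    truth_events: list[LabelEvent] = []
    for i, c in enumerate(contact_centers):
        cut = schedule[i]
        d_if = if_offset_overrides.get(i, spec.if_offset) + jit()
        d_ff = spec.ff_offset + jit()
        d_if = max(stance + 1, d_if)
        d_ff = max(1, d_ff)
        pfc = _Step(cut.other, c - d_if, c - d_if + stance)
        ffc = _Step(cut, c + d_ff - stance, c + d_ff)
        if pfc.edge >= ffc.strike:  # extreme jitter: keep steps disjoint
            ffc = _Step(cut, pfc.edge + 1, c + d_ff)
        anchors.append(pfc)
        anchors.append(ffc)
        truth_events.append(LabelEvent(cod_index=i + 1, if_frame=pfc.strike, ff_frame=ffc.edge))

    steps: list[_Step] = []
    # run-in before the first anchor and run-out after the last
    first, last = anchors[0], anchors[-1]
    foot, strike = first.foot, first.strike
    while True:
        foot = foot.other
        strike = strike - int(round(period))
        if strike < 2:
            break
        steps.append(_Step(foot, strike, strike + stance))
    foot, strike = last.foot, last.strike
    while True:
        foot = foot.other
        strike = strike + int(round(period))
        if strike + stance > n - 2:
            break
        steps.append(_Step(foot, strike, strike + stance))
    steps.extend(anchors)
    # fill gaps between CODs only: the PFC→FFC interval is flight by design
    for j, (prev, nxt) in enumerate(zip(anchors[:-1], anchors[1:])):
        if j % 2 == 0:  # (pfc_i, ffc_i) of the same COD
            continue
        steps.extend(_fill_steps(prev, nxt, period, stance))
    steps.sort(key=lambda s: s.strike)

    chans = {name: np.zeros(n, dtype=np.int8) for name in ContactChannels.channel_names()}
    for s in steps:
        pre = "left" if s.foot is Side.LEFT else "right"
        chans[f"{pre}_heel"][s.strike : s.edge] = 1
        chans[f"{pre}_toe"][s.strike : s.edge] = 1

    trial = MotionTrial(
        trial_id=spec.trial_id,
        test_type=spec.test_type,
        frame_rate=fr,
        trunk_vx=vx,
        trunk_vy=vy,
        contacts=ContactChannels(**chans),
        meta={"generator": "codseg.synthetic", "seed": str(spec.seed)},
    )
    truth = ManualLabels(trial_id=spec.trial_id, events=truth_events)
    return SyntheticTrial(trial=trial, truth=truth, cut_schedule=schedule)


def generate_trial(spec: SyntheticSpec = SyntheticSpec()) -> SyntheticTrial:
    """Generate one V-cut-like trial with ground-truth IF/FF labels."""
    return _generate(spec)


@dataclass
class LabeledItem:
    trial: MotionTrial
    labels: ManualLabels
    stratum: str


@dataclass
class LabeledDataset:
    """Trials with ground truth and a stratification key per item."""

    items: list[LabeledItem] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [it.trial.trial_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("trial_ids must be unique")
        for it in self.items:
            if it.labels.trial_id != it.trial.trial_id:
                raise ValueError(
                    f"labels for {it.labels.trial_id!r} attached to trial "
                    f"{it.trial.trial_id!r}"
                )

    def __len__(self) -> int:
        return len(self.items)

    def n_events(self) -> int:
        return sum(len(it.labels.events) for it in self.items)


_GENDERS = ("M", "F")
_CATEGORIES = ("U13", "U17", "U18")


def generate_dataset(
    n_trials: int,
    base: SyntheticSpec = SyntheticSpec(),
    seed: int = 0,
    stratified: bool = True,
) -> LabeledDataset:
    """Generate a labeled dataset with cohort-like stratification metadata.

    Gender × team category × test type combinations are assigned round-robin
    (12 strata); cruise speed and contact-edge offsets vary per trial within
    ranges that keep the true edges inside the default search region.  With
    ``stratified=False`` all items share one stratum (pooled splitting).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    combos = [
        (g, c, t)
        for g in _GENDERS
        for c in _CATEGORIES
        for t in (TestType.VCUT, TestType.VCUT_BK)
    ]
    items: list[LabeledItem] = []
    for i in range(n_trials):
        g, cat, tt = combos[i % len(combos)]
        cruise = base.cruise_speed + rng.uniform(-0.4, 0.4)
        if tt is TestType.VCUT_BK:
            cruise -= 0.3  # dribbling slows the run slightly
        spec = replace(
            base,
            trial_id=f"syn-{i:03d}",
            test_type=tt,
            cruise_speed=cruise,
            trough_speed=base.trough_speed + rng.uniform(-0.2, 0.2),
            if_offset=int(rng.integers(12, 25)),
            ff_offset=int(rng.integers(6, 15)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        syn = generate_trial(spec)
        syn.trial.meta.update(gender=g, category=cat, repetition=str(i // len(combos)))
        stratum = f"{g}|{cat}|{tt.value}" if stratified else "all"
        items.append(LabeledItem(trial=syn.trial, labels=syn.truth, stratum=stratum))
    return LabeledDataset(items=items)


def make_failure_fixture(
    mode: FailureMode, spec: SyntheticSpec = SyntheticSpec(velocity_noise_sd=0.0)
) -> SyntheticTrial:
    """Trial reproducing one documented misdetection scenario on its 2nd COD
    (MIN_TOO_LATE) or 1st COD (IF_OUTSIDE_REGION); the other CODs stay clean.

    MIN_TOO_LATE displaces the braking trough past the true toe off, so the
    detector latches a later toe-off edge; IF_OUTSIDE_REGION places the true
    heel strike more than ``region_before`` frames before the trough, so the
    detector reports a wrong or missing IF.  Truth still records the true
    edges.
    """
    mode = FailureMode(mode)
    if mode is FailureMode.MIN_TOO_LATE:
        return _generate(spec, dip_shifts={1: spec.ff_offset + 8})
    return _generate(spec, if_offset_overrides={0: 55})
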