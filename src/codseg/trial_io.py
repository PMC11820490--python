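"""Readers and writers for trials, manual labels, results and reports.

Two trial sources are supported: the Xsens MVNX XML export (per-frame
segment velocities plus the software's four binary foot-contact points) and
a plain CSV fallback with one row per frame, so data from other capture
systems can be fed through the same pipeline.
"""

from __future__ import annotations

import csv
import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import EvaluationReport
from .model import (
    CODEvent,
    ContactChannels,
    DetectionParams,
    LabelEvent,
    ManualLabels,
    MotionTrial,
    SegmentationResult,
    TestType,
)

__all__ = [
    "TrialIOError",
    "DEFAULT_TRUNK_SEGMENT",
    "DEFAULT_CONTACT_NAMES",
    "TABULAR_COLUMNS",
    "parse_mvnx",
    "parse_tabular_trial",
    "read_manual_labels",
    "write_manual_labels",
    "write_results",
    "read_results",
    "write_events_csv",
    "write_tabular_trial",
    "write_mvnx",
]


class TrialIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


DEFAULT_TRUNK_SEGMENT = "Pelvis"
# Xsens foot-contact point order
DEFAULT_CONTACT_NAMES = (
    "LeftFoot_Heel",
    "LeftFoot_Toe",
    "RightFoot_Heel",
    "RightFoot_Toe",
)
TABULAR_COLUMNS = (
    "trunk_vx",
    "trunk_vy",
    "left_heel",
    "left_toe",
    "right_heel",
    "right_toe",
)


# ---------------------------------------------------------------------------
# MVNX
# ---------------------------------------------------------------------------

def parse_mvnx(
    path: str | Path,
    trunk_segment: str = DEFAULT_TRUNK_SEGMENT,
    contact_channel_names: Sequence[str] = DEFAULT_CONTACT_NAMES,
) -> MotionTrial:
    """Read an MVNX file into a :class:`MotionTrial`.

    Only ordinary motion frames (``type="normal"``) are kept; calibration
    poses are excluded, and frame indices are 0-based over the motion frames.
    ``trunk_segment`` selects which segment's velocity components provide
    the horizontal speed (the pelvis best proxies whole-body momentum, but a
    thoracic segment can be named instead).
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise TrialIOError(f"{path}: malformed XML: {exc}") from exc
    subject = root.find("{*}subject")
    if subject is None:
        raise TrialIOError(f"{path}: no <subject> element")
    try:
        frame_rate = float(subject.get("frameRate"))
    except (TypeError, ValueError):
        raise TrialIOError(f"{path}: missing or invalid frameRate attribute")

    seg_el = subject.find("{*}segments")
    seg_labels = (
        [s.get("label") for s in seg_el.findall("{*}segment")] if seg_el is not None else []
    )
    if trunk_segment not in seg_labels:
        raise TrialIOError(
            f"{path}: segment {trunk_segment!r} not found "
            f"(available: {', '.join(map(str, seg_labels)) or 'none'})"
        )
    seg_idx = seg_labels.index(trunk_segment)

    fc_def = subject.find("{*}footContactDefinition")
    if fc_def is not None:
        fc_labels = [c.get("label") for c in fc_def.findall("{*}contactDefinition")]
    else:
        fc_labels = list(DEFAULT_CONTACT_NAMES)
    try:
        fc_idx = [fc_labels.index(name) for name in contact_channel_names]
    except ValueError:
        missing = [n for n in contact_channel_names if n not in fc_labels]
        raise TrialIOError(
            f"{path}: foot-contact channel(s) {missing} not found "
            f"(available: {', '.join(map(str, fc_labels))})"
        )

    frames_el = subject.find("{*}frames")
    if frames_el is None:
        raise TrialIOError(f"{path}: no <frames> element")
    vx, vy = [], []
    cols: list[list[int]] = [[], [], [], []]
    for fr in frames_el.findall("{*}frame"):
        if fr.get("type", "normal") != "normal":
            continue
        vel_el = fr.find("{*}velocity")
        fc_el = fr.find("{*}footContacts")
        if vel_el is None or fc_el is None:
            raise TrialIOError(f"{path}: motion frame missing velocity or footContacts")
        vel = vel_el.text.split()
        if len(vel) < 3 * (seg_idx + 1):
            raise TrialIOError(
                f"{path}: velocity vector too short for segment index {seg_idx}"
            )
        vx.append(float(vel[3 * seg_idx]))
        vy.append(float(vel[3 * seg_idx + 1]))
        fc = fc_el.text.split()
        for j, src in enumerate(fc_idx):
            cols[j].append(int(fc[src]))
    if not vx:
        raise TrialIOError(f"{path}: file contains zero motion frames")

    test_type = TestType(subject.get("testType", "VCUT"))
    return MotionTrial(
        trial_id=subject.get("label", path.stem),
        test_type=test_type,
        frame_rate=frame_rate,
        trunk_vx=np.array(vx),
        trunk_vy=np.array(vy),
        contacts=ContactChannels(
            left_heel=np.array(cols[0]),
            left_toe=np.array(cols[1]),
            right_heel=np.array(cols[2]),
            right_toe=np.array(cols[3]),
        ),
        meta={
            k: v
            for k, v in subject.attrib.items()
            if k not in ("frameRate", "label", "testType")
        },
    )


def write_mvnx(
    trial: MotionTrial,
    path: str | Path,
    trunk_segment: str = DEFAULT_TRUNK_SEGMENT,
    n_calibration_frames: int = 3,
) -> None:
    """Write a minimal MVNX-dialect file readable by :func:`parse_mvnx`.

    Velocities of segments other than the trunk are written as zeros; the
    calibration poses carry no kinematics and are skipped on read.
    """
    path = Path(path)
    seg_labels = [trunk_segment, "T8", "Head"]
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', '<mvnx version="4">']
    attrs = f'label="{trial.trial_id}" frameRate="{trial.frame_rate:g}" testType="{trial.test_type.value}"'
    for k, v in trial.meta.items():
        attrs += f' {k}="{v}"'
    lines.append(f"  <subject {attrs}>")
    lines.append("    <segments>")
    for i, lab in enumerate(seg_labels):
        lines.append(f'      <segment id="{i + 1}" label="{lab}"/>')
    lines.append("    </segments>")
    lines.append("    <footContactDefinition>")
    for i, lab in enumerate(DEFAULT_CONTACT_NAMES):
        lines.append(f'      <contactDefinition index="{i}" label="{lab}"/>')
    lines.append("    </footContactDefinition>")
    lines.append(f'    <frames segmentCount="{len(seg_labels)}">')
    for k in range(n_calibration_frames):
        kind = ("identity", "tpose", "tpose-isb")[k % 3]
        lines.append(f'      <frame time="0" type="{kind}"/>')
    c = trial.contacts
    zeros = " ".join(["0 0 0"] * (len(seg_labels) - 1))
    for t in range(trial.n_frames):
        vel = f"{float(trial.trunk_vx[t])!r} {float(trial.trunk_vy[t])!r} 0"
        if zeros:
            vel = f"{vel} {zeros}"
        fc = f"{c.left_heel[t]} {c.left_toe[t]} {c.right_heel[t]} {c.right_toe[t]}"
        lines.append(
            f'      <frame time="{t}" index="{t}" type="normal">'
            f"<velocity>{vel}</velocity><footContacts>{fc}</footContacts></frame>"
        )
    lines.append("    </frames>")
    lines.append("  </subject>")
    lines.append("</mvnx>")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tabular fallback
# ---------------------------------------------------------------------------

def parse_tabular_trial(
    path: str | Path,
    frame_rate: float,
    trial_id: str | None = None,
    test_type: TestType = TestType.VCUT,
) -> MotionTrial:
    """Read the CSV fallback format (one row per frame).

    Required columns: ``trunk_vx, trunk_vy, left_heel, left_toe, right_heel,
    right_toe``.  Contact values must be 0/1; the first offending 0-based
    data row is named in the error.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TABULAR_COLUMNS if c not in df.columns]
    if missing:
        raise TrialIOError(f"{path}: missing column(s): {', '.join(missing)}")
    for col in TABULAR_COLUMNS[2:]:
        vals = df[col].to_numpy()
        bad = np.flatnonzero(~np.isin(vals, (0, 1)))
        if len(bad):
            raise TrialIOError(
                f"{path}: contact column {col!r} has non-binary value "
                f"{vals[bad[0]]!r} at row {bad[0]}"
            )
    return MotionTrial(
        trial_id=trial_id or path.stem,
        test_type=test_type,
        frame_rate=frame_rate,
        trunk_vx=df["trunk_vx"].to_numpy(float),
        trunk_vy=df["trunk_vy"].to_numpy(float),
        contacts=ContactChannels(
            left_heel=df["left_heel"].to_numpy(),
            left_toe=df["left_toe"].to_numpy(),
            right_heel=df["right_heel"].to_numpy(),
            right_toe=df["right_toe"].to_numpy(),
        ),
    )


def write_tabular_trial(trial: MotionTrial, path: str | Path) -> None:
    c = trial.contacts
    pd.DataFrame(
        {
            "trunk_vx": trial.trunk_vx,
            "trunk_vy": trial.trunk_vy,
            "left_heel": c.left_heel,
            "left_toe": c.left_toe,
            "right_heel": c.right_heel,
            "right_toe": c.right_toe,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Manual labels
# ---------------------------------------------------------------------------

def read_manual_labels(path: str | Path, trial_id: str | None = None) -> ManualLabels:
    """Read a manual-label CSV with columns cod_index, if_frame, ff_frame."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("cod_index", "if_frame", "ff_frame") if c not in df.columns]
    if missing:
        raise TrialIOError(f"{path}: missing column(s): {', '.join(missing)}")
    try:
        events = [
            LabelEvent(int(r.cod_index), int(r.if_frame), int(r.ff_frame))
            for r in df.itertuples()
        ]
        return ManualLabels(trial_id=trial_id or path.stem, events=events)
    except ValueError as exc:
        raise TrialIOError(f"{path}: {exc}") from exc


def write_manual_labels(labels: ManualLabels, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cod_index", "if_frame", "ff_frame"])
        for e in labels.events:
            w.writerow([e.cod_index, e.if_frame, e.ff_frame])


# ---------------------------------------------------------------------------
# Results and reports
# ---------------------------------------------------------------------------

def write_results(
    result: SegmentationResult,
    path: str | Path,
    report: EvaluationReport | None = None,
) -> None:
    """Write a segmentation result (and optional report) as JSON."""
    doc = {
        "trial_id": result.trial_id,
        "test_type": result.test_type.value,
        "frame_rate": result.frame_rate,
        "params": result.params_used.to_dict(),
        "events": [e.to_dict() for e in result.events],
    }
    if report is not None:
        doc["report"] = report.to_dict()
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_results(
    path: str | Path,
) -> tuple[SegmentationResult, EvaluationReport | None]:
    doc = json.loads(Path(path).read_text())
    result = SegmentationResult(
        trial_id=doc["trial_id"],
        test_type=TestType(doc.get("test_type", "VCUT")),
        frame_rate=float(doc.get("frame_rate", 60.0)),
        params_used=DetectionParams.from_dict(doc["params"]),
        events=[CODEvent.from_dict(e) for e in doc["events"]],
    )
    report = (
        EvaluationReport.from_dict(doc["report"]) if doc.get("report") is not None else None
    )
    return result, report


def write_events_csv(result: SegmentationResult, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["cod_index", "minimum_frame", "if_frame", "ff_frame", "pfc_side", "ffc_side", "status"]
        )
        for e in result.events:
            d = e.to_dict()
            w.writerow([d[k] if d[k] is not None else "" for k in (
                "cod_index", "minimum_frame", "if_frame", "ff_frame", "pfc_side", "ffc_side", "status"
            )])
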