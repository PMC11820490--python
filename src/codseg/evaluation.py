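"""Automatic-vs-manual agreement statistics.

All frame differences are signed *automatic − manual*.  The battery mirrors
common method-comparison practice in movement analysis: distribution
summaries (median / mode / IQR), mean absolute error |E| and error SD s(E),
average precision AP_k (percentage of events detected within k frames),
Bland–Altman bias with 1.96·SD limits of agreement, Pearson correlation of
total cutting times, and a pooled RMSE used as the tuning objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Literal, Mapping

import numpy as np
from scipy import stats as sstats
from scipy.optimize import linear_sum_assignment

from .model import ManualLabels, SegmentationResult

__all__ = [
    "EventPair",
    "KindSummary",
    "EvaluationReport",
    "match_events",
    "difference_summaries",
    "error_stats",
    "average_precision",
    "bland_altman",
    "cutting_time_correlation",
    "rmse",
    "build_report",
]

Kind = Literal["IF", "FF"]


@dataclass(frozen=True)
class EventPair:
    """One manual COD paired with (at most) one automatic event."""

    cod_index: int
    manual_if: int
    manual_ff: int
    auto_if: int | None = None
    auto_ff: int | None = None
    matched: bool = True  # False: no automatic event paired at all

    def diff(self, kind: Kind) -> int | None:
        if not self.matched:
            return None
        if kind == "IF":
            return None if self.auto_if is None else self.auto_if - self.manual_if
        return None if self.auto_ff is None else self.auto_ff - self.manual_ff


def match_events(
    auto: SegmentationResult,
    manual: ManualLabels,
    max_separation: int | None = None,
) -> list[EventPair]:
    """Pair automatic events with manual CODs.

    Equal counts pair in time order.  Otherwise a minimum-total-distance
    assignment between automatic minimum frames and manual event midpoints
    is used, capped at ``max_separation`` frames (default: one search-region
    width from the detection parameters).  Every manual event yields exactly
    one pair; manual events without an automatic partner are flagged
    unmatched, surplus automatic events are dropped.
    """
    if max_separation is None:
        max_separation = auto.params_used.region_width
    mans = manual.events
    autos = auto.events
    pairs: list[EventPair] = []
    if len(autos) == len(mans):
        assign = {j: j for j in range(len(mans))}
    else:
        mids = np.array([(e.if_frame + e.ff_frame) / 2.0 for e in mans])
        mins = np.array([e.minimum_frame for e in autos])
        if len(mins) == 0:
            assign = {}
        else:
            cost = np.abs(mins[None, :] - mids[:, None])
            big = max_separation * 1000.0 + 1.0
            cost = np.where(cost > max_separation, big, cost)
            rows, cols = linear_sum_assignment(cost)
            assign = {
                int(r): int(c)
                for r, c in zip(rows, cols)
                if cost[r, c] <= max_separation
            }
    for j, ev in enumerate(mans):
        a = autos[assign[j]] if j in assign else None
        pairs.append(
            EventPair(
                cod_index=ev.cod_index,
                manual_if=ev.if_frame,
                manual_ff=ev.ff_frame,
                auto_if=None if a is None else a.if_frame,
                auto_ff=None if a is None else a.ff_frame,
                matched=a is not None,
            )
        )
    return pairs


def _diffs(pairs: Iterable[EventPair], kind: Kind) -> np.ndarray:
    vals = [p.diff(kind) for p in pairs]
    return np.array([v for v in vals if v is not None], dtype=float)


def difference_summaries(
    pairs: Iterable[EventPair], kind: Kind
) -> tuple[float, int, float]:
    """(median, mode, IQR) of signed differences for one event kind.

    IQR is Q3−Q1 with linear interpolation; the mode is the most frequent
    integer difference, ties broken toward the smallest absolute value and
    then the smaller value.
    """
    d = _diffs(pairs, kind)
    if len(d) == 0:
        raise ValueError(f"no matched {kind} differences")
    median = float(np.median(d))
    q1, q3 = np.percentile(d, [25, 75])
    values, counts = np.unique(d.astype(int), return_counts=True)
    order = sorted(
        zip(values, counts), key=lambda vc: (-vc[1], abs(vc[0]), vc[0])
    )
    mode = int(order[0][0])
    return median, mode, float(q3 - q1)


def error_stats(pairs: Iterable[EventPair], kind: Kind) -> tuple[float, float]:
    """|E| (mean absolute error) and s(E) (sample SD of signed error)."""
    d = _diffs(pairs, kind)
    if len(d) < 2:
        raise ValueError(f"need at least 2 matched {kind} differences, got {len(d)}")
    return float(np.mean(np.abs(d))), float(np.std(d, ddof=1))


def average_precision(pairs: Iterable[EventPair], kind: Kind, k: float) -> float:
    """AP_k: percentage of manual events detected within k frames.

    Undetected or unmatched events count in the denominator only, so
    misdetections lower the score.
    """
    pairs = list(pairs)
    n = len(pairs)
    if n == 0:
        raise ValueError("no events to score")
    hits = sum(1 for p in pairs if (d := p.diff(kind)) is not None and abs(d) <= k)
    return 100.0 * hits / n


def bland_altman(pairs: Iterable[EventPair], kind: Kind) -> tuple[float, float, float]:
    """(bias, loa_low, loa_high) with the standard 1.96·SD limits."""
    d = _diffs(pairs, kind)
    if len(d) < 2:
        raise ValueError("Bland–Altman needs at least 2 matched differences")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def cutting_time_correlation(
    pairs: Iterable[EventPair],
    frame_rate: float,
    method: Literal["pearson", "identity_line"] = "pearson",
) -> tuple[float, float]:
    """(r, R²) between automatic and manual total cutting times (ms).

    Total cutting time per COD is (FF − IF)·1000/frame_rate.  With the
    default ``pearson`` method R² is the square of Pearson r; the
    ``identity_line`` variant instead reports 1 − SS_res/SS_tot about the
    y = x line (r is Pearson r in both cases).
    """
    usable = [
        p
        for p in pairs
        if p.matched and p.auto_if is not None and p.auto_ff is not None
    ]
    if len(usable) < 3:
        raise ValueError("need at least 3 fully detected pairs")
    ms = 1000.0 / frame_rate
    auto_t = np.array([(p.auto_ff - p.auto_if) * ms for p in usable])
    man_t = np.array([(p.manual_ff - p.manual_if) * ms for p in usable])
    if np.ptp(auto_t) == 0 or np.ptp(man_t) == 0:
        raise ValueError("degenerate: zero variance in cutting times")
    r = float(sstats.pearsonr(auto_t, man_t).statistic)
    if method == "pearson":
        r2 = r * r
    else:
        ss_res = float(np.sum((auto_t - man_t) ** 2))
        ss_tot = float(np.sum((auto_t - np.mean(auto_t)) ** 2))
        r2 = 1.0 - ss_res / ss_tot
    return r, r2


def rmse(
    pairs: Iterable[EventPair],
    penalty: float | None = None,
    region_width: int = 65,
) -> float:
    """Pooled RMSE over IF and FF differences, the tuning objective.

    Each missing side of a matched pair, and each unmatched manual event,
    contributes one ``penalty`` term (default: squared region width) to the
    mean, so parameter sets that drop events are penalised rather than
    rewarded.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no events")
    if penalty is None:
        penalty = float(region_width) ** 2
    total = 0.0
    n = 0
    for p in pairs:
        if not p.matched:
            total += penalty
            n += 1
            continue
        for kind in ("IF", "FF"):
            d = p.diff(kind)  # type: ignore[arg-type]
            if d is None:
                total += penalty
            else:
                total += float(d) ** 2
            n += 1
    return float(np.sqrt(total / n))


@dataclass
class KindSummary:
    """Agreement summary for one event kind (IF or FF)."""

    median: float
    mode: int
    iqr: float
    abs_mean_error: float
    error_sd: float
    ap: dict[int, float]
    bias: float
    loa_low: float
    loa_high: float
    n_matched: int
    n_unmatched: int

    def to_dict(self) -> dict[str, Any]:
        d = self.__dict__.copy()
        d["ap"] = {str(k): v for k, v in self.ap.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "KindSummary":
        d = dict(d)
        d["ap"] = {int(k): float(v) for k, v in d["ap"].items()}
        return cls(**d)


@dataclass
class EvaluationReport:
    """Full agreement bundle for one set of trials."""

    if_summary: KindSummary
    ff_summary: KindSummary
    rmse: float
    pearson_r: float | None = None
    r_squared: float | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "if_summary": self.if_summary.to_dict(),
            "ff_summary": self.ff_summary.to_dict(),
            "rmse": self.rmse,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "extra": self.extra,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "EvaluationReport":
        return cls(
            if_summary=KindSummary.from_dict(d["if_summary"]),
            ff_summary=KindSummary.from_dict(d["ff_summary"]),
            rmse=d["rmse"],
            pearson_r=d.get("pearson_r"),
            r_squared=d.get("r_squared"),
            extra=dict(d.get("extra", {})),
        )


def _kind_summary(
    pairs: list[EventPair], kind: Kind, ap_thresholds: Iterable[int]
) -> KindSummary:
    median, mode, iqr = difference_summaries(pairs, kind)
    abs_e, sd_e = error_stats(pairs, kind)
    bias, lo, hi = bland_altman(pairs, kind)
    matched = sum(1 for p in pairs if p.diff(kind) is not None)
    return KindSummary(
        median=median,
        mode=mode,
        iqr=iqr,
        abs_mean_error=abs_e,
        error_sd=sd_e,
        ap={int(k): average_precision(pairs, kind, k) for k in ap_thresholds},
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        n_matched=matched,
        n_unmatched=len(pairs) - matched,
    )


def build_report(
    pairs: list[EventPair],
    frame_rate: float,
    ap_thresholds: Iterable[int] = (2, 3, 4),
    region_width: int = 65,
    r2_method: Literal["pearson", "identity_line"] = "pearson",
) -> EvaluationReport:
    """Assemble the full agreement report from matched pairs."""
    r: float | None
    try:
        r, r2 = cutting_time_correlation(pairs, frame_rate, method=r2_method)
    except ValueError:
        r, r2 = None, None
    return EvaluationReport(
        if_summary=_kind_summary(pairs, "IF", ap_thresholds),
        ff_summary=_kind_summary(pairs, "FF", ap_thresholds),
        rmse=rmse(pairs, region_width=region_width),
        pearson_r=r,
        r_squared=r2,
    )
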