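"""Trunk horizontal speed, zero-phase low-pass filtering, and trough finding.

The detector's anchor signal is the trunk's horizontal speed
``V_hor[t] = sqrt(vx[t]^2 + vy[t]^2)``, low-pass filtered with a 4th-order
Butterworth design applied forward and backward (zero phase lag, doubled
magnitude attenuation).  Braking troughs are interior local minima whose
topographic prominence — depth relative to the lower of the two enclosing
higher flanks — meets a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .model import MotionTrial

__all__ = [
    "VelocityMinimum",
    "VelocityTrace",
    "horizontal_speed",
    "lowpass_filter",
    "velocity_trace",
    "find_velocity_minima",
]


@dataclass(frozen=True)
class VelocityMinimum:
    frame: int
    value: float
    prominence: float


@dataclass
class VelocityTrace:
    raw: np.ndarray
    filtered: np.ndarray
    frame_rate: float


def horizontal_speed(trial: MotionTrial) -> np.ndarray:
    """Euclidean norm of the trunk velocity components in the horizontal plane."""
    return np.hypot(trial.trunk_vx, trial.trunk_vy)


def min_filter_length(order: int = 4) -> int:
    """Smallest series length filtfilt accepts with default padding."""
    # padlen default is 3 * max(len(a), len(b)) = 3 * (order + 1); need len > padlen
    return 3 * (order + 1) + 1


def lowpass_filter(
    series: np.ndarray,
    frame_rate: float,
    cutoff: float = 1.5,
    order: int = 4,
    pad_method: str | None = "odd",
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (design applied forward and backward).

    Parameters
    ----------
    series
        Speed samples, m/s.
    frame_rate
        Sampling rate, Hz.
    cutoff
        −3 dB frequency of the one-way design, Hz; must be below Nyquist.
    order
        Order of the one-way design; the two-way magnitude response is the
        square of the one-way response.
    pad_method
        Edge padding passed to ``scipy.signal.filtfilt`` (``"odd"``,
        ``"even"``, ``"constant"`` or ``None``).
    """
    x = np.asarray(series, dtype=float)
    nyq = frame_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz, got {cutoff}")
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    minlen = min_filter_length(order)
    if len(x) < minlen:
        raise ValueError(
            f"series of length {len(x)} too short for stable two-way filtering; "
            f"need at least {minlen} samples"
        )
    b, a = signal.butter(order, cutoff, btype="low", fs=frame_rate)
    return signal.filtfilt(b, a, x, padtype=pad_method)


def velocity_trace(
    trial: MotionTrial,
    cutoff: float = 1.5,
    order: int = 4,
    pad_method: str | None = "odd",
) -> VelocityTrace:
    raw = horizontal_speed(trial)
    filt = lowpass_filter(raw, trial.frame_rate, cutoff, order, pad_method)
    return VelocityTrace(raw=raw, filtered=filt, frame_rate=trial.frame_rate)


def find_velocity_minima(
    filtered: np.ndarray, prominence: float = 1.5
) -> list[VelocityMinimum]:
    """Interior local minima whose prominence meets ``prominence``.

    Prominence is the standard peak prominence computed on the negated
    series.  Endpoints are never minima; a plateau minimum is reported at its
    first frame (deterministic tie-break).
    """
    x = np.asarray(filtered, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    peaks, props = signal.find_peaks(-x, prominence=prominence, plateau_size=1)
    out = [
        VelocityMinimum(frame=int(lf), value=float(x[lf]), prominence=float(p))
        for lf, p in zip(props["left_edges"], props["prominences"])
    ]
    return sorted(out, key=lambda m: m.frame)
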