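"""VeDBA and multi-scale wrap-corrected angular velocities (AVeY/AVeP/AVeR, AAV).

The derivation pipeline mirrors the field protocol: orientation angles are
presmoothed with a 2 s window at the native rate (linear mean for pitch and
roll, circular mean for yaw), the streams are subsampled to 1 Hz by plain
selection (every 40th sample at 40 Hz), and angular velocities are plain
finite differences of the smoothed values over steps of 1, 5 and 10 samples.
Yaw differences are wrap-corrected so a 10° → 350° change reads as a 20°
anticlockwise turn (-20), never a 330° clockwise one; the largest possible
per-step value is therefore ±180°.  Multi-scale AVeY values are raw
differences over the interval (°/5s, °/10s), not per-second rescalings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .logger_io import SensorSeries, subsample
from .orientation import circular_smooth, derive_orientation, smooth
from .magcal import EllipsoidFit

__all__ = [
    "RotationMetricsSeries",
    "vedba",
    "wrap_delta",
    "angular_velocity",
    "aav",
    "compute_metrics",
]


@dataclass
class RotationMetricsSeries:
    """Time-aligned activity metrics at the analysis (post-subsampling) rate.

    vedba in g; avep/aver/avey_1/aav in °/s; avey_5 in °/5s; avey_10 in
    °/10s.  ``heading`` carries the presmoothed yaw series the differentials
    were taken from, for downstream circular summaries and CuHe.
    """

    t: np.ndarray
    vedba: np.ndarray
    avep: np.ndarray
    aver: np.ndarray
    avey_1: np.ndarray
    avey_5: np.ndarray
    avey_10: np.ndarray
    aav: np.ndarray
    heading: np.ndarray | None = None
    rate_hz: float = 1.0

    def __len__(self) -> int:
        return self.t.shape[0]

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time": self.t,
            "vedba": self.vedba,
            "avep": self.avep,
            "aver": self.aver,
            "avey_1": self.avey_1,
            "avey_5": self.avey_5,
            "avey_10": self.avey_10,
            "aav": self.aav,
        }
        if self.heading is not None:
            data["heading"] = self.heading
        return pd.DataFrame(data)


def vedba(acc: np.ndarray, window_s: float = 2.0, rate_hz: float = 40.0) -> np.ndarray:
    """Vectorial dynamic body acceleration, g.

    Static acceleration is a centred ``window_s`` running mean per channel;
    the dynamic component is raw minus static; VeDBA is the Euclidean norm of
    the three dynamic components.
    """
    acc = np.asarray(acc, dtype=float).reshape(-1, 3)
    if acc.shape[0] == 0:
        raise ValueError("empty series")
    static = np.column_stack([smooth(acc[:, i], window_s, rate_hz) for i in range(3)])
    dyn = acc - static
    return np.linalg.norm(dyn, axis=1)


def wrap_delta(h_prev, h_curr):
    """Wrap-corrected heading difference in [-180, 180].

    ``d = h_curr - h_prev``; 360 is added when d < -180 and subtracted when
    d > 180 (strict inequalities, so an exact half-revolution keeps its sign).
    Inputs are headings in [0, 360); scalars or arrays.
    """
    d = np.asarray(h_curr, dtype=float) - np.asarray(h_prev, dtype=float)
    d = np.where(d < -180.0, d + 360.0, d)
    d = np.where(d > 180.0, d - 360.0, d)
    if np.ndim(d) == 0:
        return float(d)
    return d


def angular_velocity(
    angle, step_s: float, rate_hz: float = 1.0, circular: bool = False
) -> np.ndarray:
    """Finite difference ``x[i] - x[i-step]`` of a smoothed angle series.

    Units are degrees per step interval (°/s for step 1 at 1 Hz, °/5s for
    step 5, …) — raw differences, not rescaled.  The first ``step`` outputs
    are NaN.  With ``circular=True`` the difference is wrap-corrected via
    :func:`wrap_delta` (for yaw); pitch/roll are bounded in ±90° so their
    differences never need wrapping.
    """
    x = np.asarray(angle, dtype=float)
    step = int(round(step_s * rate_hz))
    if step < 1:
        raise ValueError(f"step must span at least one sample, got {step}")
    if step >= x.shape[0]:
        raise ValueError(f"step {step} >= series length {x.shape[0]}")
    out = np.full(x.shape[0], np.nan)
    if circular:
        out[step:] = wrap_delta(x[:-step], x[step:])
    else:
        out[step:] = x[step:] - x[:-step]
    return out


def aav(avep, aver, avey) -> np.ndarray:
    """Absolute angular velocity: per-sample norm of (AVeP, AVeR, AVeY), °/s."""
    p = np.asarray(avep, dtype=float)
    r = np.asarray(aver, dtype=float)
    y = np.asarray(avey, dtype=float)
    if not (p.shape == r.shape == y.shape):
        raise ValueError(f"misaligned lengths: {p.shape}, {r.shape}, {y.shape}")
    return np.sqrt(p * p + r * r + y * y)


def compute_metrics(
    series: SensorSeries,
    fit: EllipsoidFit | None = None,
    window_s: float = 2.0,
    subsample_n: int = 40,
    scales: tuple[int, ...] = (1, 5, 10),
    post_smooth_s: float | None = None,
) -> RotationMetricsSeries:
    """Full metrics chain from a raw series: smooth → subsample → differentiate.

    VeDBA is computed at the native rate and subsampled alongside the
    orientation angles.  ``post_smooth_s``, if given, applies an additional
    linear running mean to the AVeY channels after differentiation (a
    display-oriented option, off by default).
    """
    ori = derive_orientation(series, window_s=window_s, fit=fit)
    pitch_s = smooth(ori.pitch, window_s, series.rate_hz)
    roll_s = smooth(ori.roll, window_s, series.rate_hz)
    head_s = circular_smooth(ori.heading, window_s, series.rate_hz)
    ved = vedba(series.acc, window_s, series.rate_hz)

    sl = slice(None, None, subsample_n)
    t1 = series.t[sl]
    rate1 = series.rate_hz / subsample_n
    pitch1, roll1, head1, ved1 = pitch_s[sl], roll_s[sl], head_s[sl], ved[sl]

    avep = angular_velocity(pitch1, 1, rate1, circular=False)
    aver = angular_velocity(roll1, 1, rate1, circular=False)
    avey = {k: angular_velocity(head1, k, rate1, circular=True) for k in scales}
    if post_smooth_s:
        avey = {k: smooth(v, post_smooth_s, rate1) for k, v in avey.items()}
    base = min(scales)
    return RotationMetricsSeries(
        t=t1,
        vedba=ved1,
        avep=avep,
        aver=aver,
        avey_1=avey.get(1, avey[base]),
        avey_5=avey.get(5, np.full_like(t1, np.nan)),
        avey_10=avey.get(10, np.full_like(t1, np.nan)),
        aav=aav(avep, aver, avey.get(1, avey[base])),
        heading=head1,
        rate_hz=rate1,
    )
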