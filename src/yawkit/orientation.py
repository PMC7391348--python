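"""Static acceleration, pitch/roll, tilt-compensated heading, circular stats.

Conventions
-----------
Body axes: x surge (anterior), y sway, z heave (dorsal).  A level, motionless
tag reads static acceleration (0, 0, 1) g.  Pitch is positive nose-up, roll
positive to the sway side, both reported in [-90, +90]°.  Heading is degrees
clockwise from magnetic North in [0, 360): North 0°/360°, East 90°, South
180°, West 270°, from

    H = mod(360 + atan2(-m_y, m_x) * 180/pi, 360)

where (m_x, m_y) are the calibrated, tilt-corrected horizontal magnetometer
components.

Pitch and roll come from the smoothed (static) gravity vector S:

    pitch = atan2(S_x, sqrt(S_y^2 + S_z^2)) * 180/pi
    roll  = atan2(S_y, sqrt(S_x^2 + S_z^2)) * 180/pi

Tilt correction de-rotates the mag vector by roll about the surge axis and
then by pitch about the sway axis.  With this roll formula the de-rotation is
exact whenever pitch and roll are not simultaneously large (the roll above
equals the Euler roll only at zero pitch); this matches the operating regime
of carapace-mounted tags on slow swimmers, and degrades gracefully — never
catastrophically — outside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .logger_io import SensorSeries
from .magcal import EllipsoidFit, apply_calibration

__all__ = [
    "OrientationSeries",
    "smooth",
    "pitch_roll",
    "tilt_correct",
    "heading",
    "circular_mean",
    "circular_smooth",
    "derive_orientation",
]

#: horizontal mag component below this fraction of |m| flags heading invalid
_HORIZONTAL_TOL = 1e-6
#: mean resultant length below this flags a circular mean undefined
_RESULTANT_TOL = 1e-12


@dataclass
class OrientationSeries:
    """Per-sample pitch, roll (deg, [-90, 90]) and heading (deg, [0, 360)).

    ``valid`` is False where the derivation is degenerate (zero static
    vector, or magnetic field parallel to the body vertical); pitch/roll/
    heading are NaN there.
    """

    t: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    heading: np.ndarray
    valid: np.ndarray
    rate_hz: float

    def __len__(self) -> int:
        return self.t.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.t,
                "pitch": self.pitch,
                "roll": self.roll,
                "heading": self.heading,
                "valid": self.valid.astype(int),
            }
        )


def _window_bounds(n: int, window_s: float, rate_hz: float) -> np.ndarray:
    """Per-sample symmetric half-width in samples, truncated at the edges."""
    if n == 0:
        raise ValueError("empty series")
    if window_s <= 0:
        raise ValueError(f"window_s must be positive, got {window_s}")
    half = int(round(window_s * rate_hz / 2.0))
    i = np.arange(n)
    return np.minimum(half, np.minimum(i, n - 1 - i))


def smooth(x, window_s: float, rate_hz: float) -> np.ndarray:
    """Centred running mean, window truncated symmetrically at the edges.

    The window covers samples i-h .. i+h with h = round(window_s*rate_hz/2)
    (2h+1 points), shrinking symmetrically near the boundaries so the output
    has the same length as the input.  Non-finite samples are excluded from
    each window's mean rather than poisoning it.
    """
    x = np.asarray(x, dtype=float)
    h = _window_bounds(x.shape[0], window_s, rate_hz)
    finite = np.isfinite(x)
    xs = np.concatenate([[0.0], np.cumsum(np.where(finite, x, 0.0))])
    cnt = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])
    i = np.arange(x.shape[0])
    total = xs[i + h + 1] - xs[i - h]
    num = cnt[i + h + 1] - cnt[i - h]
    with np.errstate(invalid="ignore"):
        out = np.where(num > 0, total / np.maximum(num, 1), np.nan)
    return out


def pitch_roll(static_acc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pitch and roll (degrees) from static acceleration vectors, shape (n, 3).

    Returns ``(pitch, roll, valid)``; samples with a (near-)zero static vector
    are marked invalid and carry NaN angles.
    """
    s = np.asarray(static_acc, dtype=float).reshape(-1, 3)
    sx, sy, sz = s.T
    norm = np.linalg.norm(s, axis=1)
    valid = np.isfinite(norm) & (norm > 1e-12)
    with np.errstate(invalid="ignore"):
        pitch = np.degrees(np.arctan2(sx, np.hypot(sy, sz)))
        roll = np.degrees(np.arctan2(sy, np.hypot(sx, sz)))
    pitch = np.where(valid, pitch, np.nan)
    roll = np.where(valid, roll, np.nan)
    return pitch, roll, valid


def tilt_correct(
    mag: np.ndarray, pitch: np.ndarray, roll: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotate calibrated mag vectors into the horizontal frame.

    De-rotates by roll about the surge (x) axis, then by pitch about the sway
    (y) axis.  Returns ``(m_x, m_y, valid)`` where ``valid`` is False when the
    horizontal component is negligible relative to the field magnitude (field
    parallel to the body vertical: heading undefined).
    """
    m = np.asarray(mag, dtype=float).reshape(-1, 3)
    beta = np.radians(np.asarray(pitch, dtype=float))
    phi = np.radians(np.asarray(roll, dtype=float))
    mx, my, mz = m.T
    cphi, sphi = np.cos(phi), np.sin(phi)
    # un-roll: Rx(roll)
    m1y = cphi * my - sphi * mz
    m1z = sphi * my + cphi * mz
    cb, sb = np.cos(beta), np.sin(beta)
    # un-pitch: Ry(-pitch)
    hx = cb * mx - sb * m1z
    hy = m1y
    norm = np.linalg.norm(m, axis=1)
    with np.errstate(invalid="ignore"):
        valid = (
            np.isfinite(hx)
            & np.isfinite(hy)
            & (norm > 0)
            & (np.hypot(hx, hy) > _HORIZONTAL_TOL * norm)
        )
    return hx, hy, valid


def heading(m_x, m_y) -> np.ndarray:
    """Compass heading in [0, 360) from horizontal-frame mag components.

    North maps to 0°/360°, East to 90°, South to 180°, West to 270°.
    (0, 0) yields NaN.
    """
    m_x = np.asarray(m_x, dtype=float)
    m_y = np.asarray(m_y, dtype=float)
    with np.errstate(invalid="ignore"):
        h = np.mod(360.0 + np.degrees(np.arctan2(-m_y, m_x)), 360.0)
    zero = (m_x == 0) & (m_y == 0)
    if np.ndim(h) == 0:
        return float("nan") if zero else float(h)
    return np.where(zero, np.nan, h)


def circular_mean(angles_deg) -> float:
    """Mean direction (degrees, [0, 360)) of a set of angles.

    Angles are mapped to unit vectors, averaged, and the resultant direction
    converted back to degrees.  NaN angles are ignored; if no finite angle
    remains or the mean resultant length is below 1e-12 (antipodal
    cancellation) the mean is undefined and NaN is returned.  Empty input
    raises ValueError.
    """
    a = np.asarray(angles_deg, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("circular_mean of empty sequence")
    a = a[np.isfinite(a)]
    if a.size == 0:
        return float("nan")
    rad = np.radians(a)
    s, c = np.sin(rad).mean(), np.cos(rad).mean()
    if np.hypot(s, c) < _RESULTANT_TOL:
        return float("nan")
    return float(np.mod(360.0 + np.degrees(np.arctan2(s, c)), 360.0))


def circular_smooth(heading_deg, window_s: float, rate_hz: float) -> np.ndarray:
    """Rolling circular mean of a heading series (wrap-safe smoothing).

    Same window geometry as :func:`smooth` but each window is averaged on the
    unit circle, so e.g. {359°, 1°} smooths to ≈0°, never 180°.  Windows whose
    resultant vanishes (or contain no finite sample) yield NaN.
    """
    h = np.asarray(heading_deg, dtype=float)
    hw = _window_bounds(h.shape[0], window_s, rate_hz)
    rad = np.radians(h)
    finite = np.isfinite(rad)
    sin_c = np.concatenate([[0.0], np.cumsum(np.where(finite, np.sin(rad), 0.0))])
    cos_c = np.concatenate([[0.0], np.cumsum(np.where(finite, np.cos(rad), 0.0))])
    cnt = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])
    i = np.arange(h.shape[0])
    num = cnt[i + hw + 1] - cnt[i - hw]
    with np.errstate(invalid="ignore"):
        s = (sin_c[i + hw + 1] - sin_c[i - hw]) / np.maximum(num, 1)
        c = (cos_c[i + hw + 1] - cos_c[i - hw]) / np.maximum(num, 1)
        out = np.mod(360.0 + np.degrees(np.arctan2(s, c)), 360.0)
    out[(num == 0) | (np.hypot(s, c) < _RESULTANT_TOL)] = np.nan
    return out


def derive_orientation(
    series: SensorSeries,
    window_s: float = 2.0,
    fit: EllipsoidFit | None = None,
) -> OrientationSeries:
    """Full per-sample orientation chain: static acc → pitch/roll → heading.

    Parameters
    ----------
    series : SensorSeries
        Raw (or already calibrated) logger series.
    window_s : float
        Running-mean window for the static (gravity) component; 2 s default.
    fit : EllipsoidFit, optional
        If given, hard/soft-iron calibration is applied to the mag channels
        first; otherwise the mag channels are assumed already calibrated.
    """
    if fit is not None:
        series = apply_calibration(series, fit)
    static = np.column_stack(
        [smooth(series.acc[:, i], window_s, series.rate_hz) for i in range(3)]
    )
    pitch, roll, valid_pr = pitch_roll(static)
    hx, hy, valid_h = tilt_correct(series.mag, pitch, roll)
    head = heading(hx, hy)
    valid = valid_pr & valid_h
    head = np.where(valid, head, np.nan)
    return OrientationSeries(
        t=series.t, pitch=pitch, roll=roll, heading=head, valid=valid, rate_hz=series.rate_hz
    )
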