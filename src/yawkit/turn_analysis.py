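"""Threshold-crossing turn counters and cumulative heading (CuHe).

Turn coverage runs a conditional signed cumulative sum over wrap-corrected
yaw angular velocity (AVeY, °/s): rotation in one direction accumulates,
rotation in the other decrements, and every time the accumulator magnitude
reaches a threshold angle (20/45/90/180° by default) a turn event of that
sign is emitted and the accumulator resets.  The running state is expressed
as a signed percentage of the threshold (0 to ±100, + clockwise,
- anticlockwise).

Cumulative heading (CuHe) instead tracks *which* yaw orientations have been
occupied: the circle is split into bins (1° default) and a bin counts as
visited when any sample — or any bin swept between consecutive samples along
the shorter wrap-corrected arc — falls in it.  The visited percentage is
monotone between resets; when all 360° have been covered at least once the
counter registers a full revolution and clears (re-marking the current bin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rotation_metrics import wrap_delta

__all__ = [
    "TurnCoverageSeries",
    "CuHeSeries",
    "turn_coverage",
    "turns_per_minute",
    "cuhe",
    "cuhe_from_avey",
]


@dataclass
class TurnCoverageSeries:
    """Running turn-coverage state for one threshold angle.

    ``percent`` is the signed accumulator as a percentage of the threshold;
    ``events`` the cumulative event count per sample; ``event_times`` and
    ``event_signs`` (+1 clockwise, -1 anticlockwise) one entry per event.
    """

    t: np.ndarray
    threshold: float
    percent: np.ndarray
    events: np.ndarray
    event_times: np.ndarray
    event_signs: np.ndarray

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event_times.shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.t, "percent": self.percent, "events": self.events}
        )


@dataclass
class CuHeSeries:
    """Cumulative-heading state: percent of yaw circle visited, reset count."""

    t: np.ndarray
    percent: np.ndarray
    revolutions: np.ndarray
    bin_deg: float

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def total_revolutions(self) -> int:
        return int(self.revolutions[-1]) if len(self) else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.t, "percent": self.percent, "revolutions": self.revolutions}
        )


def turn_coverage(
    t, avey, threshold: float, reset: str = "remainder"
) -> TurnCoverageSeries:
    """Conditional running cumulative sum of AVeY against a threshold angle.

    Parameters
    ----------
    t, avey : array-like
        Sample times (s) and wrap-corrected yaw angular velocity (°/s).
        Non-finite AVeY samples contribute nothing to the accumulator.
    threshold : float
        Turn angle in degrees (> 0).
    reset : {"remainder", "full"}
        After an event, either carry the overshoot past the threshold
        (default; makes event totals independent of sample phase) or zero
        the accumulator.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if reset not in ("remainder", "full"):
        raise ValueError(f"reset must be 'remainder' or 'full', got {reset!r}")
    t = np.asarray(t, dtype=float)
    avey = np.asarray(avey, dtype=float)
    if t.shape != avey.shape:
        raise ValueError("t and avey must be aligned")
    n = t.shape[0]
    percent = np.empty(n)
    events = np.empty(n, dtype=np.int64)
    ev_times: list[float] = []
    ev_signs: list[int] = []
    c = 0.0
    for i in range(n):
        dv = avey[i]
        if np.isfinite(dv):
            c += dv
        while abs(c) >= threshold:
            sign = 1 if c > 0 else -1
            ev_times.append(t[i])
            ev_signs.append(sign)
            if reset == "remainder":
                c -= sign * threshold
            else:
                c = 0.0
        percent[i] = 100.0 * c / threshold
        events[i] = len(ev_times)
    return TurnCoverageSeries(
        t=t,
        threshold=float(threshold),
        percent=percent,
        events=events,
        event_times=np.asarray(ev_times, dtype=float),
        event_signs=np.asarray(ev_signs, dtype=np.int64),
    )


def turns_per_minute(
    coverage: TurnCoverageSeries, interval_s: float = 60.0, mode: str = "tumbling"
) -> tuple[np.ndarray, np.ndarray]:
    """Turn-event rate scaled to events per minute.

    With ``mode="tumbling"`` (default) the record is cut into consecutive
    ``interval_s`` windows starting at the first sample and the returned times
    are window starts; with ``mode="rolling"`` each sample gets the count of
    events in the trailing ``interval_s`` window.  Returns ``(times, rate)``.
    """
    if not interval_s > 0:
        raise ValueError(f"interval must be positive, got {interval_s}")
    ev = coverage.event_times
    scale = 60.0 / interval_s
    if mode == "tumbling":
        if len(coverage) == 0:
            return np.array([]), np.array([])
        t0, t1 = coverage.t[0], coverage.t[-1]
        nwin = max(1, int(np.ceil((t1 - t0) / interval_s))) if t1 > t0 else 1
        edges = t0 + interval_s * np.arange(nwin + 1)
        counts, _ = np.histogram(ev, bins=edges)
        return edges[:-1], counts * scale
    if mode == "rolling":
        counts = np.array(
            [np.count_nonzero((ev > ti - interval_s) & (ev <= ti)) for ti in coverage.t]
        )
        return coverage.t.copy(), counts * scale
    raise ValueError(f"mode must be 'tumbling' or 'rolling', got {mode!r}")


def _mark_arc(visited: np.ndarray, a: float, b: float, bin_deg: float) -> None:
    """Mark every bin intersecting the (unwrapped) arc from a to b."""
    nb = visited.shape[0]
    lo, hi = (a, b) if a <= b else (b, a)
    k0 = int(np.floor(lo / bin_deg))
    k1 = int(np.floor(hi / bin_deg))
    for k in range(k0, k1 + 1):
        visited[k % nb] = True


def cuhe(t, heading, bin_deg: float = 1.0) -> CuHeSeries:
    """Cumulative heading: percentage of yaw orientations visited since reset.

    ``bin_deg`` must divide 360.  Between consecutive valid samples every bin
    along the shorter wrap-corrected arc is marked, so fast turns cannot skip
    orientations.  On reaching 100% coverage the revolution counter
    increments, the visited set clears, and the current bin is re-marked.
    Non-finite headings carry the previous state forward.
    """
    nb = 360.0 / bin_deg
    if abs(nb - round(nb)) > 1e-9:
        raise ValueError(f"bin_deg must divide 360, got {bin_deg}")
    nb = int(round(nb))
    t = np.asarray(t, dtype=float)
    h = np.asarray(heading, dtype=float)
    if t.shape != h.shape:
        raise ValueError("t and heading must be aligned")
    n = t.shape[0]
    visited = np.zeros(nb, dtype=bool)
    percent = np.empty(n)
    revolutions = np.empty(n, dtype=np.int64)
    nrev = 0
    nvis = 0
    prev = None
    for i in range(n):
        hi_ = h[i]
        if np.isfinite(hi_):
            hi_ = hi_ % 360.0
            if prev is None:
                visited[int(hi_ / bin_deg) % nb] = True
            else:
                _mark_arc(visited, prev, prev + wrap_delta(prev, hi_), bin_deg)
            prev = hi_
            nvis = int(visited.sum())
            if nvis == nb:
                nrev += 1
                visited[:] = False
                visited[int(hi_ / bin_deg) % nb] = True
                nvis = 1
        percent[i] = 100.0 * nvis / nb
        revolutions[i] = nrev
    return CuHeSeries(t=t, percent=percent, revolutions=revolutions, bin_deg=float(bin_deg))


def cuhe_from_avey(
    t, avey, initial_heading: float, bin_deg: float = 1.0
) -> CuHeSeries:
    """CuHe via integration of wrap-corrected AVeY from a starting heading.

    Reconstructs the heading track as the running sum of AVeY (°/s at 1 Hz)
    from ``initial_heading`` and delegates to :func:`cuhe`.  Equivalent to the
    direct-heading path wherever the per-step rotation stays within ±180°;
    provided because the field protocol phrases the counters in terms of AVeY.
    """
    avey = np.asarray(avey, dtype=float)
    steps = np.where(np.isfinite(avey), avey, 0.0)
    h = (initial_heading + np.cumsum(steps)) % 360.0
    return cuhe(t, h, bin_deg=bin_deg)
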