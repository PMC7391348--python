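"""Reading, validation and resampling of logger time series.

A deployment is a delimited-text table with one row per sample: tri-axial
acceleration in g (surge/sway/heave), tri-axial magnetic intensity in Gauss,
and optional depth (m, positive downward) and temperature (°C) channels, at a
nominal fixed rate (40 Hz for the loggers this package targets).  Time is
stored internally as seconds from deployment start; files may carry either an
explicit time column or just an implicit sample index plus the nominal rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: canonical channel names, in file order
ACC_COLS = ("acc_x", "acc_y", "acc_z")
MAG_COLS = ("mag_x", "mag_y", "mag_z")
OPTIONAL_COLS = ("depth", "temp")

DEFAULT_SCHEMA = {name: name for name in ("time",) + ACC_COLS + MAG_COLS + OPTIONAL_COLS}


@dataclass
class SensorSeries:
    """Time-indexed raw tri-axial acc (g) + mag (Gauss) with optional depth/temp.

    Attributes
    ----------
    t : ndarray of float
        Seconds since deployment start, strictly increasing.
    acc, mag : ndarray, shape (n, 3)
        Acceleration (g) and magnetic intensity (Gauss) along the
        surge (x), sway (y) and heave (z) body axes.
    depth : ndarray or None
        Depth in metres, positive downward.
    temp : ndarray or None
        Temperature in °C.
    rate_hz : float
        Nominal sampling rate.
    animal_id : str
        Deployment label.
    """

    t: np.ndarray
    acc: np.ndarray
    mag: np.ndarray
    rate_hz: float
    depth: np.ndarray | None = None
    temp: np.ndarray | None = None
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=float)
        if self.temp is not None:
            self.temp = np.asarray(self.temp, dtype=float)
        n = self.t.shape[0]
        for name in ("acc", "mag"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValidationError(f"{name} must have shape ({n}, 3), got {arr.shape}")
        for name in ("depth", "temp"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != (n,):
                raise ValidationError(f"{name} must have shape ({n},), got {arr.shape}")
        if not self.rate_hz > 0:
            raise ValidationError(f"rate_hz must be positive, got {self.rate_hz}")
        if n > 1:
            bad = np.nonzero(np.diff(self.t) <= 0)[0]
            if bad.size:
                raise ValidationError(
                    f"time not strictly increasing at index {int(bad[0]) + 1}"
                )

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        """Deployment duration in seconds (sample count over nominal rate)."""
        return len(self) / self.rate_hz

    # convenience single-channel views
    @property
    def acc_x(self) -> np.ndarray:
        return self.acc[:, 0]

    @property
    def acc_y(self) -> np.ndarray:
        return self.acc[:, 1]

    @property
    def acc_z(self) -> np.ndarray:
        return self.acc[:, 2]

    @property
    def mag_x(self) -> np.ndarray:
        return self.mag[:, 0]

    @property
    def mag_y(self) -> np.ndarray:
        return self.mag[:, 1]

    @property
    def mag_z(self) -> np.ndarray:
        return self.mag[:, 2]

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.t}
        for i, name in enumerate(ACC_COLS):
            data[name] = self.acc[:, i]
        for i, name in enumerate(MAG_COLS):
            data[name] = self.mag[:, i]
        if self.depth is not None:
            data["depth"] = self.depth
        if self.temp is not None:
            data["temp"] = self.temp
        return pd.DataFrame(data)

    def with_mag(self, mag: np.ndarray) -> "SensorSeries":
        """Copy of this series with the mag channels replaced."""
        return replace(self, mag=np.asarray(mag, dtype=float))


def read_tag_csv(
    path,
    schema: dict | None = None,
    rate_hz: float = 40.0,
    animal_id: str = "",
) -> SensorSeries:
    """Read a delimited logger file into a validated :class:`SensorSeries`.

    ``schema`` maps canonical channel names (``time``, ``acc_x`` … ``mag_z``,
    ``depth``, ``temp``) to the column names actually present in the file;
    unmapped optional channels are simply absent.  The delimiter (comma or
    tab) is auto-detected.  If no ``time`` column is mapped, sample index over
    ``rate_hz`` is used.  Rows containing non-finite values in any mapped
    channel are counted and reported via logging but kept (downstream
    operations treat them as invalid samples rather than imputing).
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise SchemaError(f"could not parse {path}: {exc}") from None

    def col(name, required):
        mapped = schema.get(name)
        if mapped is None or mapped not in df.columns:
            if required:
                raise SchemaError(f"missing required column {name!r} (mapped to {mapped!r})")
            return None
        series = pd.to_numeric(df[mapped], errors="coerce")
        return series.to_numpy(dtype=float)

    acc = np.column_stack([col(name, True) for name in ACC_COLS])
    mag = np.column_stack([col(name, True) for name in MAG_COLS])
    depth = col("depth", False)
    temp = col("temp", False)

    tcol = schema.get("time")
    if tcol is not None and tcol in df.columns:
        t = pd.to_numeric(df[tcol], errors="coerce").to_numpy(dtype=float)
        t = t - t[0] if len(t) else t
    else:
        t = np.arange(len(df), dtype=float) / rate_hz

    channels = [acc, mag] + [c[:, None] for c in (depth, temp) if c is not None]
    finite = np.all(np.isfinite(np.hstack(channels)), axis=1) if len(df) else np.array([], bool)
    n_bad = int((~finite).sum())
    if n_bad:
        logger.warning("%s: %d row(s) with non-finite values flagged", path, n_bad)

    return SensorSeries(
        t=t, acc=acc, mag=mag, depth=depth, temp=temp, rate_hz=rate_hz, animal_id=animal_id
    )


def count_nonfinite_rows(series: SensorSeries) -> int:
    """Number of samples with a non-finite value in any acc/mag channel."""
    return int((~(np.isfinite(series.acc).all(axis=1) & np.isfinite(series.mag).all(axis=1))).sum())


def subsample(series: SensorSeries, n: int) -> SensorSeries:
    """Keep every ``n``-th sample (decimation by selection, no averaging).

    Matches the study convention of reducing a 40 Hz stream to 1 Hz by
    selecting samples 0, 40, 80, …; the nominal rate is divided by ``n``.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"subsample factor must be a positive integer, got {n!r}")
    if n > len(series):
        raise ValueError(f"subsample factor {n} exceeds series length {len(series)}")
    sl = slice(None, None, n)
    return SensorSeries(
        t=series.t[sl],
        acc=series.acc[sl],
        mag=series.mag[sl],
        depth=None if series.depth is None else series.depth[sl],
        temp=None if series.temp is None else series.temp[sl],
        rate_hz=series.rate_hz / n,
        animal_id=series.animal_id,
    )


def write_metrics_csv(obj, path) -> None:
    """Write any time-indexed series (object with ``to_frame`` or a DataFrame)
    to CSV with full float precision; NaN cells are written literally as "NaN"
    so the file round-trips exactly."""
    frame = obj if isinstance(obj, pd.DataFrame) else obj.to_frame()
    frame.to_csv(path, index=False, na_rep="NaN", float_format="%.12g")


def read_metrics_csv(path) -> pd.DataFrame:
    """Round-trip companion to :func:`write_metrics_csv`."""
    return pd.read_csv(path)
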