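"""Hard/soft-iron magnetometer calibration by ellipsoid fitting.

A distortion-free magnetometer rotated through all orientations traces a
sphere (the "m-sphere") centred on the origin with radius equal to the local
field intensity.  Ferromagnetic material near the sensor biases the readings
(hard iron: a constant offset) and warps them (soft iron: a linear map), so
the calibration cloud becomes an off-centre ellipsoid.  Fitting that
ellipsoid and mapping it back onto a unit sphere restores the geometry that
tilt-compensated heading relies on.

The fit is the classic algebraic least-squares quadric fit: solve for the
nine coefficients of ``x'Mx + 2b'x = 1`` by linear least squares, take the
centre ``c = -M^{-1} b``, and extract the unique symmetric positive-definite
square root of the recentred quadratic form as the soft-iron correction.  The
symmetric choice contains no rotation, which is all heading needs: only
sphericity matters, not the (unobservable) global orientation of the fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InsufficientDataError
from .logger_io import SensorSeries

__all__ = ["EllipsoidFit", "fit_ellipsoid", "apply_calibration"]


@dataclass
class EllipsoidFit:
    """Result of an m-sphere calibration fit.

    Attributes
    ----------
    offset : ndarray, shape (3,)
        Fitted ellipsoid centre = hard-iron bias, Gauss.
    shape : ndarray, shape (3, 3)
        Symmetric positive-definite soft-iron correction, normalised to
        determinant 1 (unitless).
    mean_radius : float
        Mean norm of ``shape @ (m - offset)`` over the calibration points,
        Gauss; dividing by it puts corrected vectors on the unit sphere.
    rms_residual : float
        RMS of ``|shape @ (m - offset)| / mean_radius - 1`` over the
        calibration points (unitless sphericity residual).
    """

    offset: np.ndarray
    shape: np.ndarray
    mean_radius: float
    rms_residual: float

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)
        self.shape = np.asarray(self.shape, dtype=float).reshape(3, 3)

    @classmethod
    def identity(cls, mean_radius: float = 1.0) -> "EllipsoidFit":
        """No-op calibration (zero offset, identity shape)."""
        return cls(np.zeros(3), np.eye(3), float(mean_radius), 0.0)

    def correct(self, m: np.ndarray) -> np.ndarray:
        """Apply the calibration to raw mag vectors, shape (..., 3)."""
        m = np.asarray(m, dtype=float)
        return (m - self.offset) @ self.shape.T / self.mean_radius

    # -- JSON round-trip (CLI artefact format) --------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "offset": self.offset.tolist(),
                "shape": self.shape.ravel().tolist(),  # row-major
                "mean_radius": self.mean_radius,
                "rms_residual": self.rms_residual,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EllipsoidFit":
        d = json.loads(text)
        return cls(
            np.array(d["offset"], dtype=float),
            np.array(d["shape"], dtype=float).reshape(3, 3),
            float(d["mean_radius"]),
            float(d["rms_residual"]),
        )


def fit_ellipsoid(points: np.ndarray) -> EllipsoidFit:
    """Least-squares algebraic ellipsoid fit to raw calibration mag vectors.

    Parameters
    ----------
    points : array-like, shape (n, 3)
        Raw magnetometer readings from a calibration rotation covering all
        orientations.  Non-finite rows are dropped.  At least 9 points in
        general position are required to constrain the 9 quadric parameters.

    Raises
    ------
    InsufficientDataError
        Fewer than 9 finite points.
    DegenerateGeometryError
        Coplanar/collinear cloud or a quadric that is not an ellipsoid.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    pts = pts[np.isfinite(pts).all(axis=1)]
    n = pts.shape[0]
    if n < 9:
        raise InsufficientDataError(f"ellipsoid fit needs >= 9 points, got {n}")

    x, y, z = pts.T
    # design for A x^2 + B y^2 + C z^2 + 2D xy + 2E xz + 2F yz + 2G x + 2H y + 2I z = 1
    design = np.column_stack(
        [x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z, 2 * x, 2 * y, 2 * z]
    )
    # centre and scale the cloud first for conditioning
    scale = float(np.max(np.abs(pts))) or 1.0
    coef, _, rank, _ = np.linalg.lstsq(design / scale**2, np.ones(n), rcond=None)
    coef = coef / scale**2
    if rank < 9:
        raise DegenerateGeometryError(
            "calibration points are rank-deficient (coplanar or collinear)"
        )
    A, B, C, D, E, F, G, H, I = coef
    M = np.array([[A, D, E], [D, B, F], [E, F, C]])
    b = np.array([G, H, I])
    eigvals = np.linalg.eigvalsh(M)
    if eigvals[0] <= 0:
        raise DegenerateGeometryError("fitted quadric is not an ellipsoid")
    center = -np.linalg.solve(M, b)
    # recentred form: (m - c)' M (m - c) = k
    k = 1.0 + center @ M @ center
    if k <= 0:
        raise DegenerateGeometryError("fitted quadric is not an ellipsoid")
    # symmetric PD square root of M/k maps the ellipsoid to the unit sphere
    w, V = np.linalg.eigh(M / k)
    W = (V * np.sqrt(w)) @ V.T
    shape = W / np.cbrt(np.linalg.det(W))  # det-1 normalisation -> unique scale split
    corrected = (pts - center) @ shape.T
    norms = np.linalg.norm(corrected, axis=1)
    mean_radius = float(norms.mean())
    rms_residual = float(np.sqrt(np.mean((norms / mean_radius - 1.0) ** 2)))
    return EllipsoidFit(center, shape, mean_radius, rms_residual)


def apply_calibration(series: SensorSeries, fit: EllipsoidFit) -> SensorSeries:
    """Return a copy of ``series`` with mag channels hard/soft-iron corrected.

    Each mag sample ``m`` becomes ``shape @ (m - offset) / mean_radius``; for
    distortion-free data this leaves directions unchanged and norms ~1.
    """
    return series.with_mag(fit.correct(series.mag))
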