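"""Flat U-dive detection, per-dive aggregation and association statistics.

A dive is a maximal excursion of the depth channel below a surface threshold
(0.5 m default, the pressure-sensor noise floor); only dives reaching at
least 3 m are retained.  The bottom phase is the span between the first and
last sample at or below 80% of maximum depth; a dive is classed flat-U
("type 1a") when that phase is long enough and depth-stable (bottom-depth
s.d. over max depth <= 0.1 by default).  Per-dive metric means — VeDBA,
|AVeY|, circular mean heading, turn rates, CuHe revolutions — are computed
over the bottom phase only, which is the analysis unit for the association
statistics.

``association_stats`` reproduces the field analysis on a per-dive table:
Spearman rank correlations across the rotation metrics, and a linear mixed
model of mean VeDBA on mean |AVeY| with per-animal random intercepts and
slopes (statsmodels MixedLM), reporting the fixed slope with Wald CI, a
likelihood-ratio test against the no-slope null (ML fits), Nakagawa
marginal/conditional R², and the intercept-based ICC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .orientation import circular_mean
from .rotation_metrics import RotationMetricsSeries
from .turn_analysis import CuHeSeries, TurnCoverageSeries

logger = logging.getLogger(__name__)

__all__ = [
    "DiveRecord",
    "AssociationReport",
    "detect_dives",
    "classify_flat_u",
    "per_dive_summary",
    "association_stats",
]


@dataclass
class DiveRecord:
    """One detected dive and (after summary) its bottom-phase statistics."""

    dive_id: str
    animal_id: str
    t_start: float
    t_end: float
    max_depth: float
    bottom_start: float
    bottom_end: float
    flatness: float
    is_flat_u: bool = False
    mean_vedba: float = np.nan
    mean_abs_avey: float = np.nan
    mean_heading: float = np.nan
    turns_per_min: dict = dc_field(default_factory=dict)
    cuhe_revolutions: int = 0

    @property
    def bottom_duration(self) -> float:
        return self.bottom_end - self.bottom_start

    def to_dict(self) -> dict:
        d = {
            "dive_id": self.dive_id,
            "animal_id": self.animal_id,
            "t_start": self.t_start,
            "t_end": self.t_end,
            "max_depth": self.max_depth,
            "bottom_start": self.bottom_start,
            "bottom_end": self.bottom_end,
            "flatness": self.flatness,
            "is_flat_u": self.is_flat_u,
            "mean_vedba": self.mean_vedba,
            "mean_abs_avey": self.mean_abs_avey,
            "mean_heading": self.mean_heading,
            "cuhe_revolutions": self.cuhe_revolutions,
        }
        for thr, rate in self.turns_per_min.items():
            d[f"turns_per_min_{int(thr)}"] = rate
        return d


def dives_to_frame(dives: list[DiveRecord]) -> pd.DataFrame:
    return pd.DataFrame([d.to_dict() for d in dives])


def detect_dives(
    t,
    depth,
    surface_threshold: float = 0.5,
    min_depth: float = 3.0,
    bottom_fraction: float = 0.8,
    animal_id: str = "",
) -> list[DiveRecord]:
    """Detect dives as maximal sub-surface excursions of the depth trace.

    Runs of ``depth > surface_threshold`` become candidate dives; those with
    maximum depth >= ``min_depth`` (3 m default) are retained.  Phase
    boundaries use the bottom-depth fraction rule: the bottom phase spans the
    first to the last sample at >= ``bottom_fraction * max_depth``.
    """
    if depth is None:
        raise ConfigError("series has no depth channel; dive detection requires depth")
    if not surface_threshold < min_depth:
        raise ValueError("surface_threshold must be below min_depth")
    t = np.asarray(t, dtype=float)
    depth = np.asarray(depth, dtype=float)
    below = np.isfinite(depth) & (depth > surface_threshold)
    if not below.any():
        return []
    edges = np.diff(below.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)  # exclusive
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(len(below))
    dives = []
    k = 0
    for s, e in zip(starts, ends):
        seg = depth[s:e]
        max_depth = float(np.nanmax(seg))
        if max_depth < min_depth:
            continue
        deep = np.nonzero(seg >= bottom_fraction * max_depth)[0]
        b0, b1 = s + deep[0], s + deep[-1]
        bottom = depth[b0 : b1 + 1]
        flatness = float(np.std(bottom) / max_depth)
        dives.append(
            DiveRecord(
                dive_id=f"{animal_id or 'dive'}_{k:03d}",
                animal_id=animal_id,
                t_start=float(t[s]),
                t_end=float(t[e - 1]),
                max_depth=max_depth,
                bottom_start=float(t[b0]),
                bottom_end=float(t[b1]),
                flatness=flatness,
            )
        )
        k += 1
    return dives


def classify_flat_u(
    dive: DiveRecord,
    t=None,
    depth=None,
    flatness_max: float = 0.1,
    bottom_fraction: float = 0.8,
    min_bottom_s: float = 30.0,
) -> bool:
    """Flat-U ("type 1a") test: long, depth-stable bottom phase.

    If the depth trace is supplied the bottom phase and flatness are
    recomputed with ``bottom_fraction``; otherwise the values stored on the
    record are used.  True iff bottom duration >= ``min_bottom_s`` and
    bottom-depth s.d. / max depth <= ``flatness_max``.
    """
    flatness = dive.flatness
    b0, b1 = dive.bottom_start, dive.bottom_end
    if depth is not None and t is not None:
        t = np.asarray(t, dtype=float)
        depth = np.asarray(depth, dtype=float)
        mask = (t >= dive.t_start) & (t <= dive.t_end)
        seg_t, seg_d = t[mask], depth[mask]
        deep = seg_d >= bottom_fraction * dive.max_depth
        if deep.any():
            b0, b1 = float(seg_t[deep][0]), float(seg_t[deep][-1])
            flatness = float(np.std(seg_d[deep]) / dive.max_depth)
        else:
            return False
    ok = (b1 - b0) >= min_bottom_s and flatness <= flatness_max
    dive.is_flat_u = bool(ok)
    dive.flatness = flatness
    return dive.is_flat_u


def per_dive_summary(
    dive: DiveRecord,
    metrics: RotationMetricsSeries,
    turns: dict[float, TurnCoverageSeries] | None = None,
    cuhe: CuHeSeries | None = None,
) -> DiveRecord | None:
    """Fill bottom-phase summary statistics on a dive record.

    Arithmetic means of VeDBA and |AVeY| and the circular mean of heading are
    taken over samples with ``bottom_start <= t <= bottom_end``; turn events
    within the bottom phase are scaled to events per minute; CuHe revolutions
    are counted within the phase.  Returns None (with a log entry) if the
    bottom phase contains no metric samples.
    """
    mask = (metrics.t >= dive.bottom_start) & (metrics.t <= dive.bottom_end)
    if not mask.any():
        logger.warning("dive %s dropped: empty bottom phase", dive.dive_id)
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dive.mean_vedba = float(np.nanmean(metrics.vedba[mask]))
        dive.mean_abs_avey = float(np.nanmean(np.abs(metrics.avey_1[mask])))
    if metrics.heading is not None:
        dive.mean_heading = circular_mean(metrics.heading[mask])
    minutes = max(dive.bottom_duration, 1e-9) / 60.0
    if turns:
        dive.turns_per_min = {
            thr: float(
                np.count_nonzero(
                    (cov.event_times >= dive.bottom_start)
                    & (cov.event_times <= dive.bottom_end)
                )
                / minutes
            )
            for thr, cov in turns.items()
        }
    if cuhe is not None:
        cmask = (cuhe.t >= dive.bottom_start) & (cuhe.t <= dive.bottom_end)
        if cmask.any():
            revs = cuhe.revolutions[cmask]
            dive.cuhe_revolutions = int(revs[-1] - revs[0])
    return dive


@dataclass
class AssociationReport:
    """Mixed-model and rank-correlation summary of per-dive metrics."""

    slope: float
    slope_se: float
    slope_ci: tuple[float, float]
    slope_t: float
    lrt_chi2: float
    lrt_p: float
    r2_marginal: float
    r2_conditional: float
    icc: float
    n_dives: int
    n_animals: int
    random_structure: str
    spearman: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_se": self.slope_se,
            "slope_ci": list(self.slope_ci),
            "slope_t": self.slope_t,
            "lrt_chi2": self.lrt_chi2,
            "lrt_p": self.lrt_p,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "icc": self.icc,
            "n_dives": self.n_dives,
            "n_animals": self.n_animals,
            "random_structure": self.random_structure,
            "spearman": self.spearman.to_dict(),
        }


def _fit_mixedlm(y, X, groups, exog_re, reml):
    import statsmodels.regression.mixed_linear_model as mlm

    model = mlm.MixedLM(y, X, groups=groups, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(reml=reml, method="lbfgs")


def association_stats(
    dives,
    x_col: str = "mean_abs_avey",
    y_col: str = "mean_vedba",
    metric_cols: list[str] | None = None,
    outlier_cutoff: float | None = None,
) -> AssociationReport:
    """Spearman correlations and mixed model of per-dive VeDBA on |AVeY|.

    ``dives`` may be a list of :class:`DiveRecord` or a DataFrame with at
    least ``animal_id``, ``x_col`` and ``y_col``.  Requires >= 2 animals with
    >= 3 dives each.  The mixed model uses per-animal random intercepts and
    slopes; a singular random-slope fit falls back to random intercepts with
    a warning.  ``outlier_cutoff``, if given, drops dives whose absolute
    studentized OLS residual exceeds it before fitting.
    """
    if not isinstance(dives, pd.DataFrame):
        dives = dives_to_frame(list(dives))
    missing = {x_col, y_col, "animal_id"} - set(dives.columns)
    if missing:
        raise ValueError(f"per-dive table lacks columns {sorted(missing)} (no dives?)")
    df = dives.dropna(subset=[x_col, y_col]).copy()
    counts = df.groupby("animal_id").size()
    if len(counts) < 2 or (counts < 3).any():
        raise ValueError("mixed model needs >= 2 animals with >= 3 dives each")

    if outlier_cutoff is not None:
        import statsmodels.api as sm

        ols = sm.OLS(df[y_col], sm.add_constant(df[x_col])).fit()
        infl = ols.get_influence().resid_studentized_internal
        df = df[np.abs(infl) <= outlier_cutoff]

    x = df[x_col].to_numpy(dtype=float)
    y = df[y_col].to_numpy(dtype=float)
    groups = df["animal_id"].to_numpy()
    X = np.column_stack([np.ones_like(x), x])
    exog_re = X

    random_structure = "intercept+slope"
    try:
        res = _fit_mixedlm(y, X, groups, exog_re, reml=True)
        if not np.all(np.isfinite(np.asarray(res.bse)[:2])) or not np.all(
            np.isfinite(np.linalg.cholesky(res.cov_re + 1e-14 * np.eye(len(res.cov_re))))
        ):
            raise np.linalg.LinAlgError("singular random-effects covariance")
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn(
            "random-slope fit singular; falling back to random intercepts",
            stacklevel=2,
        )
        random_structure = "intercept"
        exog_re = X[:, :1]
        res = _fit_mixedlm(y, X, groups, exog_re, reml=True)

    slope = float(np.asarray(res.fe_params)[1])
    se = float(np.asarray(res.bse)[1])
    ci = (slope - 1.96 * se, slope + 1.96 * se)
    tval = slope / se if se > 0 else np.nan

    # likelihood-ratio test for the fixed slope (ML fits, same random structure)
    full_ml = _fit_mixedlm(y, X, groups, exog_re, reml=False)
    null_ml = _fit_mixedlm(y, X[:, :1], groups, exog_re, reml=False)
    lrt = max(0.0, 2.0 * (full_ml.llf - null_ml.llf))
    lrt_p = float(stats.chi2.sf(lrt, df=1))

    # Nakagawa variance decomposition
    var_fixed = float(np.var(X @ res.fe_params))
    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    z = exog_re
    var_random = float(np.mean(np.einsum("ij,jk,ik->i", z, cov_re, z)))
    var_resid = float(res.scale)
    total = var_fixed + var_random + var_resid
    r2_m = var_fixed / total
    r2_c = (var_fixed + var_random) / total
    icc = float(cov_re[0, 0] / (cov_re[0, 0] + var_resid))

    metric_cols = metric_cols or [
        c
        for c in ("mean_abs_avey", "mean_vedba", "mean_heading", "cuhe_revolutions")
        if c in df.columns
    ]
    sub = df[metric_cols].dropna()
    if len(sub) >= 3 and len(metric_cols) >= 2:
        rho = stats.spearmanr(sub.to_numpy()).statistic
        if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        spearman = pd.DataFrame(rho, index=metric_cols, columns=metric_cols)
    else:
        spearman = pd.DataFrame(index=metric_cols, columns=metric_cols, dtype=float)

    return AssociationReport(
        slope=slope,
        slope_se=se,
        slope_ci=ci,
        slope_t=float(tval),
        lrt_chi2=float(lrt),
        lrt_p=lrt_p,
        r2_marginal=float(r2_m),
        r2_conditional=float(r2_c),
        icc=icc,
        n_dives=int(len(df)),
        n_animals=int(len(counts)),
        random_structure=random_structure,
        spearman=spearman,
    )
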