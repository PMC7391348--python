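import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from yawkit import (
    DiveRecord,
    RotationMetricsSeries,
    association_stats,
    classify_flat_u,
    cuhe,
    detect_dives,
    per_dive_summary,
    simulate_dive_summaries,
    turn_coverage,
)
from yawkit.errors import ConfigError


def trapezoid_depth(max_depth, n_ramp=20, n_bottom=120, n_surface=30):
    """Surface, linear descent, flat bottom, ascent, surface."""
    surf = np.zeros(n_surface)
    ramp = np.linspace(0, max_depth, n_ramp, endpoint=False)
    return np.concatenate([surf, ramp, np.full(n_bottom, max_depth), ramp[::-1], surf])


class TestDetectDives:
    def test_single_trapezoid_retained(self):
        d = trapezoid_depth(5.0)
        dives = detect_dives(np.arange(len(d), dtype=float), d)
        assert len(dives) == 1
        dv = dives[0]
        assert dv.max_depth == pytest.approx(5.0)
        assert dv.t_start < dv.bottom_start < dv.bottom_end < dv.t_end

    def test_shallow_dive_excluded(self):
        d = trapezoid_depth(2.5)
        assert detect_dives(np.arange(len(d), dtype=float), d) == []

    def test_two_excursions_found_with_boundaries(self):
        d = np.concatenate([trapezoid_depth(5.0), trapezoid_depth(8.0)])
        t = np.arange(len(d), dtype=float)
        dives = detect_dives(t, d)
        assert len(dives) == 2
        # boundary oracle: first/last sample above surface threshold per excursion
        for dv in dives:
            seg = (t >= dv.t_start) & (t <= dv.t_end)
            assert (d[seg] > 0.5).all()
            before = t == dv.t_start - 1
            assert d[before][0] <= 0.5

    def test_missing_depth_is_config_error(self):
        with pytest.raises(ConfigError):
            detect_dives(np.arange(5.0), None)

    def test_retention_filter_idempotent(self):
        d = np.concatenate([trapezoid_depth(5.0), trapezoid_depth(2.0)])
        dives = detect_dives(np.arange(len(d), dtype=float), d)
        assert all(dv.max_depth >= 3.0 for dv in dives)
        assert len(dives) == 1


class TestClassifyFlatU:
    def _dive(self, depth):
        t = np.arange(len(depth), dtype=float)
        return detect_dives(t, depth)[0], t, depth

    def test_long_flat_bottom_is_flat_u(self):
        dv, t, d = self._dive(trapezoid_depth(5.0))
        assert classify_flat_u(dv, t, d) is True

    def test_v_shaped_dive_rejected(self):
        ramp = np.linspace(0, 5.0, 20, endpoint=False)  # fast descent, no dwell
        d = np.concatenate([np.zeros(10), ramp, ramp[::-1], np.zeros(10)])
        dv, t, d = self._dive(d)
        assert classify_flat_u(dv, t, d) is False

    @pytest.mark.parametrize("rel_sd,expected", [(0.05, True), (0.2, False)])
    def test_flatness_threshold_on_record(self, rel_sd, expected):
        # stored-flatness path: rule is s.d./max_depth <= 0.1
        dv = DiveRecord(
            dive_id="d", animal_id="a", t_start=0.0, t_end=200.0, max_depth=5.0,
            bottom_start=20.0, bottom_end=180.0, flatness=rel_sd,
        )
        assert classify_flat_u(dv) is expected

    def test_flatness_recomputed_matches_direct_sd_oracle(self, rng):
        d = trapezoid_depth(5.0, n_bottom=200)
        noise = rng.normal(0, 0.15, 200)
        d[50:250] = 5.0 + noise - noise.mean()
        dv, t, dd = self._dive(d)
        got = classify_flat_u(dv, t, dd)
        mask = dd >= 0.8 * dv.max_depth
        expected_flat = np.std(dd[mask]) / dv.max_depth
        assert dv.flatness == pytest.approx(expected_flat, rel=1e-9)
        assert got == (expected_flat <= 0.1)


def _metrics(t, vedba, avey, heading=None):
    nan = np.full_like(t, np.nan)
    return RotationMetricsSeries(
        t=t, vedba=vedba, avep=nan, aver=nan, avey_1=avey,
        avey_5=nan, avey_10=nan, aav=np.abs(avey), heading=heading,
    )


class TestPerDiveSummary:
    def _record(self, b0=10.0, b1=110.0):
        return DiveRecord(
            dive_id="d0", animal_id="a", t_start=0.0, t_end=120.0,
            max_depth=5.0, bottom_start=b0, bottom_end=b1, flatness=0.01,
        )

    def test_constant_metrics(self):
        t = np.arange(121.0)
        dv = per_dive_summary(self._record(), _metrics(t, np.full(121, 0.04), np.full(121, 5.0)))
        assert dv.mean_vedba == pytest.approx(0.04)
        assert dv.mean_abs_avey == pytest.approx(5.0)

    def test_alternating_avey_absolute_mean(self):
        t = np.arange(121.0)
        avey = np.where(t % 2 == 0, 10.0, -10.0)
        dv = per_dive_summary(self._record(), _metrics(t, np.zeros(121), avey))
        assert dv.mean_abs_avey == pytest.approx(10.0)

    def test_against_brute_force_bottom_recomputation(self, rng):
        t = np.arange(200.0)
        ved = rng.uniform(0, 0.1, 200)
        avey = rng.uniform(-50, 50, 200)
        heading = rng.uniform(0, 360, 200)
        rec = self._record(b0=30.0, b1=150.0)
        cov = turn_coverage(t, avey, 45.0)
        ch = cuhe(t, heading)
        dv = per_dive_summary(rec, _metrics(t, ved, avey, heading), {45.0: cov}, ch)
        mask = (t >= 30.0) & (t <= 150.0)
        assert dv.mean_vedba == pytest.approx(ved[mask].mean(), abs=1e-12)
        assert dv.mean_abs_avey == pytest.approx(np.abs(avey[mask]).mean(), abs=1e-12)
        n_ev = np.count_nonzero((cov.event_times >= 30.0) & (cov.event_times <= 150.0))
        assert dv.turns_per_min[45.0] == pytest.approx(n_ev / 2.0)

    def test_empty_bottom_phase_dropped(self):
        rec = self._record(b0=500.0, b1=600.0)
        assert per_dive_summary(rec, _metrics(np.arange(10.0), np.zeros(10), np.zeros(10))) is None


class TestAssociationStats:
    def test_perfectly_monotone_spearman(self):
        x = np.tile(np.arange(10.0), 3)
        df = pd.DataFrame(
            {
                "animal_id": np.repeat(["a", "b", "c"], 10),
                "mean_abs_avey": x,
                "mean_vedba": 0.01 + 0.002 * x,
            }
        )
        rep = association_stats(df)
        assert rep.spearman.loc["mean_abs_avey", "mean_vedba"] == pytest.approx(1.0)

    def test_recovers_generating_slope(self):
        df = simulate_dive_summaries(seed=101)
        rep = association_stats(df)
        assert rep.slope == pytest.approx(0.0029, rel=0.2)
        assert abs(rep.slope - 0.0029) < 2 * rep.slope_se + 1e-4
        assert rep.lrt_p < 0.01
        assert 0.0 < rep.r2_marginal < rep.r2_conditional <= 1.0

    def test_too_few_animals_raises(self):
        df = simulate_dive_summaries(n_animals=1, seed=0)
        with pytest.raises(ValueError):
            association_stats(df)

    def test_outlier_cutoff_drops_rows(self):
        df = simulate_dive_summaries(seed=7)
        df.loc[0, "mean_vedba"] += 1.0  # gross outlier
        rep = association_stats(df, outlier_cutoff=4.0)
        assert rep.n_dives == len(df) - 1

    def test_matches_lme4_oracle(self, tmp_path):
        """Independent cross-check of the mixed model against R lme4."""
        df = simulate_dive_summaries(n_animals=4, dives_per_animal=30, seed=55)
        csv = tmp_path / "dives.csv"
        df.to_csv(csv, index=False)
        script = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- lmer(mean_vedba ~ mean_abs_avey + (1 + mean_abs_avey | animal_id),"
            " data = d, REML = TRUE);"
            "cat(fixef(m)[2], sqrt(vcov(m)[2,2]), sep=',')"
        )
        out = subprocess.run(
            [shutil.which("Rscript") or "Rscript", "-e", script],
            capture_output=True, text=True, check=True,
        )
        r_slope, r_se = (float(v) for v in out.stdout.strip().split(","))
        rep = association_stats(df)
        assert rep.slope == pytest.approx(r_slope, rel=1e-3)
        assert rep.slope_se == pytest.approx(r_se, rel=0.05)
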