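"""Pairwise regressions, distribution summaries and profile smoothing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qwamap import (
    IDENTITY_OBSERVATION,
    MethodObservation,
    compute_ring_metrics,
    aggregate_profiles,
    build_sector_series,
    compare_all,
    fit_profile,
    lumen_distribution,
    observe,
    offset_bootstrap_ci,
    pairwise_regression,
)
from qwamap.errors import ConfigError, InsufficientDataError


def series(values, start_year=2000):
    return pd.Series(values, index=range(start_year, start_year + len(values)), dtype=float)


class TestPairwiseRegression:
    def test_self_comparison_is_identity_line(self):
        s = series([3.0, 5.0, 9.0, 12.0])
        r = pairwise_regression(s, s)
        assert r.r2 == pytest.approx(1.0, abs=1e-12)
        assert r.slope == pytest.approx(1.0, rel=1e-12)
        assert r.offset_pct == pytest.approx(0.0, abs=1e-12)

    def test_scaling_recovered_in_slope_and_offset(self):
        s = series([2.0, 4.0, 7.0, 11.0, 13.0])
        r = pairwise_regression(s, 1.1 * s)
        assert r.slope == pytest.approx(1.1, rel=1e-12)
        assert r.offset_pct == pytest.approx(10.0, rel=1e-12)

    def test_matches_closed_form_ols(self):
        """slope = cov(x,y)/var(x), r² = corr²: direct hand formulas."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = rng.integers(3, 40)
            x = rng.uniform(1, 100, n)
            y = 2.0 + rng.uniform(0.5, 2.0) * x + rng.normal(0, 5, n)
            r = pairwise_regression(series(x), series(y))
            xc, yc = x - x.mean(), y - y.mean()
            slope = (xc @ yc) / (xc @ xc)
            r2 = (xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc))
            assert r.slope == pytest.approx(slope, rel=1e-10)
            assert r.r2 == pytest.approx(r2, rel=1e-10)
            assert r.intercept == pytest.approx(y.mean() - slope * x.mean(), rel=1e-8)

    def test_fewer_than_three_years_rejected(self):
        with pytest.raises(InsufficientDataError):
            pairwise_regression(series([1.0, 2.0]), series([1.0, 2.0]))

    def test_zero_reference_years_excluded_and_counted(self):
        ref = series([0.0, 2.0, 4.0, 8.0])
        cmp = 1.5 * ref
        r = pairwise_regression(ref, cmp)
        assert r.n_zero_ref_excluded == 1
        assert r.offset_pct == pytest.approx(50.0, rel=1e-12)

    def test_bootstrap_ci_brackets_known_offset(self):
        rng = np.random.default_rng(3)
        ref = series(rng.uniform(10, 20, 30))
        cmp = ref * 1.2 * (1 + rng.normal(0, 0.02, 30))
        lo, hi = offset_bootstrap_ci(ref, cmp, n_boot=500, seed=1)
        assert lo <= 20.0 <= hi
        assert hi - lo < 5.0


class TestCompareAll:
    def test_identical_copies_give_identity_comparisons(self, diffuse_truth, config):
        ident = observe(diffuse_truth, IDENTITY_OBSERVATION)
        tables = {m: ident for m in ("thin_section", "micro_ct", "surface_picture")}
        frame = compare_all(tables, config)
        assert set(frame["parameter"]) == {"mla", "vd", "vn", "dh", "rca"}
        np.testing.assert_allclose(frame["r2"], 1.0, atol=1e-9)
        np.testing.assert_allclose(frame["slope"], 1.0, rtol=1e-9)
        np.testing.assert_allclose(frame["offset_pct"], 0.0, atol=1e-9)

    def test_detection_limit_gives_negative_vd_offset(self, diffuse_truth, config):
        tables = {
            "thin_section": observe(diffuse_truth, IDENTITY_OBSERVATION),
            "micro_ct": observe(
                diffuse_truth,
                MethodObservation(method_label="micro_ct", min_detectable_area=1500.0),
            ),
        }
        frame = compare_all(tables, config).set_index(["parameter", "compared"])
        assert frame.loc[("vd", "micro_ct"), "offset_pct"] < 0

    def test_missing_reference_is_config_error(self, diffuse_truth, config):
        with pytest.raises(ConfigError):
            compare_all({"micro_ct": observe(diffuse_truth, IDENTITY_OBSERVATION)}, config)

    def test_imposed_linear_distortion_recovered(self, diffuse_truth, config):
        biased = observe(
            diffuse_truth,
            MethodObservation(method_label="biased", area_gain=1.15, area_noise_cv=0.02),
        )
        tables = {
            "thin_section": observe(diffuse_truth, IDENTITY_OBSERVATION),
            "biased": biased,
        }
        frame = compare_all(tables, config).set_index(["parameter", "compared"])
        # RCA is a lumen-area sum over a fixed AOI, so the 15% gain must lie
        # within the 95% CI of the recovered regression slope
        row = frame.loc[("rca", "biased")]
        ref_m, cmp_m = (
            compute_ring_metrics(tables["thin_section"], config),
            compute_ring_metrics(tables["biased"], config),
        )
        x, y = ref_m["rca"].to_numpy(), cmp_m["rca"].to_numpy()
        resid = y - (row["intercept"] + row["slope"] * x)
        se = np.sqrt(resid @ resid / (len(x) - 2) / ((x - x.mean()) @ (x - x.mean())))
        half = stats.t.ppf(0.975, len(x) - 2) * se
        assert row["slope"] - half <= 1.15 <= row["slope"] + half
        # and the offset sits above the pure gain (extra cells pass the cut-off)
        assert row["offset_pct"] > 10.0


class TestLumenDistribution:
    def test_density_integrates_to_one(self, diffuse_truth):
        d = lumen_distribution(diffuse_truth.table)
        width = d["log10_area"].iloc[1] - d["log10_area"].iloc[0]
        assert (d["density"] * width).sum() == pytest.approx(1.0, abs=1e-6)

    def test_cutoff_zeroes_density_below(self, diffuse_truth):
        d = lumen_distribution(diffuse_truth.table, cutoff=1000.0)
        assert (d["area_um2"] >= 1000.0 * (1 - 1e-6)).all()

    def test_ring_porous_density_has_two_modes(self, ring_porous_truth):
        d = lumen_distribution(ring_porous_truth.table, cutoff=500.0, n_bins=40)
        dens = np.convolve(d["density"], np.ones(3) / 3, mode="same")
        peaks = [
            i
            for i in range(1, len(dens) - 1)
            if dens[i] > dens[i - 1] and dens[i] >= dens[i + 1] and dens[i] > 0.05 * dens.max()
        ]
        assert len(peaks) >= 2
        # the two modes sit on opposite sides of the mixture midpoint
        mid = (ring_porous_truth.model.lw_log_mean + ring_porous_truth.model.ew_log_mean) / 2
        log10_mid = mid / np.log(10)
        assert d["log10_area"].iloc[peaks[0]] < log10_mid < d["log10_area"].iloc[peaks[-1]]

    def test_empty_table_gives_empty_summary(self, hand_table):
        d = lumen_distribution(hand_table([]))
        assert len(d) == 0


class TestAggregateProfiles:
    def test_single_ring_is_identity(self, hand_table, config):
        table = hand_table([2000.0, 3000.0], ring_width=300.0, x=[50.0, 200.0])
        s = build_sector_series(table, config, "vessels_only")
        agg = aggregate_profiles(s, "ks")
        assert len(agg) == len(s)
        np.testing.assert_allclose(agg["value"], s["ks"])

    def test_common_relative_axis(self, diffuse_truth, ring_porous_truth):
        cfg_d = diffuse_truth.config
        s1 = build_sector_series(diffuse_truth.table, cfg_d, "vessels_only")
        s2 = build_sector_series(ring_porous_truth.table, ring_porous_truth.config, "vessels_only")
        agg = aggregate_profiles({"a": s1, "b": s2}, "ks")
        assert agg["rel_position"].between(0, 100).all()

    def test_unknown_parameter_rejected(self, diffuse_truth, config):
        s = build_sector_series(diffuse_truth.table, config, "vessels_only")
        with pytest.raises(ConfigError):
            aggregate_profiles(s, "nonexistent")


def synthetic_profile(shape, methods=("thin_section",), n_years=6, noise=0.0, seed=0):
    """Long-format profile data from a known mean curve."""
    rng = np.random.default_rng(seed)
    rows = []
    for method in methods:
        for year in range(2000, 2000 + n_years):
            x = np.linspace(2.5, 97.5, 20)
            v = shape(x, method) + rng.normal(0, noise, x.size)
            for xi, vi in zip(x, v):
                rows.append(
                    {"method": method, "year": year, "rel_position": xi, "value": vi}
                )
    return pd.DataFrame(rows)


class TestFitProfile:
    def test_constant_profile_reproduced(self):
        agg = synthetic_profile(lambda x, m: np.full_like(x, 5.0))
        fits, _ = fit_profile(agg, "ks", n_boot=50, seed=0)
        fit = fits["thin_section"]
        np.testing.assert_allclose(fit.mean, 5.0, atol=1e-6)
        assert np.all(fit.lower <= fit.mean) and np.all(fit.upper >= fit.mean)
        assert (fit.upper - fit.lower).max() < 1e-6

    def test_noiseless_linear_profile_reproduced(self):
        agg = synthetic_profile(lambda x, m: 2.0 + 0.03 * x)
        fits, _ = fit_profile(agg, "ks", n_boot=50, seed=0)
        fit = fits["thin_section"]
        np.testing.assert_allclose(fit.mean, 2.0 + 0.03 * fit.grid, atol=1e-6)

    def test_constant_shift_between_methods_flagged_everywhere(self):
        shapes = {"thin_section": 0.0, "shifted": 1.0}
        agg = synthetic_profile(
            lambda x, m: 3.0 + shapes[m] + 0.01 * x,
            methods=("thin_section", "shifted"),
            noise=0.05,
            seed=2,
        )
        _, flags = fit_profile(agg, "ks", reference="thin_section", n_boot=100, seed=1)
        assert flags["differs"].all()

    def test_single_year_flagged_low_confidence(self):
        agg = synthetic_profile(lambda x, m: 1.0 + 0.02 * x, n_years=1, noise=0.01)
        fits, _ = fit_profile(agg, "ks", n_boot=20, seed=0)
        assert fits["thin_section"].low_confidence

    def test_row_order_invariance(self):
        agg = synthetic_profile(lambda x, m: 1.0 + 0.02 * x, noise=0.1, seed=4)
        shuffled = agg.sample(frac=1.0, random_state=9).reset_index(drop=True)
        f1, _ = fit_profile(agg, "ks", n_boot=30, seed=5)
        f2, _ = fit_profile(shuffled, "ks", n_boot=30, seed=5)
        np.testing.assert_allclose(
            f1["thin_section"].mean, f2["thin_section"].mean, rtol=1e-8
        )

    def test_bands_bracket_mean(self, diffuse_truth, config):
        s = build_sector_series(diffuse_truth.table, config, "vessels_only")
        agg = aggregate_profiles({"thin_section": s}, "rho")
        fits, _ = fit_profile(agg, "rho", n_boot=60, seed=3)
        fit = fits["thin_section"]
        assert np.all(fit.lower <= fit.mean + 1e-12)
        assert np.all(fit.upper >= fit.mean - 1e-12)
        assert np.all(np.diff(fit.grid) > 0)
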