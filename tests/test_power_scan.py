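"""Partial correlations, power grid scan and criterion selection."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bennscale.anthropometry import compute_index
from bennscale.cohort import GeneratorParams, generate_cohort
from bennscale.power_scan import (BennExponentSelector, PowerGrid,
                                  allometric_exponent_loglog,
                                  build_criterion_table,
                                  find_height_independent_power,
                                  find_max_corr_power, partial_corr,
                                  scan_powers)


def _partial_corr_oracle(x, y, control):
    """Independent two-stage OLS oracle: residualize via normal equations,
    then plain Pearson correlation."""
    X = np.column_stack([np.ones(len(x)), control])
    bx = np.linalg.solve(X.T @ X, X.T @ x)
    by = np.linalg.solve(X.T @ X, X.T @ y)
    rx, ry = x - X @ bx, y - X @ by
    return np.corrcoef(rx, ry)[0, 1]


class TestPowerGrid:
    def test_default_grid_has_10001_points(self):
        assert PowerGrid().powers.shape == (10001,)

    def test_powers_are_exact_hundredths(self):
        p = PowerGrid(-5, 5, 0.01).powers
        assert p[0] == -5.0 and p[-1] == 5.0
        # every power is exactly k/100 for integer k: no accumulation drift
        np.testing.assert_array_equal(p, np.arange(-500, 501) / 100.0)
        assert np.all(np.diff(p) > 0)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            PowerGrid(1, -1, 0.01)
        with pytest.raises(ValueError):
            PowerGrid(0, 1, 0.005)


class TestPartialCorr:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=100)
        c = rng.normal(size=100)
        r, lo, hi = partial_corr(x, x, c)
        assert r == 1.0 and hi == 1.0

    def test_six_point_toy_matches_two_stage_ols(self):
        x = np.arange(1.0, 7.0)
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        control = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        r, _, _ = partial_corr(x, y, control)
        assert r == pytest.approx(_partial_corr_oracle(x, y, control),
                                  abs=1e-12)

    def test_uncorrelated_control_approaches_plain_pearson(self, rng):
        n = 50_000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        c = rng.normal(size=n)  # independent of x and y
        r, _, _ = partial_corr(x, y, c)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.01)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_recursion_formula(self, seed):
        """r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))."""
        g = np.random.default_rng(seed)
        n = 60
        z = g.normal(size=n)
        x = 0.3 * z + g.normal(size=n)
        y = -0.5 * z + g.normal(size=n)
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        expect = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        r, _, _ = partial_corr(x, y, z)
        assert r == pytest.approx(expect, abs=1e-10)

    def test_undefined_correlation_flagged(self, rng):
        c = rng.normal(size=50)
        with pytest.raises(ValueError, match="undefined correlation"):
            partial_corr(2.0 * c + 1.0, rng.normal(size=50), c)

    def test_rejects_degenerate_inputs(self, rng):
        with pytest.raises(ValueError):
            partial_corr([1.0, 2.0], [1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            partial_corr(rng.normal(size=20), rng.normal(size=20),
                         np.ones(20))

    def test_fisher_ci_width_halves_when_n_quadruples(self, rng):
        z = rng.normal(size=40_000)
        x = 0.4 * z + rng.normal(size=40_000)
        y = 0.4 * z + rng.normal(size=40_000)
        widths = {}
        for n in (10_000, 40_000):
            r, lo, hi = partial_corr(x[:n], y[:n], z[:n])
            widths[n] = np.arctanh(hi) - np.arctanh(lo)
        assert widths[40_000] / widths[10_000] == pytest.approx(0.5, rel=0.05)


class TestScanPowers:
    def test_weight_curve_is_one_at_power_zero(self, female_cohort):
        curves = scan_powers(female_cohort, ["weight"], PowerGrid(-1, 1, 0.01))
        i = np.where(curves["weight"].powers == 0.0)[0][0]
        assert curves["weight"].r[i] == pytest.approx(1.0, abs=1e-12)

    def test_curve_consistent_with_direct_partial_corr(self, female_cohort):
        curves = scan_powers(female_cohort, ["bf_pct"], PowerGrid(1, 3, 0.5))
        i = np.where(curves["bf_pct"].powers == 2.0)[0][0]
        bmi = compute_index(female_cohort["weight_kg"],
                            female_cohort["height_m"], 2.0)
        r, _, _ = partial_corr(bmi, female_cohort["bf_pct"].to_numpy(),
                               female_cohort["age"].to_numpy())
        assert curves["bf_pct"].r[i] == pytest.approx(r, abs=1e-10)

    def test_scale_invariance_of_curves(self, female_cohort):
        """Rescaling weight (hence the index) by any positive constant
        leaves every correlation unchanged."""
        grid = PowerGrid(-2, 2, 0.25)
        base = scan_powers(female_cohort, ["height", "bf_pct"], grid)
        scaled = female_cohort.copy()
        scaled["weight_kg"] *= 1000.0  # express weight in grams
        # keep fatness measures fixed: only the index scale changes
        scaled[["fat_mass_kg", "fat_free_mass_kg", "bf_pct"]] = \
            female_cohort[["fat_mass_kg", "fat_free_mass_kg", "bf_pct"]]
        other = scan_powers(scaled, ["height", "bf_pct"], grid)
        for m in ("height", "bf_pct"):
            np.testing.assert_allclose(other[m].r, base[m].r, atol=1e-12)

    def test_ci_brackets_r(self, female_cohort):
        curves = scan_powers(female_cohort, None, PowerGrid(-2, 3, 0.1))
        for c in curves.values():
            assert np.all(c.ci_lo <= c.r + 1e-12)
            assert np.all(c.r <= c.ci_hi + 1e-12)
            assert np.all(np.abs(c.r) <= 1.0)

    def test_rejects_mixed_sex(self, mixed_cohort):
        with pytest.raises(ValueError, match="single-sex"):
            scan_powers(mixed_cohort, ["height"], PowerGrid(-1, 1, 0.5))


class TestCriterionSelection:
    def test_noise_free_allometry_recovers_exponent_exactly(self):
        p = GeneratorParams.female_defaults(n=2_000, seed=3, p_true=2.0)
        p = dataclasses.replace(p, weight_log_sd=0.0, age_weight_slope=0.0)
        c = generate_cohort(p)
        with pytest.warns(UserWarning, match="zero residual variance"):
            curves = scan_powers(c, ["height"], PowerGrid(-5, 5, 0.01))
        opt = find_height_independent_power(curves["height"])
        assert opt.power == 2.00
        assert opt.sign_change_bracketed

    def test_height_estimate_near_truth(self, female_cohort):
        curves = scan_powers(female_cohort, ["height"], PowerGrid(-5, 5, 0.01))
        opt = find_height_independent_power(curves["height"])
        assert opt.power == pytest.approx(1.4, abs=0.25)  # n = 2,000
        assert opt.sign_change_bracketed

    def test_monotone_decrease_near_crossing(self, female_cohort):
        curves = scan_powers(female_cohort, ["height"], PowerGrid(-5, 5, 0.01))
        opt = find_height_independent_power(curves["height"])
        i = np.where(curves["height"].powers == opt.power)[0][0]
        window = curves["height"].r[i - 20:i + 21]
        assert np.all(np.diff(window) < 0)

    def test_weight_criterion_is_power_zero(self, female_cohort):
        curves = scan_powers(female_cohort, ["weight"], PowerGrid(-5, 5, 0.01))
        opt = find_max_corr_power(curves["weight"])
        assert opt.power == 0.0
        assert opt.r_at_optimum == pytest.approx(1.0, abs=1e-12)

    def test_max_corr_matches_brute_force(self, female_cohort):
        grid = PowerGrid(-3, 3, 0.25)
        curves = scan_powers(female_cohort, ["bf_pct"], grid)
        opt = find_max_corr_power(curves["bf_pct"])
        idx = compute_index(female_cohort["weight_kg"],
                            female_cohort["height_m"], opt.power)
        best = -2.0
        for p in grid.powers:  # exhaustive direct evaluation
            r, _, _ = partial_corr(
                compute_index(female_cohort["weight_kg"],
                              female_cohort["height_m"], p),
                female_cohort["bf_pct"].to_numpy(),
                female_cohort["age"].to_numpy())
            best = max(best, r)
        assert opt.r_at_optimum == pytest.approx(best, abs=1e-10)

    def test_criterion_table_structure(self, female_cohort):
        rows = build_criterion_table(female_cohort, PowerGrid(-3, 3, 0.05))
        assert len(rows) == 9  # old formula + height + 7 fatness criteria
        assert rows[0].criterion == "old_formula" and rows[0].power == 2.0
        assert rows[1].criterion == "height"
        for row in rows:
            assert len(row.correlations) == 8
        # each fatness row maximizes the correlation with its own measure
        by_name = {r.criterion: r for r in rows}
        for m in ("bf_pct", "weight", "fat_mass"):
            own = by_name[m].correlations[m]
            for other in rows:
                assert own >= other.correlations[m] - 1e-10


def test_loglog_regression_cross_check(female_cohort):
    est = allometric_exponent_loglog(female_cohort)
    assert est == pytest.approx(1.4, abs=0.2)


def test_selector_estimator(female_cohort):
    from sklearn.base import clone
    sel = BennExponentSelector(grid=PowerGrid(-5, 5, 0.01)).fit(female_cohort)
    assert sel.power_ == pytest.approx(1.4, abs=0.25)
    idx = sel.transform(female_cohort)
    expect = compute_index(female_cohort["weight_kg"],
                           female_cohort["height_m"], sel.power_)
    np.testing.assert_allclose(idx, expect)
    assert clone(sel).get_params()["criterion"] == "height"
    with pytest.raises(ValueError):
        BennExponentSelector(criterion="nope").fit(female_cohort)
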