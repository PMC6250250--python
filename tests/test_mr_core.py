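"""Estimator correctness against hand calculations and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrpipe import mr_core
from mrpipe.mr_core import (
    MrEstimate,
    RatioEstimate,
    egger,
    f_statistic,
    ivw_fixed,
    wald_ratio,
    wald_ratios,
    weighted_median,
    weighted_median_point,
    weighted_mode,
    weighted_mode_point,
)
from mrpipe.summary_io import HarmonizedInstrument

from conftest import make_instruments, random_panel


def ratio(theta, se, rsid="rs1"):
    return RatioEstimate(rsid=rsid, theta=theta, se_theta=se)


class TestFStatistic:
    @pytest.mark.parametrize(
        "r2,n,expected",
        [
            (0.0, 1000, 0.0),
            (0.5, 4, 2.0),
            (0.001, 166066, 0.001 * 166064 / 0.999),
        ],
    )
    def test_values(self, r2, n, expected):
        assert f_statistic(r2, n) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 100)
        with pytest.raises(ValueError):
            f_statistic(0.1, 2)

    def test_weak_flag_boundary(self):
        s = mr_core.instrument_strength("rs1", 0.001, 166066)
        assert not s.weak
        assert mr_core.instrument_strength("rs2", 0.0, 100).weak


class TestWaldRatio:
    def inst(self, bx=0.1, sx=0.01, by=0.05, sy=0.02):
        return HarmonizedInstrument("rs1", bx, sx, by, sy, "A")

    def test_zero_numerator_orders_agree(self):
        first = wald_ratio(self.inst(by=0.0), "first")
        second = wald_ratio(self.inst(by=0.0), "second")
        assert first.theta == second.theta == 0.0
        assert first.se_theta == second.se_theta == pytest.approx(0.2)

    def test_second_order_hand_value(self):
        r = wald_ratio(self.inst(), "second")
        assert r.theta == pytest.approx(0.5)
        assert r.se_theta == pytest.approx(math.sqrt(0.04 + 0.0025), rel=1e-12)
        assert r.weight == pytest.approx(r.se_theta**-2, rel=1e-12)

    def test_first_order_hand_value(self):
        assert wald_ratio(self.inst(), "first").se_theta == pytest.approx(0.2)

    @settings(max_examples=30, derandomize=True)
    @given(c=st.floats(0.1, 10))
    def test_scale_invariance_of_theta(self, c):
        base = wald_ratio(self.inst())
        scaled = wald_ratio(self.inst(bx=0.1 * c, by=0.05 * c))
        assert scaled.theta == pytest.approx(base.theta, rel=1e-12)

    def test_zero_beta_x_names_snp(self):
        with pytest.raises(ZeroDivisionError, match="rs1"):
            wald_ratio(self.inst(bx=0.0))


class TestIvwFixed:
    def test_single_snp_identity(self):
        est = ivw_fixed([ratio(0.3, 0.1)])
        assert est.beta == pytest.approx(0.3) and est.se == pytest.approx(0.1)

    def test_equal_weights_closed_form(self):
        est = ivw_fixed([ratio(0.2, 0.05, f"rs{i}") for i in range(9)])
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.05 / 3, rel=1e-12)

    def test_matches_brute_force_oracle(self):
        thetas, ses = [0.2, 0.4, 0.6], [0.1, 0.2, 0.3]
        est = ivw_fixed([ratio(t, s, f"rs{i}") for i, (t, s) in enumerate(zip(thetas, ses))])
        # independent weighted-average computation
        num = den = 0.0
        for t, s in zip(thetas, ses):
            num += t / s**2
            den += 1 / s**2
        assert est.beta == pytest.approx(num / den, rel=1e-12)
        assert est.se == pytest.approx(den**-0.5, rel=1e-12)

    def test_estimate_within_ratio_range_and_se_shrinks(self, rng):
        ratios = [ratio(rng.normal(0.1, 0.3), rng.uniform(0.05, 0.5), f"rs{i}") for i in range(20)]
        prev_se = math.inf
        for j in range(1, 21):
            est = ivw_fixed(ratios[:j])
            assert min(r.theta for r in ratios[:j]) <= est.beta <= max(r.theta for r in ratios[:j])
            assert est.se < prev_se
            prev_se = est.se

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            ivw_fixed([])


def constrained_origin_slope(instruments, se_order="second"):
    """Independent zero-intercept weighted fit of beta_y on beta_x."""
    bx = np.array([abs(i.beta_x) for i in instruments])
    by = np.array([i.beta_y * np.sign(i.beta_x) for i in instruments])
    sy = np.array([i.se_y for i in instruments])
    sx = np.array([i.se_x for i in instruments])
    if se_order == "second":
        w = 1.0 / (sy**2 + (by / bx) ** 2 * sx**2)
    else:
        w = sy**-2.0
    return float(np.sum(w * bx * by) / np.sum(w * bx**2))


class TestEgger:
    def test_noiseless_line_recovered(self):
        bx = np.array([0.05, 0.08, 0.11, 0.14])
        a, t = 0.003, 0.4
        panel = make_instruments(bx, [0.01] * 4, a + t * bx, [0.005] * 4)
        est = egger(panel)
        assert est.beta == pytest.approx(t, abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(a, abs=1e-10)
        assert est.extras["q_prime"] == pytest.approx(0.0, abs=1e-16)

    def test_matches_wls_normal_equations_oracle(self, four_snp_panel):
        est = egger(four_snp_panel, "second")
        bx = np.array([i.beta_x for i in four_snp_panel])
        by = np.array([i.beta_y for i in four_snp_panel])
        sx = np.array([i.se_x for i in four_snp_panel])
        sy = np.array([i.se_y for i in four_snp_panel])
        w = 1.0 / (sy**2 + (by / bx) ** 2 * sx**2)
        X = np.column_stack([np.ones_like(bx), bx])
        coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * by))
        assert est.extras["intercept"] == pytest.approx(coef[0], rel=1e-10)
        assert est.beta == pytest.approx(coef[1], rel=1e-10)

    def test_zero_intercept_constraint_recovers_ivw(self, rng):
        """The through-origin version of the Egger fit is exactly IVW."""
        for _ in range(10):
            panel = random_panel(rng)
            ivw = ivw_fixed(wald_ratios(panel))
            assert constrained_origin_slope(panel) == pytest.approx(ivw.beta, rel=1e-10)

    def test_too_few_instruments(self):
        panel = make_instruments([0.1, 0.2], [0.01] * 2, [0.01, 0.02], [0.005] * 2)
        with pytest.raises(ValueError):
            egger(panel)

    def test_zero_spread_is_singular(self):
        panel = make_instruments([0.1] * 4, [0.01] * 4, [0.01] * 4, [0.005] * 4)
        with pytest.raises(ValueError, match="singular"):
            egger(panel)


class TestWeightedMedian:
    def test_degenerate_distribution(self):
        ratios = [ratio(0.3, 0.01 * (i + 1), f"rs{i}") for i in range(5)]
        est = weighted_median(ratios, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.3)
        assert est.se < 0.02

    def test_three_equal_weights_hits_middle(self):
        ratios = [ratio(t, 0.1, f"rs{i}") for i, t in enumerate([1.0, 2.0, 3.0])]
        assert weighted_median_point(ratios) == pytest.approx(2.0, rel=1e-12)

    def test_matches_fine_grid_oracle(self, four_snp_ratios):
        est = weighted_median_point(four_snp_ratios)
        theta = np.array([r.theta for r in four_snp_ratios])
        w = np.array([r.weight for r in four_snp_ratios])
        order = np.argsort(theta)
        th, ww = theta[order], w[order]
        p = (np.cumsum(ww) - ww / 2) / np.sum(ww)
        # brute-force: evaluate the piecewise-linear quantile path on a fine
        # grid and take the point whose cumulative weight is closest to 1/2
        grid = np.linspace(th[0], th[-1], 200001)
        pg = np.interp(grid, th, p)
        oracle = grid[np.argmin(np.abs(pg - 0.5))]
        assert est == pytest.approx(oracle, abs=(th[-1] - th[0]) / 100000)

    def test_equal_weights_match_unweighted_interpolated_median(self, rng):
        theta = rng.normal(0, 1, 7)
        ratios = [ratio(t, 1.0, f"rs{i}") for i, t in enumerate(theta)]
        est = weighted_median_point(ratios)
        th = np.sort(theta)
        p = (np.arange(1, 8) - 0.5) / 7
        assert est == pytest.approx(float(np.interp(0.5, p, th)), rel=1e-12)

    def test_bootstrap_reproducible(self, four_snp_ratios):
        a = weighted_median(four_snp_ratios, n_boot=300, seed=42)
        b = weighted_median(four_snp_ratios, n_boot=300, seed=42)
        assert a.se == b.se and a.ci_low == b.ci_low

    def test_preconditions(self, four_snp_ratios):
        with pytest.raises(ValueError):
            weighted_median(four_snp_ratios[:2])
        with pytest.raises(ValueError):
            weighted_median(four_snp_ratios, n_boot=10)


class TestWeightedMode:
    def test_point_mass(self):
        ratios = [ratio(0.25, 0.1 * (i + 1), f"rs{i}") for i in range(4)]
        assert weighted_mode_point(ratios) == pytest.approx(0.25)

    def test_concordant_cluster_beats_outliers(self):
        ratios = [ratio(0.1 + 0.005 * i, 0.05, f"rs{i}") for i in range(5)]
        ratios += [ratio(1.0, 0.5, "rs_out1"), ratio(1.05, 0.5, "rs_out2")]
        est = weighted_mode_point(ratios)
        assert 0.05 < est < 0.2
        # independent dense-grid density maximization with the same
        # bandwidth rule
        theta = np.array([r.theta for r in ratios])
        w = np.array([r.weight for r in ratios])
        w = w / w.sum()
        h = mr_core.mode_bandwidth(theta)
        grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, mr_core.MODE_GRID_POINTS)
        dens = [float(np.sum(w * np.exp(-((g - theta) ** 2) / (2 * h * h)))) for g in grid]
        assert est == pytest.approx(grid[int(np.argmax(dens))], rel=1e-12)

    def test_order_invariance(self, rng, four_snp_ratios):
        base = weighted_mode_point(four_snp_ratios)
        perm = list(four_snp_ratios)
        rng.shuffle(perm)
        assert weighted_mode_point(perm) == pytest.approx(base, rel=1e-12)

    def test_bootstrap_reproducible(self, four_snp_ratios):
        a = weighted_mode(four_snp_ratios, n_boot=200, seed=7)
        b = weighted_mode(four_snp_ratios, n_boot=200, seed=7)
        assert a.se == b.se

    def test_bad_phi(self, four_snp_ratios):
        with pytest.raises(ValueError):
            weighted_mode(four_snp_ratios, phi=0.0)


class TestEstimatorInvariants:
    def flip_subset(self, panel, mask):
        return make_instruments(
            [(-1 if m else 1) * i.beta_x for i, m in zip(panel, mask)],
            [i.se_x for i in panel],
            [(-1 if m else 1) * i.beta_y for i, m in zip(panel, mask)],
            [i.se_y for i in panel],
        )

    @settings(max_examples=25, derandomize=True)
    @given(mask=st.lists(st.booleans(), min_size=8, max_size=8))
    def test_orientation_invariance(self, mask):
        """Flipping the reported allele of any SNP subset leaves every
        pooled estimate unchanged."""
        rng = np.random.default_rng(99)
        panel = random_panel(rng)
        flipped = self.flip_subset(panel, mask)
        r0, r1 = wald_ratios(panel), wald_ratios(flipped)
        assert ivw_fixed(r1).beta == pytest.approx(ivw_fixed(r0).beta, rel=1e-12)
        assert egger(flipped).beta == pytest.approx(egger(panel).beta, rel=1e-12)
        assert weighted_median_point(r1) == pytest.approx(weighted_median_point(r0), rel=1e-12)
        assert weighted_mode_point(r1) == pytest.approx(weighted_mode_point(r0), rel=1e-12)

    def test_or_scale_is_exp_of_log_scale(self, four_snp_panel, four_snp_ratios):
        for est in (
            ivw_fixed(four_snp_ratios),
            egger(four_snp_panel),
            weighted_median(four_snp_ratios, n_boot=200, seed=0),
            weighted_mode(four_snp_ratios, n_boot=200, seed=0),
        ):
            assert est.or_ == pytest.approx(math.exp(est.beta), rel=1e-12)
            assert est.or_ci_low == pytest.approx(math.exp(est.ci_low), rel=1e-12)
            assert est.or_ci_high == pytest.approx(math.exp(est.ci_high), rel=1e-12)
            assert est.ci_low <= est.beta <= est.ci_high
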