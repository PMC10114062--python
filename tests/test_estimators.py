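import numpy as np
import pytest

from mrscreen.estimators import (
    MRInput,
    egger,
    heterogeneity,
    ivw_mre,
    leave_one_out,
    plot_frames,
    simex_egger,
    wald_ratios,
    weighted_median,
    weighted_mode,
    _weighted_median_core,
    _weighted_mode_core,
)


def _mri(b_X, b_Y, se_X=None, se_Y=None, **kw):
    b_X = np.asarray(b_X, float)
    b_Y = np.asarray(b_Y, float)
    se_X = np.full_like(b_X, 0.001) if se_X is None else np.asarray(se_X, float)
    se_Y = np.full_like(b_Y, 1.0) if se_Y is None else np.asarray(se_Y, float)
    return MRInput(b_X, se_X, b_Y, se_Y, **kw)


class TestWaldRatios:
    def test_basic_ratio_and_se(self):
        out = wald_ratios(_mri([1.0], [0.5], se_Y=[0.1]))
        assert out == [(0.5, 0.1)]

    def test_negative_exposure_effect_flips_sign(self):
        out = wald_ratios(_mri([-1.0], [0.5], se_Y=[0.1]))
        assert out[0][0] == pytest.approx(-0.5)
        assert out[0][1] == pytest.approx(0.1)

    def test_zero_exposure_effect_excluded(self):
        out = wald_ratios(_mri([0.0, 1.0], [0.5, 0.5]))
        assert len(out) == 1

    def test_first_order_delta_close_to_second_order_for_precise_exposure(self):
        # second-order delta expansion: var ~ (se_Y/b_X)^2 + (b_Y se_X / b_X^2)^2;
        # with se_X/|b_X| < 0.05 the first-order se is within 1%
        b_X, b_Y, se_X, se_Y = 1.0, 0.5, 0.04, 0.1
        first = se_Y / abs(b_X)
        second = np.sqrt((se_Y / b_X) ** 2 + (b_Y * se_X / b_X**2) ** 2)
        assert abs(second - first) / second < 0.02


class TestIvwMre:
    def test_closed_form_two_instrument_example(self):
        res, het = ivw_mre(_mri([1.0, 1.0], [0.5, 0.7]))
        assert res.estimate == pytest.approx(0.6)
        assert het.Q == pytest.approx(0.02)
        assert het.i2_percent == 0.0
        assert res.se == pytest.approx(np.sqrt(0.5))  # floored at fixed effects

    def test_identical_ratios_no_heterogeneity(self):
        res, het = ivw_mre(_mri([1.0, 2.0, 3.0], [0.4, 0.8, 1.2]))
        assert het.Q == pytest.approx(0.0, abs=1e-20)
        assert het.i2_percent == 0.0

    def test_i2_from_q(self):
        assert heterogeneity(8.0, 4).i2_percent == pytest.approx(50.0)
        assert heterogeneity(2.0, 4).i2_percent == 0.0

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(3)
        b_X = rng.normal(0.1, 0.05, 20)
        b_Y = 0.3 * b_X + rng.normal(0, 0.01, 20)
        se_Y = rng.uniform(0.005, 0.02, 20)
        base, _ = ivw_mre(_mri(b_X, b_Y, se_Y=se_Y))
        flip = rng.random(20) < 0.5
        s = np.where(flip, -1.0, 1.0)
        flipped, _ = ivw_mre(_mri(b_X * s, b_Y * s, se_Y=se_Y))
        assert flipped.estimate == pytest.approx(base.estimate)
        assert flipped.se == pytest.approx(base.se)

    def test_single_instrument_not_applicable(self):
        res, _ = ivw_mre(_mri([1.0], [0.5]))
        assert not res.applicable

    def test_no_floor_config_can_shrink_se(self):
        mri = _mri([1.0, 2.0, 3.0], [0.4, 0.8, 1.2])  # Q = 0
        floored, _ = ivw_mre(mri)
        free, _ = ivw_mre(mri, se_floor=False)
        assert free.se < floored.se


class TestEgger:
    def test_exact_affine_data(self):
        res = egger(_mri([1.0, 2.0, 3.0], [1.1, 2.1, 3.1]))
        assert res.estimate == pytest.approx(1.0)
        assert res.extra["egger_intercept"] == pytest.approx(0.1)

    def test_no_spread_flagged_unusable(self):
        res = egger(_mri([1.0, 1.0, 1.0], [0.5, 0.6, 0.7]))
        assert not res.applicable

    def test_orientation_invariance_to_joint_sign_flips(self):
        rng = np.random.default_rng(5)
        b_X = rng.normal(0.1, 0.05, 15)
        b_Y = 0.05 + 0.4 * b_X + rng.normal(0, 0.01, 15)
        base = egger(_mri(b_X, b_Y))
        s = np.where(rng.random(15) < 0.5, -1.0, 1.0)
        flipped = egger(_mri(b_X * s, b_Y * s))
        assert flipped.estimate == pytest.approx(base.estimate)
        assert flipped.extra["egger_intercept"] == pytest.approx(
            base.extra["egger_intercept"]
        )

    def test_i2gx_approaches_one_without_measurement_error(self):
        rng = np.random.default_rng(9)
        b_X = rng.normal(0.1, 0.05, 200)
        res = egger(_mri(b_X, 0.3 * b_X, se_X=np.full(200, 1e-6)))
        assert res.extra["i2gx"] > 0.999
        assert res.estimate == pytest.approx(0.3, abs=1e-6)

    def test_too_few_instruments(self):
        assert not egger(_mri([1.0, 2.0], [0.1, 0.2])).applicable


class TestSimexEgger:
    def test_single_point_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            simex_egger(_mri([1, 2, 3], [1, 2, 3]), lambda_grid=[1.0])

    def test_no_measurement_error_matches_plain_egger(self):
        rng = np.random.default_rng(11)
        b_X = rng.normal(0.1, 0.05, 30)
        b_Y = 0.4 * b_X + rng.normal(0, 0.005, 30)
        mri = _mri(b_X, b_Y, se_X=np.full(30, 1e-8), se_Y=np.full(30, 0.005))
        naive = egger(mri)
        sx = simex_egger(mri, seed=1, B=200)
        assert sx.estimate == pytest.approx(naive.estimate, abs=1e-4)

    def test_corrects_attenuation_bias(self):
        rng = np.random.default_rng(13)
        L, slope = 60, 0.5
        bx_true = rng.uniform(0.05, 0.25, L)
        se_X = np.full(L, 0.04)
        b_X = bx_true + rng.normal(0, se_X)
        b_Y = slope * bx_true + rng.normal(0, 0.01, L)
        mri = _mri(b_X, b_Y, se_X=se_X, se_Y=np.full(L, 0.01))
        naive = egger(mri)
        assert 0.6 < naive.extra["i2gx"] <= 0.95
        sx = simex_egger(mri, seed=2)
        assert abs(sx.estimate - slope) < abs(naive.estimate - slope)


class TestWeightedMedian:
    def test_symmetric_equal_weight_example(self):
        res = weighted_median(_mri([1.0, 1.0, 1.0], [0.4, 0.5, 0.9]), boot_B=50, seed=0)
        assert res.estimate == pytest.approx(0.5)

    def test_matches_segment_scan_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            L = int(rng.integers(5, 16))
            ratios = rng.normal(0.3, 0.5, L)
            weights = rng.uniform(0.1, 5.0, L)
            est = _weighted_median_core(ratios, weights)
            assert est == pytest.approx(_brute_force_wm(ratios, weights), abs=1e-12)

    def test_robust_to_single_wild_outlier(self):
        rng = np.random.default_rng(19)
        b_X = np.full(10, 0.1)
        b_Y = 0.05 + rng.normal(0, 0.001, 10)
        b_Y[0] = 5.0  # wild ratio
        mri = _mri(b_X, b_Y, se_Y=np.full(10, 0.01))
        res = weighted_median(mri, boot_B=300, seed=5)
        assert abs(res.estimate - 0.5) <= res.se


def _brute_force_wm(ratios, weights):
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order] / np.sum(weights)
    s = np.cumsum(w) - w / 2
    if 0.5 <= s[0]:
        return r[0]
    if 0.5 >= s[-1]:
        return r[-1]
    for k in range(len(r) - 1):
        if s[k] <= 0.5 <= s[k + 1]:
            return r[k] + (0.5 - s[k]) / (s[k + 1] - s[k]) * (r[k + 1] - r[k])
    raise AssertionError


class TestWeightedMode:
    def test_dominant_cluster_wins(self):
        res = weighted_mode(
            _mri([1.0] * 4, [0.5, 0.5, 0.5, 2.0]), boot_B=50, seed=0
        )
        assert res.estimate == pytest.approx(0.5, abs=0.05)

    def test_matches_dense_grid_argmax(self):
        rng = np.random.default_rng(23)
        ratios = rng.normal(0.3, 0.2, 12)
        weights = rng.uniform(0.5, 2.0, 12)
        est = _weighted_mode_core(ratios, weights, grid_size=512)
        # brute force on a 20x denser grid
        w = weights / weights.sum()
        mu = np.sum(w * ratios)
        sd = np.sqrt(np.sum(w * (ratios - mu) ** 2))
        med = _brute_force_wm(ratios, weights)
        mad = 1.4826 * _brute_force_wm(np.abs(ratios - med), weights)
        h = 0.9 * min(sd, mad) * len(ratios) ** (-0.2)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512 * 20)
        dens = np.sum(
            w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2),
            axis=1,
        )
        fine = grid[np.argmax(dens)]
        spacing = (grid[-1] - grid[0]) / 511
        assert abs(est - fine) <= spacing

    def test_identical_ratios_returned_exactly(self):
        res = weighted_mode(_mri([1.0, 2.0, 4.0], [0.7, 1.4, 2.8]), boot_B=0)
        assert res.estimate == pytest.approx(0.7)


class TestLeaveOneOut:
    def test_counts_and_l_used(self):
        out = leave_one_out(_mri([1, 2, 3], [0.5, 1.0, 1.5]))
        assert len(out) == 3
        assert all(r.L_used == 2 for _, r in out)

    def test_planted_outlier_shifts_exactly_one_fit(self):
        b_X = np.full(10, 1.0)
        b_Y = np.full(10, 0.5)
        b_Y[3] = 3.0
        out = leave_one_out(_mri(b_X, b_Y, se_Y=np.full(10, 0.05)))
        ests = {vid: r.estimate for vid, r in out}
        clean = [e for vid, e in ests.items() if vid != "v3"]
        assert ests["v3"] == pytest.approx(0.5)
        assert min(clean) > 0.6  # still dragged up by the outlier


class TestPlotFrames:
    def test_shapes_and_slope_consistency(self):
        mri = _mri([1.0, 2.0, 3.0, 4.0], [0.5, 1.0, 1.5, 2.0])
        res, _ = ivw_mre(mri)
        scatter, funnel, forest = plot_frames(mri, [res])
        assert len(funnel) == 4
        assert (forest["kind"] == "pooled").sum() == 1
        np.testing.assert_allclose(
            scatter["fit_ivw_mre"], res.estimate * mri.b_X, rtol=1e-12
        )
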