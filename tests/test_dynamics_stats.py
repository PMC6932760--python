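"""Welch tests, two-phase slope fits, displacement and rocking analyses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from spindlequant import (
    displacement_analysis,
    fit_phase_slopes,
    normalize_t0,
    rocking_analysis,
    timepoint_comparison,
    welch_t_test,
)
from spindlequant.dynamics_stats import benjamini_hochberg
from spindlequant.quantify import Track


def welch_formula_oracle(a, b):
    """Direct transcription of the Welch statistic and Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    sa = a.var(ddof=1) / len(a)
    sb = b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, p


class TestWelch:
    def test_identical_groups_give_t0_p1(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0

    def test_swapping_groups_negates_t_keeps_p(self):
        a, b = [1.0, 2.0, 4.0], [2.5, 3.1, 5.0]
        r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_formula_oracle_and_scipy(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a = rng.normal(0, 1, 10)
            b = rng.normal(0.5, 2, 10)
            res = welch_t_test(a, b)
            t_o, p_o = welch_formula_oracle(a, b)
            assert res.t_statistic == pytest.approx(t_o)
            assert res.p_value == pytest.approx(p_o)
            sp = sps.ttest_ind(a, b, equal_var=False)
            assert res.t_statistic == pytest.approx(sp.statistic)
            assert res.p_value == pytest.approx(sp.pvalue)

    def test_both_groups_constant_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            welch_t_test([1.0, 1.0, 1.0], [2.0, 2.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        shift=st.floats(-100, 100),
        seed=st.integers(0, 1000),
    )
    def test_p_invariant_to_common_shift_and_exchange(self, shift, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 8)
        b = rng.normal(1, 3, 12)
        base = welch_t_test(a, b)
        shifted = welch_t_test(a + shift, b + shift)
        swapped = welch_t_test(b, a)
        assert shifted.p_value == pytest.approx(base.p_value, rel=1e-9)
        assert swapped.p_value == pytest.approx(base.p_value, rel=1e-12)


def normal_equation_slope(t, y):
    """Closed-form OLS slope/intercept via the normal equations."""
    t, y = np.asarray(t, float), np.asarray(y, float)
    n = len(t)
    sxx = (t**2).sum() - t.sum() ** 2 / n
    sxy = (t * y).sum() - t.sum() * y.sum() / n
    slope = sxy / sxx
    return slope, y.mean() - slope * t.mean()


class TestPhaseSlopes:
    def test_exact_line_recovered_on_both_windows(self):
        t = np.arange(0, 700, 30.0)
        v = 3.0 + 0.5 * t
        fit = fit_phase_slopes(t, v, 540.0)
        assert fit.slope1 == pytest.approx(0.5, rel=1e-12)
        assert fit.slope2 == pytest.approx(0.5, rel=1e-12)
        assert fit.r_squared1 == pytest.approx(1.0)
        assert fit.r_squared2 == pytest.approx(1.0)

    def test_two_piece_line_recovered_to_machine_precision(self):
        t = np.arange(0, 690, 30.0)
        v = np.where(t <= 540, 1 + 0.01024 * t,
                     1 + 0.01024 * 540 + 0.06733 * (t - 540))
        fit = fit_phase_slopes(t, v, 540.0)
        assert fit.slope1 == pytest.approx(0.01024, rel=1e-9)
        assert fit.slope2 == pytest.approx(0.06733, rel=1e-9)

    def test_boundary_point_belongs_to_phase_one(self):
        t = np.array([0.0, 270.0, 540.0, 541.0, 600.0])
        v = np.array([0.0, 1.0, 5.0, 0.0, 0.0])
        fit = fit_phase_slopes(t, v, 540.0)
        s1, _ = normal_equation_slope(t[:3], v[:3])
        assert fit.slope1 == pytest.approx(s1)

    def test_random_series_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 660, 30.0)
        v = rng.normal(0, 1, t.size)
        fit = fit_phase_slopes(t, v, 540.0)
        s1, i1 = normal_equation_slope(t[t <= 540], v[t <= 540])
        s2, i2 = normal_equation_slope(t[t > 540], v[t > 540])
        assert fit.slope1 == pytest.approx(s1)
        assert fit.slope2 == pytest.approx(s2)
        assert fit.intercept1 == pytest.approx(i1)
        assert fit.intercept2 == pytest.approx(i2)

    def test_insufficient_points_in_a_phase_rejected(self):
        with pytest.raises(ValueError, match=">= 2 points"):
            fit_phase_slopes([0, 30, 60], [1, 2, 3], 540.0)

    def test_noise_free_fig2_ground_truth_series_recovers_printed_slopes(self):
        from dataclasses import replace
        from spindlequant import builtin_preset, generate_movie

        p = replace(builtin_preset("fig2_rtnl1"), n_cytoplasm_sites=2)
        _, gt = generate_movie(p)
        t = p.times_s()
        fit = fit_phase_slopes(t, gt.pole_fold(), 540.0)
        assert fit.slope1 == pytest.approx(0.01024, abs=1e-5)
        assert fit.slope2 == pytest.approx(0.06733, abs=1e-5)


def _pole_track(xy, track_id=1, interval=35.0):
    xy = np.asarray(xy, float)
    n = len(xy)
    return Track(
        track_id=track_id,
        roi_class="spindle",
        frames=np.arange(n),
        times_s=np.arange(n) * interval,
        mean_intensity=np.ones(n),
        max_intensity=np.ones(n),
        centroid_x_um=xy[:, 0],
        centroid_y_um=xy[:, 1],
    )


class TestDisplacement:
    def test_static_pole_has_zero_everything(self):
        fit = displacement_analysis(_pole_track([(5, 5)] * 6))
        assert np.all(fit.displacement_um == 0)
        assert fit.max_displacement_um == 0
        assert fit.se_mean_step_um == 0
        assert fit.slope == 0.0
        assert 0 <= fit.r_squared <= 1
        assert 0 < fit.p_value <= 1

    def test_uniform_drift_gives_linear_model(self):
        v = 0.2  # um per frame
        xy = [(5 + v * k, 5) for k in range(8)]
        fit = displacement_analysis(_pole_track(xy, interval=35.0))
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(v / 35.0)
        assert fit.max_displacement_um == pytest.approx(v * 7)
        assert fit.se_mean_step_um == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_global_translation_and_rotation(self):
        rng = np.random.default_rng(3)
        xy = rng.normal(0, 0.3, (7, 2)).cumsum(axis=0) + 10
        base = displacement_analysis(_pole_track(xy))
        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = xy @ rot.T + np.array([12.0, -4.0])
        other = displacement_analysis(_pole_track(moved))
        assert other.displacement_um == pytest.approx(base.displacement_um)
        assert other.se_mean_step_um == pytest.approx(base.se_mean_step_um)
        assert other.max_displacement_um == pytest.approx(base.max_displacement_um)

    def test_track_with_gap_rejected(self):
        tr = _pole_track([(0, 0)] * 4)
        tr.frames = np.array([0, 1, 3, 4])
        with pytest.raises(ValueError, match="gap"):
            displacement_analysis(tr)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            displacement_analysis(_pole_track([(0, 0), (1, 1)]))


class TestRocking:
    def test_rigid_rotation_by_five_degrees(self):
        a0, b0 = np.array([4.0, 5.0]), np.array([6.0, 5.0])
        mid = (a0 + b0) / 2
        theta = np.deg2rad(5.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        a1 = (a0 - mid) @ rot.T + mid
        b1 = (b0 - mid) @ rot.T + mid
        series = rocking_analysis(
            _pole_track([a0, a1, a0]), _pole_track([b0, b1, b0])
        )
        assert series.angle_deg[1] == pytest.approx(5.0, abs=1e-9)
        assert series.amplitude_deg == pytest.approx(5.0, abs=1e-9)

    def test_no_rotation_gives_zero_series(self):
        series = rocking_analysis(
            _pole_track([(4, 5)] * 5), _pole_track([(6, 5)] * 5)
        )
        assert np.all(series.angle_deg == 0)
        assert series.amplitude_deg == 0

    def test_sign_follows_rotation_direction(self):
        a = _pole_track([(4, 5), (4, 5)])
        b_ccw = _pole_track([(6, 5), (6 - 0.0, 5.2)])
        assert rocking_analysis(a, b_ccw).angle_deg[1] > 0

    def test_coincident_poles_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            rocking_analysis(
                _pole_track([(4, 5), (5, 5)]), _pole_track([(6, 5), (5, 5)])
            )


def _fold_tracks(folds, roi_class="spindle", start_id=1):
    tracks = []
    for k, fold in enumerate(folds):
        fold = np.asarray(fold, float)
        tr = Track(
            track_id=start_id + k,
            roi_class=roi_class,
            frames=np.arange(fold.size),
            times_s=np.arange(fold.size) * 35.0,
            mean_intensity=100 * fold,
            max_intensity=200 * fold,
            centroid_x_um=np.zeros(fold.size),
            centroid_y_um=np.zeros(fold.size),
        )
        tracks.append(normalize_t0(tr))
    return tracks


class TestTimepointComparison:
    def test_identical_conditions_give_p_one(self):
        folds = [[1, 1.1, 1.2], [1, 1.15, 1.25], [1, 1.05, 1.18]]
        out = timepoint_comparison(_fold_tracks(folds), _fold_tracks(folds), 2)
        assert (out["p"] == 1.0).all()
        assert (out["t"] == 0.0).all()

    def test_large_shift_gives_small_p_with_matching_sign(self):
        rng = np.random.default_rng(0)
        base = [np.concatenate([[1], 1 + rng.normal(0, 0.01, 4)])
                for _ in range(10)]
        shifted = [f + np.array([0, 0, 0, 0, 5.0]) for f in base]
        out = timepoint_comparison(
            _fold_tracks(shifted), _fold_tracks(base), 4
        )
        assert (out["p"] < 1e-6).all()
        assert (out["t"] > 0).all()

    def test_simulated_conditions_match_formula_oracle(self):
        rng = np.random.default_rng(12)
        enriched = [np.concatenate([[1], 1 + np.abs(rng.normal(0.2, 0.05, 4))])
                    for _ in range(20)]
        flat = [np.concatenate([[1], 1 + rng.normal(0, 0.05, 4)])
                for _ in range(20)]
        ta, tb = _fold_tracks(enriched), _fold_tracks(flat)
        out = timepoint_comparison(ta, tb, 3)
        row = out[out["statistic"] == "fold_mean"].iloc[0]
        ga = [t.fold_mean[3] for t in ta]
        gb = [t.fold_mean[3] for t in tb]
        t_o, p_o = welch_formula_oracle(ga, gb)
        assert row["t"] == pytest.approx(t_o)
        assert row["p"] == pytest.approx(p_o)


def test_benjamini_hochberg_matches_scipy():
    p = [0.001, 0.02, 0.04, 0.2, 0.9]
    assert benjamini_hochberg(p) == pytest.approx(
        sps.false_discovery_control(p)
    )
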