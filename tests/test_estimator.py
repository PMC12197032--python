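"""Vertical force distribution, COP/GRM computation, VPP reconstruction and
the end-to-end pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import footgrf as fg
from footgrf.estimator import (DistributionParams, FDAConfig,
                               cop_and_planar_moments, distribute_vertical,
                               estimate_grf, horizontal_from_vpp,
                               transverse_moment)

from conftest import interior

M_G = 61.6 * 9.80665


class TestDistributeVertical:
    def test_single_supporting_point_takes_all(self):
        d = np.array([[0.0, 0.03, 0.05, 0.2]])
        f = distribute_vertical(np.array([600.0]), d)
        np.testing.assert_allclose(f[0], [600.0, 0.0, 0.0, 0.0], atol=1e-9)

    def test_equal_distances_share_equally(self):
        d = np.full((1, 22), 0.01)
        f = distribute_vertical(np.array([660.0]), d)
        np.testing.assert_allclose(f[0], 30.0, atol=1e-9)

    def test_quadratic_weight_shares(self):
        # d = 0 and d = range/2 with k = 2: weights 1 and 0.25 -> 400/100 N
        d = np.array([[0.0, 0.015]])
        f = distribute_vertical(np.array([500.0]),
                                d, DistributionParams(range_d=0.030,
                                                      exponent_k=2.0))
        np.testing.assert_allclose(f[0], [400.0, 100.0], atol=1e-9)

    def test_all_out_of_range_gives_zero(self):
        d = np.full((3, 5), 0.5)
        f = distribute_vertical(np.full(3, 700.0), d)
        np.testing.assert_allclose(f, 0.0)

    def test_negative_total_clamped(self):
        d = np.zeros((2, 4))
        f = distribute_vertical(np.array([-50.0, 100.0]), d)
        np.testing.assert_allclose(f.sum(axis=1), [0.0, 100.0], atol=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.0, 0.029), st.floats(0.0, 0.029))
    def test_monotone_in_distance(self, d_small, d_big):
        # a point never gains force share by moving further from the ground
        lo, hi = sorted((d_small, d_big))
        others = np.array([0.005, 0.010, 0.020])
        f_lo = distribute_vertical(
            np.array([600.0]), np.array([[lo, *others]]))[0, 0]
        f_hi = distribute_vertical(
            np.array([600.0]), np.array([[hi, *others]]))[0, 0]
        assert f_hi <= f_lo + 1e-9

    def test_conservation_when_loaded(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0.0, 0.05, (50, 22))
        fz = rng.uniform(0.0, 900.0, 50)
        f = distribute_vertical(fz, d)
        loaded = f.sum(axis=1) > 0
        np.testing.assert_allclose(f[loaded].sum(axis=1), fz[loaded], atol=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DistributionParams(range_d=0.0)
        with pytest.raises(ValueError):
            DistributionParams(exponent_k=0.5)


class TestCopAndMoments:
    def test_point_load_identity(self):
        f = np.array([[500.0]])
        p = np.array([[[0.10, 0.05, 0.0]]])
        cop, mx, my = cop_and_planar_moments(f, p)
        np.testing.assert_allclose(cop[0], [0.10, 0.05], atol=1e-12)
        assert mx[0] == pytest.approx(500.0 * 0.05)
        assert my[0] == pytest.approx(-500.0 * 0.10)

    def test_equal_forces_cop_at_midpoint(self):
        f = np.array([[200.0, 200.0]])
        p = np.array([[[0.0, 0.0, 0.0], [0.2, 0.1, 0.0]]])
        cop, _, _ = cop_and_planar_moments(f, p)
        np.testing.assert_allclose(cop[0], [0.1, 0.05], atol=1e-12)

    def test_weighted_centroid_and_sagittal_moment(self):
        # 400/100 N at x = 0 and 0.2 -> cop_x = 0.04 m, My = -20 N m
        f = np.array([[400.0, 100.0]])
        p = np.array([[[0.0, 0.0, 0.0], [0.2, 0.0, 0.0]]])
        cop, mx, my = cop_and_planar_moments(f, p)
        assert cop[0, 0] == pytest.approx(0.04)
        assert my[0] == pytest.approx(-20.0)
        assert mx[0] == pytest.approx(0.0)

    def test_unloaded_frame_flagged(self):
        cop, mx, my = cop_and_planar_moments(
            np.zeros((1, 3)), np.zeros((1, 3, 3)))
        assert np.isnan(cop).all()
        assert mx[0] == 0.0 and my[0] == 0.0


class TestVpp:
    def test_cop_under_vpp_gives_vertical_force(self):
        fh = horizontal_from_vpp(np.array([600.0]), np.array([[0.2, -0.1]]),
                                 np.array([[0.2, -0.1, 1.0]]))
        np.testing.assert_allclose(fh, 0.0, atol=1e-12)

    def test_similar_triangles(self):
        # Fz = 600 N, VPP at (0.10, 0, 1.0), cop at origin -> Fx = 60 N
        fh = horizontal_from_vpp(np.array([600.0]), np.array([[0.0, 0.0]]),
                                 np.array([[0.10, 0.0, 1.0 - 0.0375]]),
                                 vpp_height=0.0375)
        assert fh[0, 0] == pytest.approx(60.0)
        assert fh[0, 1] == pytest.approx(0.0)

    def test_swing_phase_zero(self):
        fh = horizontal_from_vpp(np.array([0.0]), np.array([[np.nan, np.nan]]),
                                 np.array([[0.0, 0.0, 1.0]]))
        np.testing.assert_allclose(fh, 0.0)

    def test_vpp_below_ground_rejected(self):
        with pytest.raises(ValueError, match="VPP"):
            horizontal_from_vpp(np.array([100.0]), np.array([[0.0, 0.0]]),
                                np.array([[0.0, 0.0, -2.0]]))

    def test_transverse_moment_examples(self):
        assert transverse_moment(np.array([[0.5, 0.5]]),
                                 np.array([[0.0, 0.0, 700.0]]))[0] == 0.0
        mz = transverse_moment(np.array([[0.1, 0.0]]),
                               np.array([[0.0, 50.0, 600.0]]))
        assert mz[0] == pytest.approx(5.0)
        assert transverse_moment(np.array([[0.0, 0.0]]),
                                 np.array([[30.0, 50.0, 600.0]]))[0] == 0.0

    def test_nan_cop_gives_zero_moment(self):
        mz = transverse_moment(np.array([[np.nan, np.nan]]),
                               np.array([[10.0, 10.0, 0.0]]))
        assert mz[0] == 0.0


class TestPipeline:
    def test_static_standing(self, static_trial):
        rec = estimate_grf(static_trial, static_trial, 1.66, 61.6)
        assert rec.total.force[:, 2].mean() == pytest.approx(M_G, rel=1e-3)
        assert np.abs(rec.total.force[:, :2]).max() < 1.0
        split = rec.left.force[:, 2].mean() / rec.total.force[:, 2].mean()
        assert split == pytest.approx(0.5, abs=0.02)

    def test_swing_foot_record_zero(self, normal_trial, normal_estimate):
        # mid-swing (middle 40% between toe off and the next heel strike):
        # the airborne foot's record is identically zero
        scn = normal_trial.scenario
        stride_t, _, _ = scn.timing()
        swing_t = (1.0 - scn.stance_fraction) * stride_t
        t = normal_trial.truth.time
        mask = np.zeros(t.size, dtype=bool)
        for to in normal_trial.events["right"]["toe_off"]:
            mask |= (t > to + 0.3 * swing_t) & (t < to + 0.7 * swing_t)
        assert mask.sum() > 10
        assert np.abs(normal_estimate.right.force[mask]).max() < 1e-9
        assert np.abs(normal_estimate.right.moment[mask]).max() < 1e-9
        assert np.isnan(normal_estimate.right.cop[mask]).all()

    def test_conservation_framewise(self, normal_trial, normal_estimate):
        from footgrf.body import (scale_model, segment_kinematics,
                                  total_external_force)
        from footgrf.io import filter_markers
        dyn = filter_markers(normal_trial.markers, 6.0)
        model = scale_model(1.66, 61.6)
        fext = total_external_force(segment_kinematics(dyn, model), model)
        lr = normal_estimate.left.force[:, 2] + normal_estimate.right.force[:, 2]
        np.testing.assert_allclose(lr, np.maximum(0.0, fext[:, 2]), atol=1e-6)

    def test_vpp_geometry_identity(self, normal_estimate):
        # the reconstructed force line pierces COM + 37.5 mm on loaded frames
        rec = normal_estimate
        vpp = rec.body_com + np.array([0.0, 0.0, rec.vpp_height])
        for side in (rec.left, rec.right):
            loaded = side.force[:, 2] > 0
            s = vpp[loaded, 2] / side.force[loaded, 2]
            px = side.cop[loaded, 0] + side.force[loaded, 0] * s
            py = side.cop[loaded, 1] + side.force[loaded, 1] * s
            residual = np.hypot(px - vpp[loaded, 0], py - vpp[loaded, 1])
            assert residual.max() < 1e-9

    def test_cop_inside_contact_hull(self, normal_trial, normal_estimate):
        from footgrf.contact import build_contact_points, contact_distances
        from footgrf.io import filter_markers
        dyn = filter_markers(normal_trial.markers, 6.0)
        for side_name, side in (("left", normal_estimate.left),
                                ("right", normal_estimate.right)):
            cps = build_contact_points(normal_trial.static_markers, side_name)
            pts = contact_distances(cps, dyn).positions
            loaded = np.where(side.force[:, 2] > 0)[0]
            for i in loaded[:: max(1, len(loaded) // 40)]:
                xy = pts[i, :, :2]
                # COP is a convex combination of point positions: it must lie
                # within the axis-aligned bounds and, more strictly, satisfy
                # every supporting halfplane of the hull
                c = side.cop[i]
                assert xy[:, 0].min() - 1e-9 <= c[0] <= xy[:, 0].max() + 1e-9
                assert xy[:, 1].min() - 1e-9 <= c[1] <= xy[:, 1].max() + 1e-9

    def test_vertical_recovery_against_truth(self, normal_trial,
                                             normal_estimate):
        from footgrf.validation import pearson_rho
        sl = interior(normal_trial)
        rho = pearson_rho(normal_estimate.right.force[sl, 2],
                          normal_trial.truth.right.force[sl, 2])
        assert rho >= 0.97

    def test_range_limit_reduces_to_single_point(self, static_trial):
        # range_d -> 0+ with points on the floor: load still fully assigned,
        # COP pinned to the supporting points
        cfg = FDAConfig(distribution=DistributionParams(range_d=1e-6))
        rec = estimate_grf(static_trial, static_trial, 1.66, 61.6, cfg)
        assert rec.total.force[:, 2].mean() == pytest.approx(M_G, rel=1e-3)

    def test_normalized_output(self, static_trial):
        cfg = FDAConfig(normalize_by_mass=True)
        rec = estimate_grf(static_trial, static_trial, 1.66, 61.6, cfg)
        assert rec.normalized
        assert rec.total.force[:, 2].mean() == pytest.approx(9.80665, rel=1e-3)

    def test_stage_errors_are_labelled(self, static_trial):
        bad = static_trial.subset([l for l in static_trial.labels
                                   if not l.startswith("R.Heel")])
        with pytest.raises(RuntimeError, match="stage"):
            estimate_grf(bad, bad, 1.66, 61.6)

    def test_record_csv_round_trip(self, tmp_path, normal_estimate):
        path = tmp_path / "grf.csv"
        normal_estimate.to_csv(str(path))
        back = fg.GroundReactionRecord.from_csv(str(path))
        np.testing.assert_allclose(back.total.force,
                                   normal_estimate.total.force, atol=1e-6)
        np.testing.assert_allclose(back.left.moment,
                                   normal_estimate.left.moment, atol=1e-6)
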