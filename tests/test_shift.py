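import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import localtf as lt
from localtf.shift import EditOperation, ShiftField, combine_shift_fields, zero_shift_field
from localtf.volume_io import ScalarVolume


class TestDissimilarities:
    def test_mahalanobis_identity_and_euclidean(self):
        assert lt.dissim_mahalanobis([1.0, 2.0], [1.0, 2.0], np.eye(2)) == 0.0
        assert lt.dissim_mahalanobis([3.0, 4.0], [0.0, 0.0], np.eye(2)) == pytest.approx(5.0)

    def test_mahalanobis_hand_quadratic_form(self):
        V = np.diag([4.0, 1.0])
        assert lt.dissim_mahalanobis([2.0, 0.0], [0.0, 0.0], V) == pytest.approx(1.0)

    def test_mahalanobis_symmetric(self):
        V = np.array([[2.0, 0.5], [0.5, 1.0]])
        a, b = np.array([0.3, 0.9]), np.array([1.2, -0.4])
        assert lt.dissim_mahalanobis(a, b, V) == pytest.approx(lt.dissim_mahalanobis(b, a, V))

    @pytest.mark.parametrize(
        "u,v,expected",
        [([1, 0, 0], [1, 0, 0], 0.0), ([1, 0, 0], [0, 1, 0], 1.0), ([1, 0, 0], [-1, 0, 0], 2.0)],
    )
    def test_dot_examples(self, u, v, expected):
        assert lt.dissim_dot(np.array(u, float), np.array(v, float)) == pytest.approx(expected)

    def test_orientation_sign_invariant(self):
        u = np.array([0.6, 0.8, 0.0])
        assert lt.dissim_orientation(u, u) == pytest.approx(0.0)
        assert lt.dissim_orientation(u, -u) == pytest.approx(0.0)
        assert lt.dissim_orientation(u, np.array([-0.8, 0.6, 0.0])) == pytest.approx(1.0)

    def test_orientation_sixty_degrees_is_half(self):
        """The 0.5 dissimilarity bound is the 60-degree separation cone."""
        v = np.array([math.cos(math.pi / 3), math.sin(math.pi / 3), 0.0])
        assert lt.dissim_orientation(np.array([1.0, 0.0, 0.0]), v) == pytest.approx(0.5)

    def test_orientation_zero_vector_maximal(self):
        assert lt.dissim_orientation(np.zeros(3), np.array([1.0, 0, 0])) == 1.0

    def test_lambda_ratio_metric(self):
        assert lt.dissim_lambda_ratio(0.4, 0.4, 0.3) == 0.0
        assert lt.dissim_lambda_ratio(0.7, 0.4, 0.3) == pytest.approx(1.0)
        assert lt.dissim_lambda_ratio(0.8, 0.2, 0.3) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            lt.dissim_lambda_ratio(0.1, 0.2, 0.0)


class TestWeights:
    def test_f_F_examples(self):
        assert lt.f_F(0.0, 5.0) == 1.0
        assert lt.f_F(3.0, 0.0) == 1.0
        assert lt.f_F(0.1, 10.0) == pytest.approx(math.exp(-1.0))

    def test_f_E_examples(self):
        assert lt.f_E(6.0, 6.0) == pytest.approx(0.5)
        assert lt.f_E(26.0, 6.0) < 1e-8
        assert lt.f_E(0.0, 6.0) == pytest.approx(1.0 / (1.0 + math.exp(-6.0)))

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(0, 100), st.floats(0, 100), st.floats(0, 100), st.floats(0, 50)
    )
    def test_g_bounded_unit_interval(self, d_F, alpha, d_E, beta):
        g = lt.f_F(d_F, alpha) * lt.f_E(d_E, beta)
        assert 0.0 <= g <= 1.0

    def test_f_E_no_overflow_far_away(self):
        assert lt.f_E(1e4, 6.0) == 0.0  # underflows cleanly, no warning/overflow


class TestRoiDistance:
    def test_at_center_zero(self):
        assert lt.roi_distance(np.array([3.0, 4.0, 5.0]), [(3, 4, 5)]) == 0.0

    def test_isotropic_offset(self):
        assert lt.roi_distance(np.array([3.0, 4.0, 0.0]), [(0, 0, 0)]) == pytest.approx(5.0)

    def test_min_over_centers(self):
        d = lt.roi_distance(np.array([0.0, 0.0, 0.0]), [(7, 0, 0), (0, 2, 0)])
        assert d == pytest.approx(2.0)

    def test_anisotropic_scaling_relative_to_x(self):
        d = lt.roi_distance(np.array([0.0, 0.0, 1.0]), [(0, 0, 0)], spacing=(1, 1, 4))
        assert d == pytest.approx(4.0)
        d = lt.roi_distance(np.array([1.0, 0.0, 0.0]), [(0, 0, 0)], spacing=(2, 2, 8))
        assert d == pytest.approx(1.0)  # x-voxel units

    def test_empty_centers_rejected(self):
        with pytest.raises(ValueError):
            lt.roi_distance(np.zeros(3), [])


from conftest import brute_force_delta


@pytest.fixture(scope="module")
def small():
    rng = np.random.default_rng(2)
    vol, _ = lt.make_tube((16, 16, 16), (8, 8, 8), (1, 1, 0), 2.0, 0.9)
    data = np.clip(vol.data + rng.normal(0, 0.02, vol.shape), 0, 1)
    vol = ScalarVolume(data, (1.0, 1.0, 2.0))
    fv = lt.build_feature_volume(vol)
    return vol, fv


class TestComputeShiftField:

    @pytest.mark.parametrize("metric", ["orientation", "lambda_ratio", "mahalanobis", "dot"])
    def test_matches_bruteforce_triple_loop(self, small, metric):
        vol, fv = small
        edit = EditOperation((8, 8, 8), ((8, 8, 8), (4, 10, 8)), 10.0, 6.0, metric)
        field = lt.compute_shift_field(vol, fv, edit)
        expected = brute_force_delta(vol, fv, edit)
        np.testing.assert_allclose(field.delta, expected, rtol=1e-10, atol=1e-14)

    def test_worked_shift_value(self):
        """(I0 - I) * e^-1 * 0.5 for alpha=10, d_F=0.1, d_E=beta=6."""
        delta = (0.9 - 0.3) * lt.f_F(0.1, 10.0) * lt.f_E(6.0, 6.0)
        assert delta == pytest.approx(0.6 * math.exp(-1.0) * 0.5)
        assert delta == pytest.approx(0.1104, abs=5e-5)

    def test_delta_zero_at_x0_and_equal_intensity(self, small):
        vol, fv = small
        edit = EditOperation((8, 8, 8), ((6, 6, 8),), 5.0, 6.0, "orientation")
        field = lt.compute_shift_field(vol, fv, edit)
        assert field.delta[8, 8, 8] == 0.0
        equal = vol.data == vol.data[8, 8, 8]
        assert np.all(field.delta[equal] == 0.0)

    def test_alpha_monotonicity(self, small):
        vol, fv = small
        deltas = [
            np.abs(
                lt.compute_shift_field(
                    vol, fv, EditOperation((8, 8, 8), ((8, 8, 8),), a, 6.0, "orientation")
                ).delta
            )
            for a in (0.0, 1.0, 10.0, 100.0)
        ]
        for lo, hi in zip(deltas[1:], deltas):
            assert np.all(lo <= hi + 1e-15)

    def test_beta_monotonicity(self, small):
        vol, fv = small
        deltas = [
            np.abs(
                lt.compute_shift_field(
                    vol, fv, EditOperation((8, 8, 8), ((8, 8, 8),), 5.0, b, "orientation")
                ).delta
            )
            for b in (1.0, 6.0, 20.0)
        ]
        for lo, hi in zip(deltas, deltas[1:]):
            assert np.all(lo <= hi + 1e-15)

    def test_suppressed_reference_orientation_warns(self, small, caplog):
        vol, fv = small
        corner = (0, 0, 15)
        assert not np.any(fv.e3[corner])  # dark corner: no orientation
        edit = EditOperation(corner, (corner,), 10.0, 6.0, "orientation")
        with caplog.at_level("WARNING", logger="localtf.shift"):
            field = lt.compute_shift_field(vol, fv, edit)
        assert "no defined orientation" in caplog.text
        # d_F = 1 everywhere: the edit pulls nothing toward the reference
        g_max = np.exp(-edit.alpha)  # f_F capped by d_F = 1
        assert np.all(np.abs(field.delta) <= np.abs(vol.data[corner] - vol.data) * g_max + 1e-15)

    def test_out_of_bounds_edit_rejected(self, small):
        vol, fv = small
        with pytest.raises(ValueError, match="outside"):
            lt.compute_shift_field(
                vol, fv, EditOperation((8, 8, 16), ((8, 8, 8),), 1.0, 1.0, "orientation")
            )


class TestCombineAndEvaluate:
    def test_single_field_identity(self):
        f = ShiftField(np.ones((2, 2, 2)))
        np.testing.assert_array_equal(combine_shift_fields([f]).delta, f.delta)

    def test_field_plus_negation_cancels(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=(3, 3, 3))
        out = combine_shift_fields([ShiftField(d), ShiftField(-d)])
        np.testing.assert_array_equal(out.delta, 0.0)

    def test_empty_list_gives_zero_field(self):
        out = combine_shift_fields([], shape=(2, 3, 4))
        assert out.shape == (2, 3, 4)
        assert np.all(out.delta == 0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            combine_shift_fields([ShiftField(np.zeros((2, 2, 2))), ShiftField(np.zeros((3, 3, 3)))])

    def test_disjoint_rois_sum_independently(self, small_scene):
        """Edits whose ROIs are far apart do not leak into each other."""
        vol = small_scene.volume
        fv = lt.build_feature_volume(vol)
        e1 = EditOperation((10, 10, 24), ((4, 4, 24),), 2.0, 3.0, "lambda_ratio")
        e2 = EditOperation((40, 40, 24), ((44, 44, 24),), 2.0, 3.0, "lambda_ratio")
        f1 = lt.compute_shift_field(vol, fv, e1)
        f2 = lt.compute_shift_field(vol, fv, e2)
        combined = combine_shift_fields([f1, f2])
        np.testing.assert_array_equal(combined.delta, f1.delta + f2.delta)
        # each ROI is unaffected by the other edit (sigmoid tail < 1e-8)
        near1 = lt.roi_distance(
            np.stack(
                np.meshgrid(*(np.arange(n, dtype=float) for n in vol.shape), indexing="ij"),
                axis=-1,
            ),
            e1.stroke_centers,
        ) <= e1.beta
        assert np.abs(f2.delta[near1]).max() < 1e-8

    def test_shifted_tf_identity_and_clamp(self, ramp_tf):
        I = np.array([0.3, 0.5, 0.95])
        np.testing.assert_array_equal(
            lt.evaluate_shifted_tf(ramp_tf, I, 0.0), ramp_tf(I)
        )
        np.testing.assert_array_equal(
            lt.evaluate_shifted_tf(ramp_tf, 0.95, 0.5), ramp_tf(1.0)
        )

    def test_shifted_lookup_two_point_preset(self):
        tf = lt.TransferFunction1D(((0.8, (0, 0, 0, 0)), (1.0, (1, 1, 1, 1))))
        out = lt.evaluate_shifted_tf(tf, 0.3, 0.6)  # lookup at 0.9
        np.testing.assert_allclose(out, tf(0.9))
        assert out[3] == pytest.approx(0.5)

    def test_zero_shift_field_helper(self, small_scene):
        z = zero_shift_field(small_scene.volume)
        assert z.shape == small_scene.volume.shape
        assert np.all(z.delta == 0)
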