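import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pktopo.config import FULL_PROFILE
from pktopo.geometry import (BasePairFrame, apply_transform,
                             axes_to_vectors, build_a_form_helix,
                             extract_params, make_transform,
                             quasi_uniform_axes)

RNG = np.random.default_rng(20260924)


def random_frame(rng):
    M = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    return BasePairFrame(rng.normal(size=3) * 5.0, M[:, 0], M[:, 1],
                         M[:, 2])


class TestMakeTransform:
    def test_identity(self):
        t = make_transform(0, 0, 0, (0, 0, 0))
        assert np.array_equal(t.matrix, np.eye(4))

    def test_half_turn_about_z(self):
        t = make_transform(0, 0, math.pi, (0, 0, 0))
        assert np.allclose(t.rotation, np.diag([-1.0, -1.0, 1.0]),
                           atol=1e-15)

    def test_matches_quaternion_oracle(self):
        """Rodrigues construction agrees with a quaternion axis-angle
        rotation to machine precision."""
        cases = [(math.pi / 3, math.pi / 4, 1.0, (1, 2, 3))]
        for _ in range(50):
            cases.append((RNG.uniform(0, math.pi),
                          RNG.uniform(0, 2 * math.pi),
                          RNG.uniform(0, 2 * math.pi),
                          tuple(RNG.normal(size=3))))
        for theta, phi, alpha, d in cases:
            t = make_transform(theta, phi, alpha, d)
            axis = np.array([math.sin(theta) * math.cos(phi),
                             math.sin(theta) * math.sin(phi),
                             math.cos(theta)])
            oracle = Rotation.from_quat(
                np.append(axis * math.sin(alpha / 2),
                          math.cos(alpha / 2))).as_matrix()
            assert np.allclose(t.rotation, oracle, atol=1e-12)
            assert np.allclose(t.translation, d)

    @pytest.mark.parametrize("kw,name", [
        (dict(theta=-0.1, phi=0, alpha=0), "theta"),
        (dict(theta=0, phi=7.0, alpha=0), "phi"),
        (dict(theta=0, phi=0, alpha=-1.0), "alpha"),
    ])
    def test_domain_errors_name_parameter(self, kw, name):
        with pytest.raises(ValueError, match=name):
            make_transform(d=(0, 0, 0), **kw)

    def test_matrix_invariants(self):
        t = make_transform(1.1, 2.2, 3.3, (4, 5, 6))
        R = t.rotation
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)
        assert np.isclose(np.linalg.det(R), 1.0, atol=1e-9)
        assert np.array_equal(t.matrix[3], [0, 0, 0, 1])
        rebuilt = make_transform(*t.params[:3], t.params[3:])
        assert np.allclose(rebuilt.matrix, t.matrix, atol=1e-12)


class TestExtractParams:
    def test_identical_frames(self):
        f = random_frame(np.random.default_rng(7))
        t = extract_params(f, f)
        assert t.params == (0, 0, 0, 0, 0, 0) or np.allclose(
            t.params, 0, atol=1e-9)

    def test_round_trip_1000_random(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            p = make_transform(rng.uniform(0, math.pi),
                               rng.uniform(0, 2 * math.pi),
                               rng.uniform(0, 2 * math.pi),
                               rng.normal(size=3) * 10)
            f = random_frame(rng)
            rec = extract_params(f, f.transformed(p))
            assert np.allclose(rec.matrix, p.matrix, atol=1e-9)

    def test_canonical_cos_theta_nonnegative(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            f = random_frame(rng)
            g = random_frame(rng)
            t = extract_params(f, g)
            assert math.cos(t.theta) >= -1e-12

    def test_helix_step_recovers_twist_and_rise(self):
        h = build_a_form_helix(2)
        t = extract_params(h.frame_at(1), h.frame_at(2))
        assert np.isclose(t.alpha, FULL_PROFILE.twist, atol=1e-9)
        assert np.isclose(np.linalg.norm(t.translation),
                          FULL_PROFILE.rise, atol=1e-9)

    def test_five_bp_helix_accumulates_four_twists(self):
        h = build_a_form_helix(5)
        t = extract_params(h.frame_first, h.frame_last)
        expected = (4 * FULL_PROFILE.twist) % (2 * math.pi)
        assert np.isclose(t.alpha, expected, atol=1e-9)

    def test_invalid_frame_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            BasePairFrame(np.zeros(3), np.array([1.0, 0, 0]),
                          np.array([1.0, 0, 0]), np.array([0, 0, 1.0]))


class TestQuasiUniformAxes:
    def test_degenerate_single_axis(self):
        assert quasi_uniform_axes(1) == [(0.0, 0.0)]

    def test_count_error(self):
        with pytest.raises(ValueError):
            quasi_uniform_axes(0)

    def test_spread_100(self):
        V = axes_to_vectors(quasi_uniform_axes(100))
        assert V.shape == (100, 3)
        ang = np.degrees(np.arccos(np.clip(V @ V.T, -1, 1)))
        np.fill_diagonal(ang, 180.0)
        nn = ang.min(axis=1)
        assert ang.min() > 10.0
        assert nn.max() < 30.0
        assert nn.std() / nn.mean() < 0.25

    def test_symmetry_100(self):
        V = axes_to_vectors(quasi_uniform_axes(100))
        assert np.linalg.norm(V.mean(axis=0)) < 0.05


class TestHelixBuilder:
    def test_single_bp(self):
        h = build_a_form_helix(1)
        assert h.n_bp == 1
        assert np.allclose(h.frame_first.origin, h.frame_last.origin)
        assert np.allclose(h.frame_first.axes, h.frame_last.axes)

    def test_span_along_axis(self):
        h = build_a_form_helix(11)
        span = h.bp_center(11) - h.bp_center(1)
        assert np.isclose(np.linalg.norm(span), 10 * FULL_PROFILE.rise,
                          atol=1e-6)

    def test_rise_and_twist_per_step(self):
        h = build_a_form_helix(6)
        for i in range(1, 6):
            step = h.bp_center(i + 1) - h.bp_center(i)
            assert np.isclose(np.linalg.norm(step), FULL_PROFILE.rise,
                              atol=1e-6)
            x1, x2 = h.frame_at(i).x_axis, h.frame_at(i + 1).x_axis
            ang = math.acos(np.clip(x1 @ x2, -1, 1))
            assert np.isclose(ang, FULL_PROFILE.twist, atol=1e-6)

    def test_strand_counts(self):
        h = build_a_form_helix(4)
        assert h.strand5.shape == (4, 2, 3)
        assert h.strand3.shape == (4, 2, 3)

    def test_deterministic(self):
        a = build_a_form_helix(7)
        b = build_a_form_helix(7)
        assert a.beads.tobytes() == b.beads.tobytes()

    def test_size_error(self):
        with pytest.raises(ValueError):
            build_a_form_helix(0)


class TestApplyTransform:
    def test_identity(self):
        X = RNG.normal(size=(10, 3))
        t = make_transform(0, 0, 0, (0, 0, 0))
        assert np.allclose(apply_transform(t, X), X)

    def test_inverse_round_trip(self):
        X = RNG.normal(size=(10, 3))
        t = make_transform(0.3, 1.2, 2.7, (3, -1, 4))
        back = apply_transform(t.inverse(), apply_transform(t, X))
        assert np.allclose(back, X, atol=1e-9)

    def test_isometry(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            X = rng.normal(size=(8, 3)) * 5
            t = make_transform(rng.uniform(0, math.pi),
                               rng.uniform(0, 2 * math.pi),
                               rng.uniform(0, 2 * math.pi),
                               rng.normal(size=3) * 10)
            Y = apply_transform(t, X)
            D_X = np.linalg.norm(X[:, None] - X[None], axis=-1)
            D_Y = np.linalg.norm(Y[:, None] - Y[None], axis=-1)
            assert np.allclose(D_X, D_Y, atol=1e-9)
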