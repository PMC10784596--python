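"""Transform composition, SSD objective, quasi-Newton fitting."""

import numpy as np
import pytest

from cochreg import (
    AffineParams,
    CorrespondenceError,
    GeometryError,
    LandmarkSet,
    ParameterError,
    UnderdeterminedError,
    affine_least_squares,
    apply_transform,
    compose_transform,
    mae,
    register,
    ssd,
)


def random_pair(rng, n=12, spread=5.0):
    X = rng.uniform(-spread, spread, (n, 3))
    Y = rng.uniform(-spread, spread, (n, 3))
    return LandmarkSet(X), LandmarkSet(Y, source="segmented")


class TestCompose:
    def test_identity(self):
        np.testing.assert_array_equal(
            compose_transform(AffineParams.identity()), np.eye(4)
        )

    def test_pure_translation(self):
        T = compose_transform(AffineParams(t_x=1, t_y=2, t_z=3))
        np.testing.assert_allclose(apply_transform(T, np.zeros((1, 3)))[0], [1, 2, 3])

    def test_factor_product_oracle(self):
        # α = π/2 about x composed after scale (2,1,1): compare against the
        # explicit product of the four factor matrices built independently
        p = AffineParams(alpha=np.pi / 2, c_x=2.0, s_xy=0.3, reflection=(1, -1, 1))
        Rx = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
        C = np.diag([2.0, 1.0, 1.0])
        S = np.array([[1, 0.3, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        F = np.diag([1.0, -1.0, 1.0])
        expected = F @ Rx @ C @ S
        np.testing.assert_allclose(compose_transform(p)[:3, :3], expected, atol=1e-12)
        np.testing.assert_allclose(
            apply_transform(compose_transform(p), np.array([[1.0, 0, 0]]))[0],
            expected @ np.array([1.0, 0, 0]),
        )

    def test_application_order_shear_scale_rotate_reflect(self):
        # a point on +y: shear leaves it, scale doubles y, rotation about z by
        # 90° sends +y to −x, reflection flips x back to +
        p = AffineParams(gamma=np.pi / 2, c_y=2.0, reflection=(-1, 1, 1))
        out = apply_transform(compose_transform(p), np.array([[0.0, 1.0, 0.0]]))[0]
        np.testing.assert_allclose(out, [2.0, 0.0, 0.0], atol=1e-12)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ParameterError):
            AffineParams(c_x=0.0)

    def test_rigid_subset_preserves_distances(self, rng):
        # scales 1 and shears 0 give an isometry for any angles/translation
        p = AffineParams(alpha=0.7, beta=-1.1, gamma=2.2, t_x=4, t_y=-2, t_z=9)
        pts = rng.uniform(-5, 5, (10, 3))
        moved = apply_transform(compose_transform(p), pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestSSD:
    def test_zero_iff_coincident(self, mean_landmarks):
        assert ssd(mean_landmarks, mean_landmarks, AffineParams.identity()) == 0.0

    def test_single_pair_distance(self):
        a = LandmarkSet(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]))
        b = LandmarkSet(a.points + [2.0, 0, 0], source="segmented")
        assert ssd(a, b, AffineParams.identity()) == pytest.approx(16.0)

    def test_matches_naive_loop(self, rng):
        lm, lc = random_pair(rng, n=5)
        p = AffineParams(alpha=0.3, t_x=1.0, c_y=1.2, s_xz=0.1)
        T = compose_transform(p)
        expected = sum(
            float(np.sum((apply_transform(T, x[None])[0] - y) ** 2))
            for x, y in zip(lm.points, lc.points)
        )
        assert ssd(lm, lc, p) == pytest.approx(expected)

    def test_length_mismatch_rejected(self, rng):
        lm, _ = random_pair(rng, n=5)
        lc, _ = random_pair(rng, n=6)
        with pytest.raises(CorrespondenceError):
            ssd(lm, lc, AffineParams.identity())


class TestMae:
    def test_mean(self):
        assert mae([0.1, 0.3]) == pytest.approx(0.2)
        assert mae([0.0, 0.0, 0.0]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            mae([])

    def test_equal_error_identity_with_ssd(self, rng):
        # when all landmarks share one error e, MAE = e = sqrt(SSD/n)
        n, e = 8, 0.25
        X = rng.uniform(-5, 5, (n, 3))
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        lm = LandmarkSet(X)
        lc = LandmarkSet(X + e * dirs, source="segmented")
        s = ssd(lm, lc, AffineParams.identity())
        assert mae([e] * n) == pytest.approx(np.sqrt(s / n))


class TestApplyTransform:
    def test_identity_noop(self, mean_landmarks):
        out = apply_transform(np.eye(4), mean_landmarks)
        np.testing.assert_array_equal(out.points, mean_landmarks.points)
        assert out.labels == mean_landmarks.labels

    def test_composition_associativity(self, rng):
        T1 = compose_transform(AffineParams(alpha=0.4, t_x=2.0, c_z=1.3))
        T2 = compose_transform(AffineParams(beta=-0.2, t_y=-1.0, s_xy=0.2))
        pts = rng.uniform(-3, 3, (6, 3))
        np.testing.assert_allclose(
            apply_transform(T2, apply_transform(T1, pts)),
            apply_transform(T2 @ T1, pts),
            atol=1e-12,
        )

    def test_translation_round_trip(self, mean_landmarks):
        T = compose_transform(AffineParams(t_x=3, t_y=-4, t_z=5))
        back = apply_transform(np.linalg.inv(T), apply_transform(T, mean_landmarks))
        np.testing.assert_allclose(back.points, mean_landmarks.points, atol=1e-12)

    def test_bad_matrix_rejected(self, mean_landmarks):
        M = np.eye(4)
        M[3, 0] = 1.0
        with pytest.raises(ParameterError):
            apply_transform(M, mean_landmarks)


class TestRegister:
    def test_exact_affine_recovery(self, mean_landmarks):
        true = AffineParams(
            alpha=0.5, beta=-0.3, gamma=1.1, t_x=8, t_y=-5, t_z=3,
            c_x=1.1, c_y=0.9, c_z=1.05, s_xy=0.1, s_xz=-0.05, s_yz=0.15,
        )
        target = apply_transform(compose_transform(true), mean_landmarks)
        res = register(mean_landmarks, target)
        assert res.mae < 1e-4
        np.testing.assert_allclose(res.matrix, compose_transform(true), atol=1e-3)

    def test_identity_fixed_point(self, mean_landmarks):
        res = register(mean_landmarks, mean_landmarks)
        assert res.mae < 1e-8
        assert res.iterations <= 5
        np.testing.assert_allclose(res.matrix, np.eye(4), atol=1e-6)

    def test_mirrored_target_needs_reflection_search(self, mean_landmarks):
        T = np.eye(4)
        T[0, 0] = -1.0
        mirrored = apply_transform(T, mean_landmarks)
        res_off = register(mean_landmarks, mirrored)
        res_on = register(mean_landmarks, mirrored, reflection_search=True)
        assert res_on.mae < 1e-4
        assert res_off.mae > 0.1
        assert np.prod(res_on.params.reflection) == -1

    def test_ssd_history_non_increasing(self, phantom_factory):
        res = register(*_pair(phantom_factory(seed=4, noise="quantize")))
        h = np.asarray(res.ssd_history)
        assert np.all(np.diff(h) <= 1e-12)
        assert res.final_ssd <= h[0]
        assert res.iterations <= 100

    def test_four_point_exact_interpolation(self, rng):
        # 12 equations, 12 unknowns: four affinely independent pairs are fit
        # exactly by the full affine family
        X = np.array([[0.0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4]])
        Y = rng.uniform(-5, 5, (4, 3))
        res = register(LandmarkSet(X), LandmarkSet(Y, source="segmented"))
        assert res.final_ssd < 1e-10

    def test_matches_closed_form_least_squares(self, rng):
        # primary correctness oracle: reflection·rotation·scale·shear spans
        # all invertible maps, so the parametric optimum must match the
        # unrestricted linear least-squares optimum
        for _ in range(5):
            lm, lc = random_pair(rng, n=int(rng.integers(5, 14)))
            res = register(lm, lc, reflection_search=True)
            _, ssd_ls = affine_least_squares(lm, lc)
            assert res.final_ssd == pytest.approx(ssd_ls, abs=1e-6)

    def test_too_few_pairs_rejected(self, rng):
        lm, lc = random_pair(rng, n=3)
        with pytest.raises(UnderdeterminedError):
            register(lm, lc)

    def test_coplanar_model_rejected(self, rng):
        X = rng.uniform(-5, 5, (6, 3))
        X[:, 2] = 0.0
        Y = rng.uniform(-5, 5, (6, 3))
        with pytest.raises(GeometryError):
            register(LandmarkSet(X), LandmarkSet(Y, source="segmented"))

    def test_mae_equals_mean_per_landmark_error(self, phantom_factory):
        res = register(*_pair(phantom_factory(seed=6, noise="quantize")))
        assert res.mae == pytest.approx(
            np.mean(list(res.per_landmark_error.values()))
        )


def _pair(phantom):
    return phantom.model_landmarks, phantom.target_landmarks
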