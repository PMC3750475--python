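"""Tests for thin-plate-spline fitting, evaluation and warping."""

from __future__ import annotations

import numpy as np
import pytest

from zebreg.io_core import BinaryMask, OrganAtlas, Raster
from zebreg.landmarks import LandmarkSet
from zebreg.tps import (
    DegenerateLandmarksError,
    apply_tps,
    fit_tps,
    tps_objective,
    transfer_atlas,
    warp_to_reference,
)


def random_landmarks(seed: int, n: int = 10, scale: float = 100.0, jitter: float = 8.0) -> LandmarkSet:
    rng = np.random.default_rng(seed)
    p = rng.uniform(0, scale, (n, 2))
    q = p + rng.normal(0, jitter, (n, 2))
    return LandmarkSet(p=p, q=q, sigma=np.ones(n))


class TestFit:
    def test_identity_landmarks_give_identity_map(self):
        lm = random_landmarks(0)
        lm = LandmarkSet(p=lm.p, q=lm.p.copy(), sigma=lm.sigma)
        t, rep = fit_tps(lm, lam=300.0)
        assert np.linalg.norm(t.w) < 1e-8
        assert rep.bending_energy < 1e-10
        assert np.max(rep.residuals) < 1e-8
        np.testing.assert_allclose(t.affine, [[0, 0], [1, 0], [0, 1]], atol=1e-8)

    def test_affine_landmarks_recover_affine_exactly(self):
        rng = np.random.default_rng(1)
        A = np.array([[0.9, -0.3], [0.2, 1.1]])
        b = np.array([5.0, -2.0])
        p = rng.uniform(0, 100, (12, 2))
        lm = LandmarkSet(p=p, q=p @ A.T + b, sigma=np.ones(12))
        t, rep = fit_tps(lm, lam=0.0)
        assert np.linalg.norm(t.w) < 1e-6
        assert rep.bending_energy < 1e-10
        probe = rng.uniform(0, 100, (20, 2))
        np.testing.assert_allclose(apply_tps(t, probe), probe @ A.T + b, atol=1e-6)

    def test_side_conditions_hold(self):
        lm = random_landmarks(2, n=15)
        t, _ = fit_tps(lm, lam=300.0)
        scale = max(np.abs(t.w).max(), 1.0)
        assert np.max(np.abs(t.w.sum(axis=0))) < 1e-8 * scale * len(lm.p)
        assert np.max(np.abs(t.centers.T @ t.w)) < 1e-6 * scale * len(lm.p) * 100

    def test_interpolates_at_tiny_lambda(self):
        lm = random_landmarks(3, n=20)
        t, rep = fit_tps(lm, lam=1e-10)
        np.testing.assert_allclose(apply_tps(t, lm.p), lm.q, atol=1e-4)
        assert np.max(rep.residuals) < 1e-4

    def test_collinear_points_rejected(self):
        p = np.column_stack([np.arange(5.0), np.arange(5.0) * 2])
        lm = LandmarkSet(p=p, q=p + 1, sigma=np.ones(5))
        with pytest.raises(DegenerateLandmarksError):
            fit_tps(lm, lam=0.0)

    def test_large_lambda_approaches_affine_least_squares(self):
        lm = random_landmarks(4, n=12)
        t, _ = fit_tps(lm, lam=1e9)
        assert np.linalg.norm(t.w) < 1e-4
        X = np.column_stack([np.ones(len(lm.p)), lm.p])
        beta, *_ = np.linalg.lstsq(X, lm.q, rcond=None)
        probe = np.random.default_rng(5).uniform(0, 100, (10, 2))
        expected = np.column_stack([np.ones(10), probe]) @ beta
        np.testing.assert_allclose(apply_tps(t, probe), expected, atol=1e-4)

    def test_objective_consistency(self):
        lm = random_landmarks(6, n=10)
        _, rep = fit_tps(lm, lam=300.0)
        recomputed = np.sum(rep.residuals**2 / lm.sigma**2) + 300.0 * rep.bending_energy
        assert rep.objective == pytest.approx(recomputed, rel=1e-6)


class TestMinimizerProperties:
    @pytest.mark.parametrize("seed", range(3))
    def test_closed_form_dominates_perturbed_candidates(self, seed):
        lm = random_landmarks(seed, n=10)
        t, rep = fit_tps(lm, lam=300.0)
        P = np.column_stack([np.ones(len(lm.p)), lm.p])
        proj = np.eye(len(lm.p)) - P @ np.linalg.pinv(P)
        rng = np.random.default_rng(seed + 100)
        for _ in range(50):
            dw = proj @ rng.normal(0, 0.01 + 0.1 * np.abs(t.w).max(), t.w.shape)
            da = rng.normal(0, 0.01, t.affine.shape)
            j = tps_objective(lm, t.w + dw, t.affine + da, lam=300.0)
            assert j >= rep.objective - 1e-9 * max(1.0, rep.objective)

    def test_lambda_monotonicity(self):
        lm = random_landmarks(7, n=12)
        bends, sums = [], []
        for lam in (0.1, 1.0, 10.0, 300.0, 1e4):
            _, rep = fit_tps(lm, lam=lam)
            bends.append(rep.bending_energy)
            sums.append(float(np.sum(rep.residuals**2)))
        assert all(b2 <= b1 + 1e-9 for b1, b2 in zip(bends, bends[1:]))
        assert all(s2 >= s1 - 1e-9 for s1, s2 in zip(sums, sums[1:]))

    def test_rotation_equivariance(self):
        lm = random_landmarks(8, n=10)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        lm_rot = LandmarkSet(p=lm.p @ R.T, q=lm.q @ R.T, sigma=lm.sigma)
        _, rep = fit_tps(lm, lam=300.0)
        _, rep_rot = fit_tps(lm_rot, lam=300.0)
        np.testing.assert_allclose(np.sort(rep.residuals), np.sort(rep_rot.residuals), atol=1e-6)
        assert rep.bending_energy == pytest.approx(rep_rot.bending_energy, rel=1e-6, abs=1e-9)

    def test_bending_energy_matches_physical_integral(self):
        # integral of f_xx^2 + 2 f_xy^2 + f_yy^2 over the plane = 8*pi*w'Kw
        lm = random_landmarks(9, n=6, scale=60.0, jitter=5.0)
        t, rep = fit_tps(lm, lam=10.0)

        lo, hi = lm.p.min(), lm.p.max()
        c, half = (lo + hi) / 2, (hi - lo) / 2 * 10.0  # 10x extent captures the tail
        n = 900
        xs = np.linspace(c - half, c + half, n)
        step = xs[1] - xs[0]
        total = 0.0
        for xv in xs:
            pts = np.column_stack([np.full(n, xv) + step / 3, xs + step / 3])
            u = pts[:, None, 0] - t.centers[None, :, 0]
            v = pts[:, None, 1] - t.centers[None, :, 1]
            r2 = np.maximum(u * u + v * v, 1e-30)
            lg = 0.5 * np.log(r2)
            for d in range(2):
                fxx = (2 * lg + 1 + 2 * u * u / r2) @ t.w[:, d]
                fyy = (2 * lg + 1 + 2 * v * v / r2) @ t.w[:, d]
                fxy = (2 * u * v / r2) @ t.w[:, d]
                total += np.sum(fxx**2 + 2 * fxy**2 + fyy**2) * step**2
        assert total / (8 * np.pi) == pytest.approx(rep.bending_energy, rel=0.02)


class TestApplyAndWarp:
    def test_apply_at_landmarks_matches_report_residuals(self):
        lm = random_landmarks(10, n=12)
        t, rep = fit_tps(lm, lam=300.0)
        res = np.linalg.norm(lm.q - apply_tps(t, lm.p), axis=1)
        np.testing.assert_array_equal(res, rep.residuals)

    def test_identity_landmarks_warp_is_identity(self):
        rng = np.random.default_rng(11)
        img = Raster(rng.uniform(0, 255, (40, 60)))
        pts = rng.uniform(5, 35, (8, 2))
        lm = LandmarkSet(p=pts, q=pts.copy(), sigma=np.ones(8))
        t, _ = fit_tps(lm, lam=300.0)
        out = warp_to_reference(t, img, (40, 60))
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-6)

    def test_zero_image_warps_to_zero(self):
        img = Raster(np.zeros((30, 30)))
        lm = random_landmarks(12, n=6, scale=25.0, jitter=3.0)
        t, _ = fit_tps(lm, lam=300.0)
        assert np.all(warp_to_reference(t, img, (30, 30)).pixels == 0.0)

    def test_transfer_atlas_identity_and_empty(self):
        rng = np.random.default_rng(13)
        ref = Raster(rng.uniform(0, 255, (30, 40)))
        organ = np.zeros((30, 40), dtype=bool)
        organ[10:20, 15:30] = True
        atlas = OrganAtlas(ref, {"yolk": BinaryMask(organ), "empty": BinaryMask(np.zeros((30, 40)))})
        pts = rng.uniform(2, 28, (8, 2))
        lm = LandmarkSet(p=pts, q=pts.copy(), sigma=np.ones(8))
        t, _ = fit_tps(lm, lam=300.0)
        out = transfer_atlas(atlas, t, (30, 40))
        np.testing.assert_array_equal(out["yolk"].pixels, organ.astype(np.uint8))
        assert out["empty"].area == 0

    def test_round_trip_warp_preserves_body_content(self):
        """Warping the deformed target back with (a fit of) the inverse of the
        true deformation recovers the reference inside the body (normalized
        cross-correlation >= 0.95).  Noise-free phantom: the check measures
        warp/resampling fidelity, not the sensor-noise ceiling."""
        from zebreg.phantom import PhantomSpec, _body_mask, make_reference, make_target
        from scipy import ndimage

        spec = PhantomSpec(canvas=(300, 600), deform_scale=5.0, noise_sigma=0.0, seed=15)
        green_ref, atlas = make_reference(spec)
        target = make_target((green_ref, atlas), spec)
        # the generator's deformation maps target coords -> reference coords;
        # warping back needs the reference -> target direction, fitted from
        # dense samples of the forward map.
        rng = np.random.default_rng(14)
        pts_t = rng.uniform(0, np.array(spec.canvas) - 1, (100, 2))
        pts_r = apply_tps(target.deformation, pts_t)
        back = LandmarkSet(p=pts_r, q=pts_t, sigma=np.ones(100))
        t_back, _ = fit_tps(back, lam=1e-6)
        recovered = warp_to_reference(t_back, target.green, spec.canvas)
        body = ndimage.binary_erosion(_body_mask(spec.canvas), iterations=5)
        ncc = np.corrcoef(recovered.pixels[body], green_ref.pixels[body])[0, 1]
        assert ncc >= 0.95
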