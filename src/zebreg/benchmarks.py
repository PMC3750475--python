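"""Self-validation experiments on synthetic data.

Each function runs one well-defined experiment end to end — generating its
own inputs from a seed, running the pipeline, and measuring the result —
and returns plain numbers.  They back both the acceptance test suite and
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .io_core import Raster
from .landmarks import LandmarkSet
from .phantom import PhantomSpec, make_reference, make_target
from .pipeline import LARGE_ORGANS, SMALL_ORGANS, phantom_registration_experiment
from .segmentation import otsu_threshold
from .spots import (
    atrous_decompose,
    correct_bleedthrough,
    detect_spots,
    multiscale_product,
)
from .tps import fit_tps, apply_tps, tps_objective

__all__ = [
    "tps_interpolation_residual",
    "tps_affine_fit_metrics",
    "tps_dominance_violations",
    "tps_lambda_monotonicity",
    "otsu_oracle_agreement",
    "wavelet_reconstruction_error",
    "wavelet_impulse_peak",
    "spot_recovery",
    "bleedthrough_recovery",
    "registration_accuracy",
    "greedy_match_count",
]


def _random_landmarks(seed: int, n: int = 10, scale: float = 100.0, jitter: float = 8.0) -> LandmarkSet:
    rng = np.random.default_rng(seed)
    p = rng.uniform(0, scale, (n, 2))
    q = p + rng.normal(0, jitter, (n, 2))
    return LandmarkSet(p=p, q=q, sigma=np.ones(n))


def tps_interpolation_residual(seeds: list[int], n: int = 20) -> float:
    """Worst landmark residual (px) of near-interpolating fits (lambda 1e-10)."""
    worst = 0.0
    for seed in seeds:
        lm = _random_landmarks(seed, n=n)
        t, _ = fit_tps(lm, lam=1e-10)
        worst = max(worst, float(np.max(np.linalg.norm(apply_tps(t, lm.p) - lm.q, axis=1))))
    return worst


def tps_affine_fit_metrics(seed: int, n: int = 12) -> tuple[float, float]:
    """(warp-coefficient norm, bending energy) for affinely related landmarks."""
    rng = np.random.default_rng(seed)
    A = np.array([[1.1, 0.2], [-0.3, 0.9]])
    b = np.array([4.0, -7.0])
    p = rng.uniform(0, 100, (n, 2))
    lm = LandmarkSet(p=p, q=p @ A.T + b, sigma=np.ones(n))
    t, rep = fit_tps(lm, lam=0.0)
    return float(np.linalg.norm(t.w)), rep.bending_energy


def tps_dominance_violations(
    seeds: list[int], n_candidates: int = 200, lam: float = 300.0
) -> int:
    """Number of perturbed candidates beating the closed-form minimizer of J."""
    violations = 0
    for seed in seeds:
        lm = _random_landmarks(seed, n=10)
        t, rep = fit_tps(lm, lam=lam)
        P = np.column_stack([np.ones(len(lm.p)), lm.p])
        proj = np.eye(len(lm.p)) - P @ np.linalg.pinv(P)  # keep side conditions
        rng = np.random.default_rng(seed + 10_000)
        scale = 0.01 + 0.1 * float(np.abs(t.w).max())
        for _ in range(n_candidates):
            dw = proj @ rng.normal(0, scale, t.w.shape)
            da = rng.normal(0, 0.01, t.affine.shape)
            j = tps_objective(lm, t.w + dw, t.affine + da, lam=lam)
            if j < rep.objective - 1e-9 * max(1.0, rep.objective):
                violations += 1
    return violations


def tps_lambda_monotonicity(
    seed: int, lambdas: tuple[float, ...] = (0.1, 1.0, 10.0, 300.0, 1e4)
) -> tuple[int, int]:
    """Counts of (bending increases, residual-sum decreases) along the lambda path.

    Both counts are zero when the expected monotonicity holds.
    """
    lm = _random_landmarks(seed, n=12)
    bends, sums = [], []
    for lam in lambdas:
        _, rep = fit_tps(lm, lam=lam)
        bends.append(rep.bending_energy)
        sums.append(float(np.sum(rep.residuals**2)))
    bend_up = sum(b2 > b1 + 1e-9 * max(1.0, b1) for b1, b2 in zip(bends, bends[1:]))
    res_down = sum(s2 < s1 - 1e-9 * max(1.0, s1) for s1, s2 in zip(sums, sums[1:]))
    return bend_up, res_down


def _brute_force_otsu(pixels: np.ndarray) -> float:
    counts, edges = np.histogram(pixels, bins=256, range=(pixels.min(), pixels.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_var, best_k = -1.0, 0
    total = counts.sum()
    for k in range(255):
        w0 = counts[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            var = 0.0
        else:
            mu0 = float(np.sum(counts[: k + 1] * centers[: k + 1])) / w0
            mu1 = float(np.sum(counts[k + 1 :] * centers[k + 1 :])) / w1
            var = float(w0) * float(w1) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_k = var, k
    return float(centers[best_k])


def otsu_oracle_agreement(seed: int, n_images: int = 50, shape=(32, 32)) -> float:
    """Fraction of random images where the threshold equals exhaustive search."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_images):
        img = rng.integers(0, 256, shape).astype(float)
        thr, _ = otsu_threshold(Raster(img))
        hits += thr == _brute_force_otsu(img)
    return hits / n_images


def wavelet_reconstruction_error(seed: int, levels_list=(1, 2, 3, 4), shape=(128, 128)) -> float:
    """Worst relative error of A_J + sum(W_i) vs A_0 over random images."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for levels in levels_list:
        img = rng.uniform(0, 255, shape)
        stack = atrous_decompose(Raster(img), levels=levels)
        recon = stack.approximations[-1] + sum(stack.details)
        worst = max(worst, float(np.max(np.abs(recon - img)) / np.max(np.abs(img))))
    return worst


def wavelet_impulse_peak() -> float:
    """W_1 at the center of a unit impulse (analytically 1 - (3/8)^2)."""
    img = np.zeros((65, 65))
    img[32, 32] = 1.0
    stack = atrous_decompose(Raster(img), levels=1)
    return float(stack.details[0][32, 32])


def greedy_match_count(truth: np.ndarray, found: np.ndarray, radius: float = 3.0) -> int:
    """One-to-one nearest matching of detected centroids to true centers."""
    if len(found) == 0 or len(truth) == 0:
        return 0
    d = cdist(truth, found)
    used_t: set[int] = set()
    used_f: set[int] = set()
    for dist, t, f in sorted(
        (d[t, f], t, f) for t in range(d.shape[0]) for f in range(d.shape[1])
    ):
        if dist > radius:
            break
        if t in used_t or f in used_f:
            continue
        used_t.add(t)
        used_f.add(f)
    return len(used_t)


def spot_recovery(seeds: list[int], spec: PhantomSpec | None = None) -> tuple[float, float]:
    """(mean recall, mean precision) of spot detection on full phantoms.

    The red channel is bleed-through-corrected against the green channel
    before decomposition; detected centroids match truth within 3 px.
    """
    recalls, precisions = [], []
    for seed in seeds:
        s = (spec or PhantomSpec()).with_seed(seed)
        ref = make_reference(s)
        target = make_target(ref, s)
        fit = correct_bleedthrough(target.red, target.green)
        stack = atrous_decompose(fit.corrected, levels=3)
        found = detect_spots(multiscale_product(stack), stack)
        tp = greedy_match_count(target.truth_spots, found.centroids())
        recalls.append(tp / len(target.truth_spots))
        precisions.append(tp / len(found) if len(found) else 0.0)
    return float(np.mean(recalls)), float(np.mean(precisions))


def bleedthrough_recovery(seeds: list[int], noise_sigma: float = 6.0) -> tuple[float, float]:
    """(mean beta_hat, worst |beta_hat - beta|) on phantoms at SNR ~20."""
    betas = []
    for seed in seeds:
        spec = PhantomSpec(noise_sigma=noise_sigma).with_seed(seed)
        ref = make_reference(spec)
        target = make_target(ref, spec)
        betas.append(correct_bleedthrough(target.red, target.green).beta_hat)
    betas = np.array(betas)
    return float(betas.mean()), float(np.max(np.abs(betas - 0.25)))


def registration_accuracy(seeds: list[int]) -> dict[str, float]:
    """End-to-end phantom registration summary over seeds.

    Returns the auto-landmark mean Simpson over the four largest organs, the
    seven-organ mean with three manual center landmarks added, and the
    fraction of seeds where those manual landmarks strictly improved the
    small-organ (eye, otic vesicle, pectoral fin) mean.
    """
    auto_large, auto_small, manual_all, manual_small = [], [], [], []
    improved = 0
    for seed in seeds:
        rep_auto, _ = phantom_registration_experiment(seed, manual=False)
        rep_manual, _ = phantom_registration_experiment(seed, manual=True)
        a_small = float(np.mean([rep_auto[o] for o in SMALL_ORGANS]))
        m_small = float(np.mean([rep_manual[o] for o in SMALL_ORGANS]))
        auto_large.append(float(np.mean([rep_auto[o] for o in LARGE_ORGANS])))
        auto_small.append(a_small)
        manual_all.append(rep_manual.mean)
        manual_small.append(m_small)
        improved += m_small > a_small
    return {
        "auto_large_mean": float(np.mean(auto_large)),
        "auto_small_mean": float(np.mean(auto_small)),
        "manual_all_mean": float(np.mean(manual_all)),
        "manual_small_mean": float(np.mean(manual_small)),
        "small_improved_fraction": improved / len(seeds),
    }
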