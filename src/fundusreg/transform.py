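"""Similarity/affine estimation with distance-constrained RANSAC.

The number of RANSAC iterations needed to draw at least one outlier-free
minimal sample with confidence p is

    N = ceil( log(1 - p) / log(1 - (1 - v)^m) )

with v the outlier rate and m the minimal sample size (2 for similarity,
3 for affine). Minimal samples are additionally required to have source
points at least ``min_sample_dist`` apart, which spreads the sample and
damps the leverage of keypoint localization error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .descriptors import MatchSet
from .types import DegenerateInputError, FundusImage, TransformModel


@dataclass
class RansacConfig:
    """Sampling and consensus parameters.

    p_success is the confidence that one sample is outlier-free (0.99 by
    convention); n_iter caps the adaptively updated iteration count;
    inlier_tol is the reprojection error (px) below which a match counts
    as an inlier; min_sample_dist (px) is the minimum pairwise distance
    between source points of a minimal sample.
    """

    p_success: float = 0.99
    outlier_rate: float = 0.5
    n_iter: int = 10_000
    inlier_tol: float = 5.0
    min_sample_dist: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_success < 1.0):
            raise ValueError("p_success must lie in (0, 1)")


@dataclass
class RegistrationResult:
    model: TransformModel | None
    inliers: MatchSet
    n_candidates: int
    converged: bool
    diagnostic: str = ""
    n_iterations_run: int = 0


def min_sample_size(kind: str) -> int:
    return 2 if kind == "similarity" else 3


def fit_similarity(src: np.ndarray, tgt: np.ndarray) -> TransformModel:
    """Least-squares similarity (rotation + uniform scale + translation).

    Solves for [[a, -b, tx], [b, a, ty]] linearly; exact for two pairs.
    """
    src = np.asarray(src, dtype=float).reshape(-1, 2)
    tgt = np.asarray(tgt, dtype=float).reshape(-1, 2)
    if len(src) < 2:
        raise DegenerateInputError("similarity needs at least 2 correspondences")
    if np.allclose(src, src[0], atol=1e-12):
        raise DegenerateInputError("coincident source points")
    n = len(src)
    A = np.zeros((2 * n, 4))
    A[0::2, 0] = src[:, 0]
    A[0::2, 1] = -src[:, 1]
    A[0::2, 2] = 1.0
    A[1::2, 0] = src[:, 1]
    A[1::2, 1] = src[:, 0]
    A[1::2, 3] = 1.0
    b = tgt.reshape(-1)
    (a, bb, tx, ty), *_ = np.linalg.lstsq(A, b, rcond=None)
    T = np.array([[a, -bb, tx], [bb, a, ty], [0.0, 0.0, 1.0]])
    return TransformModel(kind="similarity", T=T)


def fit_affine(src: np.ndarray, tgt: np.ndarray) -> TransformModel:
    """Least-squares affine; exact for three non-collinear pairs."""
    src = np.asarray(src, dtype=float).reshape(-1, 2)
    tgt = np.asarray(tgt, dtype=float).reshape(-1, 2)
    if len(src) < 3:
        raise DegenerateInputError("affine needs at least 3 correspondences")
    hom = np.hstack([src, np.ones((len(src), 1))])
    if np.linalg.matrix_rank(hom, tol=1e-9 * max(1.0, np.abs(src).max())) < 3:
        raise DegenerateInputError("collinear source points")
    sol, *_ = np.linalg.lstsq(hom, tgt, rcond=None)
    T = np.vstack([sol.T, [0.0, 0.0, 1.0]])
    return TransformModel(kind="affine", T=T)


def fit_transform(src: np.ndarray, tgt: np.ndarray, kind: str) -> TransformModel:
    return fit_similarity(src, tgt) if kind == "similarity" else fit_affine(src, tgt)


def ransac_iterations(p_success: float, outlier_rate: float, sample_size: int) -> int:
    """Iteration count N from confidence p, outlier rate v, sample size m."""
    v, p, m = outlier_rate, p_success, sample_size
    if not (0.0 <= v < 1.0):
        raise ValueError("outlier_rate must lie in [0, 1)")
    if v == 0.0:
        return 1
    w = (1.0 - v) ** m
    return int(math.ceil(math.log(1.0 - p) / math.log(1.0 - w)))


def _reprojection_errors(model: TransformModel, src: np.ndarray, tgt: np.ndarray) -> np.ndarray:
    return np.linalg.norm(model.apply(src) - tgt, axis=1)


def ransac_fit(
    matches: MatchSet,
    kps_source: np.ndarray,
    kps_target: np.ndarray,
    kind: str = "similarity",
    cfg: RansacConfig | None = None,
) -> RegistrationResult:
    """Distance-constrained RANSAC over cross-checked correspondences.

    Minimal samples are drawn by rejection until their source points are
    pairwise >= cfg.min_sample_dist apart (bounded retries). The best
    model by inlier count (ties: lower mean reprojection error) is refit
    by least squares on its inlier set. The iteration budget adapts to
    the best inlier ratio seen so far and is capped at cfg.n_iter.
    Deterministic for a fixed cfg.seed.
    """
    if cfg is None:
        cfg = RansacConfig()
    m = min_sample_size(kind)
    kps_source = np.asarray(kps_source, dtype=float).reshape(-1, 2)
    kps_target = np.asarray(kps_target, dtype=float).reshape(-1, 2)

    idx_s = np.array([p[0] for p in matches.pairs], dtype=int)
    idx_t = np.array([p[1] for p in matches.pairs], dtype=int)
    n = len(idx_s)
    if n < m:
        return RegistrationResult(
            model=None, inliers=MatchSet(pairs=[], direction="symmetric"),
            n_candidates=n, converged=False,
            diagnostic=f"{n} matches < minimal sample size {m} for {kind}",
        )
    src = kps_source[idx_s]
    tgt = kps_target[idx_t]

    rng = np.random.default_rng(cfg.seed)
    best_inliers: np.ndarray | None = None
    best_err = np.inf
    n_needed = cfg.n_iter
    it = 0
    failed_samples = 0
    while it < min(n_needed, cfg.n_iter):
        it += 1
        sample = None
        for _ in range(100):
            cand = rng.choice(n, size=m, replace=False)
            pts = src[cand]
            d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
            if (d[np.triu_indices(m, 1)] >= cfg.min_sample_dist).all():
                sample = cand
                break
        if sample is None:
            failed_samples += 1
            if failed_samples >= 10:
                break
            continue
        try:
            model = fit_transform(src[sample], tgt[sample], kind)
        except DegenerateInputError:
            continue
        errs = _reprojection_errors(model, src, tgt)
        inliers = errs <= cfg.inlier_tol
        k = int(inliers.sum())
        mean_err = float(errs[inliers].mean()) if k else np.inf
        if best_inliers is None or k > best_inliers.sum() or (
            k == best_inliers.sum() and mean_err < best_err
        ):
            best_inliers = inliers
            best_err = mean_err
            if k >= m:
                v_est = min(1.0 - k / n, 0.999)
                n_needed = ransac_iterations(cfg.p_success, v_est, m)

    if best_inliers is None or best_inliers.sum() < m:
        return RegistrationResult(
            model=None, inliers=MatchSet(pairs=[], direction="symmetric"),
            n_candidates=n, converged=False,
            diagnostic="no sample satisfied the distance constraint"
            if best_inliers is None else "insufficient consensus",
            n_iterations_run=it,
        )

    final = fit_transform(src[best_inliers], tgt[best_inliers], kind)
    errs = _reprojection_errors(final, src, tgt)
    inlier_idx = np.nonzero(best_inliers)[0]
    pairs = [(int(idx_s[i]), int(idx_t[i]), float(errs[i])) for i in inlier_idx]
    return RegistrationResult(
        model=final,
        inliers=MatchSet(pairs=pairs, direction="symmetric"),
        n_candidates=n,
        converged=True,
        n_iterations_run=it,
    )


def warp_source(
    src: FundusImage, model: TransformModel
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Warp the source image into the target frame on an enlarged canvas.

    The canvas is the bounding box of the target frame united with the
    transformed source corners; ``offset`` is the canvas origin in target
    coordinates. Intensities are pulled by inverse mapping with bilinear
    interpolation; the FOV mask uses nearest-neighbour.
    """
    H, W = src.shape
    corners = np.array([[0, 0], [W - 1, 0], [0, H - 1], [W - 1, H - 1]], dtype=float)
    mapped = model.apply(corners)
    x_min = int(math.floor(min(0.0, mapped[:, 0].min())))
    y_min = int(math.floor(min(0.0, mapped[:, 1].min())))
    x_max = int(math.ceil(max(W - 1.0, mapped[:, 0].max())))
    y_max = int(math.ceil(max(H - 1.0, mapped[:, 1].max())))
    out_w = x_max - x_min + 1
    out_h = y_max - y_min + 1

    ys, xs = np.mgrid[0:out_h, 0:out_w]
    tx = xs + x_min
    ty = ys + y_min
    inv = np.linalg.inv(model.T)
    sx = inv[0, 0] * tx + inv[0, 1] * ty + inv[0, 2]
    sy = inv[1, 0] * tx + inv[1, 1] * ty + inv[1, 2]
    coords = np.stack([sy.ravel(), sx.ravel()])

    warped = np.zeros((out_h, out_w, 3), dtype=np.uint8)
    for c in range(3):
        ch = ndimage.map_coordinates(
            src.rgb[:, :, c].astype(float), coords, order=1, mode="constant", cval=0.0
        )
        warped[:, :, c] = np.clip(np.round(ch.reshape(out_h, out_w)), 0, 255)
    mask = ndimage.map_coordinates(
        src.fov_mask.astype(np.uint8), coords, order=0, mode="constant", cval=0
    ).reshape(out_h, out_w).astype(bool)
    return warped, mask, (x_min, y_min)
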