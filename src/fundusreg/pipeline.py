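"""End-to-end registration: the glue over the stage modules.

segmentation -> skeleton -> bifurcations -> descriptors -> matching ->
cross-check -> RANSAC -> warp -> blend. Images whose field of view is
wider than the working diameter are downscaled before feature work and
the fitted transform is mapped back to native coordinates; every
pixel-unit default (window size, descriptor patch, distances) is defined
at working scale.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.transform import resize

from . import blending, descriptors, segmentation, skeleton, transform
from .descriptors import MatchSet
from .types import FundusImage, TransformModel


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, validated up front.

    Pixel-valued settings are at working scale (field-of-view diameter
    normalised to ``working_fov`` px, no upscaling).
    """

    n: int = 7
    sigma: float = 1.5
    tophat_radius: int = 9
    saturate_frac: float = 0.03
    dedupe_radius: float = 5.0
    match_mode: str = "ratio"
    match_threshold: float = 0.8
    p_success: float = 0.99
    inlier_tol: float = 5.0
    min_sample_dist: float = 50.0
    ransac_cap: int = 10_000
    seed: int = 0
    kind: str = "similarity"
    octaves: int = 3
    working_fov: int = 1024

    def validate(self) -> None:
        if self.n < 3 or self.n % 2 == 0:
            raise ValueError("n must be odd and >= 3")
        if not (0.0 <= self.saturate_frac < 0.5):
            raise ValueError("saturate_frac must be in [0, 0.5)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.match_mode not in ("ratio", "magnitude"):
            raise ValueError("match_mode must be 'ratio' or 'magnitude'")
        if self.match_threshold <= 0:
            raise ValueError("match_threshold must be positive")
        if not (0.0 < self.p_success < 1.0):
            raise ValueError("p_success must lie in (0, 1)")
        if self.kind not in ("similarity", "affine"):
            raise ValueError("kind must be 'similarity' or 'affine'")
        if self.octaves < 1:
            raise ValueError("octaves must be >= 1")
        if self.working_fov < 64:
            raise ValueError("working_fov too small")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class RegistrationOutput:
    """Fitted model in native coordinates plus per-stage diagnostics."""

    result: transform.RegistrationResult
    model: TransformModel | None
    keypoints_source: np.ndarray
    keypoints_target: np.ndarray
    matches: MatchSet
    scale: float
    stage_counts: dict = field(default_factory=dict)
    stage_times: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.result.converged


def _fov_diameter(mask: np.ndarray) -> float:
    return 2.0 * math.sqrt(float(mask.sum()) / math.pi)


def _rescale(img: FundusImage, s: float) -> FundusImage:
    if s == 1.0:
        return img
    h, w = img.shape
    nh, nw = max(1, round(h * s)), max(1, round(w * s))
    rgb = np.clip(
        np.round(resize(img.rgb.astype(float), (nh, nw), order=1, anti_aliasing=True, preserve_range=True)),
        0, 255,
    ).astype(np.uint8)
    mask = resize(img.fov_mask.astype(float), (nh, nw), order=0, preserve_range=True) > 0.5
    return FundusImage(rgb=rgb, fov_mask=mask, id=img.id)


def extract_keypoints(img: FundusImage, cfg: PipelineConfig):
    """Segment, thin and detect junctions; returns (enhanced, keypoints)."""
    enhanced, _, vessels = segmentation.segment(
        img, n=cfg.n, sigma=cfg.sigma, tophat_radius=cfg.tophat_radius,
        saturate_frac=cfg.saturate_frac,
    )
    skel = skeleton.zhang_suen_thin(vessels)
    kps = skeleton.detect_bifurcations(
        skel, dedupe_radius=cfg.dedupe_radius,
        fov_mask=img.fov_mask, rim_margin=float(cfg.tophat_radius),
    )
    return enhanced, kps


def register_pair(
    source: FundusImage, target: FundusImage, cfg: PipelineConfig | None = None
) -> RegistrationOutput:
    """Full feature-based registration of one fundus pair.

    Returns the fitted transform acting in native source/target pixel
    coordinates (target = T @ source) with stage counts and timings.
    """
    if cfg is None:
        cfg = PipelineConfig()
    cfg.validate()

    diam = max(_fov_diameter(source.fov_mask), _fov_diameter(target.fov_mask))
    s = min(1.0, cfg.working_fov / diam)
    src_w = _rescale(source, s)
    tgt_w = _rescale(target, s)

    counts: dict = {}
    times: dict = {}

    t0 = time.perf_counter()
    enh_s, kps_s = extract_keypoints(src_w, cfg)
    enh_t, kps_t = extract_keypoints(tgt_w, cfg)
    times["features"] = time.perf_counter() - t0
    counts["keypoints_source"] = len(kps_s)
    counts["keypoints_target"] = len(kps_t)

    t0 = time.perf_counter()
    empty = MatchSet(pairs=[], direction="symmetric")
    if len(kps_s) == 0 or len(kps_t) == 0:
        result = transform.RegistrationResult(
            model=None, inliers=empty, n_candidates=0, converged=False,
            diagnostic="no keypoints detected",
        )
        return RegistrationOutput(
            result=result, model=None,
            keypoints_source=kps_s.points / s, keypoints_target=kps_t.points / s,
            matches=empty, scale=s, stage_counts=counts, stage_times=times,
        )

    desc_s, kept_s = descriptors.compute_descriptors(enh_s, kps_s)
    desc_t, kept_t = descriptors.compute_descriptors(enh_t, kps_t)
    counts["described_source"] = len(desc_s)
    counts["described_target"] = len(desc_t)

    if desc_s and desc_t:
        matches = descriptors.match_descriptors(
            desc_s, desc_t, threshold=cfg.match_threshold, mode=cfg.match_mode
        )
    else:
        matches = empty
    counts["cross_checked_matches"] = len(matches)
    times["matching"] = time.perf_counter() - t0

    pts_s = kps_s.points[kept_s].astype(float) if len(kept_s) else np.empty((0, 2))
    pts_t = kps_t.points[kept_t].astype(float) if len(kept_t) else np.empty((0, 2))

    t0 = time.perf_counter()
    rcfg = transform.RansacConfig(
        p_success=cfg.p_success, n_iter=cfg.ransac_cap, inlier_tol=cfg.inlier_tol,
        min_sample_dist=cfg.min_sample_dist, seed=cfg.seed,
    )
    result = transform.ransac_fit(matches, pts_s, pts_t, kind=cfg.kind, cfg=rcfg)
    times["ransac"] = time.perf_counter() - t0
    counts["inliers"] = len(result.inliers)

    model_native = None
    if result.converged and result.model is not None:
        S = np.diag([s, s, 1.0])
        model_native = TransformModel(
            kind=result.model.kind, T=np.linalg.inv(S) @ result.model.T @ S
        )
    return RegistrationOutput(
        result=result, model=model_native,
        keypoints_source=pts_s / s, keypoints_target=pts_t / s,
        matches=matches, scale=s, stage_counts=counts, stage_times=times,
    )


def mosaic(
    source: FundusImage, target: FundusImage, model: TransformModel, octaves: int = 3
) -> np.ndarray:
    """Warp the source into the target frame and pyramid-blend the pair."""
    warped, warped_mask, (ox, oy) = transform.warp_source(source, model)
    H, W = warped.shape[:2]
    tgt_img = np.zeros((H, W, 3), dtype=float)
    tgt_mask = np.zeros((H, W), dtype=float)
    th, tw = target.shape
    y0, x0 = -oy, -ox
    tgt_img[y0 : y0 + th, x0 : x0 + tw] = target.rgb
    tgt_mask[y0 : y0 + th, x0 : x0 + tw] = target.fov_mask
    blended = blending.blend_pair(
        warped.astype(float), warped_mask.astype(float), tgt_img, tgt_mask, octaves=octaves
    )
    return np.clip(np.round(blended), 0, 255).astype(np.uint8)
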