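"""Seeded synthetic fundus image pairs with full ground truth.

The generator emulates the features of colour fundus photographs that
the registration pipeline depends on: a dark surround with a circular
field of view, a branching vascular tree that is darker than the tissue
in the green channel (hence bright after green-channel inversion), an
optional central vessel reflex (a thin bright stripe along each vessel
axis), a smooth radial illumination falloff, sensor noise, and a known
similarity or affine transform relating the two views of a pair with a
configurable overlap regime (above or below 75%, mirroring the
super-resolution/longitudinal versus mosaicking use cases). Everything —
vessel geometry, junction coordinates, the planted transform and ten
control points in the overlap — is recorded, so every pipeline stage can
be scored against exact ground truth.

All randomness flows from a single integer seed; identical seeds and
parameters give byte-identical images.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .evaluation import write_control_points
from .types import ControlPointSet, FundusImage, TransformModel

CANVAS = 768
FOV_DIAMETER = 700

# background tissue colour at full illumination and vessel darkening
_BG = np.array([175.0, 120.0, 35.0])
_VESSEL_DROP = np.array([30.0, 75.0, 10.0])
_REFLEX_STRENGTH = 0.45


@dataclass
class Segment:
    p0: np.ndarray
    p1: np.ndarray
    width: float


@dataclass
class VascularScene:
    """Vessel geometry on a canvas: segments plus true junction points."""

    segments: list[Segment]
    junctions: np.ndarray  # (N, 2) float (x, y)
    canvas: int
    fov_radius: float

    @property
    def center(self) -> np.ndarray:
        return np.array([(self.canvas - 1) / 2.0, (self.canvas - 1) / 2.0])

    def transformed(self, model: TransformModel) -> "VascularScene":
        segs = [
            Segment(p0=model.apply(s.p0)[0], p1=model.apply(s.p1)[0], width=s.width)
            for s in self.segments
        ]
        junc = model.apply(self.junctions) if len(self.junctions) else self.junctions
        return VascularScene(segments=segs, junctions=junc, canvas=self.canvas, fov_radius=self.fov_radius)


@dataclass
class SyntheticPair:
    source: FundusImage
    target: FundusImage
    true_model: TransformModel
    true_junctions_source: np.ndarray
    true_junctions_target: np.ndarray
    control_points: ControlPointSet
    params: dict = field(default_factory=dict)
    overlap: float = float("nan")

    def save(self, out_dir) -> None:
        """Write a FIRE-like pair directory: two PNGs, the control-point
        text file, and a JSON manifest with the planted matrix."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        Image.fromarray(self.source.rgb).save(out / "source.png")
        Image.fromarray(self.target.rgb).save(out / "target.png")
        write_control_points(self.control_points, out / "control_points.txt")
        manifest = {
            "pair_id": self.params.get("pair_id", out.name),
            "true_model": {"kind": self.true_model.kind, "matrix": self.true_model.T.tolist()},
            "overlap": self.overlap,
            "params": self.params,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def generate_tree(
    seed: int,
    canvas: int = CANVAS,
    n_roots: int = 4,
    depth: int = 5,
    fov_radius: float = FOV_DIAMETER / 2,
) -> VascularScene:
    """Recursive always-split binary vascular tree.

    Each segment splits into two children whose directions deviate from
    the parent by an angle drawn uniformly from 20-50 degrees (one to
    each side); widths taper from 6 px at the root generation to 2 px at
    the leaves, lengths shrink geometrically, and branches heading out of
    the field of view are steered back toward the centre. Every branch
    point is recorded as a true junction: with always-splitting this
    yields n_roots * (2^(depth-1) - 1) junctions.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    center = np.array([(canvas - 1) / 2.0, (canvas - 1) / 2.0])
    segments: list[Segment] = []
    junctions: list[np.ndarray] = []

    def width_at(d: int) -> float:
        if depth == 1:
            return 6.0
        return 6.0 - (d - 1) * 4.0 / (depth - 1)

    def steer(p: np.ndarray, direction: np.ndarray, length: float) -> np.ndarray:
        d = direction
        for _ in range(3):
            end = p + length * d
            if np.linalg.norm(end - center) <= 0.88 * fov_radius:
                break
            d = _unit(0.55 * d + 0.45 * _unit(center - p))
        return d

    def grow(p: np.ndarray, direction: np.ndarray, d: int, presteered: bool = False) -> None:
        length = 105.0 * 0.75 ** (d - 1)
        if not presteered:
            direction = steer(p, direction, length)
        q = p + length * direction
        segments.append(Segment(p0=p.copy(), p1=q.copy(), width=width_at(d)))
        if d < depth:
            junctions.append(q.copy())
            theta = math.atan2(direction[1], direction[0])
            child_len = 105.0 * 0.75**d
            dirs = []
            for sign in (+1.0, -1.0):
                delta = math.radians(rng.uniform(20.0, 50.0)) * sign
                child = np.array([math.cos(theta + delta), math.sin(theta + delta)])
                dirs.append(steer(q, child, child_len))
            # steering toward the centre can align siblings; keep the fork
            # visible by enforcing a minimum angular separation
            a0 = math.atan2(dirs[0][1], dirs[0][0])
            a1 = math.atan2(dirs[1][1], dirs[1][0])
            sep = abs((a0 - a1 + math.pi) % (2 * math.pi) - math.pi)
            min_sep = math.radians(35.0)
            if sep < min_sep:
                push = (min_sep - sep) / 2.0
                sign0 = 1.0 if ((a0 - a1 + math.pi) % (2 * math.pi) - math.pi) >= 0 else -1.0
                dirs[0] = np.array([math.cos(a0 + sign0 * push), math.sin(a0 + sign0 * push)])
                dirs[1] = np.array([math.cos(a1 - sign0 * push), math.sin(a1 - sign0 * push)])
            for child in dirs:
                grow(q, child, d + 1, presteered=True)

    for k in range(n_roots):
        ang = 2.0 * math.pi * k / n_roots + rng.uniform(-0.3, 0.3)
        start = center + 0.15 * fov_radius * np.array([math.cos(ang), math.sin(ang)])
        direction = np.array([math.cos(ang + rng.uniform(-0.2, 0.2)),
                              math.sin(ang + rng.uniform(-0.2, 0.2))])
        grow(start, direction, 1)

    junc = np.asarray(junctions, dtype=float) if junctions else np.empty((0, 2))
    return VascularScene(segments=segments, junctions=junc, canvas=canvas, fov_radius=fov_radius)


def rasterize_scene(scene: VascularScene, reflex: bool = True) -> np.ndarray:
    """Anti-aliased vessel opacity map in [0, 1].

    Each segment is drawn as a capsule; the optional central reflex
    carves a 1-px-wide dimmer stripe along the axis of segments wide
    enough to carry one (emulating the specular stripe that can split
    naive segmentations).
    """
    size = scene.canvas
    alpha = np.zeros((size, size), dtype=np.float64)
    ridge = np.zeros_like(alpha)
    for seg in scene.segments:
        half = seg.width / 2.0
        pad = int(math.ceil(half + 2.0))
        x0 = int(max(0, math.floor(min(seg.p0[0], seg.p1[0])) - pad))
        x1 = int(min(size - 1, math.ceil(max(seg.p0[0], seg.p1[0])) + pad))
        y0 = int(max(0, math.floor(min(seg.p0[1], seg.p1[1])) - pad))
        y1 = int(min(size - 1, math.ceil(max(seg.p0[1], seg.p1[1])) + pad))
        if x1 < x0 or y1 < y0:
            continue
        ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
        pts = np.stack([xs, ys], axis=-1).astype(float)
        ab = seg.p1 - seg.p0
        denom = float(ab @ ab)
        if denom == 0:
            continue
        t = np.clip(((pts - seg.p0) @ ab) / denom, 0.0, 1.0)
        nearest = seg.p0 + t[..., None] * ab
        dist = np.linalg.norm(pts - nearest, axis=-1)
        cover = np.clip(half + 0.5 - dist, 0.0, 1.0)
        np.maximum(alpha[y0 : y1 + 1, x0 : x1 + 1], cover, out=alpha[y0 : y1 + 1, x0 : x1 + 1])
        if reflex and seg.width >= 3.5:
            r = np.clip(1.0 - dist, 0.0, 1.0)
            np.maximum(ridge[y0 : y1 + 1, x0 : x1 + 1], r, out=ridge[y0 : y1 + 1, x0 : x1 + 1])
    return np.clip(alpha - _REFLEX_STRENGTH * ridge, 0.0, 1.0)


def render_fundus(
    vessels: np.ndarray,
    illumination: float = 0.25,
    noise_sigma: float = 0.0,
    exposure_gain: float = 1.0,
    fov_radius: float = FOV_DIAMETER / 2,
    rng: np.random.Generator | None = None,
    image_id: str = "",
) -> FundusImage:
    """Compose vessels, illumination, field of view and noise into RGB.

    ``vessels`` is an opacity map in [0, 1]; ``illumination`` is the
    fractional radial falloff at the field-of-view rim (0 = flat). The
    vessels darken the green channel most, so the inverted green channel
    is vessel-bright as the segmentation expects.
    """
    size = vessels.shape[0]
    center = (size - 1) / 2.0
    ys, xs = np.mgrid[0:size, 0:size]
    r = np.hypot(xs - center, ys - center)
    illum = 1.0 - illumination * np.clip(r / fov_radius, 0.0, 1.2) ** 2
    disc = np.clip(fov_radius - r + 0.5, 0.0, 1.0)

    img = np.zeros((size, size, 3), dtype=np.float64)
    for c in range(3):
        channel = (_BG[c] * illum - _VESSEL_DROP[c] * vessels) * disc
        img[:, :, c] = channel
    img *= exposure_gain
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img += rng.normal(0.0, noise_sigma, img.shape) * (disc > 0)[..., None]
    rgb = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return FundusImage(rgb=rgb, fov_mask=r <= fov_radius, id=image_id)


def _similarity_about(center: np.ndarray, scale: float, theta: float, t: np.ndarray) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    R = scale * np.array([[c, -s], [s, c]])
    T = np.eye(3)
    T[:2, :2] = R
    T[:2, 2] = center - R @ center + t
    return T


def _measure_overlap(model: TransformModel, center: np.ndarray, radius: float, step: int = 4) -> float:
    """Fraction of the source FOV whose image under the model lands inside
    the target FOV (discs share canvas geometry)."""
    lo = int(center[0] - radius)
    hi = int(center[0] + radius) + 1
    ys, xs = np.mgrid[lo:hi:step, lo:hi:step]
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    inside_src = np.linalg.norm(pts - center, axis=1) <= radius
    pts = pts[inside_src]
    mapped = model.apply(pts)
    inside_tgt = np.linalg.norm(mapped - center, axis=1) <= radius
    return float(inside_tgt.mean())


def _draw_transform(
    rng: np.random.Generator,
    center: np.ndarray,
    radius: float,
    kind: str,
    overlap_regime: str,
) -> tuple[TransformModel, float]:
    """Random similarity/affine whose translation magnitude is bisected to
    hit the requested overlap regime (>75% for high, <75% for low)."""
    scale = rng.uniform(0.95, 1.05)
    theta = math.radians(rng.uniform(-10.0, 10.0))
    direction = rng.uniform(0.0, 2.0 * math.pi)
    u = np.array([math.cos(direction), math.sin(direction)])
    target_overlap = rng.uniform(0.80, 0.92) if overlap_regime == "high" else rng.uniform(0.55, 0.70)

    shear = np.eye(2)
    if kind == "affine":
        shear[0, 1] = rng.uniform(-0.05, 0.05)
        shear[1, 0] = rng.uniform(-0.05, 0.05)

    def model_at(d: float) -> TransformModel:
        T = _similarity_about(center, scale, theta, d * u)
        if kind == "affine":
            A = np.eye(3)
            A[:2, :2] = shear
            A[:2, 2] = center - shear @ center
            T = T @ A
        return TransformModel(kind=kind, T=T)

    lo, hi = 0.0, 2.0 * radius
    o0 = _measure_overlap(model_at(lo), center, radius)
    # scale/rotation alone already push rim points out of the target FOV;
    # the translation can only lower the overlap further
    if o0 < target_overlap:
        if overlap_regime == "high" and o0 <= 0.76:
            raise ValueError("requested overlap unreachable on this canvas")
        target_overlap = o0 - 0.005
    for _ in range(30):
        mid = (lo + hi) / 2.0
        if _measure_overlap(model_at(mid), center, radius) >= target_overlap:
            lo = mid
        else:
            hi = mid
    model = model_at(lo)
    return model, _measure_overlap(model, center, radius, step=2)


def _sample_control_points(
    rng: np.random.Generator,
    model: TransformModel,
    center: np.ndarray,
    radius: float,
    n_points: int = 10,
    margin: float = 25.0,
) -> ControlPointSet:
    src_pts = []
    r_eff = radius - margin
    while len(src_pts) < n_points:
        p = center + rng.uniform(-r_eff, r_eff, size=2)
        if np.linalg.norm(p - center) > r_eff:
            continue
        q = model.apply(p)[0]
        if np.linalg.norm(q - center) <= r_eff:
            src_pts.append(p)
    src = np.asarray(src_pts)
    return ControlPointSet(src=src, tgt=model.apply(src))


def make_pair(
    scene: VascularScene,
    kind: str = "similarity",
    overlap_regime: str = "high",
    exposure_gain: float = 1.0,
    noise_sigma: float = 0.0,
    illumination: float = 0.25,
    reflex: bool = True,
    seed: int = 0,
    pair_id: str = "",
) -> SyntheticPair:
    """Render a registrable pair from one vascular scene.

    The source view renders the scene as-is; the target view renders the
    scene after the planted transform (content moves, the field-of-view
    disc stays put, as when the camera refixates), with its own noise
    realisation and an optional exposure gain. Ten control points are
    sampled uniformly in the overlap; applying the planted model to
    their source coordinates reproduces the target coordinates exactly.
    """
    if kind not in ("similarity", "affine"):
        raise ValueError("kind must be 'similarity' or 'affine'")
    if overlap_regime not in ("high", "low"):
        raise ValueError("overlap_regime must be 'high' or 'low'")
    rng = np.random.default_rng(seed)
    center = scene.center
    radius = scene.fov_radius

    model, overlap = _draw_transform(rng, center, radius, kind, overlap_regime)

    src_alpha = rasterize_scene(scene, reflex=reflex)
    tgt_alpha = rasterize_scene(scene.transformed(model), reflex=reflex)
    source = render_fundus(
        src_alpha, illumination=illumination, noise_sigma=noise_sigma,
        fov_radius=radius, rng=rng, image_id=f"{pair_id}_source",
    )
    target = render_fundus(
        tgt_alpha, illumination=illumination, noise_sigma=noise_sigma,
        exposure_gain=exposure_gain, fov_radius=radius, rng=rng,
        image_id=f"{pair_id}_target",
    )

    cps = _sample_control_points(rng, model, center, radius)
    junc_src = scene.junctions
    junc_tgt = model.apply(junc_src) if len(junc_src) else junc_src
    in_src = np.linalg.norm(junc_src - center, axis=1) <= radius if len(junc_src) else np.array([], bool)
    in_tgt = np.linalg.norm(junc_tgt - center, axis=1) <= radius if len(junc_tgt) else np.array([], bool)

    return SyntheticPair(
        source=source,
        target=target,
        true_model=model,
        true_junctions_source=junc_src[in_src] if len(junc_src) else junc_src,
        true_junctions_target=junc_tgt[in_tgt] if len(junc_tgt) else junc_tgt,
        control_points=cps,
        overlap=overlap,
        params={
            "pair_id": pair_id,
            "seed": seed,
            "kind": kind,
            "overlap_regime": overlap_regime,
            "exposure_gain": exposure_gain,
            "noise_sigma": noise_sigma,
            "illumination": illumination,
            "reflex": reflex,
        },
    )


def generate_pair(
    seed: int,
    kind: str = "similarity",
    overlap_regime: str = "high",
    exposure_gain: float = 1.0,
    noise_sigma: float = 0.0,
    illumination: float = 0.25,
    reflex: bool = True,
    canvas: int = CANVAS,
    n_roots: int = 4,
    depth: int = 5,
    pair_id: str | None = None,
) -> SyntheticPair:
    """One-call generator: tree, renderings and ground truth from a seed."""
    scene = generate_tree(seed, canvas=canvas, n_roots=n_roots, depth=depth)
    return make_pair(
        scene,
        kind=kind,
        overlap_regime=overlap_regime,
        exposure_gain=exposure_gain,
        noise_sigma=noise_sigma,
        illumination=illumination,
        reflex=reflex,
        seed=seed + 1_000_003,
        pair_id=pair_id if pair_id is not None else f"S{seed:03d}",
    )
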