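"""HOG keypoint description and second-nearest-neighbour matching.

Each landmark is described by gradient-orientation histograms over a
16 x 16 patch split into sixteen 4 x 4 cells with eight 45-degree
orientation bins, giving a 128-dimensional vector. The patch is
standardised before differentiation and the concatenated histogram is
L2-normalised, clipped at 0.2 and renormalised, making the descriptor
invariant to affine intensity changes of the patch. Descriptors are not
rotation-invariant; the small inter-image rotations of same-eye fundus
pairs are absorbed by the similarity fit downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .types import EnhancedImage, KeypointSet

PATCH = 16
CELL = 4
N_BINS = 8
DESCRIPTOR_DIM = (PATCH // CELL) ** 2 * N_BINS  # 128
_CLIP = 0.2


@dataclass
class Descriptor:
    vector: np.ndarray
    keypoint: tuple[int, int]

    @property
    def is_zero(self) -> bool:
        return not np.any(self.vector)


@dataclass
class MatchSet:
    """Accepted correspondences (index_source, index_target, distance)."""

    pairs: list[tuple[int, int, float]]
    direction: str = "source->target"

    def __len__(self) -> int:
        return len(self.pairs)

    def as_index_map(self) -> dict[int, int]:
        return {i: j for i, j, _ in self.pairs}


def compute_descriptor(e: EnhancedImage | np.ndarray, pt: tuple[int, int]) -> Descriptor:
    """Describe the 16 x 16 neighbourhood of one keypoint.

    The keypoint sits at patch offset (8, 8); the window must fit inside
    the image. A constant patch yields the flagged all-zero descriptor.
    """
    gray = e.gray if isinstance(e, EnhancedImage) else np.asarray(e)
    x, y = int(pt[0]), int(pt[1])
    h, w = gray.shape
    if not (PATCH // 2 <= x <= w - PATCH // 2 and PATCH // 2 <= y <= h - PATCH // 2):
        raise ValueError(f"16x16 window at {pt} does not fit inside the image")
    patch = gray[y - 8 : y + 8, x - 8 : x + 8].astype(np.float64)

    std = patch.std()
    if std == 0:
        return Descriptor(vector=np.zeros(DESCRIPTOR_DIM), keypoint=(x, y))
    patch = (patch - patch.mean()) / std

    gy, gx = np.gradient(patch)
    mag = np.hypot(gx, gy)
    ang = np.arctan2(gy, gx) % (2.0 * np.pi)  # counterclockwise from +x
    bins = np.minimum((ang / (2.0 * np.pi) * N_BINS).astype(int), N_BINS - 1)

    vec = np.zeros(DESCRIPTOR_DIM)
    for cy in range(PATCH // CELL):
        for cx in range(PATCH // CELL):
            cell = (cy * (PATCH // CELL) + cx) * N_BINS
            sl = (slice(cy * CELL, (cy + 1) * CELL), slice(cx * CELL, (cx + 1) * CELL))
            vec[cell : cell + N_BINS] = np.bincount(
                bins[sl].ravel(), weights=mag[sl].ravel(), minlength=N_BINS
            )
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec = np.minimum(vec / norm, _CLIP)
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
    return Descriptor(vector=vec, keypoint=(x, y))


def compute_descriptors(e: EnhancedImage, kps: KeypointSet) -> tuple[list[Descriptor], np.ndarray]:
    """Describe every keypoint whose window fits; returns the descriptors
    and the indices of the keypoints kept (window-clipped and constant
    patches are dropped)."""
    gray = np.asarray(e.gray)
    h, w = gray.shape
    descs, kept = [], []
    for i, (x, y) in enumerate(kps.points):
        if not (PATCH // 2 <= x <= w - PATCH // 2 and PATCH // 2 <= y <= h - PATCH // 2):
            continue
        d = compute_descriptor(e, (x, y))
        if d.is_zero:
            continue
        descs.append(d)
        kept.append(i)
    return descs, np.asarray(kept, dtype=int)


def _distance_matrix(A: list[Descriptor], B: list[Descriptor]) -> np.ndarray:
    va = np.stack([d.vector for d in A])
    vb = np.stack([d.vector for d in B])
    return cdist(va, vb)


def match_one_direction(
    A: list[Descriptor],
    B: list[Descriptor],
    threshold: float = 0.2,
    mode: str = "ratio",
) -> MatchSet:
    """Second-nearest-neighbour acceptance of candidate correspondences.

    ``ratio`` accepts a's nearest neighbour b1 when d(a, b1)/d(a, b2)
    <= threshold; ``magnitude`` accepts when d(a, b1) <= threshold*|b1|.
    Candidates without a second neighbour (|B| < 2) are rejected, and
    nearest-neighbour ties break toward the lower index.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if mode not in ("ratio", "magnitude"):
        raise ValueError(f"unknown mode {mode!r}")
    if not A or not B:
        raise ValueError("descriptor lists must be nonempty")
    pairs: list[tuple[int, int, float]] = []
    if len(B) < 2:
        return MatchSet(pairs=pairs)
    D = _distance_matrix(A, B)
    for i in range(len(A)):
        order = np.lexsort((np.arange(len(B)), D[i]))  # stable: lower index wins ties
        j1, j2 = int(order[0]), int(order[1])
        d1, d2 = float(D[i, j1]), float(D[i, j2])
        if mode == "ratio":
            ok = d1 <= threshold * d2
        else:
            ok = d1 <= threshold * float(np.linalg.norm(B[j1].vector))
        if ok:
            pairs.append((i, j1, d1))
    return MatchSet(pairs=pairs)


def cross_check(ab: MatchSet, ba: MatchSet) -> MatchSet:
    """Keep (i, j) accepted as i->j forward and j->i backward; the result
    is symmetric and one-to-one."""
    back = ba.as_index_map()
    pairs = [(i, j, d) for i, j, d in ab.pairs if back.get(j) == i]
    return MatchSet(pairs=pairs, direction="symmetric")


def match_descriptors(
    A: list[Descriptor], B: list[Descriptor], threshold: float = 0.2, mode: str = "ratio"
) -> MatchSet:
    """Cross-checked second-nearest-neighbour matching in both directions."""
    ab = match_one_direction(A, B, threshold=threshold, mode=mode)
    ba = match_one_direction(B, A, threshold=threshold, mode=mode)
    return cross_check(ab, MatchSet(pairs=ba.pairs, direction="target->source"))
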