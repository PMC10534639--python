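"""Skeletonization and bifurcation detection.

The vessel mask is thinned to one-pixel curves with the two-subpass
Zhang-Suen algorithm, which preserves 8-connectivity, and junction
landmarks are then located with the hit-or-miss transform

    A (*) B = (A erode B1)  intersect  (A^c erode B2)

using a bank of 3x3 ternary stencils describing T-shaped, Y-shaped and
cross junction neighbourhoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import json

import numpy as np
from scipy import ndimage

from .types import KeypointSet, VesselMask


@dataclass
class Skeleton:
    """One-pixel-wide binary skeleton of a vessel mask."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)


@dataclass(frozen=True)
class StructuringPair:
    """Ternary 3x3 stencil for the hit-or-miss transform.

    ``b1`` marks cells that must be skeleton foreground, ``b2`` cells that
    must be background; cells in neither are don't-care. The centre cell
    is always in b1 (a junction is itself a skeleton pixel).
    """

    name: str
    b1: tuple
    b2: tuple

    def __post_init__(self) -> None:
        b1 = np.asarray(self.b1, dtype=bool)
        b2 = np.asarray(self.b2, dtype=bool)
        if b1.shape != (3, 3) or b2.shape != (3, 3):
            raise ValueError("stencils must be 3x3")
        if (b1 & b2).any():
            raise ValueError("b1 and b2 must be disjoint")
        if not b1[1, 1]:
            raise ValueError("centre cell must belong to b1")

    @property
    def fg(self) -> np.ndarray:
        return np.asarray(self.b1, dtype=bool)

    @property
    def bg(self) -> np.ndarray:
        return np.asarray(self.b2, dtype=bool)

    def to_ternary(self) -> np.ndarray:
        """3x3 int grid with 1 = b1, 0 = b2, -1 = don't-care."""
        out = np.full((3, 3), -1, dtype=int)
        out[self.fg] = 1
        out[self.bg] = 0
        return out

    @classmethod
    def from_ternary(cls, name: str, grid) -> "StructuringPair":
        grid = np.asarray(grid, dtype=int)
        return cls(name=name, b1=tuple(map(tuple, (grid == 1).astype(int))),
                   b2=tuple(map(tuple, (grid == 0).astype(int))))


def _neighbors(padded: np.ndarray) -> list[np.ndarray]:
    """p2..p9 clockwise from north, as views on a 1-padded array."""
    return [
        padded[:-2, 1:-1],   # p2 N
        padded[:-2, 2:],     # p3 NE
        padded[1:-1, 2:],    # p4 E
        padded[2:, 2:],      # p5 SE
        padded[2:, 1:-1],    # p6 S
        padded[2:, :-2],     # p7 SW
        padded[1:-1, :-2],   # p8 W
        padded[:-2, :-2],    # p9 NW
    ]


def zhang_suen_thin(v: VesselMask | np.ndarray) -> Skeleton:
    """Two-subpass iterative thinning; deletions within a sub-pass are
    simultaneous and iteration stops at the first unchanged pass.

    With neighbours p2..p9 clockwise from north, a pixel is deleted in
    sub-pass 1 when 2 <= B(p) <= 6, A(p) == 1, p2*p4*p6 == 0 and
    p4*p6*p8 == 0; sub-pass 2 swaps the last two products for
    p2*p4*p8 == 0 and p2*p6*p8 == 0. B counts nonzero neighbours and A
    counts 0-to-1 transitions in the clockwise circular sequence.
    """
    mask = v.mask if isinstance(v, VesselMask) else np.asarray(v)
    img = mask.astype(np.uint8)

    while True:
        changed = False
        for subpass in (0, 1):
            padded = np.pad(img, 1)
            nb = _neighbors(padded)
            B = sum(n.astype(np.int32) for n in nb)
            ring = nb + [nb[0]]
            A = sum(((ring[i] == 0) & (ring[i + 1] == 1)) for i in range(8)).astype(np.int32)
            p2, p4, p6, p8 = nb[0], nb[2], nb[4], nb[6]
            if subpass == 0:
                cond = (p2 * p4 * p6 == 0) & (p4 * p6 * p8 == 0)
            else:
                cond = (p2 * p4 * p8 == 0) & (p2 * p6 * p8 == 0)
            delete = (img == 1) & (B >= 2) & (B <= 6) & (A == 1) & cond
            if delete.any():
                img[delete] = 0
                changed = True
        if not changed:
            break
    return Skeleton(mask=img.astype(bool))


# compass cells clockwise from north and their (row, col) in the 3x3 grid
_RING_ORDER = ["N", "NE", "E", "SE", "S", "SW", "W", "NW"]
_CELL_RC = {
    "N": (0, 1), "NE": (0, 2), "E": (1, 2), "SE": (2, 2),
    "S": (2, 1), "SW": (2, 0), "W": (1, 0), "NW": (0, 0),
}


def _stencil(name: str, fg: set[str], bg: set[str]) -> StructuringPair:
    b1 = np.zeros((3, 3), dtype=int)
    b2 = np.zeros((3, 3), dtype=int)
    b1[1, 1] = 1
    for c in fg:
        b1[_CELL_RC[c]] = 1
    for c in bg:
        b2[_CELL_RC[c]] = 1
    return StructuringPair(name=name, b1=tuple(map(tuple, b1)), b2=tuple(map(tuple, b2)))


def build_structuring_bank() -> list[StructuringPair]:
    """Default bank of junction stencils.

    One fully specified stencil (b2 = complement of b1, no don't-cares)
    for every 3x3 neighbourhood whose 8-cell ring, read clockwise, shows
    at least three zero-to-one transitions — i.e. at least three distinct
    skeleton branches leave the centre pixel. This enumerates every
    T-shaped, Y-shaped and cross junction in all orientations, including
    the mixed axis/diagonal forms thinning actually produces. Because
    each stencil pins all eight ring cells, no two stencils can fire on
    the same neighbourhood.
    """
    bank: list[StructuringPair] = []
    for code in range(256):
        ring = [(code >> i) & 1 for i in range(8)]
        transitions = sum(ring[i] == 0 and ring[(i + 1) % 8] == 1 for i in range(8))
        if transitions >= 3:
            fg = {c for i, c in enumerate(_RING_ORDER) if ring[i]}
            bg = {c for i, c in enumerate(_RING_ORDER) if not ring[i]}
            bank.append(_stencil(f"J{code:03d}", fg, bg))
    return bank


def _bank_ring_codes(bank: list[StructuringPair]) -> np.ndarray | None:
    """8-bit ring codes for a fully specified bank, else None.

    A bank with don't-care cells cannot be collapsed to a code lookup
    and falls back to per-stencil hit-or-miss.
    """
    codes = []
    for pair in bank:
        tern = pair.to_ternary()
        if (tern == -1).any():
            return None
        codes.append(sum((1 << i) * int(tern[_CELL_RC[c]]) for i, c in enumerate(_RING_ORDER)))
    return np.asarray(codes, dtype=np.int32)


def save_bank(bank: list[StructuringPair], path) -> None:
    with open(path, "w") as fh:
        json.dump([{"name": s.name, "stencil": s.to_ternary().tolist()} for s in bank], fh)


def load_bank(path) -> list[StructuringPair]:
    with open(path) as fh:
        data = json.load(fh)
    return [StructuringPair.from_ternary(d["name"], d["stencil"]) for d in data]


def hit_or_miss(skeleton: np.ndarray, pair: StructuringPair) -> np.ndarray:
    """Pixels whose neighbourhood matches one stencil; border pixels whose
    3x3 neighbourhood leaves the image are never flagged."""
    A = np.asarray(skeleton).astype(bool)
    hits = ndimage.binary_hit_or_miss(A, structure1=pair.fg, structure2=pair.bg)
    hits[0, :] = hits[-1, :] = False
    hits[:, 0] = hits[:, -1] = False
    return hits


def _merge_close(points: np.ndarray, patterns: np.ndarray, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Union clusters of detections closer than radius; each cluster is
    represented by its centroid."""
    n = len(points)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    for i in range(n):
        for j in range(i + 1, n):
            if d2[i, j] < radius * radius:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    roots = np.array([find(i) for i in range(n)])
    out_pts, out_pat = [], []
    for r in np.unique(roots):
        members = np.where(roots == r)[0]
        out_pts.append(points[members].mean(axis=0))
        out_pat.append(patterns[members[0]])
    return np.asarray(out_pts), np.asarray(out_pat)


def detect_bifurcations(
    s: Skeleton,
    bank: list[StructuringPair] | None = None,
    dedupe_radius: float = 5.0,
    fov_mask: np.ndarray | None = None,
    rim_margin: float = 9.0,
) -> KeypointSet:
    """Hit-or-miss junction detection over a stencil bank.

    Detections closer than ``dedupe_radius`` are merged to their centroid
    rounded to the nearest skeleton pixel. When ``fov_mask`` is given,
    points within ``rim_margin`` pixels of the mask edge are discarded
    (the rim carries top-hat edge artefacts, not anatomy).
    """
    if bank is None:
        bank = build_structuring_bank()
    A = s.mask
    points, patterns = [], []
    codes = _bank_ring_codes(bank)
    if codes is not None:
        # fully specified bank: one ring-code lookup is exactly the union
        # of the per-stencil hit-or-miss responses
        pad = np.pad(A, 1).astype(np.int32)
        H, W = A.shape
        ring = np.zeros((H, W), dtype=np.int32)
        for i, c in enumerate(_RING_ORDER):
            dr, dc = _CELL_RC[c][0] - 1, _CELL_RC[c][1] - 1
            ring |= pad[1 + dr : 1 + dr + H, 1 + dc : 1 + dc + W] << i
        code_to_idx = np.full(256, -1, dtype=np.int32)
        code_to_idx[codes] = np.arange(len(codes))
        hit = A & (code_to_idx[ring] >= 0)
        hit[0, :] = hit[-1, :] = False
        hit[:, 0] = hit[:, -1] = False
        ys, xs = np.nonzero(hit)
        points.extend(zip(xs.tolist(), ys.tolist()))
        patterns.extend(code_to_idx[ring[ys, xs]].tolist())
    else:
        for idx, pair in enumerate(bank):
            ys, xs = np.nonzero(hit_or_miss(A, pair))
            points.extend(zip(xs.tolist(), ys.tolist()))
            patterns.extend([idx] * len(xs))
    if not points:
        return KeypointSet(points=np.empty((0, 2), dtype=int), source_pattern=np.empty(0, dtype=int))

    pts = np.asarray(points, dtype=float)
    pats = np.asarray(patterns, dtype=int)
    pts, pats = _merge_close(pts, pats, dedupe_radius)

    # snap centroids back onto the skeleton
    sk_ys, sk_xs = np.nonzero(A)
    sk = np.stack([sk_xs, sk_ys], axis=1).astype(float)
    snapped = []
    for p in pts:
        j = int(np.argmin(((sk - p) ** 2).sum(axis=1)))
        snapped.append(sk[j])
    pts = np.asarray(snapped, dtype=int)

    if fov_mask is not None:
        dist = ndimage.distance_transform_edt(fov_mask)
        keep = dist[pts[:, 1], pts[:, 0]] > rim_margin
        pts, pats = pts[keep], pats[keep]
    return KeypointSet(points=pts, source_pattern=pats)
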