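"""Core container types shared across the registration pipeline.

Coordinates are 0-based with x increasing rightward (columns) and y
increasing downward (rows); points are stored as ``(x, y)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class DegenerateInputError(ValueError):
    """Raised when an input is structurally unusable (empty field of view,
    constant image where a correlation is required, coincident/collinear
    points for a transform fit)."""


@dataclass
class FundusImage:
    """A colour fundus photograph plus its circular field-of-view mask.

    Attributes
    ----------
    rgb : (H, W, 3) uint8 array
    fov_mask : (H, W) bool array, True inside the illuminated field of view
    id : opaque label used in reports
    """

    rgb: np.ndarray
    fov_mask: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        self.fov_mask = np.asarray(self.fov_mask).astype(bool)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be H x W x 3")
        if self.fov_mask.shape != self.rgb.shape[:2]:
            raise ValueError("fov_mask must match rgb spatial dimensions")
        if not self.fov_mask.any():
            raise DegenerateInputError("fov_mask is empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


@dataclass
class EnhancedImage:
    """Preprocessed single-channel intensity surface (0-255) with its mask.

    Values outside ``fov_mask`` are zero; inside the mask the intensities
    span the full 0-255 range after contrast stretching.
    """

    gray: np.ndarray
    fov_mask: np.ndarray

    def __post_init__(self) -> None:
        self.gray = np.asarray(self.gray)
        self.fov_mask = np.asarray(self.fov_mask).astype(bool)
        if self.gray.shape != self.fov_mask.shape:
            raise ValueError("gray and fov_mask must share dimensions")


@dataclass
class VesselMask:
    """Binary coarse vessel segmentation restricted to the field of view."""

    mask: np.ndarray
    fov_mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.fov_mask = np.asarray(self.fov_mask).astype(bool)
        if self.mask.shape != self.fov_mask.shape:
            raise ValueError("mask and fov_mask must share dimensions")

    @property
    def foreground_fraction(self) -> float:
        """Vessel fraction inside the field of view."""
        n_fov = int(self.fov_mask.sum())
        if n_fov == 0:
            return 0.0
        return float((self.mask & self.fov_mask).sum() / n_fov)


@dataclass
class KeypointSet:
    """Bifurcation/crossover landmarks detected on a vessel skeleton.

    ``points`` is an (N, 2) integer array of (x, y); ``source_pattern``
    gives, per point, the index of the structuring pair that fired.
    """

    points: np.ndarray
    source_pattern: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=int).reshape(-1, 2)
        self.source_pattern = np.asarray(self.source_pattern, dtype=int).reshape(-1)
        if len(self.points) != len(self.source_pattern):
            raise ValueError("points and source_pattern lengths differ")

    def __len__(self) -> int:
        return len(self.points)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"x": self.points[:, 0], "y": self.points[:, 1], "pattern": self.source_pattern}
        ).to_csv(path, index=False)


@dataclass
class TransformModel:
    """Planar transform, target = T @ source on homogeneous (x, y, 1) columns.

    ``kind`` is ``"similarity"`` (rotation + uniform scale + translation,
    4 dof) or ``"affine"`` (6 dof). The last matrix row is (0, 0, 1).
    """

    kind: str
    T: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float).reshape(3, 3)
        if self.kind not in ("similarity", "affine"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if not np.allclose(self.T[2], [0.0, 0.0, 1.0]):
            raise ValueError("last row of T must be (0, 0, 1)")

    @property
    def dof(self) -> int:
        return 4 if self.kind == "similarity" else 6

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) points from the source frame into the target frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.hstack([pts, np.ones((len(pts), 1))])
        out = hom @ self.T.T
        return out[:, :2]

    def inverse(self) -> "TransformModel":
        return TransformModel(kind=self.kind, T=np.linalg.inv(self.T))

    def compose(self, other: "TransformModel") -> "TransformModel":
        """self after other: returns T_self @ T_other."""
        kind = "similarity" if self.kind == other.kind == "similarity" else "affine"
        return TransformModel(kind=kind, T=self.T @ other.T)

    def to_json(self, path=None) -> str:
        payload = json.dumps({"kind": self.kind, "matrix": self.T.tolist()}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "TransformModel":
        try:
            data = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path) as fh:
                data = json.load(fh)
        return cls(kind=data["kind"], T=np.asarray(data["matrix"]))

    @classmethod
    def identity(cls, kind: str = "similarity") -> "TransformModel":
        return cls(kind=kind, T=np.eye(3))


@dataclass
class ControlPointSet:
    """Ground-truth correspondences ((x_src, y_src), (x_tgt, y_tgt))."""

    src: np.ndarray
    tgt: np.ndarray

    def __post_init__(self) -> None:
        self.src = np.asarray(self.src, dtype=float).reshape(-1, 2)
        self.tgt = np.asarray(self.tgt, dtype=float).reshape(-1, 2)
        if self.src.shape != self.tgt.shape:
            raise ValueError("source and target point arrays must match")
        if len(self.src) < 1:
            raise ValueError("control point set must contain at least one pair")
        if not (np.isfinite(self.src).all() and np.isfinite(self.tgt).all()):
            raise ValueError("control point coordinates must be finite")

    def __len__(self) -> int:
        return len(self.src)
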