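"""Mask-normalised Laplacian-pyramid blending.

Each image is decomposed into band-pass levels (Gaussian level minus the
upsampled next level); at every level the two Laplacians are combined as
a mask-weighted average

    fused = (L_A * M_A + L_B * M_B) / (M_A + M_B)

with binary input masks becoming fractional weights under repeated
blur-and-decimate, which is what produces the seam-free transition.
Collapsing the fused pyramid yields the mosaic. With a single octave the
method reduces exactly to per-pixel mask-weighted averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

_PYR_SIGMA = 1.0


@dataclass
class PyramidLevel:
    laplacian: np.ndarray
    mask: np.ndarray
    octave: int


def _downsample(img: np.ndarray) -> np.ndarray:
    blurred = ndimage.gaussian_filter(img, sigma=_PYR_SIGMA, mode="nearest")
    return blurred[::2, ::2]


def _upsample(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return resize(img, shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True)


def _check_size(img: np.ndarray, octaves: int) -> None:
    if octaves < 1:
        raise ValueError("octaves must be >= 1")
    if min(img.shape[:2]) < 2**octaves:
        raise ValueError(f"image of shape {img.shape[:2]} too small for {octaves} octaves")


def build_gaussian_pyramid(img: np.ndarray, octaves: int) -> list[np.ndarray]:
    levels = [np.asarray(img, dtype=float)]
    for _ in range(octaves - 1):
        levels.append(_downsample(levels[-1]))
    return levels


def build_laplacian_pyramid(img: np.ndarray, octaves: int) -> list[np.ndarray]:
    """Band-pass levels 0..octaves-2 plus the residual Gaussian level."""
    img = np.asarray(img, dtype=float)
    _check_size(img, octaves)
    gauss = build_gaussian_pyramid(img, octaves)
    laps = [
        gauss[k] - _upsample(gauss[k + 1], gauss[k].shape[:2])
        for k in range(octaves - 1)
    ]
    laps.append(gauss[-1])
    return laps


def collapse_pyramid(laps: list[np.ndarray]) -> np.ndarray:
    out = laps[-1]
    for lap in reversed(laps[:-1]):
        out = lap + _upsample(out, lap.shape[:2])
    return out


def blend_pair(
    imgA: np.ndarray,
    maskA: np.ndarray,
    imgB: np.ndarray,
    maskB: np.ndarray,
    octaves: int = 3,
) -> np.ndarray:
    """Fuse two registered images with nonnegative support masks.

    Colour images are blended per channel. Pixels outside both masks are
    zero; the output is clipped to 0-255.
    """
    imgA = np.asarray(imgA, dtype=float)
    imgB = np.asarray(imgB, dtype=float)
    maskA = np.asarray(maskA, dtype=float)
    maskB = np.asarray(maskB, dtype=float)
    if imgA.shape != imgB.shape or maskA.shape != maskB.shape or imgA.shape[:2] != maskA.shape:
        raise ValueError("images and masks must share spatial dimensions")
    if (maskA < 0).any() or (maskB < 0).any():
        raise ValueError("masks must be nonnegative")
    _check_size(imgA, octaves)

    if imgA.ndim == 3:
        channels = [
            blend_pair(imgA[..., c], maskA, imgB[..., c], maskB, octaves)
            for c in range(imgA.shape[2])
        ]
        return np.stack(channels, axis=-1)

    lapsA = build_laplacian_pyramid(imgA, octaves)
    lapsB = build_laplacian_pyramid(imgB, octaves)
    mA, mB = maskA, maskB
    fused = []
    for k in range(octaves):
        denom = mA + mB
        level = np.zeros_like(lapsA[k])
        np.divide(lapsA[k] * mA + lapsB[k] * mB, denom, out=level, where=denom > 0)
        fused.append(level)
        if k < octaves - 1:
            mA, mB = _downsample(mA), _downsample(mB)

    out = collapse_pyramid(fused)
    outside = (maskA + maskB) == 0
    out[outside] = 0.0
    return np.clip(out, 0.0, 255.0)


def checkerboard_overlay(imgA: np.ndarray, imgB: np.ndarray, tile: int = 32) -> np.ndarray:
    """Diagnostic overlay alternating square tiles of the two inputs."""
    imgA = np.asarray(imgA)
    imgB = np.asarray(imgB)
    if imgA.shape != imgB.shape:
        raise ValueError("inputs must share shape")
    ys, xs = np.mgrid[0 : imgA.shape[0], 0 : imgA.shape[1]]
    board = ((ys // tile) + (xs // tile)) % 2 == 0
    out = imgB.copy()
    out[board] = imgA[board]
    return out
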