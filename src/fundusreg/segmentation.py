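"""Coarse vessel segmentation by co-occurrence thresholding.

The segmentation works on the inverted green channel of a colour fundus
photograph, where vessels appear brighter than the surrounding tissue.
A global intensity threshold tau_i is chosen as the gray level at which
the intensity CDF is farthest from the identity line (a triangle-style
geometric criterion on the unit square). A normalised gray-level
co-occurrence matrix (NGLCM) over neighbouring pixel pairs then yields
the background co-occurrence probability P_bg and the matrix correlation,
which together set tau_sd, the maximum number of background-intensity
pixels tolerated inside an n x n window centred on a vessel pixel:

    tau_sd = floor(P_bg * corr * n^2)

A pixel is classified as vessel when the count of sub-threshold pixels
in its window does not exceed tau_sd.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .types import DegenerateInputError, EnhancedImage, FundusImage, VesselMask

# Offsets of the 8-neighbourhood used for the omnidirectional d=1
# co-occurrence accumulation.
_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


@dataclass
class NGLCM:
    """Normalised gray-level co-occurrence matrix and its statistics.

    P is 256 x 256, sums to one, and is symmetric because every ordered
    pair of 8-adjacent in-mask pixels is accumulated in both directions.
    """

    P: np.ndarray
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    corr: float
    d: int = 1


@dataclass
class SegmentationModel:
    """Thresholds governing pixel classification.

    tau_i : global intensity threshold from the CDF criterion
    delta_f : CDF span f(255) - f(0)
    cdf : the 256-entry cumulative distribution the threshold came from
    p_bg : probability mass of background-background co-occurrences
    corr : NGLCM correlation
    tau_sd : window background-count threshold, floor(p_bg * corr * n^2)
    n : odd window side length
    """

    tau_i: int
    delta_f: float
    cdf: np.ndarray
    p_bg: float
    corr: float
    tau_sd: int
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.tau_i <= 255):
            raise ValueError("tau_i out of range")
        if not (0.0 <= self.p_bg <= 1.0):
            raise ValueError("p_bg out of range")
        if self.n < 3 or self.n % 2 == 0:
            raise ValueError("window size n must be odd and >= 3")
        if not (0 <= self.tau_sd <= self.n * self.n):
            raise ValueError("tau_sd out of range")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "tau_i": int(self.tau_i),
                "delta_f": float(self.delta_f),
                "p_bg": float(self.p_bg),
                "corr": float(self.corr),
                "tau_sd": int(self.tau_sd),
                "n": int(self.n),
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def extract_fov_mask(img: FundusImage | np.ndarray, threshold_frac: float = 0.1) -> np.ndarray:
    """Recover the circular field of view from the dark surround.

    Thresholds the mean-channel intensity at ``threshold_frac * 255``,
    keeps the largest connected bright component, and closes small gaps.
    """
    rgb = img.rgb if isinstance(img, FundusImage) else np.asarray(img)
    intensity = rgb.astype(float).mean(axis=2)
    bright = intensity > threshold_frac * 255.0
    if not bright.any():
        raise DegenerateInputError("no field of view: image is entirely dark")
    labels, n = ndimage.label(bright)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        bright = labels == (1 + int(np.argmax(sizes)))
    closed = ndimage.binary_closing(bright, structure=morphology.disk(5))
    return ndimage.binary_fill_holes(closed)


def preprocess(
    img: FundusImage,
    sigma: float = 1.5,
    tophat_radius: int = 9,
    saturate_frac: float = 0.03,
) -> EnhancedImage:
    """Build the vessel-bright intensity surface used by every later stage.

    Pipeline: invert the green channel (255 - G), zero outside the field
    of view, Gaussian smooth, white top-hat with a disc structuring
    element, then a linear contrast stretch that saturates
    ``saturate_frac`` of the in-mask pixels at each tail.
    """
    if not (0.0 <= saturate_frac < 0.5):
        raise ValueError("saturate_frac must be in [0, 0.5)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    mask = img.fov_mask
    if not mask.any():
        raise DegenerateInputError("fov_mask is empty")

    green = img.rgb[:, :, 1].astype(float)
    inv = (255.0 - green) * mask
    smooth = ndimage.gaussian_filter(inv, sigma=sigma)
    tophat = morphology.white_tophat(smooth, morphology.disk(tophat_radius))

    vals = tophat[mask]
    lo = np.percentile(vals, 100.0 * saturate_frac)
    hi = np.percentile(vals, 100.0 * (1.0 - saturate_frac))
    if hi <= lo:
        stretched = np.zeros_like(tophat)
    else:
        stretched = (tophat - lo) / (hi - lo) * 255.0
    out = np.clip(np.round(stretched), 0, 255).astype(np.uint8)
    out[~mask] = 0
    return EnhancedImage(gray=out, fov_mask=mask)


def compute_cdf(e: EnhancedImage) -> tuple[np.ndarray, float]:
    """Empirical intensity CDF over in-mask pixels.

    Returns ``(cdf, delta_f)`` where ``cdf[l]`` is the fraction of
    in-mask pixels with intensity <= l and ``delta_f = cdf[255] - cdf[0]``.
    """
    vals = np.asarray(e.gray)[e.fov_mask].astype(np.int64)
    if vals.size == 0:
        raise DegenerateInputError("fov_mask contains no pixels")
    hist = np.bincount(vals, minlength=256)[:256]
    cdf = np.cumsum(hist) / vals.size
    return cdf, float(cdf[255] - cdf[0])


def global_threshold(cdf: np.ndarray, delta_f: float) -> int:
    """Gray level maximising the CDF's distance to the identity diagonal.

    The intensity axis is normalised to [0, 1] so both curves live on the
    unit square; the score at level l is

        |f(l) + delta_f * (1 - l/255) - 1| / sqrt(1 + delta_f^2)

    and ties break toward the smaller level.
    """
    levels = np.arange(256) / 255.0
    dist = np.abs(cdf + delta_f * (1.0 - levels) - 1.0) / math.sqrt(1.0 + delta_f**2)
    return int(np.argmax(dist))


def compute_nglcm(e: EnhancedImage) -> NGLCM:
    """Omnidirectional d=1 co-occurrence matrix over in-mask pixel pairs.

    One count is accumulated for every ordered pair of 8-adjacent pixels
    that both lie inside the field of view, so the matrix is symmetric.
    Raises on constant images, where the correlation is undefined.
    """
    gray = np.asarray(e.gray).astype(np.int64)
    mask = e.fov_mask
    if mask.sum() < 2:
        raise DegenerateInputError("need at least two in-mask pixels")

    P = np.zeros((256, 256), dtype=np.float64)
    H, W = gray.shape
    for dy, dx in _NEIGHBOR_OFFSETS:
        ys = slice(max(0, dy), min(H, H + dy))
        xs = slice(max(0, dx), min(W, W + dx))
        ys0 = slice(max(0, -dy), min(H, H - dy))
        xs0 = slice(max(0, -dx), min(W, W - dx))
        valid = mask[ys0, xs0] & mask[ys, xs]
        a = gray[ys0, xs0][valid]
        b = gray[ys, xs][valid]
        np.add.at(P, (a, b), 1.0)
    total = P.sum()
    if total == 0:
        raise DegenerateInputError("no adjacent in-mask pixel pairs")
    P /= total

    levels = np.arange(256, dtype=np.float64)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(px @ levels)
    mu_y = float(py @ levels)
    sigma_x = float(np.sqrt(px @ (levels - mu_x) ** 2))
    sigma_y = float(np.sqrt(py @ (levels - mu_y) ** 2))
    if sigma_x * sigma_y == 0.0:
        raise DegenerateInputError("constant image: NGLCM correlation undefined")
    corr = float(((levels - mu_x)[:, None] * (levels - mu_y)[None, :] * P).sum() / (sigma_x * sigma_y))
    return NGLCM(P=P, mu_x=mu_x, mu_y=mu_y, sigma_x=sigma_x, sigma_y=sigma_y, corr=corr)


def background_cooccurrence(g: NGLCM, tau_i: int) -> float:
    """Mass of pairs whose two intensities are both below tau_i."""
    t = int(np.clip(tau_i, 0, 256))
    return float(g.P[:t, :t].sum())


def window_threshold(p_bg: float, corr: float, n: int) -> int:
    """tau_sd = floor(p_bg * corr * n^2); negative correlation clamps to 0."""
    if n < 3 or n % 2 == 0:
        raise ValueError("window size n must be odd and >= 3")
    return int(math.floor(p_bg * max(corr, 0.0) * n * n))


def fit_segmentation_model(e: EnhancedImage, n: int = 7) -> SegmentationModel:
    """Derive all thresholds of the classification rule from one image."""
    cdf, delta_f = compute_cdf(e)
    tau_i = global_threshold(cdf, delta_f)
    g = compute_nglcm(e)
    p_bg = background_cooccurrence(g, tau_i)
    tau_sd = window_threshold(p_bg, g.corr, n)
    return SegmentationModel(
        tau_i=tau_i, delta_f=delta_f, cdf=cdf, p_bg=p_bg, corr=g.corr, tau_sd=tau_sd, n=n
    )


def segment_vessels(e: EnhancedImage, m: SegmentationModel) -> VesselMask:
    """Window-count classification of every in-mask pixel.

    A pixel is background when more than tau_sd pixels of its n x n
    window have intensity below tau_i; windows are clipped at image
    borders with missing pixels counted as background, and pixels outside
    the field of view are both background and counted as background.
    """
    gray = np.asarray(e.gray)
    mask = e.fov_mask
    bg = ((gray < m.tau_i) | ~mask).astype(np.int64)
    kernel = np.ones((m.n, m.n), dtype=np.int64)
    counts = ndimage.correlate(bg, kernel, mode="constant", cval=1)
    vessel = mask & (counts <= m.tau_sd)
    return VesselMask(mask=vessel, fov_mask=mask)


def segment(img: FundusImage, n: int = 7, sigma: float = 1.5,
            tophat_radius: int = 9, saturate_frac: float = 0.03) -> tuple[EnhancedImage, SegmentationModel, VesselMask]:
    """Convenience: preprocess, fit the model, and classify in one call."""
    e = preprocess(img, sigma=sigma, tophat_radius=tophat_radius, saturate_frac=saturate_frac)
    model = fit_segmentation_model(e, n=n)
    return e, model, segment_vessels(e, model)
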