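"""Vessel segmentation: CDF threshold, NGLCM statistics, window rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fundusreg as fr
from fundusreg.segmentation import (
    NGLCM,
    background_cooccurrence,
    compute_cdf,
    compute_nglcm,
    extract_fov_mask,
    fit_segmentation_model,
    global_threshold,
    preprocess,
    segment_vessels,
    window_threshold,
)
from fundusreg.types import DegenerateInputError, EnhancedImage, FundusImage


def _enh(gray, mask=None):
    gray = np.asarray(gray, dtype=np.uint8)
    if mask is None:
        mask = np.ones_like(gray, dtype=bool)
    return EnhancedImage(gray=gray, fov_mask=mask)


# ---------------------------------------------------------------- FOV mask

class TestExtractFov:
    def test_all_dark_image_rejected(self):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        with pytest.raises(DegenerateInputError):
            extract_fov_mask(img)

    def test_white_disc_recovered(self):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        ys, xs = np.mgrid[0:64, 0:64]
        disc = np.hypot(xs - 31.5, ys - 31.5) <= 24
        img[disc] = 255
        mask = extract_fov_mask(img)
        assert (mask & disc).sum() / disc.sum() > 0.98
        assert (mask & ~disc).sum() / disc.sum() < 0.1

    def test_synthetic_fundus_disc_area(self, pair0):
        mask = extract_fov_mask(pair0.source)
        true_area = pair0.source.fov_mask.sum()
        assert abs(int(mask.sum()) - int(true_area)) / true_area < 0.01


# -------------------------------------------------------------- preprocess

class TestPreprocess:
    def test_constant_green_zeroes_out(self):
        rgb = np.zeros((40, 40, 3), dtype=np.uint8)
        rgb[:, :, 1] = 90
        img = FundusImage(rgb=rgb, fov_mask=np.ones((40, 40), dtype=bool))
        e = preprocess(img)
        assert e.gray.max() == 0

    def test_thin_bright_line_survives_tophat(self):
        # vessel-like line in the (inverted) green channel on a flat background
        rgb = np.full((64, 64, 3), 200, dtype=np.uint8)
        rgb[30:33, 8:56, 1] = 130  # dark green stripe -> bright after inversion
        img = FundusImage(rgb=rgb, fov_mask=np.ones((64, 64), dtype=bool))
        e = preprocess(img, saturate_frac=0.0)
        line = e.gray[31, 16:48].astype(int)
        background = e.gray[10, 16:48].astype(int)
        in_contrast = 70  # 200 - 130
        assert line.mean() - background.mean() >= in_contrast

    def test_default_saturation_level(self):
        import inspect

        sig = inspect.signature(preprocess)
        assert sig.parameters["saturate_frac"].default == 0.03

    def test_outside_mask_is_zero_and_full_span_inside(self, pair0):
        e = preprocess(pair0.source)
        assert e.gray[~e.fov_mask].max() == 0
        inside = e.gray[e.fov_mask]
        assert inside.min() == 0 and inside.max() == 255

    def test_empty_mask_rejected(self):
        rgb = np.full((16, 16, 3), 100, dtype=np.uint8)
        with pytest.raises((DegenerateInputError, ValueError)):
            FundusImage(rgb=rgb, fov_mask=np.zeros((16, 16), dtype=bool))


# --------------------------------------------------------------------- CDF

class TestCdf:
    def test_constant_image_step_cdf(self):
        cdf, delta_f = compute_cdf(_enh(np.full((8, 8), 100)))
        assert cdf[99] == 0.0 and cdf[100] == 1.0 and cdf[255] == 1.0
        assert delta_f == 1.0

    def test_uniform_histogram(self):
        gray = np.arange(256, dtype=np.uint8).reshape(16, 16)
        cdf, _ = compute_cdf(_enh(gray))
        np.testing.assert_allclose(cdf, (np.arange(256) + 1) / 256)

    def test_four_pixel_example(self):
        cdf, _ = compute_cdf(_enh(np.array([[10, 10], [20, 30]])))
        assert cdf[10] == 0.5 and cdf[20] == 0.75 and cdf[29] == 0.75 and cdf[30] == 1.0

    def test_mask_restriction(self):
        gray = np.array([[10, 200], [10, 200]])
        mask = np.array([[True, False], [True, False]])
        cdf, _ = compute_cdf(_enh(gray, mask))
        assert cdf[10] == 1.0


# -------------------------------------------------------- global threshold

def _brute_force_threshold(cdf, delta_f):
    best, best_d = 0, -1.0
    for l in range(256):
        d = abs(cdf[l] + delta_f * (1 - l / 255) - 1) / np.sqrt(1 + delta_f**2)
        if d > best_d + 1e-15:
            best, best_d = l, d
    return best


class TestGlobalThreshold:
    def test_identity_cdf_zero_distance(self):
        cdf = np.arange(256) / 255.0
        assert global_threshold(cdf, 1.0) == 0

    def test_step_cdf(self):
        cdf = np.zeros(256)
        cdf[100:] = 1.0
        assert global_threshold(cdf, 1.0) == 100

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        hist = rng.integers(0, 100, size=256)
        hist[rng.integers(0, 256)] += 1  # nonempty
        cdf = np.cumsum(hist) / hist.sum()
        delta_f = float(cdf[255] - cdf[0])
        assert global_threshold(cdf, delta_f) == _brute_force_threshold(cdf, delta_f)


# ------------------------------------------------------------------- NGLCM

def _brute_force_nglcm(gray, mask):
    """Double loop over all ordered 8-adjacent in-mask pixel pairs."""
    H, W = gray.shape
    P = np.zeros((256, 256))
    for y in range(H):
        for x in range(W):
            if not mask[y, x]:
                continue
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == dx == 0:
                        continue
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < H and 0 <= xx < W and mask[yy, xx]:
                        P[gray[y, x], gray[yy, xx]] += 1
    return P / P.sum()


class TestNglcm:
    def test_constant_image_raises(self):
        with pytest.raises(DegenerateInputError):
            compute_nglcm(_enh(np.full((8, 8), 50)))

    def test_checkerboard_against_oracle(self):
        ys, xs = np.mgrid[0:8, 0:8]
        gray = np.where((ys + xs) % 2 == 0, 0, 255).astype(np.uint8)
        g = compute_nglcm(_enh(gray))
        P_ref = _brute_force_nglcm(gray, np.ones_like(gray, dtype=bool))
        np.testing.assert_allclose(g.P, P_ref, atol=1e-12)
        # axis neighbours are opposite, diagonal neighbours equal
        assert g.P[0, 255] > 0 and g.P[0, 0] > 0

    def test_random_image_equals_brute_force(self):
        rng = np.random.default_rng(5)
        gray = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        mask = rng.random((8, 8)) > 0.2
        g = compute_nglcm(_enh(gray, mask))
        np.testing.assert_allclose(g.P, _brute_force_nglcm(gray, mask), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_sums_to_one_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        gray = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        g = compute_nglcm(_enh(gray))
        assert abs(g.P.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(g.P, g.P.T, atol=1e-12)
        assert -1.0 <= g.corr <= 1.0


# ----------------------------------------------- background co-occurrence

class TestBackgroundCooccurrence:
    @pytest.fixture()
    def g(self):
        rng = np.random.default_rng(2)
        gray = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        return compute_nglcm(_enh(gray))

    def test_zero_threshold_empty_sum(self, g):
        assert background_cooccurrence(g, 0) == 0.0

    def test_full_threshold_total_mass(self, g):
        assert abs(background_cooccurrence(g, 256) - 1.0) < 1e-9

    def test_monotone_in_threshold(self, g):
        vals = [background_cooccurrence(g, t) for t in range(0, 257, 16)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


# --------------------------------------------------------- window threshold

class TestWindowThreshold:
    def test_zero_probability(self):
        assert window_threshold(0.0, 0.9, 7) == 0

    def test_direct_arithmetic(self):
        assert window_threshold(0.8, 0.9, 7) == 35  # floor(0.8*0.9*49)

    def test_negative_correlation_clamps(self):
        assert window_threshold(0.8, -1.0, 7) == 0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            window_threshold(0.5, 0.5, 6)


# --------------------------------------------------------- segment_vessels

def _brute_force_segment(gray, mask, tau_i, tau_sd, n):
    H, W = gray.shape
    out = np.zeros((H, W), dtype=bool)
    h = n // 2
    for y in range(H):
        for x in range(W):
            if not mask[y, x]:
                continue
            count = 0
            for dy in range(-h, h + 1):
                for dx in range(-h, h + 1):
                    yy, xx = y + dy, x + dx
                    if not (0 <= yy < H and 0 <= xx < W):
                        count += 1
                    elif not mask[yy, xx] or gray[yy, xx] < tau_i:
                        count += 1
            out[y, x] = count <= tau_sd
    return out


class TestSegmentVessels:
    def _model(self, tau_i, tau_sd, n=5):
        cdf = np.linspace(0, 1, 256)
        return fr.SegmentationModel(
            tau_i=tau_i, delta_f=1.0, cdf=cdf, p_bg=0.5, corr=0.5, tau_sd=tau_sd, n=n
        )

    def test_all_dark_gives_empty_mask(self):
        e = _enh(np.full((20, 20), 10))
        v = segment_vessels(e, self._model(tau_i=50, tau_sd=3))
        assert not v.mask.any()

    def test_bright_line_is_vessel(self):
        gray = np.full((64, 64), 10, dtype=np.uint8)
        gray[30:33, :] = 200
        v = segment_vessels(_enh(gray), self._model(tau_i=50, tau_sd=20, n=5))
        assert v.mask[31, 20:44].all()
        assert not v.mask[10, 20:44].any()

    @pytest.mark.parametrize("seed", range(3))
    def test_equals_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        gray = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        mask = rng.random((32, 32)) > 0.1
        m = self._model(tau_i=int(rng.integers(20, 230)), tau_sd=int(rng.integers(0, 25)))
        got = segment_vessels(_enh(gray, mask), m)
        expected = _brute_force_segment(gray, mask, m.tau_i, m.tau_sd, m.n)
        np.testing.assert_array_equal(got.mask, expected)

    def test_monotone_in_tau_sd(self):
        rng = np.random.default_rng(9)
        gray = rng.integers(0, 256, size=(40, 40)).astype(np.uint8)
        e = _enh(gray)
        prev = None
        for tau_sd in (0, 5, 12, 20, 25):
            cur = segment_vessels(e, self._model(tau_i=128, tau_sd=tau_sd)).mask
            if prev is not None:
                assert (prev <= cur).all()  # raising tau_sd never shrinks vessels
            prev = cur

    def test_fraction_in_sanity_band_on_synthetic_fundus(self, pair0):
        e = preprocess(pair0.source)
        m = fit_segmentation_model(e)
        v = segment_vessels(e, m)
        assert 0.05 <= v.foreground_fraction <= 0.25

    def test_model_serializes(self, tmp_path):
        m = self._model(tau_i=17, tau_sd=12)
        path = tmp_path / "model.json"
        m.to_json(path)
        import json

        data = json.loads(path.read_text())
        assert data["tau_i"] == 17 and data["n"] == 5
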