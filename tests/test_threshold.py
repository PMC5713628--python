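import numpy as np
import pytest

from phenokit import threshold


def hist_to_image(hist):
    """Materialize a 256-bin histogram as a 1xN grayscale image."""
    vals = np.repeat(np.arange(256, dtype=np.uint8), hist)
    return vals.reshape(1, -1)


def triangle_oracle(hist, object_type="light", xstep=1):
    """Exhaustive perpendicular-distance search, written independently."""
    hist = np.asarray(hist, float)
    peak = int(np.argmax(hist))
    occupied = np.nonzero(hist)[0]
    end = int(occupied[-1]) if object_type == "light" else int(occupied[0])
    step = xstep if object_type == "light" else -xstep
    best, best_d = None, -1.0
    x = peak + (1 if object_type == "light" else -1)
    candidates = []
    c = x
    while (c < end) if object_type == "light" else (c > end):
        candidates.append(c)
        c += step
    for lvl in candidates:
        # distance from point to line through (peak,h[peak]) and (end,h[end])
        num = abs((end - peak) * (hist[lvl] - hist[peak])
                  - (hist[end] - hist[peak]) * (lvl - peak))
        d = num / np.hypot(end - peak, hist[end] - hist[peak])
        if d > best_d:
            best, best_d = lvl, d
    return peak if best is None else best


def otsu_oracle(hist):
    """Brute-force weighted within-class variance minimization.

    Exact rational arithmetic, so histogram splits over empty gaps tie
    exactly and the first (lowest) level wins, with no float-summation
    ambiguity.
    """
    from fractions import Fraction

    counts = [int(c) for c in hist]
    best, best_v = None, None
    for t in range(256):
        w0 = sum(counts[: t + 1])
        w1 = sum(counts[t + 1:])
        if w0 == 0 or w1 == 0:
            continue
        s0 = sum(l * c for l, c in enumerate(counts[: t + 1]))
        s1 = sum(l * c for l, c in enumerate(counts[t + 1:], start=t + 1))
        q0 = sum(l * l * c for l, c in enumerate(counts[: t + 1]))
        q1 = sum(l * l * c for l, c in enumerate(counts[t + 1:], start=t + 1))
        # w0*var0 + w1*var1 = (q0 - s0^2/w0) + (q1 - s1^2/w1)
        v = Fraction(q0) - Fraction(s0 * s0, w0) + Fraction(q1) - Fraction(s1 * s1, w1)
        if best_v is None or v < best_v:
            best, best_v = t, v
    return best


def random_bimodal_hist(rng):
    """Two Gaussian bumps plus noise — peak interior, right tail occupied."""
    hist = np.zeros(256, dtype=np.int64)
    m1 = rng.integers(30, 110)
    m2 = rng.integers(150, 230)
    for m, n, s in ((m1, rng.integers(500, 2000), rng.integers(5, 20)),
                    (m2, rng.integers(50, 400), rng.integers(5, 20))):
        samples = np.clip(rng.normal(m, s, n).round().astype(int), 0, 255)
        hist += np.bincount(samples, minlength=256)
    return hist


class TestTriangle:
    def test_bimodal_matches_exhaustive_oracle(self):
        hist = np.zeros(256, np.int64)
        hist[10], hist[200] = 1000, 100
        img = hist_to_image(hist)
        res = threshold.triangle_auto_threshold(img, object_type="light")
        assert res.threshold_value == triangle_oracle(hist)
        assert np.array_equal(res.histogram, hist)

    def test_matches_oracle_on_100_random_histograms(self, rng):
        for _ in range(100):
            hist = random_bimodal_hist(rng)
            got = threshold.triangle_threshold_from_hist(hist, "light")
            assert got == triangle_oracle(hist)

    def test_xstep_strides_candidates(self, rng):
        for _ in range(20):
            hist = random_bimodal_hist(rng)
            t2 = threshold.triangle_threshold_from_hist(hist, "light", xstep=2)
            assert t2 == triangle_oracle(hist, xstep=2)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            threshold.triangle_auto_threshold(np.full((5, 5), 9, np.uint8))

    def test_dark_polarity_uses_low_tail(self):
        hist = np.zeros(256, np.int64)
        hist[200], hist[30] = 1000, 120
        t = threshold.triangle_threshold_from_hist(hist, "dark")
        assert t == triangle_oracle(hist, "dark")
        assert 30 < t < 200


class TestOtsu:
    def test_two_delta_peaks(self):
        hist = np.zeros(256, np.int64)
        hist[50], hist[200] = 500, 500
        img = hist_to_image(hist)
        res = threshold.otsu_auto_threshold(img)
        assert 50 <= res.threshold_value < 200
        assert res.threshold_value == otsu_oracle(hist)

    def test_matches_oracle_on_100_random_histograms(self, rng):
        for _ in range(100):
            hist = random_bimodal_hist(rng)
            assert threshold.otsu_threshold_from_hist(hist) == otsu_oracle(hist)

    def test_agrees_with_skimage_within_one_level(self, rng):
        from skimage.filters import threshold_otsu

        for _ in range(10):
            img = hist_to_image(random_bimodal_hist(rng))
            ours = threshold.otsu_auto_threshold(img).threshold_value
            ref = threshold_otsu(img)
            assert abs(ours - ref) <= 1

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            threshold.otsu_auto_threshold(np.full((4, 4), 100, np.uint8))


class TestAdaptive:
    def test_uniform_image_positive_offset_empty_mask(self):
        img = np.full((20, 20), 100, np.uint8)
        out = threshold.adaptive_threshold(img, "mean", 5, offset=-1,
                                           object_type="light")
        assert (out == 0).all()

    def test_step_edge_transitions_near_boundary_only(self):
        img = np.zeros((10, 20), np.uint8)
        img[:, :10] = 50
        img[:, 10:] = 200
        out = threshold.adaptive_threshold(img, "mean", 3, 0, "light")
        changed = np.nonzero(out[0] != out[0, 0])[0]
        assert changed.min() >= 9  # only within one block of the edge

    def test_matches_sliding_window_oracle(self, rng):
        img = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        out = threshold.adaptive_threshold(img, "mean", 3, 2.0, "light")
        padded = np.pad(img.astype(float), 1, mode="edge")
        for y in range(12):
            for x in range(12):
                local = padded[y:y + 3, x:x + 3].mean()
                expect = 255 if img[y, x] > local - 2.0 else 0
                assert out[y, x] == expect

    def test_gradient_defeats_global_but_not_adaptive(self):
        # linear ramp spanning the full gray range with a small bright blob
        img = np.tile(np.linspace(0, 220, 200).astype(np.uint8), (50, 1))
        img[20:30, 40:50] = np.minimum(255, img[20:30, 40:50].astype(int) + 35)
        out = threshold.adaptive_threshold(img, "mean", 21, 5, "light")
        blob = np.zeros_like(img, bool)
        blob[21:29, 41:49] = True
        assert (out[blob] == 255).all()

    def test_constant_image_constant_mask(self):
        img = np.full((15, 15), 42, np.uint8)
        for method in ("mean", "gaussian"):
            out = threshold.adaptive_threshold(img, method, 5, 0, "dark")
            assert len(np.unique(out)) == 1

    def test_even_block_rejected(self):
        with pytest.raises(ValueError):
            threshold.adaptive_threshold(np.zeros((5, 5), np.uint8), "mean", 4)


class TestBinaryAndPolarity:
    def test_binary_counting_oracle(self, rng):
        img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        out = threshold.binary_threshold(img, 127, "light")
        assert (out == 255).sum() == (img > 127).sum()

    def test_value_extremes(self, rng):
        img = rng.integers(0, 256, (8, 8), dtype=np.uint8)
        assert ((threshold.binary_threshold(img, 0, "light") == 255)
                == (img > 0)).all()
        assert (threshold.binary_threshold(img, 255, "light") == 0).all()

    def test_polarity_flip_complements_off_boundary(self, rng):
        img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        light = threshold.binary_threshold(img, 100, "light")
        dark = threshold.binary_threshold(img, 100, "dark")
        off_boundary = img != 100
        assert (light[off_boundary] != dark[off_boundary]).all()
        assert (light[~off_boundary] == 0).all() and (dark[~off_boundary] == 0).all()

    def test_masks_strictly_binary(self, rng):
        img = rng.integers(0, 256, (10, 10), dtype=np.uint8)
        for m in (threshold.triangle_auto_threshold(img).mask,
                  threshold.otsu_auto_threshold(img).mask,
                  threshold.adaptive_threshold(img, "gaussian", 5)):
            assert set(np.unique(m)) <= {0, 255}
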