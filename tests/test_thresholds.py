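import numpy as np
import pytest

from octaquant import (BinaryMap, DegenerateHistogramError, PhansalkarParams,
                       huang_threshold, image_histogram, maxentropy_threshold,
                       median_local_binarize, phansalkar_binarize)

from oracles import (naive_huang, naive_kapur, naive_local_median,
                     naive_phansalkar)


def _two_spike(level_a, level_b, count=8):
    h = np.zeros(256, dtype=int)
    h[level_a] = count
    h[level_b] = count
    return h


class TestHuang:
    def test_two_spikes_are_separated(self):
        h = _two_spike(10, 200)
        t = huang_threshold(h)
        assert 10 <= t < 200
        assert t == naive_huang(h)

    def test_extreme_spikes_tie_break_to_lowest(self):
        # all interior candidates have zero fuzziness; lowest one wins
        assert huang_threshold(_two_spike(0, 255)) == 0

    def test_binarization_recovers_bright_pixels(self):
        img = np.empty((4, 4), dtype=np.uint8)
        img.ravel()[:8] = 40
        img.ravel()[8:] = 210
        t = huang_threshold(image_histogram(img))
        assert (img > t).sum() == 8

    def test_degenerate_histogram_raises(self):
        h = np.zeros(256, int)
        h[77] = 100
        with pytest.raises(DegenerateHistogramError):
            huang_threshold(h)

    def test_matches_oracle_on_random_histograms(self, rng):
        for _ in range(25):
            h = np.zeros(256, int)
            levels = rng.choice(256, size=rng.integers(2, 30), replace=False)
            h[levels] = rng.integers(1, 60, size=levels.size)
            assert huang_threshold(h) == naive_huang(h)


class TestMaxEntropy:
    def test_two_spikes_are_separated(self):
        h = _two_spike(50, 180)
        t = maxentropy_threshold(h)
        assert 50 <= t < 180

    def test_uniform_histogram_matches_brute_force(self):
        h = np.ones(256, int)
        assert maxentropy_threshold(h) == naive_kapur(h)

    def test_degenerate_histogram_raises(self):
        h = np.zeros(256, int)
        h[0] = 5
        with pytest.raises(DegenerateHistogramError):
            maxentropy_threshold(h)

    def test_matches_oracle_on_random_histograms(self, rng):
        for _ in range(25):
            h = np.zeros(256, int)
            levels = rng.choice(256, size=rng.integers(2, 30), replace=False)
            h[levels] = rng.integers(1, 60, size=levels.size)
            assert maxentropy_threshold(h) == naive_kapur(h)


def test_global_thresholds_depend_on_histogram_only(rng):
    img = rng.random((16, 16))
    shuffled = rng.permutation(img.ravel()).reshape(16, 16)
    assert (huang_threshold(image_histogram(img))
            == huang_threshold(image_histogram(shuffled)))
    assert (maxentropy_threshold(image_histogram(img))
            == maxentropy_threshold(image_histogram(shuffled)))


class TestMedianLocal:
    def test_constant_image_is_all_background(self):
        out = median_local_binarize(np.full((12, 12), 0.4), 3)
        assert not out.pixels.any()

    def test_single_bright_pixel_detected(self):
        img = np.zeros((15, 15))
        img[7, 7] = 1.0
        out = median_local_binarize(img, 5)
        assert out.pixels[7, 7]
        assert out.pixels.sum() == 1

    def test_matches_naive_oracle(self, rng):
        for radius in (1, 2, 4):
            img = rng.random((16, 16))
            assert np.array_equal(median_local_binarize(img, radius).pixels,
                                  naive_local_median(img, radius))

    def test_quantized_fast_path_matches_oracle(self, rng):
        img = np.round(rng.random((20, 20)) * 255) / 255
        assert np.array_equal(median_local_binarize(img, 3).pixels,
                              naive_local_median(img, 3))

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError):
            median_local_binarize(np.zeros((10, 10)), 11)


class TestPhansalkar:
    def test_constant_half_gray_is_all_foreground(self):
        # closed form: t = 0.5 * (1 + 2 e^-5 - 0.25) ~ 0.3817 < 0.5
        out = phansalkar_binarize(np.full((40, 40), 0.5))
        assert out.pixels.all()

    def test_all_zero_image_is_all_background(self):
        out = phansalkar_binarize(np.zeros((40, 40)))
        assert not out.pixels.any()

    def test_matches_naive_oracle(self, rng):
        for radius in (2, 5):
            img = rng.random((24, 24))
            got = phansalkar_binarize(
                img, PhansalkarParams(radius_px=radius)).pixels
            assert np.array_equal(got, naive_phansalkar(img, radius))

    def test_unnormalised_input_rejected(self):
        with pytest.raises(ValueError):
            phansalkar_binarize(np.full((20, 20), 3.0))


def test_local_binarization_commutes_with_translation(rng):
    """Shifting the image shifts the map (away from the border band)."""
    img = rng.random((24, 24))
    shifted = np.roll(img, (3, 5), axis=(0, 1))
    r = 2
    a = median_local_binarize(img, r).pixels
    b = median_local_binarize(shifted, r).pixels
    inner = np.roll(a, (3, 5), axis=(0, 1))[6:-6, 6:-6]
    assert np.array_equal(inner, b[6:-6, 6:-6])


def test_binary_map_validation():
    with pytest.raises(ValueError):
        BinaryMap(np.zeros((4, 4), dtype=float))
    with pytest.raises(ValueError):
        PhansalkarParams(radius_px=0)
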