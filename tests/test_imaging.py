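"""Otsu thresholding, segmentation and sliding-threshold quantification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage.filters import threshold_otsu as skimage_otsu

from vacuoquant.imaging import (
    CellMask,
    compare_classes,
    otsu_threshold,
    population_bands,
    quantify_cell,
    segment_cell,
)
from vacuoquant.synth import CellImagePair, ImageParams, SeverityClass, generate_cell_image


def brute_force_otsu(pixels: np.ndarray) -> int:
    """Exhaustive between-class-variance argmax over all 256 levels.

    Independent reference: class 0 holds values < t, class 1 values >= t;
    the lowest maximizing t wins.
    """
    flat = np.asarray(pixels).ravel().astype(int)
    best_t, best_v = None, -1.0
    n = flat.size
    for t in range(1, 256):
        lo = flat[flat < t]
        hi = flat[flat >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / n, hi.size / n
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def make_pair(cd4, lamp, cell_id="c", cls=SeverityClass.CONTROL):
    cd4 = np.asarray(cd4, dtype=np.uint8)
    lamp = np.asarray(lamp, dtype=np.uint8)
    return CellImagePair(cd4, lamp, None, float("nan"), cell_id, cls)


class TestOtsu:
    def test_perfectly_bimodal_lowest_tie_break(self):
        assert otsu_threshold(np.array([0, 0, 0, 255, 255, 255])) == 1

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(np.full((8, 8), 7))

    @given(st.integers(0, 2**31 - 1), st.integers(4, 400))
    def test_matches_bruteforce_on_random_arrays(self, seed, size):
        rng = np.random.default_rng(seed)
        kind = seed % 3
        if kind == 0:
            arr = rng.integers(0, 256, size)
        elif kind == 1:  # bimodal
            arr = np.concatenate(
                [
                    rng.normal(60, 15, size // 2 + 1),
                    rng.normal(190, 20, size // 2 + 1),
                ]
            ).clip(0, 255).astype(int)
        else:  # sparse support, many ties
            arr = rng.choice([0, 3, 250, 255], size)
        if np.unique(arr).size < 2:
            arr = np.append(arr, [0, 255])
        assert otsu_threshold(arr) == brute_force_otsu(arr)

    def test_agrees_with_skimage_partition(self):
        rng = np.random.default_rng(5)
        arr = np.concatenate(
            [rng.normal(50, 10, 500), rng.normal(200, 10, 500)]
        ).clip(0, 255).astype(np.uint8)
        ours = otsu_threshold(arr)
        theirs = skimage_otsu(arr)
        # conventions differ (>= t vs > t) but the induced split must agree
        assert np.array_equal(arr >= ours, arr > theirs)

    def test_shift_invariance_below_saturation(self):
        rng = np.random.default_rng(6)
        arr = rng.integers(0, 100, 300)
        assert otsu_threshold(arr + 50) == otsu_threshold(arr) + 50


class TestSegmentation:
    def test_zero_noise_mask_is_exact(self):
        pair = generate_cell_image(
            "control", 0, seed=1, params=ImageParams(noise_sd=0.0)
        )
        mask = segment_cell(pair)
        assert np.array_equal(mask.mask, pair.true_mask)
        assert mask.area_px == int(pair.true_mask.sum())
        assert mask.source_channel == "CD4"

    def test_default_noise_high_overlap(self):
        pair = generate_cell_image("classical", 8, seed=2)
        mask = segment_cell(pair)
        inter = (mask.mask & pair.true_mask).sum()
        union = (mask.mask | pair.true_mask).sum()
        assert inter / union >= 0.9

    def test_largest_component_wins(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        yy, xx = np.mgrid[0:64, 0:64]
        big = np.hypot(yy - 20, xx - 20) <= 12
        small = np.hypot(yy - 50, xx - 50) <= 5
        img[big | small] = 200
        mask = segment_cell(img)
        assert mask.mask[20, 20] and not mask.mask[50, 50]
        assert mask.area_px == int(big.sum())

    def test_holes_are_filled(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        yy, xx = np.mgrid[0:64, 0:64]
        d = np.hypot(yy - 32, xx - 32)
        img[d <= 15] = 200
        img[d <= 4] = 0  # dark interior (a vacuole) must not punch a hole
        mask = segment_cell(img)
        assert mask.mask[32, 32]


class TestQuantify:
    def test_uniform_lamp_is_a_step_curve(self):
        cd4 = np.full((8, 8), 200, dtype=np.uint8)
        lamp = np.full((8, 8), 100, dtype=np.uint8)
        pair = make_pair(cd4, lamp)
        mask = CellMask(np.ones((8, 8), bool), 64, otsu_threshold=1)
        quant, curve = quantify_cell(pair, mask)
        assert quant.mean_lamp1 == 100.0
        assert (curve.pct_at_level[: 101] == 100.0).all()
        assert (curve.pct_at_level[101:] == 0.0).all()

    def test_four_pixel_hand_computed_example(self):
        lamp = np.array([[0, 50], [100, 150]], dtype=np.uint8)
        pair = make_pair(np.full((2, 2), 9), lamp)
        mask = CellMask(np.ones((2, 2), bool), 4, otsu_threshold=1)
        quant, curve = quantify_cell(pair, mask)
        assert quant.mean_lamp1 == 75.0
        assert curve.pct_at_level[50] == 75.0
        assert curve.pct_at_level[101] == 25.0
        assert curve.pct_at_level[0] == 100.0

    def test_empty_mask_and_shape_mismatch_rejected(self):
        pair = make_pair(np.zeros((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValueError, match="empty mask"):
            quantify_cell(pair, CellMask(np.zeros((4, 4), bool), 0, 1))
        with pytest.raises(ValueError, match="shape mismatch"):
            quantify_cell(pair, CellMask(np.ones((5, 5), bool), 25, 1))

    def test_curve_invariants_and_mean_identity_on_generated_cells(self):
        """pct_at_level[0] = 100, the curve is non-increasing, and
        sum(pct[1:])/100 equals the mean exactly (each pixel of intensity v
        contributes to exactly v levels >= 1)."""
        for j, cls in enumerate(["control", "classical", "protracted"]):
            pair = generate_cell_image(cls, 4 * j, seed=100 + j)
            mask = segment_cell(pair)
            quant, curve = quantify_cell(pair, mask)
            assert curve.pct_at_level[0] == 100.0
            assert (np.diff(curve.pct_at_level) <= 0).all()
            assert curve.pct_at_level.min() >= 0.0
            assert abs(
                curve.pct_at_level[1:].sum() / 100.0 - quant.mean_lamp1
            ) < 1e-9


class TestBandsAndComparison:
    def _curves(self, n, cls="classical", vac=8, seed0=0):
        out = []
        for j in range(n):
            pair = generate_cell_image(cls, vac, seed=seed0 + j)
            out.append(quantify_cell(pair, segment_cell(pair))[1])
        return out

    def test_single_curve_bands_collapse_to_it(self):
        curve = self._curves(1)[0]
        bands = population_bands([curve])
        for arr in (bands.median, bands.q25, bands.q75, bands.p2_5, bands.p97_5):
            assert np.allclose(arr, curve.pct_at_level)

    def test_identical_curves_zero_width(self):
        curve = self._curves(1)[0]
        bands = population_bands([curve] * 7)
        assert np.allclose(bands.p97_5 - bands.p2_5, 0.0)

    def test_band_ordering_invariant(self):
        bands = population_bands(self._curves(12))
        assert (bands.p2_5 <= bands.q25 + 1e-12).all()
        assert (bands.q25 <= bands.median + 1e-12).all()
        assert (bands.median <= bands.q75 + 1e-12).all()
        assert (bands.q75 <= bands.p97_5 + 1e-12).all()

    def test_empty_curve_list_rejected(self):
        with pytest.raises(ValueError):
            population_bands([])

    def test_deciles_on_known_means(self):
        from vacuoquant.imaging import CellQuant

        quants = [CellQuant(str(i), float(i), 10) for i in range(1, 11)]
        row = compare_classes({"demo": quants}).iloc[0]
        expected = [1.9, 2.8, 3.7, 4.6, 5.5, 6.4, 7.3, 8.2, 9.1]
        got = [row[f"p{d}"] for d in range(10, 100, 10)]
        assert got == pytest.approx(expected)
        assert row["mean_of_means"] == pytest.approx(5.5)

    def test_single_cell_deciles_equal_its_mean(self):
        from vacuoquant.imaging import CellQuant

        row = compare_classes({"demo": [CellQuant("c", 42.0, 5)]}).iloc[0]
        assert all(row[f"p{d}"] == 42.0 for d in range(10, 100, 10))

    def test_classical_mean_of_means_exceeds_control(self):
        control = [
            quantify_cell(p, segment_cell(p))[0]
            for p in (generate_cell_image("control", 0, seed=j) for j in range(15))
        ]
        classical = [
            quantify_cell(p, segment_cell(p))[0]
            for p in (
                generate_cell_image("classical", 10, seed=j) for j in range(15)
            )
        ]
        df = compare_classes({"control": control, "classical": classical})
        means = df.set_index("class")["mean_of_means"]
        assert means["classical"] > means["control"]
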