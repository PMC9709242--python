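"""Mitochondrial pipelines: preprocessing, detection, the 7-px size rule,
point counting, and the red:green ratio with its preset contrasts."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from spermaquant.core import ChannelStack, Image2D, LabelMap
from spermaquant.mitochondria import (MitoParams, count_mitochondria_per_cell,
                                      detect_mitochondria, find_maxima,
                                      jc1_ratio, measure_mitochondria,
                                      preprocess_mito, size_filter)
from spermaquant.synth import SynthesisConfig, synth_jc1_field


def _blob_image(centers, sigma=2.0, amp=200.0, shape=(160, 160), bg=5.0):
    img = np.full(shape, bg)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for r, c in centers:
        img += amp * np.exp(-0.5 * ((rr - r) ** 2 + (cc - c) ** 2) / sigma ** 2)
    return img


class TestSizeFilter:
    def test_seven_pixel_rule_keeps_exactly_the_two_larger_components(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[1, 1:4] = True              # 3 px
        mask[5, 5:12] = True             # 7 px
        mask[10:13, 20:24] = True        # 12 px
        out = size_filter(mask, min_size_px=7)
        n = ndi.label(out, structure=np.ones((3, 3)))[1]
        assert n == 2
        assert not out[1, 1]

    def test_no_surviving_component_is_below_the_cutoff(self, rng):
        mask = rng.uniform(size=(128, 128)) > 0.75
        out = size_filter(mask, min_size_px=7)
        lab, n = ndi.label(out, structure=np.ones((3, 3)))
        if n:
            assert np.bincount(lab.ravel())[1:].min() >= 7


class TestPreprocess:
    def test_linear_gradient_background_is_flattened(self):
        rows = np.linspace(0, 40, 128)
        img = np.broadcast_to(rows[:, None], (128, 128)).copy() + 10
        out = preprocess_mito(Image2D(img), MitoParams(clahe_kernel_px=32)).pixels
        # fit a plane: residual slope should be well under the input's
        slope_in = np.polyfit(np.arange(128), img.mean(axis=1), 1)[0]
        slope_out = np.polyfit(np.arange(128), out.mean(axis=1), 1)[0]
        assert abs(slope_out) < 0.1 * abs(slope_in)

    def test_blob_signal_survives_background_subtraction(self):
        img = _blob_image([(80, 80)], sigma=3.0, amp=300.0, bg=0.0)
        params = MitoParams(clahe_kernel_px=32)
        out = preprocess_mito(Image2D(img), params).pixels
        mask = img > 30
        assert out[mask].sum() >= 0.5 * img[mask].sum()
        assert np.all(np.isfinite(out)) and out.min() >= 0

    def test_tile_larger_than_image_raises(self):
        with pytest.raises(ValueError, match="tile"):
            preprocess_mito(Image2D(np.zeros((32, 32))), MitoParams(clahe_kernel_px=64))


class TestDetection:
    def test_blank_field_detects_nothing(self):
        assert detect_mitochondria(Image2D(np.zeros((64, 64)))).n_objects == 0
        noise = Image2D(np.abs(np.random.default_rng(0).normal(5, 1, (64, 64))))
        assert detect_mitochondria(noise).n_objects <= 2

    def test_isolated_blobs_are_each_detected_once(self):
        centers = [(30, 30), (30, 120), (120, 30), (120, 120), (75, 75)]
        img = Image2D(_blob_image(centers))
        det = detect_mitochondria(img, intensity=img)
        assert det.n_objects == len(centers)

    def test_round_blob_aspect_ratio_is_near_unity(self):
        cfg = SynthesisConfig(seed=5, image_size=(512, 512), n_cells=9,
                              jc1_cell_radius_px=(18.0, 0.5), mito_per_cell=(2.0, 0.0),
                              mito_elongation=(1.0, 0.0), mito_radius_px=(3.0, 0.0))
        stack, truth = synth_jc1_field(cfg)
        params = MitoParams()
        det = detect_mitochondria(preprocess_mito(stack["red"], params), params,
                                  intensity=stack["red"])
        table = measure_mitochondria(det, image=stack["red"])
        assert len(table) == len(truth.mitochondria)
        assert table["aspect_ratio"].mean() <= 1.10

    def test_elongated_blob_aspect_ratio_recovers_truth(self):
        cfg = SynthesisConfig(seed=5, image_size=(512, 512), n_cells=9,
                              jc1_cell_radius_px=(20.0, 0.5), mito_per_cell=(1.0, 0.0),
                              mito_elongation=(3.0, 0.0), mito_radius_px=(2.0, 0.0))
        stack, truth = synth_jc1_field(cfg)
        params = MitoParams()
        det = detect_mitochondria(preprocess_mito(stack["red"], params), params,
                                  intensity=stack["red"])
        table = measure_mitochondria(det, image=stack["red"])
        assert len(table) == len(truth.mitochondria)
        assert 2.5 <= table["aspect_ratio"].mean() <= 3.5

    def test_green_excess_recovers_low_mmp_fraction(self):
        cfg = SynthesisConfig(seed=7, image_size=(640, 640), n_cells=16,
                              jc1_cell_radius_px=(16.0, 0.5), mito_per_cell=(3.0, 0.0),
                              mito_elongation=(1.2, 0.1), mito_radius_px=(2.2, 0.1),
                              low_mmp_fraction=0.3)
        stack, truth = synth_jc1_field(cfg)
        params = MitoParams()
        n = {}
        for role in ("green", "red"):
            det = detect_mitochondria(preprocess_mito(stack[role], params), params,
                                      intensity=stack[role])
            n[role] = det.n_objects
        excess = n["green"] - n["red"]
        configured = int(truth.mitochondria["low_mmp"].sum())
        assert excess == pytest.approx(configured, rel=0.20, abs=2)


class TestFindMaxima:
    def test_plateau_with_two_equal_maxima_merges_to_one_point(self):
        img = np.zeros((32, 32))
        img[10:14, 10:18] = 100.0        # flat plateau
        mask = img > 0
        points = find_maxima(img, mask, tolerance=5.0)
        assert len(points) == 1

    def test_two_well_separated_peaks_stay_distinct(self):
        img = _blob_image([(10, 10), (10, 40)], sigma=2.0, shape=(50, 50), bg=0.0)
        points = find_maxima(img, img > 1.0, tolerance=5.0)
        assert len(points) == 2

    def test_oracle_brute_force_agreement_on_random_fields(self, rng):
        """Every accepted maximum must not be reachable from a higher one
        through pixels above (its value - tolerance) — checked by flooding."""
        img = ndi.gaussian_filter(rng.uniform(0, 100, (48, 48)), 2.0)
        mask = np.ones_like(img, dtype=bool)
        tol = 5.0
        points = find_maxima(img, mask, tolerance=tol)
        assert len(points) >= 1
        for r, c in points:
            flood = img >= img[r, c] - tol
            lab, _ = ndi.label(flood, structure=np.ones((3, 3)))
            region = lab == lab[r, c]
            higher = [(r2, c2) for r2, c2 in points
                      if (r2, c2) != (r, c) and region[r2, c2] and img[r2, c2] > img[r, c]]
            assert not higher


class TestCounting:
    def _cells_two(self):
        cells = np.zeros((160, 160), dtype=np.int32)
        cells[10:80, 10:150] = 1
        cells[90:150, 10:150] = 2
        return LabelMap(cells, 2)

    def test_five_isolated_blobs_in_one_cell_count_five(self):
        centers = [(30, 30), (30, 70), (30, 110), (60, 50), (60, 90)]
        img = Image2D(_blob_image(centers))
        det = detect_mitochondria(img, intensity=img)
        counts = count_mitochondria_per_cell(det, self._cells_two(), image=img)
        assert counts[1] == 5 and counts[2] == 0

    def test_two_cells_with_three_and_four_blobs(self):
        top = [(30, 30), (30, 80), (30, 130)]
        bottom = [(120, 30), (120, 70), (120, 110), (120, 150 - 10)]
        img = Image2D(_blob_image(top + bottom))
        det = detect_mitochondria(img, intensity=img)
        counts = count_mitochondria_per_cell(det, self._cells_two(), image=img)
        assert counts[1] == 3 and counts[2] == 4

    def test_counts_conserve_total_detections(self, jc1_preset_stacks):
        stack, _ = jc1_preset_stacks["wt-jc1"]
        from spermaquant.segmentation import segment_jc1_cells
        cells = segment_jc1_cells(stack)
        params = MitoParams()
        pre = preprocess_mito(stack["red"], params)
        det = detect_mitochondria(pre, params, intensity=stack["red"])
        counts = count_mitochondria_per_cell(det, cells, image=pre, params=params)
        assert sum(counts.values()) == det.n_objects

    def test_geometry_mismatch_raises(self):
        det = LabelMap(np.zeros((32, 32), dtype=np.int32), 0)
        cells = LabelMap(np.zeros((64, 64), dtype=np.int32), 0)
        with pytest.raises(ValueError, match="geometry"):
            count_mitochondria_per_cell(det, cells)


class TestJc1Ratio:
    def _stack(self, red, green):
        return ChannelStack(channels={"red": Image2D(red), "green": Image2D(green)})

    def _one_cell(self, shape=(32, 32)):
        cells = np.zeros(shape, dtype=np.int32)
        cells[8:24, 8:24] = 1
        return LabelMap(cells, 1)

    def test_simple_totals_give_ratio_two(self):
        cells = self._one_cell()
        red = np.where(cells.labels == 1, 200.0 / 256, 0.0)
        green = np.where(cells.labels == 1, 100.0 / 256, 0.0)
        rec = jc1_ratio(self._stack(red, green), cells)[0]
        assert rec.red_green_ratio == pytest.approx(2.0)

    def test_zero_red_channel_gives_zero_ratios(self):
        cells = self._one_cell()
        green = np.where(cells.labels == 1, 3.0, 0.0)
        rec = jc1_ratio(self._stack(np.zeros((32, 32)), green), cells)[0]
        assert rec.red_green_ratio == 0.0 and rec.ratio_defined

    def test_zero_green_total_is_flagged_undefined_not_infinite(self):
        cells = self._one_cell()
        red = np.where(cells.labels == 1, 3.0, 0.0)
        rec = jc1_ratio(self._stack(red, np.zeros((32, 32))), cells)[0]
        assert not rec.ratio_defined and np.isnan(rec.red_green_ratio)

    def test_missing_channel_raises(self):
        with pytest.raises(ValueError, match="channel"):
            jc1_ratio(ChannelStack(channels={"red": Image2D(np.zeros((32, 32)))}),
                      self._one_cell())

    def test_mutant_ratio_spread_exceeds_wild_type_at_matched_mean(self, jc1_preset_stacks):
        """The mutant JC-1 preset encodes a wider membrane-potential spread
        at the same mean: the measured per-cell ratios must reproduce the
        greater-variance contrast with means within 10%."""
        from spermaquant.segmentation import segment_jc1_cells
        stats = {}
        for name in ("wt-jc1", "mut-jc1"):
            stack, _ = jc1_preset_stacks[name]
            cells = segment_jc1_cells(stack)
            ratios = np.array([r.red_green_ratio for r in jc1_ratio(stack, cells)
                               if r.ratio_defined])
            stats[name] = (ratios.mean(), ratios.var())
        assert stats["mut-jc1"][1] > stats["wt-jc1"][1]
        assert stats["mut-jc1"][0] == pytest.approx(stats["wt-jc1"][0], rel=0.10)


class TestPresetContrasts:
    def test_all_four_morphometry_contrasts_reproduce_published_directions(
            self, jc1_preset_stacks):
        """Mutant mitochondria must measure larger, longer, more elongated
        and less circular than wild-type — the four published directions."""
        from spermaquant.segmentation import segment_jc1_cells
        params = MitoParams()
        means = {}
        for name in ("wt-jc1", "mut-jc1"):
            stack, _ = jc1_preset_stacks[name]
            cells = segment_jc1_cells(stack)
            det = detect_mitochondria(preprocess_mito(stack["red"], params), params,
                                      intensity=stack["red"])
            table = measure_mitochondria(det, image=stack["red"], cells=cells)
            means[name] = table[["area_px", "aspect_ratio", "feret_px", "circularity"]].mean()
        wt, mut = means["wt-jc1"], means["mut-jc1"]
        assert mut["area_px"] > wt["area_px"]
        assert mut["aspect_ratio"] > wt["aspect_ratio"]
        assert mut["feret_px"] > wt["feret_px"]
        assert mut["circularity"] < wt["circularity"]
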