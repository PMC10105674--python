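"""Per-cell immunolabel quantification: background subtraction, whole-cell
and linear (zonal) methods, redistribution ratio, line profiles."""

import numpy as np
import pytest
from pydantic import ValidationError

from icmq import intensity
from icmq.geometry import GeometryError
from icmq.synthetic import SynthImageTruth, synth_micrograph
from icmq.types import CellAnnotation, Micrograph

from conftest import rect


class TestMeanBackground:
    def test_uniform_image_returns_its_value(self, flat_image):
        assert intensity.mean_background(flat_image, rect(2, 2, 8, 8)) == 50.0

    def test_two_pixel_roi_arithmetic_mean(self):
        img = Micrograph(pixels=np.array([[10.0, 20.0]]), bit_depth=8)
        assert intensity.mean_background(img, rect(0, 0, 2, 1)) == 15.0

    def test_empty_roi_is_an_error(self, flat_image):
        with pytest.raises(GeometryError):
            intensity.mean_background(flat_image, rect(100, 100, 104, 104))


class TestNetPixelIntensity:
    def test_image_at_background_gives_zeros(self, flat_image):
        assert not intensity.net_pixel_intensity(flat_image, 50.0).any()

    def test_brightfield_polarity_darker_is_positive(self):
        img = Micrograph(pixels=np.full((2, 2), 30.0))
        assert intensity.net_pixel_intensity(img, 50.0)[0, 0] == 20.0

    def test_clip_rule_for_pixels_brighter_than_background(self):
        img = Micrograph(pixels=np.full((2, 2), 60.0))
        assert intensity.net_pixel_intensity(img, 50.0)[0, 0] == 0.0
        assert intensity.net_pixel_intensity(img, 50.0, clip_negative=False)[0, 0] == -10.0

    def test_fluorescence_polarity_brighter_is_positive(self):
        img = Micrograph(pixels=np.full((2, 2), 60.0), polarity="fluorescence_bright_label")
        assert intensity.net_pixel_intensity(img, 50.0)[0, 0] == 10.0


class TestWholeCell:
    def test_hand_enumerated_3x3_cell(self, cell_3x3):
        # 3x3 cell at 20 against background 50 -> net 30/px; 1-px nucleus
        img = Micrograph(pixels=np.full((8, 8), 20.0))
        res = intensity.whole_cell_label(img, cell_3x3, 50.0)
        assert res.cell_area_px == 9
        assert res.nuclear_area_px == 1
        assert res.cytoplasmic_area_px == 8
        assert res.net_label_cell == 270.0
        assert res.net_label_cytoplasm == 240.0

    def test_image_at_background_gives_zero_label(self, cell_3x3, flat_image):
        res = intensity.whole_cell_label(flat_image, cell_3x3, 50.0)
        assert res.net_label_cytoplasm == 0.0

    def test_nucleus_overlapping_cell_edge_rejected_at_annotation(self):
        with pytest.raises(ValidationError, match="nucleus"):
            CellAnnotation(
                cell_id="bad",
                polygon=rect(1, 1, 4, 4),
                nucleus=rect(3, 3, 6, 6),
                axis=((2.5, 1.0), (2.5, 4.0)),
            )


class TestLinearMethod:
    @pytest.mark.parametrize("n_zones", [1, 3, 7, 10])
    def test_zones_partition_the_whole_cell_sum_exactly(self, cell_3x3, n_zones):
        rng = np.random.default_rng(4)
        img = Micrograph(pixels=rng.uniform(10, 50, (8, 8)))
        zones, total = intensity.linear_cell_label(img, cell_3x3, 50.0, n_zones)
        assert len(zones) == n_zones
        assert zones.sum() == pytest.approx(total, rel=0, abs=1e-9)
        whole = intensity.whole_cell_label(img, cell_3x3, 50.0)
        assert total == pytest.approx(whole.net_label_cell)

    def test_uniform_label_spreads_evenly_over_zones(self):
        scene = synth_micrograph(SynthImageTruth(gradient_shape="uniform", noise_sd=0.0))
        zones, total = intensity.linear_cell_label(scene.image, scene.annotation, 200.0, 10)
        assert np.allclose(zones / total, 0.1, atol=0.01)

    def test_linear_gradient_zone_sums_decrease_from_apex(self):
        scene = synth_micrograph(SynthImageTruth(gradient_shape="linear", noise_sd=0.0))
        zones, _ = intensity.linear_cell_label(scene.image, scene.annotation, 200.0, 10)
        assert np.all(np.diff(zones) < 0)
        # fine-grid integration oracle: zone k of a (1 - t) profile
        t = (np.arange(10) + 0.5) / 10
        expect = (1 - t) / (1 - t).sum()
        assert np.allclose(zones / zones.sum(), expect, atol=0.01)


class TestRedistributionRatio:
    def test_uniform_label_gives_the_band_fraction(self):
        scene = synth_micrograph(SynthImageTruth(gradient_shape="uniform", noise_sd=0.0))
        r = intensity.redistribution_ratio(scene.image, scene.annotation, 200.0)
        assert r == pytest.approx(0.10, abs=0.02)

    def test_all_label_in_apical_band_gives_one(self, cell_3x3):
        img = np.full((8, 8), 50.0)
        img[1, 1:4] = 20.0  # only the most apical pixel row is labeled
        r = intensity.redistribution_ratio(
            Micrograph(pixels=img), cell_3x3, 50.0, fraction=0.34
        )
        assert r == 1.0

    def test_linear_gradient_matches_analytic_integral(self):
        scene = synth_micrograph(SynthImageTruth(gradient_shape="linear", noise_sd=0.0))
        r = intensity.redistribution_ratio(scene.image, scene.annotation, 200.0)
        assert r == pytest.approx(1 - 0.9**2, abs=0.02)

    def test_zero_label_is_undefined(self, cell_3x3, flat_image):
        with pytest.raises(ValueError, match="undefined"):
            intensity.redistribution_ratio(flat_image, cell_3x3, 50.0)

    def test_area_band_agrees_with_height_band_on_a_rectangle(self):
        scene = synth_micrograph(SynthImageTruth(gradient_shape="linear", noise_sd=0.0))
        rh = intensity.redistribution_ratio(scene.image, scene.annotation, 200.0, band="height")
        ra = intensity.redistribution_ratio(scene.image, scene.annotation, 200.0, band="area")
        assert ra == pytest.approx(rh, abs=0.02)


class TestLineProfile:
    def test_constant_image_gives_zero_profile(self, flat_image):
        prof = intensity.line_profile(flat_image, ((1.0, 1.0), (1.0, 8.0)), 50.0)
        assert np.allclose(prof, 0.0)

    def test_step_image_localizes_the_change_point(self):
        img = np.full((20, 8), 50.0)
        img[:10] = 30.0  # dark (labeled) apical half
        prof = intensity.line_profile(Micrograph(pixels=img), ((4.0, 0.5), (4.0, 19.5)), 50.0)
        assert np.all(prof[:10] == 20.0)
        assert np.all(prof[10:] == 0.0)

    def test_sample_count_contract(self, flat_image):
        prof = intensity.line_profile(flat_image, ((0.5, 0.5), (7.7, 5.9)), 50.0)
        length = np.hypot(7.2, 5.4)
        assert len(prof) == int(np.ceil(length)) + 1

    def test_line_outside_frame_is_an_error(self, flat_image):
        with pytest.raises(GeometryError):
            intensity.line_profile(flat_image, ((50.0, 50.0), (60.0, 60.0)), 50.0)


class TestCellHeight:
    def test_vertical_axis(self):
        ann = CellAnnotation(
            cell_id="c",
            polygon=rect(0, 0, 10, 10),
            nucleus=rect(4, 4, 6, 6),
            axis=((5.0, 0.0), (5.0, 10.0)),
        )
        assert intensity.cell_height(ann) == 10.0

    def test_3_4_5_triangle(self):
        ann = CellAnnotation(
            cell_id="c",
            polygon=rect(0, 0, 10, 10),
            nucleus=rect(4, 4, 6, 6),
            axis=((0.0, 0.0), (3.0, 4.0)),
        )
        assert intensity.cell_height(ann) == 5.0

    def test_degenerate_axis_rejected_at_annotation(self):
        with pytest.raises(ValidationError, match="axis"):
            CellAnnotation(
                cell_id="c",
                polygon=rect(0, 0, 10, 10),
                nucleus=rect(4, 4, 6, 6),
                axis=((5.0, 5.0), (5.0, 5.0)),
            )


def test_polarity_symmetry_leaves_every_result_unchanged():
    """Inverting the image and flipping the polarity flag is a no-op."""
    scene = synth_micrograph(SynthImageTruth(gradient_shape="linear", noise_sd=3.0, seed=9))
    bg = intensity.mean_background(scene.image, scene.background_roi)
    res = intensity.quantify_cell(scene.image, scene.annotation, bg)
    inverted = Micrograph(
        pixels=255.0 - scene.image.pixels,
        bit_depth=scene.image.bit_depth,
        polarity="fluorescence_bright_label",
    )
    res_inv = intensity.quantify_cell(inverted, scene.annotation, 255.0 - bg)
    assert res_inv.net_label_cytoplasm == pytest.approx(res.net_label_cytoplasm)
    assert res_inv.redistribution_ratio == pytest.approx(res.redistribution_ratio)
    assert np.allclose(res_inv.zonal_profile, res.zonal_profile)
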