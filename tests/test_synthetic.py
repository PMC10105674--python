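"""Synthetic generators: determinism, closed-form ground truth, and the
moment structure the recovery tests rely on."""

import numpy as np
import pytest
from pydantic import ValidationError

from icmq import synthetic
from icmq.blots import lanes_to_frame, relative_to_control
from icmq.synthetic import (
    SynthGoldTruth,
    SynthImageTruth,
    SynthPerfusionTruth,
    synth_blot,
    synth_gold_cell,
    synth_micrograph,
    synth_perfusion,
)


class TestMicrograph:
    def test_same_seed_is_bit_identical(self):
        t = SynthImageTruth(noise_sd=5.0, seed=11)
        a, b = synth_micrograph(t), synth_micrograph(t)
        assert np.array_equal(a.image.pixels, b.image.pixels)
        assert a.annotation == b.annotation

    def test_uniform_shape_truth_is_the_band_fraction(self):
        t = SynthImageTruth(gradient_shape="uniform", apical_fraction=0.10)
        assert t.apical_fraction_true == 0.10

    def test_linear_shape_truth_is_the_analytic_integral(self):
        t = SynthImageTruth(gradient_shape="linear", apical_fraction=0.10)
        assert t.apical_fraction_true == pytest.approx(1 - 0.9**2, abs=1e-12)
        # fine-grid numerical integration oracle
        s = np.linspace(0, 1, 200_001)
        dens = 1 - s
        numeric = np.trapezoid(dens[s <= 0.10], s[s <= 0.10]) / np.trapezoid(dens, s)
        assert t.apical_fraction_true == pytest.approx(numeric, abs=1e-4)

    def test_exponential_shape_truth_matches_numerical_integration(self):
        t = SynthImageTruth(gradient_shape="exponential", shape_param=0.25)
        s = np.linspace(0, 1, 200_001)
        dens = np.exp(-s / 0.25)
        numeric = np.trapezoid(dens[s <= 0.10], s[s <= 0.10]) / np.trapezoid(dens, s)
        assert t.apical_fraction_true == pytest.approx(numeric, abs=1e-4)

    def test_zero_label_zero_noise_is_flat_background(self):
        scene = synth_micrograph(SynthImageTruth(label_total=0.0, noise_sd=0.0))
        assert np.all(scene.image.pixels == 200.0)

    def test_noiseless_cytoplasmic_label_integrates_to_label_total(self):
        from icmq import intensity

        t = SynthImageTruth(gradient_shape="linear", noise_sd=0.0)
        scene = synth_micrograph(t)
        res = intensity.whole_cell_label(scene.image, scene.annotation, 200.0)
        assert res.net_label_cytoplasm == pytest.approx(t.label_total, rel=1e-9)

    def test_label_darker_than_background(self):
        scene = synth_micrograph(SynthImageTruth(noise_sd=0.0))
        from icmq.geometry import polygon_mask

        mask = polygon_mask(scene.annotation.polygon, scene.image.shape)
        assert scene.image.pixels[mask].max() < 200.0

    def test_cell_outside_frame_rejected(self):
        with pytest.raises(ValidationError, match="frame"):
            SynthImageTruth(image_shape=(64, 64), cell_rect=(10, 10, 100, 60))

    def test_label_exceeding_dynamic_range_rejected(self):
        with pytest.raises(ValueError, match="dynamic range"):
            synth_micrograph(SynthImageTruth(label_total=1e7))


class TestGoldCell:
    def test_same_seed_gives_identical_point_pattern(self):
        t = SynthGoldTruth(seed=5)
        assert synth_gold_cell(t).record == synth_gold_cell(t).record

    def test_zero_membrane_rate_gives_zero_membrane_particles(self):
        cell = synth_gold_cell(SynthGoldTruth(lambda_membrane=0.0, seed=1))
        assert cell.true_membrane_count == 0

    def test_membrane_counts_match_poisson_mean_over_500_seeds(self):
        t0 = SynthGoldTruth()
        counts = [
            synth_gold_cell(SynthGoldTruth(seed=s)).true_membrane_count for s in range(500)
        ]
        lam = t0.lambda_membrane * synth_gold_cell(t0).boundary_length_um
        se = np.sqrt(lam / 500)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(ValidationError):
            SynthGoldTruth(apical_polyline=[(5.0, 5.0), (5.0, 5.0)])

    def test_particle_counts_are_recorded_consistently(self):
        cell = synth_gold_cell(SynthGoldTruth(seed=17))
        assert len(cell.record.particles) == cell.true_membrane_count + cell.true_cytoplasm_count


class TestPerfusion:
    def test_zero_flux_zero_noise_collected_equals_perfusate(self):
        sim = synth_perfusion(SynthPerfusionTruth(J_true=0.0, cv_noise=0.0))
        assert sim.record.collections[0].collected_F == sim.record.perfusate_F

    def test_flux_formula_arithmetic(self):
        # J = 20, L = 1 mm, Vdot = 2 nl/min -> collected 10 mM below perfusate
        sim = synth_perfusion(
            SynthPerfusionTruth(J_true=20.0, tubule_length=1.0, collection_rate=2.0, cv_noise=0.0)
        )
        assert sim.collected_cl_true == pytest.approx(sim.truth.C_perfusate - 10.0)

    def test_same_seed_gives_identical_record(self):
        t = SynthPerfusionTruth(seed=3)
        assert synth_perfusion(t).record == synth_perfusion(t).record

    def test_standards_span_zero_to_beyond_perfusate(self):
        sim = synth_perfusion(SynthPerfusionTruth(cv_noise=0.0))
        levels = [c for c, _ in sim.record.standards]
        assert levels[0] == 0.0
        assert max(levels) >= sim.truth.C_perfusate

    def test_negative_collected_concentration_rejected(self):
        with pytest.raises(ValidationError):
            SynthPerfusionTruth(J_true=300.0, tubule_length=1.0, collection_rate=2.0)


class TestBlot:
    def test_no_noise_normalized_equals_abundance_up_to_constant(self):
        lanes, _ = synth_blot({"a": [1.0, 2.0], "b": [0.5]}, loading_cv=0.0, density_cv=0.0)
        norm = lanes_to_frame(lanes)["normalized_density"].to_numpy()
        assert np.allclose(norm / norm[0], [1.0, 2.0, 0.5])

    def test_equal_abundances_give_unit_group_ratio(self):
        lanes, _ = synth_blot({"a": [2.0] * 4, "b": [2.0] * 4}, loading_cv=0.3, density_cv=0.0, seed=2)
        rel = relative_to_control(lanes, "a")
        assert rel.groupby("group")["relative_density"].mean().to_numpy() == pytest.approx([1.0, 1.0])

    def test_same_seed_is_identical(self):
        a, _ = synth_blot({"a": [1.0] * 3}, seed=9)
        b, _ = synth_blot({"a": [1.0] * 3}, seed=9)
        assert a == b

    def test_half_abundance_ratio_recovered_within_2_se_over_200_seeds(self):
        ratios = []
        for seed in range(200):
            lanes, _ = synth_blot(
                {"ctrl": [1.0] * 6, "mut": [0.5] * 6}, loading_cv=0.2, seed=seed
            )
            rel = relative_to_control(lanes, "ctrl")
            ratios.append(rel.groupby("group")["relative_density"].mean()["mut"])
        ratios = np.asarray(ratios)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 0.5) < 2 * se + 1e-12

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            synth_blot({"a": [-1.0]})
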