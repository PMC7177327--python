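"""Generators: reproducibility, planted structure, infeasible configurations."""

import math

import numpy as np
import pytest

from perimir import synthdata
from perimir.synthdata import (ImageGeom, QpcrConfig, Scenario,
                               TranscriptomeConfig)
from perimir.targets import seed_site_6mer


class TestScenarioValidation:
    def test_infeasible_transcriptome_counts(self):
        with pytest.raises(ValueError, match="infeasible"):
            TranscriptomeConfig(n_genes=10, n_target_genes=12, n_up_sig=3,
                                n_down_sig=2, n_up_targets=1, n_down_targets=1)
        with pytest.raises(ValueError, match="infeasible"):
            TranscriptomeConfig(n_genes=10, n_target_genes=4, n_up_sig=3,
                                n_down_sig=2, n_up_targets=4, n_down_targets=1)

    def test_non_positive_ratios_rejected(self):
        with pytest.raises(ValueError):
            Scenario(name="x", rng_seed=1, layer_effect=0.0)
        with pytest.raises(ValueError):
            Scenario(name="x", rng_seed=1, group_scale={"TBI": -0.5})
        with pytest.raises(ValueError):
            QpcrConfig(n_case=3, n_control=3, planted_fc=0.0, ct_sd=0.3)

    def test_background_gray_bounds(self):
        with pytest.raises(ValueError):
            ImageGeom(width_um=100, depth_um=100, microns_per_pixel=2,
                      background_gray=1.2)


class TestIshSceneGeneration:
    def test_truth_within_bounds(self, small_scene_scenario):
        scene = synthdata.generate_ish_scene(small_scene_scenario, 0)
        sc = small_scene_scenario
        assert len(scene.truth) == sc.n_cells_per_subject
        assert (scene.truth.x_um.between(0, sc.image_geom.width_um)).all()
        assert (scene.truth.depth_um.between(0, sc.image_geom.depth_um)).all()
        assert (scene.truth.planted_gray
                < sc.image_geom.background_gray).all()

    def test_bit_reproducible_under_fixed_seed(self, small_scene_scenario):
        a = synthdata.generate_ish_scene(small_scene_scenario, 1)
        b = synthdata.generate_ish_scene(small_scene_scenario, 1)
        assert np.array_equal(a.image, b.image)
        assert a.truth.equals(b.truth)

    def test_subjects_have_independent_streams(self, small_scene_scenario):
        a = synthdata.generate_ish_scene(small_scene_scenario, 0)
        b = synthdata.generate_ish_scene(small_scene_scenario, 1)
        assert not np.array_equal(a.image, b.image)

    def test_layer_effect_recovered_in_planted_signal(self):
        sc = Scenario(
            name="layers", rng_seed=5,
            image_geom=ImageGeom(width_um=1000, depth_um=800,
                                 microns_per_pixel=2),
            groups=[{"group_label": "naive", "n_subjects": 1}],
            layer_effect=1.9, group_scale={"naive": 1.0},
            n_cells_per_subject=400, cell_radius_um=8.0)
        truth = synthdata.generate_ish_scene(sc, 0).truth
        deep = truth.loc[truth.layer == "deep", "planted_signal"].mean()
        sup = truth.loc[truth.layer == "superficial", "planted_signal"].mean()
        assert deep / sup == pytest.approx(1.9, abs=0.15)

    def test_identity_case_no_layer_difference(self):
        sc = Scenario(
            name="flat", rng_seed=5,
            image_geom=ImageGeom(width_um=1000, depth_um=800,
                                 microns_per_pixel=2),
            groups=[{"group_label": "naive", "n_subjects": 1}],
            layer_effect=1.0, group_scale={"naive": 1.0},
            n_cells_per_subject=400, cell_radius_um=8.0)
        truth = synthdata.generate_ish_scene(sc, 0).truth
        deep = truth.loc[truth.layer == "deep", "planted_signal"].mean()
        sup = truth.loc[truth.layer == "superficial", "planted_signal"].mean()
        assert deep / sup == pytest.approx(1.0, abs=0.1)

    def test_placement_failure_is_explicit(self):
        sc = Scenario(
            name="crowded", rng_seed=5,
            image_geom=ImageGeom(width_um=60, depth_um=60,
                                 microns_per_pixel=2),
            groups=[{"group_label": "naive", "n_subjects": 1}],
            n_cells_per_subject=50, cell_radius_um=8.0)
        with pytest.raises(RuntimeError, match="non-overlapping"):
            synthdata.generate_ish_scene(sc, 0)

    def test_subject_index_bounds(self, small_scene_scenario):
        with pytest.raises(ValueError, match="out of range"):
            synthdata.generate_ish_scene(small_scene_scenario, 99)


class TestCtGeneration:
    def test_unit_fold_change_gives_equal_dct(self, qpcr_scenario):
        sc = qpcr_scenario(planted_fc=1.0, ct_sd=0.0)
        ct = synthdata.generate_ct_table(sc, "assay")
        dct = ct.pivot_table(index=["sample_id", "group_label"],
                             columns="assay", values="ct")
        dct = (dct["target"] - dct["reference"]).groupby("group_label").mean()
        assert dct["TBI"] == pytest.approx(dct["sham"])

    @pytest.mark.parametrize("fc,expected_ddct", [
        (0.13, -math.log2(0.13)),   # ~ +2.943
        (6.97, -math.log2(6.97)),   # ~ -2.801
    ])
    def test_planted_fc_sets_expected_ddct(self, qpcr_scenario, fc,
                                           expected_ddct):
        sc = qpcr_scenario(planted_fc=fc, ct_sd=0.0)
        ct = synthdata.generate_ct_table(sc, "assay")
        wide = ct.pivot_table(index=["sample_id", "group_label"],
                              columns="assay", values="ct").reset_index()
        wide["dct"] = wide["target"] - wide["reference"]
        means = wide.groupby("group_label")["dct"].mean()
        assert means["TBI"] - means["sham"] == pytest.approx(expected_ddct)

    def test_seeded_reproducibility(self, qpcr_scenario):
        sc = qpcr_scenario(planted_fc=0.5)
        a = synthdata.generate_ct_table(sc, "assay")
        b = synthdata.generate_ct_table(sc, "assay")
        assert a.equals(b)


class TestTranscriptomeGeneration:
    def test_non_targets_have_zero_seed_matches(
            self, toy_transcriptome_scenario, mirna):
        utrs, _, planted = synthdata.generate_transcriptome(
            toy_transcriptome_scenario, mirna)
        core = seed_site_6mer(mirna)
        for gid, seq in utrs.items():
            if gid in planted:
                assert core in seq
            else:
                assert core not in seq

    def test_zero_targets_scenario(self, mirna):
        sc = Scenario(name="none", rng_seed=2,
                      transcriptome=TranscriptomeConfig(
                          n_genes=8, n_target_genes=0, n_up_sig=2,
                          n_down_sig=2, n_up_targets=0, n_down_targets=0,
                          utr_len=50))
        utrs, _, planted = synthdata.generate_transcriptome(sc, mirna)
        assert planted == set()
        core = seed_site_6mer(mirna)
        assert all(core not in s for s in utrs.values())

    def test_de_counts_exact(self, toy_transcriptome_scenario, mirna):
        _, de, _ = synthdata.generate_transcriptome(
            toy_transcriptome_scenario, mirna)
        assert ((de.p < 0.05) & (de.log2fc > 0)).sum() == 3
        assert ((de.p < 0.05) & (de.log2fc < 0)).sum() == 2
        assert de.gene_id.is_unique
        assert ((de.p > 0) & (de.p <= 1)).all()

    def test_reproducible(self, toy_transcriptome_scenario, mirna):
        a = synthdata.generate_transcriptome(toy_transcriptome_scenario, mirna)
        b = synthdata.generate_transcriptome(toy_transcriptome_scenario, mirna)
        assert a[0] == b[0] and a[1].equals(b[1]) and a[2] == b[2]


class TestCorrelatedPairs:
    def test_rho_bounds(self, rng):
        with pytest.raises(ValueError):
            synthdata.generate_correlated_pairs(1.0, 10, rng)

    def test_zero_rho_independent(self, rng):
        from scipy.stats import spearmanr
        rs = [spearmanr(*synthdata.generate_correlated_pairs(0.0, 30, rng))[0]
              for _ in range(300)]
        assert abs(np.mean(rs)) < 0.04
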