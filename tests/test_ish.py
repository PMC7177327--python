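"""Cell detection, intensity normalization, sector geometry, group contrasts."""

import numpy as np
import pandas as pd
import pytest

from perimir import synthdata
from perimir.ish import (SectorLayout, assign_sectors, compare_regions,
                         deep_superficial_fc, detect_cells,
                         estimate_background, evaluate_detection,
                         group_contrast, normalized_intensity, quantify_scene,
                         sector_summary)
from perimir.pipeline import detection_threshold, scene_layout


@pytest.fixture
def layout():
    return SectorLayout(origin_x_um=0, width_um=1000, depth_min_um=0,
                        depth_max_um=800)


def cells_df(points, intensity=0.3):
    return pd.DataFrame([
        {"cell_id": i, "x_um": x, "depth_um": d, "area_um2": 100.0,
         "mean_gray": 0.6, "sector": "none", "norm_intensity": intensity}
        for i, (x, d) in enumerate(points)])


class TestNormalizedIntensity:
    @pytest.mark.parametrize("cell,bg,expected", [
        (0.9, 0.9, 0.0),
        (0.4, 0.8, 0.5),
        (1.0, 0.8, -0.25),   # lighter than background: retained, negative
    ])
    def test_formula(self, cell, bg, expected):
        assert normalized_intensity(cell, bg) == pytest.approx(expected)

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            normalized_intensity(0.5, 0.0)

    def test_invariant_to_global_rescaling(self):
        cell, bg = 0.48, 0.84
        for c in (0.3, 0.7, 1.0):
            assert normalized_intensity(c * cell, c * bg) == pytest.approx(
                normalized_intensity(cell, bg))


class TestDetection:
    def test_planted_cells_recovered(self, small_scene_scenario):
        scene = synthdata.generate_ish_scene(small_scene_scenario, 0)
        thr = detection_threshold(small_scene_scenario)
        cells = detect_cells(scene.image, scene.microns_per_pixel, thr)
        assert len(cells) == len(scene.truth)
        metrics = evaluate_detection(cells, scene.truth,
                                     small_scene_scenario.cell_radius_um)
        assert metrics["recall"] == 1.0 and metrics["precision"] == 1.0

    def test_blank_image(self):
        img = np.full((50, 50), 0.9)
        assert len(detect_cells(img, 2.0, 0.5)) == 0

    def test_min_area_filter_removes_all(self, small_scene_scenario):
        scene = synthdata.generate_ish_scene(small_scene_scenario, 0)
        thr = detection_threshold(small_scene_scenario)
        cells = detect_cells(scene.image, scene.microns_per_pixel, thr,
                             min_area_um2=5000.0)
        assert len(cells) == 0

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            detect_cells(np.full((10, 10), 0.5), 2.0, 1.5)
        with pytest.raises(ValueError):
            detect_cells(np.empty((0, 0)), 2.0, 0.5)

    def test_background_estimate_matches_planted(self, small_scene_scenario):
        scene = synthdata.generate_ish_scene(small_scene_scenario, 0)
        thr = detection_threshold(small_scene_scenario)
        bg = estimate_background(scene.image, thr)
        assert bg == pytest.approx(
            small_scene_scenario.image_geom.background_gray, abs=0.005)


class TestSectors:
    def test_stated_conventions(self, layout):
        cells = cells_df([(250, 600), (250, 100), (750, 600), (750, 100),
                          (1500, 300)])
        labeled = assign_sectors(cells, layout)
        assert list(labeled.sector) == ["s1", "s2", "s3", "s4", "none"]

    def test_half_open_boundaries(self, layout):
        cells = cells_df([(0, 0), (500, 400), (1000, 300)])
        labeled = assign_sectors(cells, layout)
        assert list(labeled.sector) == ["s2", "s3", "none"]

    def test_window_partition(self, layout, rng):
        pts = np.column_stack([rng.uniform(0, 1000, 500),
                               rng.uniform(0, 800, 500)])
        labeled = assign_sectors(cells_df(pts), layout)
        assert set(labeled.sector) <= {"s1", "s2", "s3", "s4"}
        assert (labeled.sector != "none").all()

    def test_counts_proportional_to_area(self, rng):
        # asymmetric splits: areas 1:3 within each x-half
        layout = SectorLayout(width_um=1000, depth_max_um=800,
                              depth_split_um=200.0)
        pts = np.column_stack([rng.uniform(0, 1000, 8000),
                               rng.uniform(0, 800, 8000)])
        counts = assign_sectors(cells_df(pts), layout).sector.value_counts()
        # s1 (deep) has 3x the area of s2
        assert counts["s1"] / counts["s2"] == pytest.approx(3.0, rel=0.15)


class TestSummariesAndContrasts:
    def test_one_cell_per_sector_means(self, layout):
        cells = assign_sectors(
            cells_df([(250, 600), (250, 100), (750, 600), (750, 100)]),
            layout)
        cells["norm_intensity"] = [0.1, 0.2, 0.3, 0.4]
        summary = sector_summary(cells, layout)
        assert [summary[s]["mean_intensity"] for s in
                ("s1", "s2", "s3", "s4")] == pytest.approx(
            [0.1, 0.2, 0.3, 0.4])

    def test_equal_counts_equal_densities(self, layout, rng):
        pts = [(100, 100), (600, 100), (100, 700), (600, 700)]
        cells = assign_sectors(cells_df(pts), layout)
        summary = sector_summary(cells, layout)
        densities = {summary[s]["density_per_mm2"]
                     for s in ("s1", "s2", "s3", "s4")}
        assert len(densities) == 1

    def test_empty_sector_flagged(self, layout):
        cells = assign_sectors(cells_df([(250, 600)]), layout)
        summary = sector_summary(cells, layout)
        assert summary["s4"]["n_cells"] == 0
        assert np.isnan(summary["s4"]["mean_intensity"])

    def test_identical_groups_contrast(self, layout, rng):
        pts = np.column_stack([rng.uniform(0, 1000, 120),
                               rng.uniform(0, 800, 120)])
        cells = assign_sectors(cells_df(pts), layout)
        cells["norm_intensity"] = rng.uniform(0.2, 0.5, len(cells))
        res = group_contrast({"naive": cells, "TBI": cells.copy()}, "naive")
        assert res["percent_of_reference"]["TBI"] == pytest.approx(100.0)
        assert res["pairwise_mann_whitney"]["TBI_vs_naive"]["p"] \
            == pytest.approx(1.0)

    def test_layer_fc_estimator_consistency(self):
        """Deep/superficial FC error shrinks as planted cells increase."""
        from perimir.synthdata import ImageGeom, Scenario

        def err(n_cells, seed):
            sc = Scenario(
                name="c", rng_seed=seed,
                image_geom=ImageGeom(width_um=1000, depth_um=800,
                                     microns_per_pixel=2),
                groups=[{"group_label": "naive", "n_subjects": 4}],
                layer_effect=1.9, group_scale={"naive": 1.0},
                n_cells_per_subject=n_cells, cell_radius_um=8.0)
            errors = []
            for idx in range(4):
                scene = synthdata.generate_ish_scene(sc, idx)
                cells = quantify_scene(scene, scene_layout(sc),
                                       detection_threshold(sc))
                errors.append(abs(deep_superficial_fc(cells) - 1.9))
            return np.mean(errors)

        assert err(400, seed=31) < err(25, seed=31)


class TestCompareRegions:
    def test_identical_sets(self):
        vals = np.linspace(0.1, 0.5, 40)
        res = compare_regions(vals, vals.copy(), 0.1, 0.1)
        assert res["density_inside_per_mm2"] == res["density_outside_per_mm2"]
        assert res["intensity_test"]["p"] == pytest.approx(1.0)

    def test_planted_shift_detected(self, rng):
        inside = 0.18 * np.exp(rng.normal(0, 0.3, 120))
        outside = 0.30 * np.exp(rng.normal(0, 0.2, 120))
        res = compare_regions(inside, outside, 0.1, 0.1)
        assert res["intensity_test"]["p"] < 0.01
        assert res["inside"]["mean"] < res["outside"]["mean"]

    def test_density_scales_inversely_with_area(self):
        vals = np.full(30, 0.3)
        res = compare_regions(vals, vals, 0.05, 0.2)
        assert res["density_inside_per_mm2"] == pytest.approx(
            4 * res["density_outside_per_mm2"])

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            compare_regions([], [0.1], 0.1, 0.1)
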