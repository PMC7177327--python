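"""Per-cell ISH intensity quantification over perilesional sectors.

Cells are detected as connected components darker than a fixed grayscale
threshold; each cell's signal is the background-normalized intensity
(bg - cell)/bg, positive for expressing (darker) cells.  The perilesional
window is a 1000-um-wide sector split into a 2x2 grid: s1 proximal-deep,
s2 proximal-superficial, s3 distal-deep, s4 distal-superficial.  x runs in
um from the lesion-side edge distally; depth runs from the pial surface
down; all sector intervals are half-open [min, split).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .stats import kruskal_wallis, mann_whitney

__all__ = [
    "SectorLayout", "detect_cells", "estimate_background",
    "normalized_intensity", "assign_sectors", "sector_summary",
    "group_contrast", "compare_regions", "evaluate_detection",
    "quantify_scene",
]

DEEP_SECTORS = ("s1", "s3")
SUPERFICIAL_SECTORS = ("s2", "s4")


@dataclass
class SectorLayout:
    origin_x_um: float = 0.0
    width_um: float = 1000.0
    depth_min_um: float = 0.0
    depth_max_um: float = 800.0
    depth_split_um: float | None = None   # default: midpoint
    x_split_um: float | None = None       # default: midpoint

    def __post_init__(self) -> None:
        if self.depth_split_um is None:
            self.depth_split_um = 0.5 * (self.depth_min_um + self.depth_max_um)
        if self.x_split_um is None:
            self.x_split_um = self.origin_x_um + 0.5 * self.width_um
        if not (self.depth_min_um < self.depth_split_um < self.depth_max_um):
            raise ValueError("depth split must lie strictly inside the span")
        if not (self.origin_x_um < self.x_split_um
                < self.origin_x_um + self.width_um):
            raise ValueError("x split must lie strictly inside the span")

    def sector_area_mm2(self, sector: str) -> float:
        x0, x1 = self.origin_x_um, self.origin_x_um + self.width_um
        xs, ds = self.x_split_um, self.depth_split_um
        d0, d1 = self.depth_min_um, self.depth_max_um
        spans = {
            "s1": (xs - x0) * (d1 - ds),   # proximal, deep
            "s2": (xs - x0) * (ds - d0),   # proximal, superficial
            "s3": (x1 - xs) * (d1 - ds),   # distal, deep
            "s4": (x1 - xs) * (ds - d0),   # distal, superficial
        }
        return spans[sector] / 1e6


def detect_cells(scene_image: np.ndarray, microns_per_pixel: float,
                 gray_threshold: float, min_area_um2: float = 20.0,
                 max_area_um2: float = 2000.0) -> pd.DataFrame:
    """Connected components of pixels darker than the threshold.

    Returns one row per detected cell: centroid in um, area in um^2 and the
    mean gray over the component's pixels.  The sector column is left unset
    ("none").
    """
    img = np.asarray(scene_image, float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    if not (0.0 < gray_threshold < 1.0):
        raise ValueError("gray_threshold must be in (0, 1)")
    labels = measure.label(img < gray_threshold, connectivity=2)
    px_area = microns_per_pixel ** 2
    rows = []
    for region in measure.regionprops(labels, intensity_image=img):
        area = region.area * px_area
        if not (min_area_um2 <= area <= max_area_um2):
            continue
        r, c = region.centroid
        rows.append({
            "cell_id": len(rows),
            "x_um": c * microns_per_pixel,
            "depth_um": r * microns_per_pixel,
            "area_um2": area,
            "mean_gray": float(region.intensity_mean),
            "sector": "none",
        })
    return pd.DataFrame(rows, columns=["cell_id", "x_um", "depth_um",
                                       "area_um2", "mean_gray", "sector"])


def estimate_background(scene_image: np.ndarray, gray_threshold: float,
                        rect_px: tuple[int, int, int, int] | None = None
                        ) -> float:
    """Mean gray of the cell-free background.

    By default: all pixels at or above the detection threshold.  A caller
    may instead give an explicit rectangle (row0, row1, col0, col1).
    """
    img = np.asarray(scene_image, float)
    if rect_px is not None:
        r0, r1, c0, c1 = rect_px
        img = img[r0:r1, c0:c1]
    bg = img[img >= gray_threshold]
    if bg.size == 0:
        raise ValueError("no background pixels above threshold")
    return float(bg.mean())


def normalized_intensity(cell_mean_gray, background_mean_gray: float):
    """(bg - cell) / bg: positive for cells darker than background.

    Negative values (cell lighter than background) are legal and retained.
    """
    if background_mean_gray <= 0:
        raise ValueError("background mean gray must be positive")
    return (background_mean_gray - np.asarray(cell_mean_gray, float)) \
        / background_mean_gray


def assign_sectors(cells: pd.DataFrame, layout: SectorLayout) -> pd.DataFrame:
    """Label each cell s1..s4 (or 'none' outside the sector window)."""
    cells = cells.copy()
    x = cells["x_um"].to_numpy(float)
    d = cells["depth_um"].to_numpy(float)
    in_x = (x >= layout.origin_x_um) & (x < layout.origin_x_um + layout.width_um)
    in_d = (d >= layout.depth_min_um) & (d < layout.depth_max_um)
    proximal = x < layout.x_split_um
    deep = d >= layout.depth_split_um
    sector = np.where(proximal, np.where(deep, "s1", "s2"),
                      np.where(deep, "s3", "s4"))
    cells["sector"] = np.where(in_x & in_d, sector, "none")
    return cells


def sector_summary(cells: pd.DataFrame, layout: SectorLayout) -> dict:
    """Per-sector count, density (cells/mm^2), mean intensity and values."""
    if "norm_intensity" not in cells.columns:
        raise ValueError("cells need a norm_intensity column")
    out = {}
    for sector in ("s1", "s2", "s3", "s4"):
        vals = cells.loc[cells.sector == sector, "norm_intensity"] \
            .to_numpy(float)
        area = layout.sector_area_mm2(sector)
        out[sector] = {
            "n_cells": int(vals.size),
            "density_per_mm2": vals.size / area,
            "mean_intensity": float(vals.mean()) if vals.size else float("nan"),
            "intensities": vals,
        }
    return out


def _in_window(cells: pd.DataFrame) -> pd.DataFrame:
    return cells[cells.sector != "none"]


def deep_superficial_fc(cells: pd.DataFrame) -> float:
    """Mean intensity of deep sectors (s1, s3) over superficial (s2, s4)."""
    cells = _in_window(cells)
    deep = cells.loc[cells.sector.isin(DEEP_SECTORS), "norm_intensity"]
    sup = cells.loc[cells.sector.isin(SUPERFICIAL_SECTORS), "norm_intensity"]
    if deep.empty or sup.empty or sup.mean() == 0:
        raise ValueError("both layers need cells with nonzero mean intensity")
    return float(deep.mean() / sup.mean())


def group_contrast(cells_by_group: dict[str, pd.DataFrame],
                   reference_group: str) -> dict:
    """Cross-group comparison of per-cell intensities.

    Per group: deep/superficial fold-change and the all-sector mean
    intensity as percent of the reference group.  Significance: Kruskal-
    Wallis across all groups, then pairwise Mann-Whitney U.
    """
    if len(cells_by_group) < 2:
        raise ValueError("need at least two groups")
    if reference_group not in cells_by_group:
        raise ValueError(f"unknown reference group {reference_group!r}")
    intens = {g: _in_window(c)["norm_intensity"].to_numpy(float)
              for g, c in cells_by_group.items()}
    ref_mean = intens[reference_group].mean()
    if ref_mean == 0:
        raise ValueError("reference group mean intensity is zero")
    result = {
        "reference_group": reference_group,
        "deep_vs_superficial_fc": {
            g: deep_superficial_fc(c) for g, c in cells_by_group.items()},
        "percent_of_reference": {
            g: 100.0 * v.mean() / ref_mean for g, v in intens.items()},
        "n_cells": {g: int(v.size) for g, v in intens.items()},
    }
    kw = kruskal_wallis(list(intens.values()))
    result["kruskal_wallis"] = {"H": kw.statistic, "p": kw.p_value}
    pairwise = {}
    names = sorted(intens)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            mw = mann_whitney(intens[a], intens[b])
            pairwise[f"{a}_vs_{b}"] = {"U": mw.statistic, "p": mw.p_value,
                                       "exact": mw.exact}
    result["pairwise_mann_whitney"] = pairwise
    return result


def compare_regions(intensities_inside, intensities_outside,
                    area_inside_mm2: float, area_outside_mm2: float) -> dict:
    """Inside- vs outside-patch comparison of per-cell intensities.

    Returns densities, a Mann-Whitney test on the intensity distributions,
    and dispersion statistics, keeping the raw distributions for plotting.
    """
    inside = np.asarray(intensities_inside, float)
    outside = np.asarray(intensities_outside, float)
    if inside.size == 0 or outside.size == 0:
        raise ValueError("both regions must contain cells")
    mw = mann_whitney(inside, outside)

    def _disp(v):
        q1, q3 = np.percentile(v, [25, 75])
        return {"mean": float(v.mean()), "sd": float(v.std(ddof=1)),
                "iqr": float(q3 - q1), "n": int(v.size)}

    return {
        "density_inside_per_mm2": inside.size / area_inside_mm2,
        "density_outside_per_mm2": outside.size / area_outside_mm2,
        "intensity_test": {"U": mw.statistic, "p": mw.p_value,
                           "exact": mw.exact},
        "inside": _disp(inside),
        "outside": _disp(outside),
        "distributions": {"inside": inside, "outside": outside},
    }


def evaluate_detection(cells: pd.DataFrame, truth: pd.DataFrame,
                       match_radius_um: float) -> dict:
    """Greedy one-to-one matching of detections to planted cells."""
    det = cells[["x_um", "depth_um"]].to_numpy(float)
    tru = truth[["x_um", "depth_um"]].to_numpy(float)
    used = np.zeros(len(tru), bool)
    tp = 0
    for x, d in det:
        if len(tru) == 0:
            break
        d2 = (tru[:, 0] - x) ** 2 + (tru[:, 1] - d) ** 2
        d2[used] = np.inf
        j = int(d2.argmin())
        if d2[j] <= match_radius_um ** 2:
            used[j] = True
            tp += 1
    fp = len(det) - tp
    fn = len(tru) - tp
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "recall": tp / len(tru) if len(tru) else float("nan"),
        "precision": tp / len(det) if len(det) else float("nan"),
    }


def quantify_scene(scene, layout: SectorLayout, gray_threshold: float,
                   min_area_um2: float = 20.0,
                   max_area_um2: float = 2000.0) -> pd.DataFrame:
    """Detect, background-normalize and sector-label cells of one scene."""
    cells = detect_cells(scene.image, scene.microns_per_pixel,
                         gray_threshold, min_area_um2, max_area_um2)
    bg = estimate_background(scene.image, gray_threshold)
    cells["norm_intensity"] = normalized_intensity(cells["mean_gray"], bg)
    cells["background_gray"] = bg
    return assign_sectors(cells, layout)
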