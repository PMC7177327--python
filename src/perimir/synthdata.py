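"""Synthetic-data generators for every pipeline input.

The generators emulate the statistical structure the downstream analyses
assume, with effect sizes planted through scenario files:

* chromogenic ISH section images — darker-than-background circular cells on
  a light background, with a deep/superficial layer ratio and per-group
  scaling of the planted signal;
* qPCR Ct tables — target/reference assay pairs whose group difference of
  dCt encodes a planted fold-change;
* a transcriptome — 3'UTR sequences in which exactly the planted target
  genes carry a canonical seed site, plus a differential-expression table
  with exact planted up/down significant counts and target overlaps.

Everything is seeded: one independent stream per (scenario, subject) for
images, and caller-suppliable generators elsewhere, so any subset of a
scenario is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .targets import seed_site_6mer, _RNA_COMPLEMENT

__all__ = [
    "Scenario", "IshScene", "load_scenario",
    "generate_ish_scene", "generate_ct_table", "generate_transcriptome",
    "generate_correlated_pairs", "generate_patch_intensities",
]

_RNA = np.array(list("ACGU"))


# ---------------------------------------------------------------------------
# scenario schema


@dataclass
class ImageGeom:
    width_um: float
    depth_um: float
    microns_per_pixel: float
    background_gray: float = 0.9
    noise_gray: float = 0.002

    def __post_init__(self) -> None:
        if not (0.0 < self.background_gray <= 1.0):
            raise ValueError("background_gray must be in (0, 1]")
        if min(self.width_um, self.depth_um, self.microns_per_pixel) <= 0:
            raise ValueError("image geometry must be positive")


@dataclass
class QpcrConfig:
    n_case: int
    n_control: int
    planted_fc: float
    ct_sd: float
    reference_ct_mean: float = 20.0
    baseline_dct: float = 5.0
    case_group: str = "TBI"
    control_group: str = "sham"

    def __post_init__(self) -> None:
        if self.planted_fc <= 0:
            raise ValueError("planted_fc must be positive")
        if self.ct_sd < 0:
            raise ValueError("ct_sd must be non-negative")


@dataclass
class TranscriptomeConfig:
    n_genes: int
    n_target_genes: int
    n_up_sig: int
    n_down_sig: int
    n_up_targets: int
    n_down_targets: int
    utr_len: int = 300

    def __post_init__(self) -> None:
        c = self
        ok = (
            0 <= c.n_target_genes <= c.n_genes
            and c.n_up_targets <= min(c.n_up_sig, c.n_target_genes)
            and c.n_down_targets <= min(c.n_down_sig, c.n_target_genes)
            and c.n_up_targets + c.n_down_targets <= c.n_target_genes
            and (c.n_up_sig - c.n_up_targets) + (c.n_down_sig - c.n_down_targets)
            <= c.n_genes - c.n_target_genes
            and c.n_up_sig + c.n_down_sig <= c.n_genes
            and c.utr_len >= 10
        )
        if not ok:
            raise ValueError("infeasible transcriptome counts")


@dataclass
class CorrelationConfig:
    rho_spearman: float
    n_pairs: int = 24


@dataclass
class PatchConfig:
    n_inside: int = 60
    n_outside: int = 60
    mean_outside: float = 0.3
    inside_mean_scale: float = 0.6   # patchy area: lower mean ...
    inside_sd_scale: float = 1.5     # ... and more variable signal
    sigma: float = 0.2               # lognormal sigma outside
    area_inside_mm2: float = 0.1
    area_outside_mm2: float = 0.1


@dataclass
class Scenario:
    name: str
    rng_seed: int
    image_geom: ImageGeom | None = None
    groups: list[dict] = field(default_factory=list)
    layer_effect: float = 1.0
    group_scale: dict[str, float] = field(default_factory=dict)
    base_signal: float = 0.25
    signal_cv: float = 0.15
    n_cells_per_subject: int = 0
    cell_radius_um: float = 8.0
    qpcr: dict[str, QpcrConfig] = field(default_factory=dict)
    correlation: CorrelationConfig | None = None
    transcriptome: TranscriptomeConfig | None = None
    patch: PatchConfig | None = None

    def __post_init__(self) -> None:
        if self.layer_effect <= 0 or self.base_signal <= 0:
            raise ValueError("planted ratios and signals must be positive")
        if any(v <= 0 for v in self.group_scale.values()):
            raise ValueError("group_scale entries must be positive")

    # subjects are indexed globally, in group order, so a single integer
    # identifies (group, replicate) reproducibly
    def subject_table(self) -> list[tuple[int, str, int]]:
        out = []
        idx = 0
        for g in self.groups:
            for rep in range(int(g["n_subjects"])):
                out.append((idx, str(g["group_label"]), rep))
                idx += 1
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        if isinstance(d.get("image_geom"), dict):
            d["image_geom"] = ImageGeom(**d["image_geom"])
        if d.get("qpcr"):
            d["qpcr"] = {k: (QpcrConfig(**v) if isinstance(v, dict) else v)
                         for k, v in d["qpcr"].items()}
        if isinstance(d.get("correlation"), dict):
            d["correlation"] = CorrelationConfig(**d["correlation"])
        if isinstance(d.get("transcriptome"), dict):
            d["transcriptome"] = TranscriptomeConfig(**d["transcriptome"])
        if isinstance(d.get("patch"), dict):
            d["patch"] = PatchConfig(**d["patch"])
        return cls(**d)


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        return Scenario.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# ISH scenes


@dataclass
class IshScene:
    image: np.ndarray           # 2-D grayscale in [0, 1]
    microns_per_pixel: float
    lesion_edge_x_um: float
    group_label: str
    subject_index: int
    truth: pd.DataFrame         # x_um, depth_um, radius_um, planted_gray,
                                # planted_signal, layer


def _place_cells(rng: np.random.Generator, n: int, width: float, depth: float,
                 radius: float, margin: float) -> np.ndarray:
    """Non-overlapping centers by rejection sampling; (n, 2) array [x, depth]."""
    lo = radius + margin
    min_d2 = (2 * radius + margin) ** 2
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = max(10_000, n * 2_000)
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} non-overlapping cells of radius "
                f"{radius} um in a {width} x {depth} um field")
        x = rng.uniform(lo, width - lo)
        d = rng.uniform(lo, depth - lo)
        if all((x - cx) ** 2 + (d - cd) ** 2 >= min_d2 for cx, cd in centers):
            centers.append((x, d))
    return np.array(centers)


def generate_ish_scene(scenario: Scenario, subject_index: int) -> IshScene:
    """One synthetic ISH section for the subject with the given global index.

    Per-cell gray = background_gray * (1 - s) with s lognormal around the
    planted group/layer signal; the deep-layer planted signal is the
    superficial signal times ``layer_effect``.
    """
    if scenario.image_geom is None:
        raise ValueError(f"scenario {scenario.name!r} has no image geometry")
    subjects = scenario.subject_table()
    if not (0 <= subject_index < len(subjects)):
        raise ValueError(f"subject_index {subject_index} out of range "
                         f"(0..{len(subjects) - 1})")
    _, group, _ = subjects[subject_index]
    geom = scenario.image_geom
    rng = np.random.default_rng([int(scenario.rng_seed), int(subject_index)])

    mpp = geom.microns_per_pixel
    h = int(round(geom.depth_um / mpp))
    w = int(round(geom.width_um / mpp))
    centers = _place_cells(rng, scenario.n_cells_per_subject,
                           geom.width_um, geom.depth_um,
                           scenario.cell_radius_um, margin=2 * mpp)

    depth_split = geom.depth_um / 2.0
    scale = scenario.group_scale.get(group, 1.0)
    rows = []
    image = np.full((h, w), geom.background_gray, float)
    yy, xx = np.mgrid[0:h, 0:w]
    for (x_um, d_um) in centers:
        deep = d_um >= depth_split
        nominal = scenario.base_signal * scale * (
            scenario.layer_effect if deep else 1.0)
        s = nominal * math.exp(rng.normal(0.0, scenario.signal_cv))
        s = min(s, 0.95)
        gray = geom.background_gray * (1.0 - s)
        r_px = scenario.cell_radius_um / mpp
        mask = ((xx - x_um / mpp) ** 2 + (yy - d_um / mpp) ** 2) <= r_px ** 2
        image[mask] = gray
        rows.append({
            "x_um": x_um, "depth_um": d_um,
            "radius_um": scenario.cell_radius_um,
            "planted_gray": gray, "planted_signal": s,
            "layer": "deep" if deep else "superficial",
        })
    if geom.noise_gray > 0:
        image = np.clip(image + rng.normal(0.0, geom.noise_gray, image.shape),
                        0.0, 1.0)
    truth = pd.DataFrame(rows)
    return IshScene(image=image, microns_per_pixel=mpp, lesion_edge_x_um=0.0,
                    group_label=group, subject_index=subject_index,
                    truth=truth)


# ---------------------------------------------------------------------------
# qPCR Ct tables


def generate_ct_table(scenario: Scenario, assay: str | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Ct table for one target/reference assay pair of a scenario.

    Control-group dCt is centered at the configured baseline; case-group dCt
    at baseline - log2(planted_fc), so the expected ddCt recovers the
    planted fold-change exactly.  ct_sd is the standard deviation of the
    per-sample dCt (split ct_sd / sqrt(2) per assay).
    """
    if not scenario.qpcr:
        raise ValueError(f"scenario {scenario.name!r} has no qPCR block")
    if assay is None:
        if len(scenario.qpcr) > 1:
            raise ValueError(f"scenario has several assays "
                             f"{sorted(scenario.qpcr)}; pick one")
        assay = next(iter(scenario.qpcr))
    cfg = scenario.qpcr[assay]
    if rng is None:
        idx = sorted(scenario.qpcr).index(assay)
        rng = np.random.default_rng([int(scenario.rng_seed), 7, idx])
    per_assay_sd = cfg.ct_sd / math.sqrt(2.0)
    rows = []
    for group, n, shift in (
        (cfg.control_group, cfg.n_control, 0.0),
        (cfg.case_group, cfg.n_case, -math.log2(cfg.planted_fc)),
    ):
        for i in range(n):
            sid = f"{group}_{i + 1:02d}"
            ref_ct = cfg.reference_ct_mean + rng.normal(0.0, per_assay_sd)
            tgt_ct = (cfg.reference_ct_mean + cfg.baseline_dct + shift
                      + rng.normal(0.0, per_assay_sd))
            rows.append((sid, group, "target", tgt_ct))
            rows.append((sid, group, "reference", ref_ct))
    return pd.DataFrame(rows,
                        columns=["sample_id", "group_label", "assay", "ct"])


# ---------------------------------------------------------------------------
# transcriptome with planted seed-site targets


def _random_utr_without_core(rng: np.random.Generator, length: int,
                             core: str) -> str:
    while True:
        seq = "".join(_RNA[rng.integers(0, 4, size=length)])
        if core not in seq:
            return seq


def _planted_site(rng: np.random.Generator, core: str, m8c: str) -> str:
    """One seed site of a random canonical type (6mer core +/- flanks)."""
    kind = rng.choice(["8mer", "7mer-m8", "7mer-A1", "6mer"],
                      p=[0.3, 0.3, 0.2, 0.2])
    left = m8c if kind in ("8mer", "7mer-m8") else ""
    right = "A" if kind in ("8mer", "7mer-A1") else ""
    return left + core + right


def generate_transcriptome(scenario: Scenario, mirna: str,
                           rng: np.random.Generator | None = None):
    """(UTRSet, DETable, planted target ids) with exact planted counts.

    Non-target UTRs are rejection-sampled to contain zero 6mer seed matches,
    so the scanner's positive set equals the planted set exactly.  The DE
    table has exactly n_up_sig / n_down_sig significant genes at p < 0.05,
    of which exactly n_up_targets / n_down_targets are planted targets.
    Down-regulated targets are planted with the strongest evidence (smallest
    p, largest |log2fc|), emulating preferential repression-release of the
    seed-site-bearing transcripts.
    """
    cfg = scenario.transcriptome
    if cfg is None:
        raise ValueError(f"scenario {scenario.name!r} has no transcriptome")
    if rng is None:
        rng = np.random.default_rng([int(scenario.rng_seed), 11])
    core = seed_site_6mer(mirna)
    m8c = _RNA_COMPLEMENT[mirna.upper().replace("T", "U")[7]]

    gene_ids = [f"g{i + 1:05d}" for i in range(cfg.n_genes)]
    perm = rng.permutation(cfg.n_genes)
    target_ids = {gene_ids[i] for i in perm[: cfg.n_target_genes]}

    utrs: dict[str, str] = {}
    for gid in gene_ids:
        seq = _random_utr_without_core(rng, cfg.utr_len, core)
        if gid in target_ids:
            site = _planted_site(rng, core, m8c)
            pos = int(rng.integers(1, cfg.utr_len - len(site) - 1))
            seq = seq[:pos] + site + seq[pos + len(site):]
        utrs[gid] = seq

    # partition genes into up/down significant and the remainder
    t_list = rng.permutation(sorted(target_ids))
    nt_list = rng.permutation(sorted(set(gene_ids) - target_ids))
    up = list(t_list[: cfg.n_up_targets])
    down = list(t_list[cfg.n_up_targets: cfg.n_up_targets + cfg.n_down_targets])
    n_up_nt = cfg.n_up_sig - cfg.n_up_targets
    n_down_nt = cfg.n_down_sig - cfg.n_down_targets
    up += list(nt_list[:n_up_nt])
    down += list(nt_list[n_up_nt: n_up_nt + n_down_nt])
    up_set, down_set = set(up), set(down)

    down_targets = set(t_list[cfg.n_up_targets:
                              cfg.n_up_targets + cfg.n_down_targets])
    rows = []
    for gid in gene_ids:
        if gid in up_set:
            p = 10.0 ** rng.uniform(-6.0, math.log10(0.0499))
            lfc = rng.uniform(0.2, 3.0)
        elif gid in down_set:
            if gid in down_targets:
                p = 10.0 ** rng.uniform(-12.0, -6.0)
                lfc = -rng.uniform(1.0, 4.0)
            else:
                p = 10.0 ** rng.uniform(-5.0, math.log10(0.0499))
                lfc = -rng.uniform(0.2, 3.0)
        else:
            p = rng.uniform(0.0501, 1.0)
            lfc = rng.normal(0.0, 0.3)
        rows.append((gid, lfc, p))
    de = pd.DataFrame(rows, columns=["gene_id", "log2fc", "p"])
    return utrs, de, target_ids


# ---------------------------------------------------------------------------
# correlated pairs (Gaussian copula) and human patch intensities


def generate_correlated_pairs(rho_spearman: float, n: int,
                              rng: np.random.Generator):
    """Paired levels with a planted Spearman correlation via Gaussian copula.

    Bivariate-normal Pearson rho is chosen as 2 sin(pi rho_s / 6) so the
    population Spearman correlation equals the requested value.
    """
    if not (-1.0 < rho_spearman < 1.0):
        raise ValueError("rho_spearman must be in (-1, 1)")
    rho = 2.0 * math.sin(math.pi * rho_spearman / 6.0)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    return z[:, 0], z[:, 1]


def generate_patch_intensities(scenario: Scenario,
                               rng: np.random.Generator | None = None):
    """Per-cell intensities inside/outside a patchy-loss area.

    Inside the patch the planted per-cell signal has a lower mean and a
    larger dispersion (lognormal in both regions).
    """
    cfg = scenario.patch
    if cfg is None:
        raise ValueError(f"scenario {scenario.name!r} has no patch block")
    if rng is None:
        rng = np.random.default_rng([int(scenario.rng_seed), 13])
    outside = cfg.mean_outside * np.exp(
        rng.normal(0.0, cfg.sigma, cfg.n_outside))
    inside = cfg.mean_outside * cfg.inside_mean_scale * np.exp(
        rng.normal(0.0, cfg.sigma * cfg.inside_sd_scale, cfg.n_inside))
    return {
        "inside": inside,
        "outside": outside,
        "area_inside_mm2": cfg.area_inside_mm2,
        "area_outside_mm2": cfg.area_outside_mm2,
    }
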