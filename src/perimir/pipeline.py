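"""End-to-end scenario runs: generate -> quantify -> test -> report.

A run executes whichever stages the scenario configures (ISH imaging, qPCR
assays, miR/target correlation, transcriptome with seed-site scanning, DE
overlap, preranked enrichment and duplex MFE, patch comparison), persists
every intermediate artifact under the output directory, and writes a
self-contained JSON report whose headline table pairs each planted value
with its recovered estimate.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np

from . import MIR124_3P, __version__
from . import duplex as dx
from . import gsea, io, qpcr, synthdata, targets
from .ish import SectorLayout, compare_regions, group_contrast, quantify_scene
from .synthdata import Scenario

log = logging.getLogger("perimir")

PACKAGED_SCENARIOS = ("cohort1_7d", "cohort1_3mo", "cohort2_layers",
                      "cohort3", "human_patch", "null")


def packaged_scenario(name: str) -> Scenario:
    """Load one of the scenarios shipped with the package."""
    if name not in PACKAGED_SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; "
                         f"have {PACKAGED_SCENARIOS}")
    ref = resources.files("perimir") / "data" / "scenarios" / f"{name}.yaml"
    import yaml
    return Scenario.from_dict(yaml.safe_load(ref.read_text()))


def detection_threshold(scenario: Scenario) -> float:
    """Grayscale threshold between background and the dimmest expected cell."""
    geom = scenario.image_geom
    scales = list(scenario.group_scale.values()) or [1.0]
    s_min = (scenario.base_signal * min(scales)
             * min(1.0, scenario.layer_effect))
    return geom.background_gray * (1.0 - 0.275 * s_min)


def scene_layout(scenario: Scenario) -> SectorLayout:
    geom = scenario.image_geom
    return SectorLayout(origin_x_um=0.0, width_um=geom.width_um,
                        depth_min_um=0.0, depth_max_um=geom.depth_um)


def run_ish_stage(scenario: Scenario, out: Path | None = None) -> dict:
    """Generate and quantify every subject's scene; contrast the groups."""
    layout = scene_layout(scenario)
    thr = detection_threshold(scenario)
    cells_by_group: dict[str, list] = {}
    files = []
    import pandas as pd
    for idx, group, rep in scenario.subject_table():
        scene = synthdata.generate_ish_scene(scenario, idx)
        cells = quantify_scene(scene, layout, thr)
        cells["group_label"] = group
        cells["subject_index"] = idx
        cells_by_group.setdefault(group, []).append(cells)
        if out is not None:
            stem = f"{scenario.name}_{group}_{rep:02d}"
            io.write_image16(out / f"{stem}.tiff", scene.image)
            io.write_png_preview(out / f"{stem}.png", scene.image)
            scene.truth.to_csv(out / f"{stem}_truth.csv", index=False)
            files.append(str(out / f"{stem}.tiff"))
    merged = {g: pd.concat(dfs, ignore_index=True)
              for g, dfs in cells_by_group.items()}
    reference = "naive" if "naive" in merged else sorted(merged)[0]
    contrast = group_contrast(merged, reference) if len(merged) >= 2 else None
    if out is not None:
        pd.concat(merged.values(), ignore_index=True) \
            .to_csv(out / f"{scenario.name}_cells.csv", index=False)
        files.append(str(out / f"{scenario.name}_cells.csv"))
    return {"cells_by_group": merged, "contrast": contrast,
            "threshold": thr, "files": files}


def run_scenario(config, out_dir, seed: int | None = None) -> dict:
    """Execute every configured stage of a scenario and write a run report.

    ``config`` is a Scenario, a path to a scenario YAML file, or the name of
    a packaged scenario.  ``seed`` overrides the scenario's rng_seed.
    """
    if isinstance(config, Scenario):
        scenario = config
    elif isinstance(config, (str, Path)) and Path(str(config)).exists():
        scenario = synthdata.load_scenario(config)
    else:
        scenario = packaged_scenario(str(config))
    if seed is not None:
        scenario.rng_seed = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "scenario": scenario.name,
        "seed": int(scenario.rng_seed),
        "version": __version__,
        "stages": {},
        "headline": [],
    }

    def headline(quantity, planted, estimated, tol):
        report["headline"].append({
            "quantity": quantity, "planted": planted,
            "estimated": estimated, "tolerance": tol,
            "ok": bool(abs(estimated - planted) <= tol),
        })

    try:
        if scenario.image_geom is not None and scenario.groups:
            stage = run_ish_stage(scenario, out)
            contrast = stage["contrast"]
            report["stages"]["ish"] = {
                "threshold": stage["threshold"],
                "files": stage["files"],
                "contrast": _strip_arrays(contrast),
            }
            if contrast is not None:
                ref = contrast["reference_group"]
                fc = contrast["deep_vs_superficial_fc"].get(ref)
                if fc is not None:
                    headline("deep_vs_superficial_fc_" + ref,
                             scenario.layer_effect, fc, 0.1)
                for g, pct in contrast["percent_of_reference"].items():
                    if g == ref:
                        continue
                    planted = 100.0 * scenario.group_scale.get(g, 1.0) \
                        / scenario.group_scale.get(ref, 1.0)
                    headline(f"percent_of_{ref}_{g}", planted, pct, 5.0)

        for assay, cfg in sorted(scenario.qpcr.items()):
            ct = synthdata.generate_ct_table(scenario, assay)
            ct.to_csv(out / f"{scenario.name}_{assay}_ct.csv", index=False)
            res = qpcr.ddct_fold_change(ct, cfg.case_group, cfg.control_group)
            res.dct.to_csv(out / f"{scenario.name}_{assay}_relquant.csv",
                           index=False)
            report["stages"].setdefault("qpcr", {})[assay] = {
                "ddct": res.ddct, "fold_change": res.fold_change,
                "test": res.test,
            }
            # single-replicate band: ~2.5 sd of ddCt noise on the FC scale
            sd_ddct = cfg.ct_sd * np.sqrt(1 / cfg.n_case + 1 / cfg.n_control)
            headline(f"fold_change_{assay}", cfg.planted_fc, res.fold_change,
                     cfg.planted_fc * (2.0 ** (2.5 * sd_ddct) - 1.0))

        if scenario.correlation is not None:
            rng = np.random.default_rng([scenario.rng_seed, 17])
            x, y = synthdata.generate_correlated_pairs(
                scenario.correlation.rho_spearman,
                scenario.correlation.n_pairs, rng)
            corr = qpcr.correlate_mir_target(x, y)
            report["stages"]["correlation"] = corr
            headline("spearman_r", scenario.correlation.rho_spearman,
                     corr["r"], 0.25)

        if scenario.transcriptome is not None:
            utrs, de, planted = synthdata.generate_transcriptome(
                scenario, MIR124_3P)
            io.write_fasta(utrs, out / f"{scenario.name}_utrs.fasta")
            de.to_csv(out / f"{scenario.name}_de.csv", index=False)
            predicted = targets.predicted_target_set(utrs, MIR124_3P)
            overlap = targets.de_overlap(de, predicted)
            ranked = gsea.rank_genes(de)
            enr = gsea.gsea_significance(ranked, predicted, n_perm=200,
                                         seed=np.random.default_rng(
                                             [scenario.rng_seed, 19]))
            duplex_rows = _duplex_stage(utrs, sorted(planted)[:5])
            report["stages"]["targets"] = {
                "n_predicted_targets": len(predicted),
                "overlap": vars(overlap) | {
                    "fraction_targets_regulated":
                        overlap.fraction_targets_regulated},
                "gsea": {"es": enr.es, "nes": enr.nes, "p": enr.p_perm,
                         "fdr": enr.fdr},
                "duplex": duplex_rows,
            }
            cfg = scenario.transcriptome
            headline("n_predicted_targets", cfg.n_target_genes,
                     len(predicted), 0)
            headline("n_up_targets", cfg.n_up_targets,
                     overlap.n_up_targets, 0)
            headline("n_down_targets", cfg.n_down_targets,
                     overlap.n_down_targets, 0)

        if scenario.patch is not None:
            vals = synthdata.generate_patch_intensities(scenario)
            comp = compare_regions(vals["inside"], vals["outside"],
                                   vals["area_inside_mm2"],
                                   vals["area_outside_mm2"])
            comp.pop("distributions")
            report["stages"]["patch"] = comp
    except Exception as exc:  # stage-tagged failure, partial outputs retained
        report["error"] = f"{type(exc).__name__}: {exc}"
        io.write_json(out / f"{scenario.name}_report.json", report)
        raise
    io.write_json(out / f"{scenario.name}_report.json", report)
    return report


def _duplex_stage(utrs: dict[str, str], ids: list[str],
                  window: int = 30) -> list[dict]:
    model = dx.default_energy_model()
    rows = []
    for tid in ids:
        hits = targets.scan_sites(utrs[tid], MIR124_3P)
        if not hits:
            continue
        region = site_region(utrs[tid], hits[0].start, window)
        res = dx.duplex_mfe(MIR124_3P, region, model)
        rows.append({"transcript_id": tid, "mfe": res.mfe,
                     "binding_start": (dx.binding_start(res)
                                       if res.pairing else None)})
    return rows


def site_region(utr: str, site_start: int, window: int = 30) -> str:
    """Target region of ``window`` nt centered on a seed site (1-based start)."""
    center = site_start - 1 + 3
    lo = max(0, center - window // 2)
    return utr[lo: lo + window]


def _strip_arrays(obj):
    import numpy as _np
    if isinstance(obj, dict):
        return {k: _strip_arrays(v) for k, v in obj.items()
                if not isinstance(v, _np.ndarray)}
    return obj
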