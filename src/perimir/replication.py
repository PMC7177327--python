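"""Seeded replicate protocols for parameter-recovery summaries.

Each helper reruns one analysis stage on freshly generated synthetic data
many times and reports the median estimate, the summary used to judge how
well the pipeline recovers a planted effect size.
"""

from __future__ import annotations

import numpy as np

from . import qpcr, synthdata
from .synthdata import Scenario

__all__ = ["median_fc_recovery", "median_correlation_recovery",
           "layer_recovery", "null_contrast_fraction"]


def median_fc_recovery(scenario: Scenario, assay: str, n_reps: int = 200,
                       seed: int = 0) -> dict:
    """Median 2^-ddCt estimate over seeded replicate Ct tables."""
    cfg = scenario.qpcr[assay]
    estimates = np.empty(n_reps)
    for rep in range(n_reps):
        rng = np.random.default_rng([int(seed), 101, rep])
        ct = synthdata.generate_ct_table(scenario, assay, rng=rng)
        res = qpcr.ddct_fold_change(ct, cfg.case_group, cfg.control_group)
        estimates[rep] = res.fold_change
    return {"median_fc": float(np.median(estimates)),
            "planted_fc": cfg.planted_fc,
            "n_reps": n_reps,
            "n_per_group": (cfg.n_case, cfg.n_control)}


def median_correlation_recovery(rho_spearman: float, n_pairs: int,
                                n_reps: int = 500, seed: int = 0) -> dict:
    """Median Spearman r over replicate Gaussian-copula samples."""
    rs = np.empty(n_reps)
    for rep in range(n_reps):
        rng = np.random.default_rng([int(seed), 103, rep])
        x, y = synthdata.generate_correlated_pairs(rho_spearman, n_pairs, rng)
        rs[rep] = qpcr.correlate_mir_target(x, y)["r"]
    return {"median_r": float(np.median(rs)), "planted_r": rho_spearman,
            "n_reps": n_reps, "n_pairs": n_pairs}


def layer_recovery(scenario: Scenario, seed: int | None = None) -> dict:
    """ISH stage on every subject: layer FC and percent-of-reference."""
    from .pipeline import run_ish_stage
    if seed is not None:
        scenario = Scenario.from_dict({**_scenario_dict(scenario),
                                       "rng_seed": int(seed)})
    stage = run_ish_stage(scenario, out=None)
    contrast = stage["contrast"]
    ref = contrast["reference_group"]
    return {
        "reference_group": ref,
        "deep_vs_superficial_fc": contrast["deep_vs_superficial_fc"],
        "percent_of_reference": contrast["percent_of_reference"],
        "n_cells": contrast["n_cells"],
        "kruskal_wallis_p": contrast["kruskal_wallis"]["p"],
    }


def null_contrast_fraction(scenario: Scenario, n_runs: int = 20,
                           seed: int = 0, alpha: float = 0.05) -> dict:
    """Fraction of seeded null runs whose contrasts stay non-significant."""
    from .pipeline import run_ish_stage
    clean = 0
    for run in range(n_runs):
        sc = Scenario.from_dict({**_scenario_dict(scenario),
                                 "rng_seed": int(seed) + run})
        ps = []
        if sc.image_geom is not None and sc.groups:
            stage = run_ish_stage(sc, out=None)
            ps.append(stage["contrast"]["kruskal_wallis"]["p"])
        for assay, cfg in sc.qpcr.items():
            ct = synthdata.generate_ct_table(sc, assay)
            res = qpcr.ddct_fold_change(ct, cfg.case_group, cfg.control_group)
            ps.append(res.test["p"])
        clean += all(p > alpha for p in ps)
    return {"fraction_non_significant": clean / n_runs, "n_runs": n_runs}


def _scenario_dict(sc: Scenario) -> dict:
    """Shallow re-dict of a Scenario for seed-overridden copies."""
    import dataclasses
    d = {}
    for f in dataclasses.fields(sc):
        d[f.name] = getattr(sc, f.name)
    return d
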