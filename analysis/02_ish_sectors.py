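#!/usr/bin/env python
"""Quantify per-cell ISH intensity over the perilesional sectors.

Runs the cohort2_layers scenario (naive / sham / TBI, 3 subjects each,
400 cells per subject), reports the deep/superficial fold-change and each
group's mean per-cell intensity as percent of naive, then the human-style
inside/outside-patch comparison.  Planted values: layer FC 1.9, TBI 47%,
sham 71% of naive.
"""

import json
from pathlib import Path

from perimir.ish import compare_regions
from perimir.pipeline import packaged_scenario
from perimir.replication import layer_recovery
from perimir.synthdata import generate_patch_intensities

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rec = layer_recovery(packaged_scenario("cohort2_layers"))
    print("cohort2_layers sector analysis "
          f"({sum(rec['n_cells'].values())} cells):")
    for g, fc in sorted(rec["deep_vs_superficial_fc"].items()):
        print(f"  {g:6s} deep/superficial FC = {fc:.2f}")
    for g, pct in sorted(rec["percent_of_reference"].items()):
        print(f"  {g:6s} intensity = {pct:.1f}% of naive")
    print(f"  Kruskal-Wallis across groups: p = {rec['kruskal_wallis_p']:.2e}")

    patch_sc = packaged_scenario("human_patch")
    vals = generate_patch_intensities(patch_sc)
    comp = compare_regions(vals["inside"], vals["outside"],
                           vals["area_inside_mm2"], vals["area_outside_mm2"])
    comp.pop("distributions")
    print("human_patch inside/outside comparison:")
    print(f"  mean intensity inside {comp['inside']['mean']:.3f} "
          f"vs outside {comp['outside']['mean']:.3f}, "
          f"Mann-Whitney p = {comp['intensity_test']['p']:.2e}")

    (OUT / "ish_sectors.json").write_text(json.dumps(
        {"cohort2_layers": rec, "human_patch": comp}, indent=2) + "\n")
    print(f"wrote {OUT / 'ish_sectors.json'}")


if __name__ == "__main__":
    main()
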