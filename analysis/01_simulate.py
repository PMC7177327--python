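#!/usr/bin/env python
"""Generate the synthetic inputs for every packaged scenario.

Everything a later stage consumes is regenerated deterministically from the
scenario seeds, so the whole output tree lives under scratch/simulated/ and
is never versioned.
"""

from pathlib import Path

from perimir import MIR124_3P, io, synthdata
from perimir.pipeline import PACKAGED_SCENARIOS, packaged_scenario

ROOT = Path(__file__).resolve().parents[1]
TEXT_OUT = ROOT / "scratch" / "simulated"
IMG_OUT = ROOT / "scratch" / "simulated"


def main() -> None:
    TEXT_OUT.mkdir(parents=True, exist_ok=True)
    IMG_OUT.mkdir(parents=True, exist_ok=True)
    for name in PACKAGED_SCENARIOS:
        sc = packaged_scenario(name)
        n_items = 0
        if sc.image_geom is not None:
            for idx, group, rep in sc.subject_table():
                scene = synthdata.generate_ish_scene(sc, idx)
                stem = f"{name}_{group}_{rep:02d}"
                io.write_image16(IMG_OUT / f"{stem}.tiff", scene.image)
                io.write_png_preview(IMG_OUT / f"{stem}.png", scene.image)
                scene.truth.to_csv(TEXT_OUT / f"{stem}_truth.csv",
                                   index=False)
                n_items += 1
        for assay in sc.qpcr:
            synthdata.generate_ct_table(sc, assay).to_csv(
                TEXT_OUT / f"{name}_{assay}_ct.csv", index=False)
            n_items += 1
        if sc.transcriptome is not None:
            utrs, de, _ = synthdata.generate_transcriptome(sc, MIR124_3P)
            # the full 12000-gene FASTA is bulky; keep it in scratch
            io.write_fasta(utrs, IMG_OUT / f"{name}_utrs.fasta")
            de.to_csv(IMG_OUT / f"{name}_de.csv", index=False)
            n_items += 1
        print(f"{name}: wrote {n_items} input set(s)")


if __name__ == "__main__":
    main()
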