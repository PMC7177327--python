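"""File I/O: FASTA (RNA), Ct/DE CSV tables, 16-bit grayscale TIFF, YAML, JSON.

All round-trips are lossless at the stated precision: sequences by identity,
CSV numerics at full double precision, images to within one 16-bit step.
DNA-alphabet FASTA is transliterated T -> U on load with a logged notice.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("perimir")

CT_COLUMNS = ["sample_id", "group_label", "assay", "ct"]
DE_COLUMNS = ["gene_id", "log2fc", "p"]


def read_fasta(path) -> dict[str, str]:
    """id -> RNA sequence; DNA T is transliterated to U (logged)."""
    seqs: dict[str, str] = {}
    n_dna = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if "T" in s:
            n_dna += 1
            s = s.replace("T", "U")
        bad = set(s) - set("ACGU")
        if bad:
            raise ValueError(f"record {rec.id!r}: non-nucleotide characters "
                             f"{sorted(bad)}")
        if not s:
            raise ValueError(f"record {rec.id!r} is empty")
        seqs[rec.id] = s
    if n_dna:
        log.info("transliterated T->U in %d FASTA record(s) from %s",
                 n_dna, path)
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def _read_csv_checked(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def read_ct_table(path) -> pd.DataFrame:
    df = _read_csv_checked(path, CT_COLUMNS)
    if (df["ct"] <= 0).any():
        bad = df.index[df["ct"] <= 0].tolist()
        raise ValueError(f"{path}: non-positive Ct at rows {bad}")
    return df


def read_de_table(path) -> pd.DataFrame:
    df = _read_csv_checked(path, DE_COLUMNS)
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        bad = df.index[(df["p"] <= 0) | (df["p"] > 1)].tolist()
        raise ValueError(f"{path}: p outside (0, 1] at rows {bad}")
    return df


def read_gene_set(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_image16(path, image: np.ndarray) -> None:
    """[0, 1] grayscale grid -> 16-bit TIFF."""
    img = np.asarray(image, float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    tifffile.imwrite(str(path), np.round(img * 65535.0).astype(np.uint16))


def read_image16(path) -> np.ndarray:
    raw = tifffile.imread(str(path))
    if raw.dtype != np.uint16:
        raise ValueError(f"{path}: expected 16-bit grayscale TIFF")
    return raw.astype(float) / 65535.0


def write_png_preview(path, image: np.ndarray) -> None:
    from PIL import Image
    img = np.clip(np.asarray(image, float), 0, 1)
    Image.fromarray((img * 255).astype(np.uint8), mode="L").save(str(path))


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default,
                                     allow_nan=True) + "\n")
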