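"""Canonical miRNA seed-site scanning of 3'UTRs and DE-table overlap.

Site types follow the canonical hierarchy (strongest first):

    8mer     : seed match (miRNA nt 2-7) + complement of nt 8 on the 5' side
               of the target site + adenosine opposite position 1 (t1A)
    7mer-m8  : seed match + nt-8 complement, no t1A
    7mer-A1  : seed match + t1A, no nt-8 complement
    6mer     : seed match only

``start`` is the 1-based position of the site's 5'-most target nucleotide,
so an 8mer/7mer-m8 starts one nucleotide before its 6mer core.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "SiteHit",
    "OverlapCounts",
    "mirna_from_probe",
    "seed_site_6mer",
    "scan_sites",
    "predicted_target_set",
    "de_overlap",
]

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
SITE_STRENGTH = {"8mer": 4, "7mer-m8": 3, "7mer-A1": 2, "6mer": 1}


@dataclass(frozen=True)
class SiteHit:
    transcript_id: str
    start: int  # 1-based, 5'-most target nucleotide of the site
    site_type: str


@dataclass
class OverlapCounts:
    n_predicted_targets: int
    n_up_sig: int
    n_down_sig: int
    n_up_targets: int
    n_down_targets: int
    n_targets_missing_from_de: int
    alpha: float

    @property
    def fraction_targets_regulated(self) -> float:
        if self.n_predicted_targets == 0:
            return 0.0
        return (self.n_up_targets + self.n_down_targets) / self.n_predicted_targets


def _validate_rna(seq: str, what: str = "sequence") -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"non-RNA characters in {what}: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    seq = _validate_rna(seq)
    return "".join(_RNA_COMPLEMENT[c] for c in reversed(seq))


def mirna_from_probe(probe_sequence: str) -> str:
    """Mature miRNA from an antisense detection-probe sequence.

    Chemistry markup (LNA capitals / 2'OMe lower case) is stripped by
    uppercasing; the mature strand is the reverse complement of the probe.
    """
    return reverse_complement(probe_sequence)


def seed_site_6mer(mirna: str) -> str:
    """Target-strand 6mer seed match: reverse complement of miRNA nt 2-7."""
    mirna = _validate_rna(mirna, "miRNA")
    if len(mirna) < 8:
        raise ValueError("miRNA must be at least 8 nt to define seed sites")
    return reverse_complement(mirna[1:7])


def scan_sites(utr: str, mirna: str) -> list[SiteHit]:
    """All canonical seed sites of ``mirna`` in one 3'UTR.

    A locus is a distinct 6mer-match start; each locus is reported once at
    its strongest site type.  Returns [] for sequences too short to host a
    site.
    """
    utr = _validate_rna(utr, "UTR")
    mirna = _validate_rna(mirna, "miRNA")
    core = seed_site_6mer(mirna)
    m8_complement = _RNA_COMPLEMENT[mirna[7]]
    hits: list[SiteHit] = []
    pos = utr.find(core)
    while pos != -1:
        has_m8 = pos >= 1 and utr[pos - 1] == m8_complement
        has_a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
        if has_m8 and has_a1:
            site_type = "8mer"
        elif has_m8:
            site_type = "7mer-m8"
        elif has_a1:
            site_type = "7mer-A1"
        else:
            site_type = "6mer"
        start = pos if has_m8 else pos + 1  # to 1-based, minus one for the m8 nt
        hits.append(SiteHit("", start, site_type))
        pos = utr.find(core, pos + 1)
    return hits


def predicted_target_set(utrs: dict[str, str], mirna: str) -> set[str]:
    """Transcript ids whose 3'UTR carries at least one canonical seed site."""
    return {
        tid for tid, seq in utrs.items() if scan_sites(seq, mirna)
    }


def sites_table(utrs: dict[str, str], mirna: str) -> pd.DataFrame:
    """Long-form table of every site in a UTR set."""
    rows = [
        {"transcript_id": tid, "start": h.start, "site_type": h.site_type}
        for tid, seq in utrs.items()
        for h in scan_sites(seq, mirna)
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "start", "site_type"])


def de_overlap(de: pd.DataFrame, targets: set[str],
               alpha: float = 0.05) -> OverlapCounts:
    """Overlap of a predicted-target set with a differential-expression table.

    up = p < alpha and log2fc > 0; down = p < alpha and log2fc < 0.  Target
    ids absent from the DE table are counted and reported, not an error.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    for col in ("gene_id", "log2fc", "p"):
        if col not in de.columns:
            raise ValueError(f"DE table missing column {col!r}")
    if de["gene_id"].duplicated().any():
        raise ValueError("DE table gene_id values must be unique")
    sig = de["p"] < alpha
    up = sig & (de["log2fc"] > 0)
    down = sig & (de["log2fc"] < 0)
    is_target = de["gene_id"].isin(targets)
    missing = len(targets - set(de["gene_id"]))
    return OverlapCounts(
        n_predicted_targets=len(targets),
        n_up_sig=int(up.sum()),
        n_down_sig=int(down.sum()),
        n_up_targets=int((up & is_target).sum()),
        n_down_targets=int((down & is_target).sum()),
        n_targets_missing_from_de=missing,
        alpha=alpha,
    )
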