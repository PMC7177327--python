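"""Preranked gene-set enrichment: weighted KS running sum with permutations.

Genes are ranked by a signed evidence score (default sign(log2fc) x -log10 p,
descending).  The enrichment score (ES) is the signed maximal deviation of a
running sum that increments by |score|^w / sum_hits |score|^w at set members
("hits") and decrements by 1/(N - N_hits) elsewhere.  Significance uses
gene-set permutation: the null is the ES of random same-size sets drawn from
the ranked list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RankedList", "GseaResult", "rank_genes", "enrichment_score",
           "gsea_significance"]


@dataclass
class RankedList:
    gene_ids: list[str]
    scores: np.ndarray  # descending, aligned with gene_ids

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        if len(self.gene_ids) != self.scores.size:
            raise ValueError("gene_ids and scores must align")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be sorted descending")


@dataclass
class GseaResult:
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]
    nes: float | None = None
    p_perm: float | None = None
    fdr: float | None = None
    n_perm: int = 0
    extras: dict = field(default_factory=dict)


def rank_genes(de: pd.DataFrame, metric: str = "signed_logp") -> RankedList:
    """Build a ranked list from a DE table.

    metric 'signed_logp' (default): sign(log2fc) x -log10 p; metric 'log2fc':
    the fold-change itself.  Zero p-values are clamped to the smallest
    positive float.  Ties are broken by gene id so the order is deterministic.
    """
    if (de["p"] <= 0).any():
        de = de.copy()
        de.loc[de["p"] <= 0, "p"] = np.finfo(float).tiny
    if metric == "signed_logp":
        score = np.sign(de["log2fc"]) * (-np.log10(de["p"]))
    elif metric == "log2fc":
        score = de["log2fc"].astype(float)
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    order = pd.DataFrame({"gene_id": de["gene_id"], "score": score})
    order = order.sort_values(["score", "gene_id"],
                              ascending=[False, True], kind="mergesort")
    return RankedList(order["gene_id"].tolist(), order["score"].to_numpy())


def _running_sum(scores: np.ndarray, hit_mask: np.ndarray,
                 weight: float) -> np.ndarray:
    w = np.abs(scores) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    denom_hit = hit_w.sum()
    if denom_hit == 0:
        # all-zero scores inside the set with weight > 0: fall back to counts
        hit_w = hit_mask.astype(float)
        denom_hit = hit_w.sum()
    n_miss = (~hit_mask).sum()
    step = hit_w / denom_hit - np.where(hit_mask, 0.0, 1.0 / n_miss)
    return np.cumsum(step)


def enrichment_score(ranked: RankedList, gene_set,
                     weight: float = 1.0) -> GseaResult:
    """ES and running sum for one gene set (no permutations)."""
    gene_set = set(gene_set)
    hit_mask = np.fromiter((g in gene_set for g in ranked.gene_ids),
                           bool, count=len(ranked.gene_ids))
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == hit_mask.size:
        raise ValueError("gene set must cover some but not all ranked genes")
    rs = _running_sum(ranked.scores, hit_mask, weight)
    i = int(np.abs(rs).argmax())
    es = float(rs[i])
    if es >= 0:
        leading = [g for g, h in zip(ranked.gene_ids[: i + 1], hit_mask) if h]
    else:
        leading = [g for g, h in zip(ranked.gene_ids[i:], hit_mask[i:]) if h]
    return GseaResult(es=es, running_sum=rs, leading_edge=leading)


def gsea_significance(ranked: RankedList, gene_set, n_perm: int = 1000,
                      seed: int | np.random.Generator = 0,
                      weight: float = 1.0) -> GseaResult:
    """Gene-set-permutation significance for one set.

    p is the one-sided tail fraction of null ES of the observed sign, with
    add-one correction.  NES = ES / mean |null ES of the same sign|; FDR is
    the same-sign null tail fraction at |NES|, the standard single-set
    preranked convention.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    res = enrichment_score(ranked, gene_set, weight=weight)
    n = len(ranked.gene_ids)
    n_hits = sum(g in set(gene_set) for g in ranked.gene_ids)
    null = np.empty(n_perm)
    base = np.zeros(n, bool)
    for k in range(n_perm):
        mask = base.copy()
        mask[rng.choice(n, size=n_hits, replace=False)] = True
        rs = _running_sum(ranked.scores, mask, weight)
        null[k] = rs[np.abs(rs).argmax()]
    same_sign = null >= 0 if res.es >= 0 else null < 0
    if not same_sign.any():
        raise ValueError("degenerate permutation null: no same-sign ES")
    tail = (np.abs(null[same_sign]) >= abs(res.es)).sum()
    p = (tail + 1) / (same_sign.sum() + 1)
    mean_same = np.abs(null[same_sign]).mean()
    nes = res.es / mean_same
    null_nes = np.abs(null[same_sign]) / mean_same
    fdr = min(1.0, float((null_nes >= abs(nes)).mean()))
    res.nes = float(nes)
    res.p_perm = float(p)
    res.fdr = fdr
    res.n_perm = n_perm
    return res
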