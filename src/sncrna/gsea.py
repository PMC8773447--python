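"""Signed-rank gene list construction and pre-ranked gene-set enrichment.

The ranking metric is built from a DE table the way the emulated
analysis did: genes are split by fold-change sign, each sign group is
ordered by p-value, and the rank within the group (largest p closest to
zero) becomes the metric magnitude — downregulated genes carry a minus
sign.  The enrichment score is the signed extremum of the standard
weighted Kolmogorov-Smirnov running sum: walking the list from the top,
set members add |metric|^w normalized by the set's total weight, and
non-members subtract 1/(N - set size).  Significance comes from gene-set
permutation: random same-size sets drawn from the ranked universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import bh_fdr


@dataclass
class GseaResult:
    gene_set: str
    es: float
    p_perm: float
    fdr: float
    n_permutations: int
    running_sum: np.ndarray


def build_ranked_list(de_table: pd.DataFrame) -> pd.DataFrame:
    """Signed integer ranking metric from a DE table.

    Positive-fold-change genes get metric +r and negative-FC genes -r,
    where r ranks p descending within the sign group (the largest p gets
    r = 1, so low-significance genes sit closest to zero).  Zero-FC genes
    get metric 0.  Returns a DataFrame (gene index, ``metric`` column)
    sorted by metric descending, ties broken by gene identifier.
    """
    if de_table.index.has_duplicates:
        dups = de_table.index[de_table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate genes in DE table: {dups}")
    if not np.isfinite(de_table["log2fc"]).all() or \
            not np.isfinite(de_table["p_value"]).all():
        raise ValueError("log2fc and p_value must be finite for ranking")
    metric = pd.Series(0, index=de_table.index, dtype=int)
    for sign in (+1, -1):
        grp = de_table[np.sign(de_table["log2fc"]) == sign]
        # largest p -> rank 1 (closest to zero); ties broken by gene id
        order = grp.assign(_gene=grp.index).sort_values(
            ["p_value", "_gene"], ascending=[False, True], kind="stable"
        )
        metric.loc[order.index] = sign * np.arange(1, len(order) + 1)
    out = pd.DataFrame({"metric": metric})
    out["_gene"] = out.index
    out = out.sort_values(["metric", "_gene"], ascending=[False, True],
                          kind="stable").drop(columns="_gene")
    return out


def enrichment_score(
    ranked: pd.DataFrame, gene_set: Iterable[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and its running sum.

    Hits add |metric|^w / sum over the set of |metric|^w; misses subtract
    1/(N - |set|); the ES is the running sum's signed extremum.  A set
    whose members all carry metric 0 falls back to equal hit weights.
    """
    genes = ranked.index.to_numpy()
    metric = ranked["metric"].to_numpy(dtype=float)
    in_set = np.isin(genes, list(set(gene_set)))
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    if n_hit == len(genes):
        raise ValueError("gene set covers the whole ranked list")
    w = np.abs(metric) ** weight
    hit_w = np.where(in_set, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all set members at metric 0
        hit_w = in_set.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~in_set) / float(len(genes) - n_hit)
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def permutation_significance(
    ranked: pd.DataFrame,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    rng_seed=0,
    weight: float = 1.0,
    name: str = "set",
) -> GseaResult:
    """Gene-set permutation p-value for one set (FDR = p for a single set).

    The null draws random gene sets of the observed in-list size from the
    ranked universe.  The p-value compares the observed score against the
    same-signed portion of the null — ``p = (1 + #{|ES_null| >= |ES_obs|,
    same sign}) / (1 + #{same sign})`` — so that a null score is, to
    permutation resolution, uniformly distributed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    es_obs, running = enrichment_score(ranked, gene_set, weight)
    genes = ranked.index.to_numpy()
    n_hit = int(np.isin(genes, list(set(gene_set))).sum())
    exceed = 0
    same_sign = 0
    for _ in range(n_perm):
        null_set = rng.choice(genes, size=n_hit, replace=False)
        es_null, _ = enrichment_score(ranked, null_set, weight)
        if np.sign(es_null) == np.sign(es_obs):
            same_sign += 1
            if abs(es_null) >= abs(es_obs):
                exceed += 1
    p = (1 + exceed) / (1 + same_sign)
    return GseaResult(name, es_obs, p, p, n_perm, running)


def gsea_multi(
    ranked: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    rng_seed=0,
    weight: float = 1.0,
) -> list[GseaResult]:
    """Permutation GSEA over several sets with BH FDR across them."""
    rng = np.random.default_rng(rng_seed)
    results = [
        permutation_significance(ranked, gs, n_perm, rng, weight, name)
        for name, gs in gene_sets.items()
    ]
    fdrs = bh_fdr([r.p_perm for r in results])
    for r, f in zip(results, fdrs):
        r.fdr = float(f)
    return results
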