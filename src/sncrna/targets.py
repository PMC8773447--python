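"""Seed-based target prediction for tRFs and miRNAs.

tRF targeting follows the sliding-seed approach: every 8-nt window along
the fragment is a candidate seed, and a 3'UTR is a target when it
contains the exact reverse complement of the seed.  miRNA targeting uses
the canonical seed (nucleotides 2-8) with the standard site taxonomy:
7mer-m8 (match to the reverse complement of nt 2-8), 7mer-A1 (match to
the reverse complement of nt 2-7 followed by an A in the UTR), and 8mer
(both).  No conservation or context scoring is applied — prediction is
pure seed complementarity, which is all the downstream intersection and
enrichment stages need.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .core_io import MirnaReference, UtrReference, logger


@dataclass(frozen=True)
class SeedWindow:
    parent: str
    offset: int      # 0-based start within the small RNA
    seed_seq: str    # 5'->3'


@dataclass(frozen=True)
class TargetHit:
    window: SeedWindow
    gene: str
    utr_positions: tuple[int, ...]
    match_type: str  # 8mer-exact | 8mer | 7mer-m8 | 7mer-A1


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def enumerate_windows(parent: str, seq: str, seed_length: int = 8) -> list[SeedWindow]:
    """All seed windows at offsets 0 .. L-seed_length along the small RNA."""
    if len(seq) < seed_length:
        raise ValueError(
            f"{parent}: sequence of length {len(seq)} shorter than the "
            f"{seed_length}-nt seed"
        )
    return [SeedWindow(parent, i, seq[i:i + seed_length])
            for i in range(len(seq) - seed_length + 1)]


def _find_all(haystack: str, needle: str) -> tuple[int, ...]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return tuple(hits)


def scan_utrs(window: SeedWindow, utrs: Sequence[UtrReference]) -> list[TargetHit]:
    """Exact reverse-complement matches of one seed window in each UTR."""
    site = revcomp(window.seed_seq)
    hits = []
    for utr in utrs:
        positions = _find_all(utr.utr_seq, site)
        if positions:
            hits.append(TargetHit(window, utr.gene, positions, "8mer-exact"))
    return hits


def mirna_seed_sites(
    mirna: MirnaReference, utrs: Sequence[UtrReference]
) -> list[TargetHit]:
    """Canonical-seed site scan for one miRNA (8mer / 7mer-m8 / 7mer-A1).

    The seed is miRNA nt 2-8 (0-based positions 1-7).  A 7mer-m8 site
    matches revcomp(nt 2-8); a 7mer-A1 site matches revcomp(nt 2-7)
    followed by an A in the UTR; an 8mer satisfies both.
    """
    if len(mirna) < 8:
        raise ValueError(f"{mirna.name}: too short for a 2-8 seed")
    seed28 = mirna.canonical_seq[1:8]
    seed27 = mirna.canonical_seq[1:7]
    site_m8 = revcomp(seed28)           # 7 nt
    site_a1 = revcomp(seed27) + "A"     # 7 nt ending in A
    window = SeedWindow(mirna.name, 1, seed28)
    hits = []
    for utr in utrs:
        m8_pos = set(_find_all(utr.utr_seq, site_m8))
        a1_pos = set(_find_all(utr.utr_seq, site_a1))
        # an 8mer site matches revcomp(nt 2-8) immediately followed by A,
        # i.e. an m8 match whose m8 start also starts site_m8 + "A"
        eight = {p for p in m8_pos
                 if utr.utr_seq[p:p + 8] == site_m8 + "A"}
        m8_only = m8_pos - eight
        # site_a1 occurs inside every 8mer one base downstream; do not
        # double-report those
        a1_only = {p for p in a1_pos if (p - 1) not in eight}
        for positions, mtype in ((eight, "8mer"), (m8_only, "7mer-m8"),
                                 (a1_only, "7mer-A1")):
            if positions:
                hits.append(TargetHit(window, utr.gene,
                                      tuple(sorted(positions)), mtype))
    return hits


def predicted_genes(hits: Sequence[TargetHit]) -> list[str]:
    """Unique gene identifiers among hits, sorted."""
    return sorted({h.gene for h in hits})


def intersect_with_de(
    hits: Sequence[TargetHit],
    de_table: pd.DataFrame,
    small_rna_direction: int,
    fdr_threshold: float = 0.05,
) -> dict:
    """Intersect predicted targets with DE genes of the opposite sign.

    ``small_rna_direction`` is +1 for an upregulated small RNA, -1 for a
    downregulated one; candidate target genes must be significant (FDR
    below threshold) with fold change of the opposite sign.  Returns the
    candidate list, counts, and the percentage to one decimal (as in
    "12/178 (6.7%)").
    """
    if small_rna_direction not in (+1, -1):
        raise ValueError("small_rna_direction must be +1 or -1")
    predicted = predicted_genes(hits)
    sig = de_table[(de_table["fdr"] < fdr_threshold)]
    wanted_sign = -small_rna_direction
    opposite = set(sig.index[np.sign(sig["log2fc"]) == wanted_sign])
    candidates = [g for g in predicted if g in opposite]
    pct = round(100.0 * len(candidates) / len(predicted), 1) if predicted else 0.0
    return {
        "candidates": candidates,
        "n_candidates": len(candidates),
        "n_predicted": len(predicted),
        "percent": pct,
        "display": f"{len(candidates)}/{len(predicted)} ({pct}%)",
    }


def build_target_gene_list(
    trf_seqs: dict[str, str],
    utrs: Sequence[UtrReference],
    seed_length: int = 8,
) -> list[str]:
    """Combined target gene list from the FIRST seed window of each tRF.

    The union over fragments is de-duplicated and sorted; an empty UTR
    set yields an empty list with a warning.
    """
    if not utrs:
        logger.warning("build_target_gene_list: empty UTR set")
        return []
    genes: set[str] = set()
    for name, seq in trf_seqs.items():
        first = enumerate_windows(name, seq, seed_length)[0]
        genes.update(h.gene for h in scan_utrs(first, utrs))
    return sorted(genes)
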