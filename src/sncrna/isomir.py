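"""IsomiR cataloguing: map reads to canonical miRNAs, classify variants,
apply the retention rule, and summarize canonical fractions and top isomiRs.

An isomiR is a read that differs from the canonical mature miRNA at its
5' start (``start_shift``), its 3' end (``end_shift``), or by internal
substitutions.  Shifts are signed offsets of the read's termini relative
to the canonical termini in canonical coordinates: a negative
``start_shift`` is a 5' extension, a positive ``end_shift`` a 3'
addition.  Mapping is ungapped: the read is slid along each canonical
sequence and the placement with the fewest internal mismatches (then the
smallest total terminal shift, then the first reference in input order)
wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import MirnaReference, logger

LABEL_CANONICAL = "canonical"
LABEL_5P = "5p-isomir"
LABEL_3P = "3p-isomir"
LABEL_MIXED = "mixed"
LABEL_INTERNAL = "internal-edit"


@dataclass(frozen=True)
class ReadMapping:
    """Placement of a read against one canonical miRNA."""

    mirna: str
    start_shift: int
    end_shift: int
    internal_edits: tuple[tuple[int, str, str], ...]
    # (position within canonical, canonical base, read base)


@dataclass(frozen=True)
class IsomirSpecies:
    mirna: str
    read_seq: str
    start_shift: int
    end_shift: int
    internal_edits: tuple[tuple[int, str, str], ...]
    label: str


def map_read(
    read: str,
    refs: Sequence[MirnaReference],
    max_internal_mismatches: int = 2,
    max_terminal_shift: int = 4,
) -> ReadMapping | None:
    """Best ungapped placement of ``read`` against the canonical set.

    Returns ``None`` when no placement within the shift/mismatch budget
    exists (an unmapped read is a value, not an error).
    """
    if not read:
        raise ValueError("empty read")
    best: tuple[int, int, int, ReadMapping] | None = None
    for ref_idx, ref in enumerate(refs):
        c = ref.canonical_seq
        for start_shift in range(-max_terminal_shift, max_terminal_shift + 1):
            end_shift = start_shift + len(read) - len(c)
            if abs(end_shift) > max_terminal_shift:
                continue
            lo = max(0, start_shift)
            hi = min(len(c), start_shift + len(read))
            if hi <= lo:
                continue
            edits = []
            for pos in range(lo, hi):
                rb = read[pos - start_shift]
                if rb != c[pos]:
                    edits.append((pos, c[pos], rb))
                    if len(edits) > max_internal_mismatches:
                        break
            if len(edits) > max_internal_mismatches:
                continue
            key = (len(edits), abs(start_shift) + abs(end_shift), ref_idx)
            if best is None or key < best[:3]:
                best = (*key, ReadMapping(ref.name, start_shift, end_shift,
                                          tuple(edits)))
    return best[3] if best else None


def classify_species(read: str, mapping: ReadMapping) -> IsomirSpecies:
    """Assign the variant class from the mapped shifts and edits."""
    s, e = mapping.start_shift, mapping.end_shift
    if s == 0 and e == 0 and not mapping.internal_edits:
        label = LABEL_CANONICAL
    elif s != 0 and e != 0:
        label = LABEL_MIXED
    elif e != 0:
        label = LABEL_3P
    elif s != 0:
        label = LABEL_5P
    else:
        label = LABEL_INTERNAL
    return IsomirSpecies(mapping.mirna, read, s, e, mapping.internal_edits, label)


def profile_reads(
    read_table: pd.DataFrame,
    refs: Sequence[MirnaReference],
    max_internal_mismatches: int = 2,
    max_terminal_shift: int = 4,
) -> pd.DataFrame:
    """Map and classify a (sequence, sample, count) read table.

    Returns a long table with one row per (miRNA, species, sample):
    columns mirna, sequence, label, start_shift, end_shift, n_edits,
    sample, count.  Unmapped reads are dropped with a logged total.
    """
    cache: dict[str, IsomirSpecies | None] = {}
    rows = []
    unmapped = 0
    for seq, sample, count in read_table[["sequence", "sample", "count"]].itertuples(
            index=False):
        if seq not in cache:
            m = map_read(seq, refs, max_internal_mismatches, max_terminal_shift)
            cache[seq] = classify_species(seq, m) if m else None
        sp = cache[seq]
        if sp is None:
            unmapped += int(count)
            continue
        rows.append((sp.mirna, seq, sp.label, sp.start_shift, sp.end_shift,
                     len(sp.internal_edits), sample, int(count)))
    if unmapped:
        logger.info("isomir: %d reads unmapped", unmapped)
    return pd.DataFrame(
        rows, columns=["mirna", "sequence", "label", "start_shift",
                       "end_shift", "n_edits", "sample", "count"],
    )


def apply_retention_filter(
    profile: pd.DataFrame, fraction: float = 0.05
) -> pd.DataFrame:
    """Keep species reaching ``fraction`` of the miRNA's reads in >=1 sample.

    The rule is evaluated per sample against that sample's total mapped
    reads for the miRNA (boundary inclusive); a species passing anywhere
    is retained everywhere, with raw counts preserved.  Adds a boolean
    ``retained`` column.
    """
    if profile.empty:
        return profile.assign(retained=pd.Series(dtype=bool))
    totals = profile.groupby(["mirna", "sample"])["count"].transform("sum")
    frac = profile["count"] / totals
    passing = profile.loc[frac >= fraction, ["mirna", "sequence"]].drop_duplicates()
    keys = set(map(tuple, passing.to_numpy()))
    retained = [
        (m, s) in keys for m, s in profile[["mirna", "sequence"]].to_numpy()
    ]
    return profile.assign(retained=retained)


def _species_matrix(profile: pd.DataFrame) -> pd.DataFrame:
    return profile.pivot_table(
        index=["mirna", "sequence", "label"], columns="sample",
        values="count", aggfunc="sum", fill_value=0,
    )


def canonical_percentage(
    profile: pd.DataFrame, mirna: str,
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample canonical read percentage (0-100), with group mean (SD).

    Returns a table with columns sample, percent, and (when ``groups`` is
    given) group; group summaries are attached as ``.attrs['summary']``
    mapping group -> (mean, sd).
    """
    sub = profile[profile["mirna"] == mirna]
    if sub.empty:
        raise ValueError(f"no reads mapped to {mirna!r}")
    totals = sub.groupby("sample")["count"].sum()
    canon = (sub[sub["label"] == LABEL_CANONICAL]
             .groupby("sample")["count"].sum()
             .reindex(totals.index, fill_value=0))
    pct = 100.0 * canon / totals
    out = pd.DataFrame({"sample": pct.index, "percent": pct.to_numpy()})
    if groups is not None:
        out["group"] = out["sample"].map(groups)
        out.attrs["summary"] = {
            g: (float(v["percent"].mean()), float(v["percent"].std(ddof=1)))
            for g, v in out.groupby("group")
        }
    return out


def top_isomirs(
    profile: pd.DataFrame,
    mirna: str,
    tbi_samples: Sequence[str],
    k: int = 6,
    max_shortlist: int = 4,
) -> pd.DataFrame:
    """Shortlist the top isomiRs by TBI read abundance.

    The top ``k`` non-canonical species by summed TBI count are listed;
    among them, those detected (count > 0) in every TBI sample are kept,
    truncated to ``max_shortlist``, in descending count order.
    """
    sub = profile[(profile["mirna"] == mirna)
                  & (profile["label"] != LABEL_CANONICAL)]
    if sub.empty:
        logger.warning("top_isomirs: no isomiR species for %s", mirna)
        return pd.DataFrame(columns=["sequence", "label", "tbi_total"])
    mat = sub.pivot_table(index="sequence", columns="sample", values="count",
                          aggfunc="sum", fill_value=0)
    mat = mat.reindex(columns=list(tbi_samples), fill_value=0)
    tbi_total = mat.sum(axis=1).sort_values(ascending=False, kind="stable")
    top_k = tbi_total.iloc[:k]
    in_all = [s for s in top_k.index if (mat.loc[s] > 0).all()]
    if not in_all:
        logger.warning("top_isomirs: no isomiR of %s present in all TBI "
                       "samples", mirna)
    shortlist = in_all[:max_shortlist]
    labels = sub.drop_duplicates("sequence").set_index("sequence")["label"]
    return pd.DataFrame({
        "sequence": shortlist,
        "label": [labels[s] for s in shortlist],
        "tbi_total": [int(top_k[s]) for s in shortlist],
    })


def full_profile_counts(profile: pd.DataFrame, mirna: str) -> pd.Series:
    """Per-sample total of canonical plus retained isomiR reads.

    The full-profile total (all isomiRs included) is what correlates with
    behavioral outcome downstream.  Requires ``apply_retention_filter``
    to have been run.
    """
    if "retained" not in profile.columns:
        raise ValueError("run apply_retention_filter first")
    sub = profile[(profile["mirna"] == mirna)
                  & ((profile["label"] == LABEL_CANONICAL) | profile["retained"])]
    return sub.groupby("sample")["count"].sum()
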