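"""tRNA-derived fragment (tRF) calling from positional alignment coverage.

The original analysis spotted cleavage sites by eye in a genome browser;
here the call is made reproducible: the candidate cleavage site is the
modal read 5' start, and a site is called when the fraction of reads
starting within +/-1 nt of the candidate reaches a threshold (default
0.5).  Fragments reaching the tRNA 3' end are 3'tRFs — cleavage in the
variable region of a ~75 nt tRNA yields the characteristic 27-28 nt 3'
fragments — fragments from the 5' end are 5'tRFs, anything else internal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CountMatrix, TrnaReference, logger

CLASS_3P = "3p-tRF"
CLASS_5P = "5p-tRF"
CLASS_INTERNAL = "internal"


@dataclass
class TrnaCoverage:
    """Positional read tallies for one tRNA in one sample.

    ``start_counts[i]`` counts read 5' starts at position i,
    ``end_counts[i]`` read 3' ends (exclusive) at i, and ``depth[i]`` the
    number of reads covering i.  Reads extending past the reference are
    clipped; the clipped read count is recorded.
    """

    trna: str
    sample: str
    length: int
    start_counts: np.ndarray
    end_counts: np.ndarray
    depth: np.ndarray
    n_reads: int
    n_clipped: int = 0


@dataclass
class TrfCall:
    trna: str
    sample: str
    cleavage_pos: int
    fragment: tuple[int, int]  # [cleavage_pos, length)
    fragment_class: str
    modal_length: int
    start_fraction: float
    in_variable_region: bool
    n_reads: int


@dataclass
class NoCall:
    trna: str
    sample: str
    reason: str


def build_coverage(
    alignments: pd.DataFrame, trna: TrnaReference, sample: str | None = None
) -> TrnaCoverage:
    """Tally read starts, ends and depth for one tRNA (optionally one sample).

    ``alignments`` has columns (trna, sample, start, end, count) with
    0-based half-open intervals.
    """
    sub = alignments[alignments["trna"] == trna.name]
    if sample is not None:
        sub = sub[sub["sample"] == sample]
    L = len(trna)
    starts = np.zeros(L, dtype=np.int64)
    ends = np.zeros(L + 1, dtype=np.int64)
    depth = np.zeros(L, dtype=np.int64)
    n_reads = 0
    n_clipped = 0
    for s, e, c in sub[["start", "end", "count"]].itertuples(index=False):
        if s < 0 or s >= L:
            raise ValueError(f"{trna.name}: read start {s} outside [0,{L})")
        if e > L:  # e.g. non-templated CCA on a reference stored without it
            n_clipped += int(c)
            e = L
        starts[s] += c
        ends[e] += c
        depth[s:e] += c
        n_reads += int(c)
    return TrnaCoverage(trna.name, sample or "*", L, starts, ends[: L + 1],
                        depth, n_reads, n_clipped)


def call_cleavage(
    coverage: TrnaCoverage,
    trna: TrnaReference,
    tau: float = 0.5,
    window: int = 1,
    min_reads: int = 50,
    end_tolerance: int = 2,
) -> TrfCall | NoCall:
    """Call the dominant cleavage site from a coverage profile.

    The candidate is the modal 5' start (smallest position on ties); the
    call is made iff the fraction of reads starting within
    ``candidate +/- window`` reaches ``tau``.  The fragment runs from the
    candidate to the tRNA 3' end; its class is 3'tRF when the 3' boundary
    is within ``end_tolerance`` nt of the tRNA end, 5'tRF when the 5'
    boundary is within ``end_tolerance`` of position 0, else internal.
    """
    if coverage.n_reads < min_reads:
        return NoCall(coverage.trna, coverage.sample,
                      f"only {coverage.n_reads} reads (< {min_reads})")
    candidate = int(np.argmax(coverage.start_counts))
    lo = max(0, candidate - window)
    hi = min(coverage.length, candidate + window + 1)
    frac = float(coverage.start_counts[lo:hi].sum()) / coverage.n_reads
    if frac < tau:
        return NoCall(coverage.trna, coverage.sample,
                      f"modal-start fraction {frac:.3f} < {tau}")
    # fragment 3' end = modal read end among reads starting at the candidate;
    # for the dominant 3'-fragment population this is the tRNA end.
    end = coverage.length
    ends_after = coverage.end_counts[candidate + 1:]
    if ends_after.sum() > 0:
        end = candidate + 1 + int(np.argmax(ends_after))
    if end >= coverage.length - end_tolerance:
        cls = CLASS_3P
        end = coverage.length
    elif candidate <= end_tolerance:
        cls = CLASS_5P
    else:
        cls = CLASS_INTERNAL
    vr_lo, vr_hi = trna.variable_region
    return TrfCall(
        trna=coverage.trna,
        sample=coverage.sample,
        cleavage_pos=candidate,
        fragment=(candidate, end),
        fragment_class=cls,
        modal_length=end - candidate,
        start_fraction=frac,
        in_variable_region=vr_lo <= candidate < vr_hi,
        n_reads=coverage.n_reads,
    )


def trf_count_matrix(
    alignments: pd.DataFrame, group_labels: dict[str, str]
) -> CountMatrix:
    """Aggregate fragment reads per tRNA into a DE-ready count matrix.

    One row per tRNA — the overall change in fragments originating from
    each tRNA is what gets tested — one column per sample.
    """
    if alignments.empty:
        logger.warning("trf_count_matrix: no alignments; empty matrix")
        return CountMatrix(pd.DataFrame(dtype=np.int64), {})
    pivot = alignments.pivot_table(
        index="trna", columns="sample", values="count",
        aggfunc="sum", fill_value=0,
    ).astype(np.int64)
    pivot = pivot.sort_index()
    return CountMatrix(pivot, group_labels)
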