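"""Domain types and file I/O shared by every pipeline stage.

All coordinates in this package are 0-based, half-open ``[start, end)``.
Sequences are stored 5'->3' in the DNA alphabet; RNA input (``U``) is
silently normalized to ``T`` on read-in so that miRBase-style RNA
references and genomic DNA references can be matched directly.

Downstream stages consume only the types defined here; no stage opens
files itself.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("sncrna")

DNA_ALPHABET = frozenset("ACGTN")

GROUP_TBI = "TBI"
GROUP_SHAM = "sham"
VALID_GROUPS = (GROUP_TBI, GROUP_SHAM)


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


def normalize_seq(seq: str, *, context: str = "sequence") -> str:
    """Upper-case a nucleotide string and map RNA U to DNA T.

    Raises ``ValueError`` if any character falls outside {A,C,G,T,U,N}.
    """
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(
            f"{context}: invalid nucleotide(s) {sorted(bad)} in {seq!r}"
        )
    return s


@dataclass(frozen=True)
class MirnaReference:
    """A canonical mature miRNA sequence (miRBase-style), DNA alphabet."""

    name: str
    canonical_seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("miRNA reference needs a non-empty name")
        object.__setattr__(
            self, "canonical_seq",
            normalize_seq(self.canonical_seq, context=f"miRNA {self.name}"),
        )
        if not self.canonical_seq:
            raise ValueError(f"miRNA {self.name}: empty sequence")

    def __len__(self) -> int:
        return len(self.canonical_seq)


@dataclass(frozen=True)
class TrnaReference:
    """A mature tRNA sequence with its variable-region interval.

    ``variable_region`` is 0-based half-open; ``has_cca`` records whether
    the stored sequence already carries the post-transcriptional 3' CCA.
    """

    name: str
    seq: str
    variable_region: tuple[int, int]
    has_cca: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "seq", normalize_seq(self.seq, context=f"tRNA {self.name}")
        )
        start, end = self.variable_region
        if not (0 <= start < end <= len(self.seq)):
            raise ValueError(
                f"tRNA {self.name}: variable region [{start},{end}) outside "
                f"sequence of length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class UtrReference:
    """A 3'UTR sequence attached to a gene identifier."""

    gene: str
    utr_seq: str

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("UTR reference needs a gene identifier")
        object.__setattr__(
            self, "utr_seq", normalize_seq(self.utr_seq, context=f"UTR {self.gene}")
        )
        if not self.utr_seq:
            raise ValueError(f"UTR {self.gene}: empty sequence")


class CountMatrix:
    """A features x samples matrix of non-negative integer counts.

    Wraps a pandas DataFrame (rows = features, columns = samples) plus a
    TBI/sham group label per sample.  Labels must be unique along both
    axes and counts must be non-negative integers.
    """

    def __init__(self, counts: pd.DataFrame, group_labels: Mapping[str, str]):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in counts.columns if s not in group_labels]
        if missing:
            raise ValueError(f"samples missing from group map: {missing}")
        bad = {s: group_labels[s] for s in counts.columns
               if group_labels[s] not in VALID_GROUPS}
        if bad:
            raise ValueError(
                f"group labels must be one of {VALID_GROUPS}, got {bad}"
            )
        self.counts = counts.astype(np.int64)
        self.groups = pd.Series(
            {s: group_labels[s] for s in counts.columns}, name="group"
        )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]

    def require_both_groups(self) -> None:
        for g in VALID_GROUPS:
            if not self.samples_in_group(g):
                raise ValueError(f"group {g!r} has no samples")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"CountMatrix({len(self.feature_ids)} features x "
                f"{len(self.sample_ids)} samples)")


@dataclass
class PipelineConfig:
    """Tunable thresholds shared across stages.

    isomir_retention_fraction
        keep an isomiR species only if it reaches this fraction of the
        miRNA's reads in at least one sample (default 0.05).
    cleavage_fraction_threshold
        minimum fraction of read 5' starts at the modal position (+/-1 nt)
        for a tRNA cleavage-site call (default 0.5).
    """

    rng_seed: int = 0
    isomir_retention_fraction: float = 0.05
    cleavage_fraction_threshold: float = 0.5
    fdr_threshold: float = 0.05
    seed_length: int = 8
    gsea_weight: float = 1.0
    gsea_permutations: int = 1000

    def __post_init__(self) -> None:
        for name in ("isomir_retention_fraction", "cleavage_fraction_threshold",
                     "fdr_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.seed_length < 6:
            raise ValueError("seed_length must be >= 6")
        if self.gsea_weight < 0:
            raise ValueError("gsea_weight must be non-negative")
        if self.gsea_permutations < 1:
            raise ValueError("gsea_permutations must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _header_lines(path: str) -> dict[str, int]:
    """Map FASTA identifiers to 1-based line numbers (for error messages)."""
    lines: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                ident = line[1:].split()[0] if line[1:].strip() else ""
                if not ident:
                    raise FastaParseError(f"{path}:{i}: empty FASTA header")
                if ident in lines:
                    raise FastaParseError(
                        f"{path}:{i}: duplicate FASTA identifier {ident!r} "
                        f"(first seen on line {lines[ident]})"
                    )
                lines[ident] = i
            elif line.strip() and not lines:
                raise FastaParseError(
                    f"{path}:{i}: sequence data before any FASTA header"
                )
    return lines


def read_fasta(path: str) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(identifier, sequence), ...]`` in file order.

    Sequences are upper-cased with U mapped to T.  Malformed headers,
    duplicate identifiers, and empty records raise ``FastaParseError``
    naming the line.
    """
    header_at = _header_lines(path)
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FastaParseError(
                f"{path}:{header_at.get(rec.id, '?')}: empty record {rec.id!r}"
            )
        records.append((rec.id, normalize_seq(seq, context=f"FASTA {rec.id}")))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Tab-separated tables
# ---------------------------------------------------------------------------

def read_count_table(path: str, group_map: Mapping[str, str]) -> CountMatrix:
    """Read a TSV count table (first column feature id, header = sample ids).

    Every cell must be an integer; a fractional cell raises with its
    (feature, sample) coordinates.  Each sample must appear in
    ``group_map``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = next(zip(*np.nonzero(numeric.isna().to_numpy())))
        raise ValueError(
            f"{path}: non-numeric count at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    frac = (numeric != numeric.round())
    if frac.any().any():
        r, c = next(zip(*np.nonzero(frac.to_numpy())))
        raise ValueError(
            f"{path}: non-integer count at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    return CountMatrix(numeric.astype(np.int64), group_map)


def write_count_table(matrix: CountMatrix, path: str) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="feature")


def read_read_table(path: str) -> pd.DataFrame:
    """Read a small-RNA read table TSV: columns sequence, sample, count."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "sample": str})
    expected = {"sequence", "sample", "count"}
    if not expected.issubset(df.columns):
        raise ValueError(
            f"{path}: read table needs columns {sorted(expected)}, "
            f"found {list(df.columns)}"
        )
    df["sequence"] = df["sequence"].map(lambda s: normalize_seq(s))
    df["count"] = df["count"].astype(np.int64)
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative read counts")
    return df


def read_alignment_table(path: str) -> pd.DataFrame:
    """Read a per-tRNA positional alignment TSV: trna, sample, start, end, count."""
    df = pd.read_csv(path, sep="\t", dtype={"trna": str, "sample": str})
    expected = {"trna", "sample", "start", "end", "count"}
    if not expected.issubset(df.columns):
        raise ValueError(
            f"{path}: alignment table needs columns {sorted(expected)}, "
            f"found {list(df.columns)}"
        )
    for col in ("start", "end", "count"):
        df[col] = df[col].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: alignment intervals must satisfy start < end")
    return df
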