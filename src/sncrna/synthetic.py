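"""Synthetic inputs with the statistical structure the pipeline assumes.

Emulates a chronic-TBI small-RNA study: two groups of six animals,
negative-binomial sequencing counts with planted fold changes, multinomial
isomiR read mixtures around a canonical miRNA, tRNA alignment tables with
a dominant cleavage site in the variable region (yielding 27-28 nt 3'
fragments), ddPCR copy numbers and qPCR Ct values with planted fold
changes, and behavioral scores coupled to expression through a Gaussian
copula so that a target Spearman correlation is planted exactly in the
population.

Every generator takes an explicit seed (or ``numpy.random.Generator``)
and is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountMatrix, GROUP_SHAM, GROUP_TBI, MirnaReference, TrnaReference

DEFAULT_READS_PER_SAMPLE = 100_000  # depth per sample; configurable


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SynthDesign:
    """Parameters of a synthetic two-group small-RNA experiment.

    Defaults mirror the emulated study design: 6 TBI vs 6 sham animals,
    negative-binomial counts with dispersion 0.1 (variance mu + phi*mu^2)
    and baseline mean 500.
    """

    n_tbi: int = 6
    n_sham: int = 6
    n_features: int = 300
    planted_de: list[tuple[str, float]] = field(default_factory=list)
    # (feature_id, signed log2 fold change in TBI vs sham)
    nb_dispersion: float = 0.1
    baseline_mean: float = 500.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.n_tbi < 1 or self.n_sham < 1:
            raise ValueError("both groups need at least one sample")


def _draw_nb(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (var = mu + phi*mu^2)."""
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def gen_count_matrix(design: SynthDesign) -> CountMatrix:
    """Simulate a features x samples NB count matrix with planted DE.

    TBI-group means are the baseline shifted by the planted log2 fold
    change; sham means are the baseline.  Feature ids default to
    ``feat_0001`` style; planted features must name existing ids or
    fresh ones (appended).
    """
    rng = _rng(design.rng_seed)
    features = [f"feat_{i + 1:04d}" for i in range(design.n_features)]
    planted = dict()
    for name, lfc in design.planted_de:
        planted[name] = lfc
        if name not in features:
            features.append(name)
    samples = ([f"TBI_{i + 1}" for i in range(design.n_tbi)]
               + [f"sham_{i + 1}" for i in range(design.n_sham)])
    groups = {s: (GROUP_TBI if s.startswith("TBI") else GROUP_SHAM)
              for s in samples}
    base = np.full(len(features), float(design.baseline_mean))
    lfc = np.array([planted.get(f, 0.0) for f in features])
    mean_tbi = base * 2.0 ** lfc
    mean_sham = base
    cols = {}
    for s in samples:
        mu = mean_tbi if groups[s] == GROUP_TBI else mean_sham
        cols[s] = _draw_nb(rng, mu, design.nb_dispersion)
    df = pd.DataFrame(cols, index=features)
    return CountMatrix(df, groups)


def gen_isomir_reads(
    mirna: MirnaReference,
    composition: Mapping[str, float],
    total_reads: int,
    rng_seed,
    sample: str = "S1",
) -> pd.DataFrame:
    """Multinomial allocation of reads over explicit isomiR sequences.

    ``composition`` maps read sequences (canonical plus enumerated isomiR
    species) to proportions summing to 1.  Returns a read table with
    columns (sequence, sample, count); zero-count species are dropped.
    """
    rng = _rng(rng_seed)
    seqs = list(composition)
    props = np.array([composition[s] for s in seqs], dtype=float)
    if (props < 0).any() or not np.isclose(props.sum(), 1.0, atol=1e-8):
        raise ValueError("composition proportions must be >= 0 and sum to 1")
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    if total_reads == 0:
        return pd.DataFrame(columns=["sequence", "sample", "count"])
    counts = rng.multinomial(total_reads, props / props.sum())
    rows = [(seq, sample, int(c)) for seq, c in zip(seqs, counts) if c > 0]
    return pd.DataFrame(rows, columns=["sequence", "sample", "count"])


def canonical_isomir_mix(
    mirna: MirnaReference, canonical_fraction: float, n_species: int = 4
) -> dict[str, float]:
    """A composition of the canonical sequence plus simple 3' isomiRs.

    The non-canonical mass is spread over up to ``n_species`` 3' variants
    (single addition, double addition, single deletion, double deletion),
    matching the 3'-dominated isomiR mixtures seen in brain small-RNA data.
    """
    if not (0 <= canonical_fraction <= 1):
        raise ValueError("canonical_fraction must be in [0, 1]")
    c = mirna.canonical_seq
    variants = [c + "T", c + "TT", c[:-1], c[:-2]][:n_species]
    rest = (1.0 - canonical_fraction) / len(variants)
    mix = {c: canonical_fraction}
    for v in variants:
        mix[v] = rest
    return mix


def gen_trna_alignments(
    trna: TrnaReference,
    cleavage_pos: int,
    cleaved_fraction: float,
    n_reads: int,
    rng_seed,
    sample: str = "S1",
) -> pd.DataFrame:
    """Positional alignment table for one tRNA in one sample.

    A ``cleaved_fraction`` share of reads is the 3' fragment
    ``[cleavage_pos, len)``; the remainder start uniformly at other
    positions with lengths 18-36 nt clipped to the tRNA end, emulating
    background degradation.  Returns columns (trna, sample, start, end,
    count).
    """
    rng = _rng(rng_seed)
    if not (0 <= cleavage_pos < len(trna)):
        raise ValueError("cleavage_pos outside tRNA")
    if not (0 <= cleaved_fraction <= 1):
        raise ValueError("cleaved_fraction must be in [0, 1]")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    L = len(trna)
    n_frag = rng.binomial(n_reads, cleaved_fraction)
    n_bg = n_reads - n_frag
    intervals: dict[tuple[int, int], int] = {}
    if n_frag:
        intervals[(cleavage_pos, L)] = n_frag
    if n_bg:
        other = np.array([p for p in range(L - 15) if p != cleavage_pos])
        starts = rng.choice(other, size=n_bg)
        lengths = rng.integers(18, 37, size=n_bg)
        ends = np.minimum(starts + lengths, L)
        for s, e in zip(starts, ends):
            key = (int(s), int(e))
            intervals[key] = intervals.get(key, 0) + 1
    rows = [(trna.name, sample, s, e, c)
            for (s, e), c in sorted(intervals.items())]
    return pd.DataFrame(rows, columns=["trna", "sample", "start", "end", "count"])


DDPCR_CONTROLS = ("miR-378a-3p", "miR-3594-3p", "miR-330-5p", "let-7b-3p")


def gen_pcr_measurements(
    planted_fc: float,
    kind: str,
    n_per_group: int = 6,
    noise_cv: float = 0.1,
    rng_seed=0,
    target: str = "target",
    baseline_copies: float = 1000.0,
    baseline_dct: float = 3.0,
    replicate_sd: float = 0.2,
) -> pd.DataFrame:
    """Synthetic ddPCR or qPCR measurement tables with a planted fold change.

    ddPCR: per sample, duplicate copies/20 uL wells drawn log-normal with
    coefficient of variation ``noise_cv``; the TBI mean is ``planted_fc``
    times the sham mean.  Four endogenous-control channels (5% CV, no
    group effect) and an RNA-input column are included so the
    geometric-mean normalization exercise is non-trivial.

    qPCR: per sample, triplicate target Ct and reference Ct with
    replicate SD ``replicate_sd``; the TBI delta-Ct is the sham delta-Ct
    minus log2(planted_fc), so 2^-dCt recovers the fold change.
    """
    rng = _rng(rng_seed)
    if planted_fc <= 0:
        raise ValueError("planted_fc must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    samples = ([(f"TBI_{i + 1}", GROUP_TBI) for i in range(n_per_group)]
               + [(f"sham_{i + 1}", GROUP_SHAM) for i in range(n_per_group)])

    def lognorm(mean: float, cv: float, size) -> np.ndarray:
        if cv == 0:
            return np.full(size, mean)
        sigma2 = np.log1p(cv ** 2)
        mu = np.log(mean) - sigma2 / 2
        return rng.lognormal(mu, np.sqrt(sigma2), size=size)

    rows = []
    if kind == "ddpcr":
        for name, group in samples:
            mean = baseline_copies * (planted_fc if group == GROUP_TBI else 1.0)
            rna_input = float(lognorm(50.0, 0.05, ()))
            rep = lognorm(mean, noise_cv, 2)
            rows.append((name, group, target, rep[0], rep[1], rna_input, False))
            for ctrl in DDPCR_CONTROLS:
                crep = lognorm(baseline_copies, 0.05, 2)
                rows.append((name, group, ctrl, crep[0], crep[1], rna_input, True))
        return pd.DataFrame(
            rows,
            columns=["sample", "group", "target", "copies_rep1", "copies_rep2",
                     "rna_input_ng", "is_endogenous_control"],
        )
    if kind == "qpcr":
        for name, group in samples:
            dct = baseline_dct
            if group == GROUP_TBI:
                dct = baseline_dct - np.log2(planted_fc)
            ref_ct = 20.0 + rng.normal(0, replicate_sd, 3)
            tgt_ct = 20.0 + dct + rng.normal(0, replicate_sd, 3)
            rows.append((name, group, target,
                         tgt_ct[0], tgt_ct[1], tgt_ct[2],
                         ref_ct[0], ref_ct[1], ref_ct[2]))
        return pd.DataFrame(
            rows,
            columns=["sample", "group", "target", "ct_rep1", "ct_rep2", "ct_rep3",
                     "ref_ct_rep1", "ref_ct_rep2", "ref_ct_rep3"],
        )
    raise ValueError(f"kind must be 'ddpcr' or 'qpcr', got {kind!r}")


def latent_pearson_for_spearman(target_spearman: float) -> float:
    """Gaussian-copula inversion: latent Pearson rho = 2*sin(pi*r_s/6)."""
    return 2.0 * np.sin(np.pi * target_spearman / 6.0)


def gen_behavior(
    expression: Sequence[float],
    target_spearman: float,
    score_kind: str,
    rng_seed,
) -> np.ndarray:
    """Behavioral scores rank-coupled to expression at a target Spearman.

    Expression values are mapped to normal scores via their midranks; a
    latent Gaussian partner is drawn with Pearson correlation
    ``2*sin(pi*r_s/6)`` so the population Spearman of the continuous pair
    equals ``target_spearman``.  The latent is then mapped to the score
    scale: composite neuroscore on the 0-28 integer grid, or probe-trial
    time in the correct quadrant on [0, 60] seconds.  Discretization to
    29 levels attenuates the sample Spearman only marginally.
    """
    rng = _rng(rng_seed)
    if abs(target_spearman) > 1:
        raise ValueError("|target_spearman| must be <= 1")
    x = np.asarray(expression, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two animals")
    ranks = stats.rankdata(x)
    zx = stats.norm.ppf(ranks / (n + 1))
    rho = latent_pearson_for_spearman(target_spearman)
    eps = rng.normal(size=n)
    latent = rho * zx + np.sqrt(max(0.0, 1 - rho ** 2)) * eps
    u = stats.norm.cdf(latent)
    if score_kind == "neuroscore":
        return np.clip(np.rint(u * 28), 0, 28).astype(int)
    if score_kind == "probe_time":
        return np.clip(u * 60.0, 0.0, 60.0)
    raise ValueError(f"score_kind must be 'neuroscore' or 'probe_time', "
                     f"got {score_kind!r}")
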