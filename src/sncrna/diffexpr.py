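"""Two-group differential expression for small-RNA count matrices.

The engine follows the classic count-based workflow: trimmed-mean-of-
M-values (TMM) scaling factors between libraries, a common negative-
binomial dispersion estimated by conditional maximum likelihood on counts
rescaled to the geometric-mean effective library size, an exact
conditional NB test per feature, and Benjamini-Hochberg FDR adjustment.

The NB is parameterized by mean mu and dispersion phi with variance
mu + phi*mu^2; phi = 0 is the Poisson limit.  The exact test conditions
on the feature's overall total: with equalized library sizes the group-1
subtotal follows the convolution ratio of two NB sums, and the two-sided
p-value doubles the smaller tail (capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .core_io import CountMatrix, GROUP_SHAM, GROUP_TBI


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """Log2 TMM factor of one library against the reference library."""
    keep = (obs > 0) & (ref > 0)
    o = obs[keep] / lib_obs
    r = ref[keep] / lib_ref
    if o.size == 0:
        return 0.0
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic (delta-method) variance of M as precision weight
    w = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) \
        + (lib_ref - ref[keep]) / (lib_ref * ref[keep])
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    kept = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not kept.any() or np.nanmax(np.abs(m)) < 1e-6:
        return 0.0
    f = np.sum(m[kept] / w[kept]) / np.sum(1.0 / w[kept])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_factors(
    matrix: CountMatrix, trim_m: float = 0.3, trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> pd.Series:
    """Per-sample TMM scaling factors, normalized to geometric mean 1.

    M-values (log library-size-normalized ratios vs the reference sample)
    are doubly trimmed — 30% by M, 5% by A — and averaged with inverse
    asymptotic-variance weights.  The reference is the sample whose
    upper-quartile normalized count is closest to the mean upper-quartile.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    zero_lib = np.nonzero(lib == 0)[0]
    if zero_lib.size:
        raise ValueError(
            f"all-zero sample(s): {[matrix.sample_ids[i] for i in zero_lib]}"
        )
    if ref_sample is None:
        uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                       for j in range(counts.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = matrix.sample_ids.index(ref_sample)
    log_f = np.array([
        _tmm_pair(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx],
                  trim_m, trim_a)
        for j in range(counts.shape[1])
    ])
    factors = 2.0 ** log_f
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.sample_ids, name="tmm_factor")


def effective_library_sizes(matrix: CountMatrix, factors: pd.Series) -> pd.Series:
    lib = matrix.counts.sum(axis=0).astype(float)
    return lib * factors.reindex(lib.index)


def _equalized_counts(matrix: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Rescale counts to the geometric-mean effective library size.

    A quantile-free approximation to pseudo-counts: linear rescaling of
    each library to the common size, rounded back to integers for the
    conditional tests.
    """
    eff = effective_library_sizes(matrix, factors)
    common = np.exp(np.mean(np.log(eff)))
    scaled = matrix.counts * (common / eff)
    return scaled.round().astype(np.int64)


# ---------------------------------------------------------------------------
# Common-dispersion estimation (conditional maximum likelihood)
# ---------------------------------------------------------------------------

def _conditional_loglik(r: float, counts: np.ndarray, group_sizes) -> float:
    """Conditional NB log-likelihood given per-group totals, summed over
    features; ``r`` = 1/phi.  Equal library sizes assumed (counts already
    equalized)."""
    ll = 0.0
    start = 0
    for n in group_sizes:
        y = counts[:, start:start + n]
        z = y.sum(axis=1)
        ll += float(
            np.sum(special.gammaln(y + r))
            + np.sum(special.gammaln(n * r) - special.gammaln(z + n * r))
            - y.shape[0] * n * special.gammaln(r)
        )
        start += n
    return ll


def estimate_common_dispersion(
    matrix: CountMatrix, factors: pd.Series, max_dispersion: float = 5.0
) -> float:
    """Common NB dispersion maximizing the conditional likelihood.

    Counts are equalized to a common library size first; the likelihood
    conditions on each feature's per-group total, which removes the mean
    parameters.  Features with an all-zero group total contribute no
    information and are dropped.  The estimate is clipped to
    ``[0, max_dispersion]``.
    """
    matrix.require_both_groups()
    eq = _equalized_counts(matrix, factors)
    tbi = matrix.samples_in_group(GROUP_TBI)
    sham = matrix.samples_in_group(GROUP_SHAM)
    counts = eq[tbi + sham].to_numpy(dtype=float)
    keep = counts.sum(axis=1) > 0
    counts = counts[keep]
    if counts.size == 0:
        return 0.0
    sizes = (len(tbi), len(sham))

    def neg_ll(log_phi: float) -> float:
        return -_conditional_loglik(np.exp(-log_phi), counts, sizes)

    # optimize over log(phi) for scale robustness; compare with phi -> 0
    res = optimize.minimize_scalar(
        neg_ll, bounds=(np.log(1e-6), np.log(max_dispersion)), method="bounded",
        options={"xatol": 1e-4},
    )
    phi_hat = float(np.exp(res.x))
    # Poisson (phi -> 0) limit of the kept likelihood terms is -z*log(n)
    # per feature-group (the conditional becomes multinomial)
    ll_zero = 0.0
    start = 0
    for n in sizes:
        z = counts[:, start:start + n].sum(axis=1)
        ll_zero += float(-(z * np.log(n)).sum())
        start += n
    if ll_zero >= -res.fun:
        return 0.0
    return min(phi_hat, max_dispersion)


# ---------------------------------------------------------------------------
# Exact conditional test
# ---------------------------------------------------------------------------

def _group_sum_logpmf(k: np.ndarray, n: int, mu: float, phi: float) -> np.ndarray:
    """log P(sum of n iid NB(mu, phi) = k); NB sums stay NB with
    mean n*mu and dispersion phi/n."""
    if phi <= 1e-12:
        return stats.poisson.logpmf(k, n * mu)
    r = n / phi
    p = r / (r + n * mu)
    return stats.nbinom.logpmf(k, r, p)


def _exact_feature_p(za: int, zb: int, na: int, nb: int, phi: float) -> float:
    """Two-sided exact p for group subtotals (za, zb) given total za+zb."""
    z = za + zb
    if z == 0:
        return 1.0
    mu = z / (na + nb)
    k = np.arange(z + 1)
    logp = (_group_sum_logpmf(k, na, mu, phi)
            + _group_sum_logpmf(z - k, nb, mu, phi))
    logp -= special.logsumexp(logp)
    p = np.exp(logp)
    lower = float(p[: za + 1].sum())
    upper = float(p[za:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def exact_test(
    matrix: CountMatrix, factors: pd.Series, dispersion: float,
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """Per-feature exact NB test of TBI vs sham.

    Returns a DeTable-style DataFrame indexed by feature with columns
    log2fc (TBI over sham, pseudo-count 0.5 on normalized group means —
    testing itself uses raw equalized counts), p_value, fdr, and
    mean_expression (mean equalized count).
    """
    matrix.require_both_groups()
    eq = _equalized_counts(matrix, factors)
    tbi = matrix.samples_in_group(GROUP_TBI)
    sham = matrix.samples_in_group(GROUP_SHAM)
    za = eq[tbi].sum(axis=1).to_numpy()
    zb = eq[sham].sum(axis=1).to_numpy()
    na, nb = len(tbi), len(sham)
    pvals = np.array([
        _exact_feature_p(int(a), int(b), na, nb, dispersion)
        for a, b in zip(za, zb)
    ])
    mean_tbi = za / na
    mean_sham = zb / nb
    log2fc = np.log2(mean_tbi + pseudo_count) - np.log2(mean_sham + pseudo_count)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": bh_fdr(pvals),
            "mean_expression": eq.mean(axis=1).to_numpy(),
        },
        index=matrix.counts.index.rename("feature"),
    )
    return table


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_summary(table: pd.DataFrame, fdr_threshold: float = 0.05):
    """(n_significant, n_up, n_down) at the given FDR threshold."""
    if table.empty:
        return (0, 0, 0)
    sig = table[table["fdr"] < fdr_threshold]
    n_up = int((sig["log2fc"] > 0).sum())
    n_down = int((sig["log2fc"] < 0).sum())
    return (len(sig), n_up, n_down)


def run_de(
    matrix: CountMatrix, fdr_threshold: float = 0.05
) -> tuple[pd.DataFrame, tuple[int, int, int]]:
    """TMM -> common dispersion -> exact test -> BH, plus the summary."""
    factors = tmm_factors(matrix)
    phi = estimate_common_dispersion(matrix, factors)
    table = exact_test(matrix, factors, phi)
    return table, de_summary(table, fdr_threshold)
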