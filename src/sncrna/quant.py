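"""ddPCR and qPCR quantification arithmetic.

ddPCR absolute quantification: the duplicate copies/20-uL-well values are
averaged, divided by the total RNA input to the cDNA reaction, and then
divided by the geometric mean of the RNA-input-normalized copies of the
four endogenous-control miRNAs.  qPCR relative quantification uses
2^-dCt with dCt = mean(target Ct) - mean(reference Ct).  Group fold
change is the ratio of group means of the per-sample normalized values,
compared with an exact Mann-Whitney U test at small n.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GROUP_SHAM, GROUP_TBI

N_CONTROLS = 4


def ddpcr_normalize(records: pd.DataFrame) -> pd.Series:
    """Normalized target copies per sample.

    ``records`` has one row per (sample, assay): columns sample, target,
    copies_rep1, copies_rep2, rna_input_ng, is_endogenous_control.  Each
    sample needs exactly four endogenous-control rows with positive
    copies.  Returns a Series indexed by sample.
    """
    out = {}
    for sample, grp in records.groupby("sample"):
        step1 = (grp[["copies_rep1", "copies_rep2"]].mean(axis=1)
                 / grp["rna_input_ng"])
        ctrl = step1[grp["is_endogenous_control"].astype(bool)]
        tgt = step1[~grp["is_endogenous_control"].astype(bool)]
        if len(ctrl) != N_CONTROLS:
            raise ValueError(
                f"{sample}: need {N_CONTROLS} endogenous controls, "
                f"found {len(ctrl)}"
            )
        if (ctrl <= 0).any():
            raise ValueError(f"{sample}: control with zero copies; "
                             "geometric mean undefined")
        if len(tgt) != 1:
            raise ValueError(f"{sample}: expected exactly one target assay")
        gm = float(np.exp(np.mean(np.log(ctrl))))
        out[sample] = float(tgt.iloc[0]) / gm
    return pd.Series(out, name="normalized_copies")


def qpcr_relative(
    target_ct: Sequence[float], reference_ct: Sequence[float]
) -> float:
    """2^-dCt with dCt = mean(target Ct) - mean(reference Ct)."""
    t = np.asarray(target_ct, dtype=float)
    r = np.asarray(reference_ct, dtype=float)
    if t.size == 0 or r.size == 0:
        raise ValueError("need at least one Ct replicate per assay")
    if ((t <= 0) | (t >= 45) | (r <= 0) | (r >= 45)).any():
        raise ValueError("Ct values must lie in (0, 45)")
    dct = t.mean() - r.mean()
    return float(2.0 ** (-dct))


def qpcr_table_relative(records: pd.DataFrame) -> pd.Series:
    """Per-sample 2^-dCt values from a measurement table with triplicate
    target and reference Ct columns (``ct_rep*`` / ``ref_ct_rep*``)."""
    ct_cols = [c for c in records.columns if c.startswith("ct_rep")]
    ref_cols = [c for c in records.columns if c.startswith("ref_ct_rep")]
    return pd.Series(
        {
            row.sample: qpcr_relative(
                [getattr(row, c) for c in ct_cols],
                [getattr(row, c) for c in ref_cols],
            )
            for row in records.itertuples(index=False)
        },
        name="relative_expression",
    )


def group_fold_change(
    values: pd.Series, groups: pd.Series | dict
) -> float:
    """FC = mean(TBI) / mean(sham) of per-sample normalized values."""
    g = pd.Series(groups)
    tbi = values[[s for s in values.index if g[s] == GROUP_TBI]]
    sham = values[[s for s in values.index if g[s] == GROUP_SHAM]]
    if tbi.empty or sham.empty:
        raise ValueError("both groups need samples")
    m_tbi, m_sham = tbi.mean(), sham.mean()
    if m_tbi <= 0 or m_sham <= 0:
        raise ValueError("group means must be positive for a fold change")
    return float(m_tbi / m_sham)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x vs y from midranks (ties get half credit)."""
    allv = np.concatenate([x, y])
    ranks = stats.rankdata(allv)
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2)


def mann_whitney(
    values: pd.Series | Sequence[float], groups, exact_max_n: int = 10
) -> tuple[float, float]:
    """Mann-Whitney U and two-sided p; exact by enumeration at small n.

    For group sizes up to ``exact_max_n`` the p-value enumerates all
    group assignments of the pooled values (tie-safe); larger samples use
    the tie-corrected normal approximation.
    """
    v = pd.Series(values)
    g = pd.Series(groups)
    x = v[[s for s in v.index if g[s] == GROUP_TBI]].to_numpy(dtype=float)
    y = v[[s for s in v.index if g[s] == GROUP_SHAM]].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups need samples")
    u_obs = _u_statistic(x, y)
    n1, n2 = x.size, y.size
    if max(n1, n2) <= exact_max_n:
        pooled = np.concatenate([x, y])
        mid = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mid)
        total = 0
        extreme = 0
        for idx in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mid) >= dev_obs - 1e-12:
                extreme += 1
        p = extreme / total
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        p = float(res.pvalue)
    return u_obs, min(1.0, p)


def quantification_summary(
    values: pd.Series, groups
) -> dict:
    """Fold change plus Mann-Whitney U and p for one assay."""
    fc = group_fold_change(values, groups)
    u, p = mann_whitney(values, groups)
    return {"fold_change": fc, "u_statistic": u, "p_value": p}
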