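"""Behavioral scoring and correlation of molecular signatures with outcome.

The composite neuroscore sums seven somatomotor sub-tests — left/right
forelimb contraflexion, left/right hindlimb flexion, left/right lateral
pulsion, and an inclined-surface test — each scored 0 (severely
impaired) to 4 (normal), for a 0-28 total.  The water-maze probe trial
records time spent in each of the four quadrants over a 60 s swim; the
fraction in the former platform quadrant is compared against the 0.25
chance level.  Molecule-vs-outcome association uses the Spearman rank
correlation with midrank ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import logger

NEUROSCORE_TIMEPOINTS = ("baseline", "d2", "d7", "d14", "d21", "d90")
NEUROSCORE_CATEGORIES = (
    "forelimb_contraflexion_left", "forelimb_contraflexion_right",
    "hindlimb_flexion_left", "hindlimb_flexion_right",
    "lateral_pulsion_left", "lateral_pulsion_right",
    "inclined_surface",
)
PROBE_TRIAL_SECONDS = 60.0
CHANCE_FRACTION = 0.25


@dataclass(frozen=True)
class NeuroscoreRecord:
    animal: str
    timepoint: str
    scores: tuple[int, ...]  # seven sub-scores, order as NEUROSCORE_CATEGORIES

    def __post_init__(self) -> None:
        if self.timepoint not in NEUROSCORE_TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if len(self.scores) != len(NEUROSCORE_CATEGORIES):
            raise ValueError(
                f"need {len(NEUROSCORE_CATEGORIES)} sub-scores, "
                f"got {len(self.scores)}"
            )
        for cat, s in zip(NEUROSCORE_CATEGORIES, self.scores):
            if not (isinstance(s, (int, np.integer)) and 0 <= s <= 4):
                raise ValueError(f"{cat}: sub-score must be an integer in "
                                 f"[0, 4], got {s!r}")


@dataclass(frozen=True)
class ProbeTrialRecord:
    animal: str
    time_in_quadrant: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        t = np.asarray(self.time_in_quadrant, dtype=float)
        if (t < 0).any():
            raise ValueError("quadrant times must be non-negative")
        if abs(t.sum() - PROBE_TRIAL_SECONDS) > 0.5:
            raise ValueError(
                f"quadrant times must sum to {PROBE_TRIAL_SECONDS} s "
                f"(+/-0.5 for tracking loss), got {t.sum():.2f}"
            )


def composite_neuroscore(record: NeuroscoreRecord) -> int:
    """Sum of the seven sub-scores; 28 only when every sub-test is normal."""
    return int(sum(record.scores))


def probe_quadrant_fraction(
    record: ProbeTrialRecord, correct_quadrant: int
) -> tuple[float, float]:
    """(seconds in the correct quadrant, fraction of the 60 s trial)."""
    if not (0 <= correct_quadrant < 4):
        raise ValueError("correct_quadrant must be 0..3")
    t = float(record.time_in_quadrant[correct_quadrant])
    return t, t / PROBE_TRIAL_SECONDS


def spearman(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 8
) -> tuple[float, float]:
    """Spearman rho (midrank ties) and two-sided p.

    At n <= ``exact_max_n`` the p-value enumerates all rank permutations
    of one variable (exact under independence); larger samples use the
    standard t approximation.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    rho = float(stats.spearmanr(xv, yv).statistic)
    n = xv.size
    if n <= exact_max_n:
        rx = stats.rankdata(xv)
        ry = stats.rankdata(yv)
        obs = abs(_rank_pearson(rx, ry))
        total = 0
        extreme = 0
        for perm in permutations(range(n)):
            r = _rank_pearson(rx, ry[list(perm)])
            total += 1
            if abs(r) >= obs - 1e-12:
                extreme += 1
        p = extreme / total
    else:
        p = float(stats.spearmanr(xv, yv).pvalue)
    return rho, min(1.0, p)


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    if denom == 0:
        return 0.0
    return float((rxc * ryc).sum() / denom)


def outcome_correlation_report(
    expression: pd.DataFrame,
    behavior: pd.DataFrame,
    groups: Mapping[str, str] | None = None,
    per_group: bool = False,
) -> pd.DataFrame:
    """Spearman correlation of each molecule against each behavior measure.

    ``expression``: animals x molecules; ``behavior``: animals x
    behavioral measures.  Animals are joined on index; those missing
    either side are dropped with a logged count.  By default animals
    from both groups are pooled (matching how chronic-outcome
    correlations are usually reported); ``per_group`` adds per-group
    rows.
    """
    common = expression.index.intersection(behavior.index)
    dropped = (len(expression.index) - len(common)) + \
              (len(behavior.index) - len(common))
    if dropped:
        logger.info("outcome report: dropped %d unmatched animal record(s)",
                    dropped)
    if len(common) == 0:
        logger.warning("outcome report: no shared animals")
        return pd.DataFrame(
            columns=["molecule", "behavior", "group", "n", "rho", "p_value"]
        )
    subsets = [("all", common)]
    if per_group and groups is not None:
        g = pd.Series(groups)
        for grp in sorted(set(g[a] for a in common)):
            subsets.append((grp, [a for a in common if g[a] == grp]))
    rows = []
    for label, animals in subsets:
        if len(animals) < 3:
            continue
        for mol in expression.columns:
            for meas in behavior.columns:
                rho, p = spearman(
                    expression.loc[animals, mol].to_numpy(),
                    behavior.loc[animals, meas].to_numpy(),
                )
                rows.append((mol, meas, label, len(animals), rho, p))
    return pd.DataFrame(
        rows, columns=["molecule", "behavior", "group", "n", "rho", "p_value"]
    )
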