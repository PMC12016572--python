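"""Separation statistics: how well does a score split state1 from state0?

Two complementary views: the two-sample Kolmogorov-Smirnov statistic D
(supremum distance between the empirical score distributions of the two
states) and the ROC AUC (probability that a random state1 cell outscores a
random state0 cell, ties counted half), with a seeded stratified bootstrap
percentile confidence interval.  Both are rank statistics, invariant under
any strictly increasing transform of the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ScoreVector
from .errors import ValidationError

__all__ = ["ks_two_sample", "roc_auc", "separation_report", "SeparationReport"]


def _as_values(scores: ScoreVector | Sequence[float] | np.ndarray) -> np.ndarray:
    if isinstance(scores, ScoreVector):
        return scores.values
    return np.asarray(scores, dtype=float)


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = _as_values(scores)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValidationError("scores and labels must have equal length")
    s0, s1 = s[y == 0], s[y == 1]
    if len(s0) == 0 or len(s1) == 0:
        raise ValidationError("both states must be present")
    return s0, s1


def ks_two_sample(scores, labels) -> tuple[float, float]:
    """Two-sample K-S statistic D and asymptotic two-sided p-value.

    ``D = sup_x |ECDF_state1(x) - ECDF_state0(x)|``.
    """
    s0, s1 = _split(scores, labels)
    res = stats.ks_2samp(s1, s0, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def _auc(s: np.ndarray, y: np.ndarray) -> float:
    # Mann-Whitney with midranks: AUC = P(s1 > s0) + P(s1 == s0)/2
    n1 = int(y.sum())
    n0 = len(y) - n1
    r = stats.rankdata(s)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_auc(
    scores, labels, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float, float]:
    """ROC AUC for state1-high scores with a bootstrap percentile CI.

    The CI resamples cells within each state (stratified), ``n_boot`` times,
    seeded; returns ``(auc, ci_low, ci_high)`` at the 95% level.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    s0, s1 = _split(scores, labels)
    s = np.concatenate([s0, s1])
    y = np.concatenate([np.zeros(len(s0), int), np.ones(len(s1), int)])
    auc = _auc(s, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        b0 = s0[rng.integers(0, len(s0), len(s0))]
        b1 = s1[rng.integers(0, len(s1), len(s1))]
        boots[i] = _auc(
            np.concatenate([b0, b1]), y
        )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, float(lo), float(hi)


@dataclass
class SeparationReport:
    """Per-method separation metrics between the two states."""

    method: str
    ks_d: float
    ks_p: float
    auc: float
    ci_low: float
    ci_high: float
    n0: int
    n1: int


def separation_report(
    scores_by_method: Mapping[str, ScoreVector | np.ndarray],
    labels,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """K-S D and AUC (with CI) for each scoring method, as one table.

    Output columns: method, D, ks_p, AUC, CI_L, CI_U, n0, n1.
    """
    y = np.asarray(labels, dtype=int)
    rows = []
    for name, sc in scores_by_method.items():
        d, p = ks_two_sample(sc, y)
        auc, lo, hi = roc_auc(sc, y, n_boot=n_boot, seed=seed)
        rows.append(
            {
                "method": name,
                "D": d,
                "ks_p": p,
                "AUC": auc,
                "CI_L": lo,
                "CI_U": hi,
                "n0": int((y == 0).sum()),
                "n1": int((y == 1).sum()),
            }
        )
    return pd.DataFrame(rows)
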