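"""Rank statistics shared by the similarity and prediction modules.

Two primitives live here:

* a one-sided Mann-Whitney U test ("x stochastically greater than y"),
  computed by exact enumeration of all label assignments when the pooled
  sample is small (m + n <= 10) and by the normal approximation with tie
  correction and continuity correction otherwise;
* AUROC in its rank formulation with half credit for tied scores, which is
  equivalent to counting concordant positive/negative score pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = ["MannWhitneyResult", "mannwhitney_greater", "mann_whitney_u", "auroc"]

#: Pooled-sample size at or below which the exact null distribution is used.
EXACT_LIMIT = 10


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """U statistic for ``x`` vs ``y`` with half credit for ties."""
    x = np.asarray(x, np.float64)
    y = np.asarray(y, np.float64)
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # "exact" | "asymptotic"
    alternative: str = "greater"


def mannwhitney_greater(
    x: Sequence[float], y: Sequence[float], exact_limit: int = EXACT_LIMIT
) -> MannWhitneyResult:
    """One-sided Mann-Whitney U test of x stochastically greater than y.

    For ``len(x) + len(y) <= exact_limit`` the p-value is
    ``P(U >= u_observed)`` under the exact permutation null, enumerated over
    all ``C(m+n, m)`` assignments of the pooled values (ties handled by the
    half-credit U, so tied pools are exact too). Larger samples use the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, np.float64)
    y = np.asarray(y, np.float64)
    if x.size == 0 or y.size == 0:
        raise ValidationError("Mann-Whitney requires two non-empty samples")
    m, n = x.size, y.size
    u_obs = mann_whitney_u(x, y)
    if m + n <= exact_limit:
        pooled = np.concatenate([x, y])
        total = comb(m + n, m)
        hits = 0
        idx_all = frozenset(range(m + n))
        for xs in combinations(range(m + n), m):
            xv = pooled[list(xs)]
            yv = pooled[sorted(idx_all - set(xs))]
            if mann_whitney_u(xv, yv) >= u_obs - 1e-12:
                hits += 1
        return MannWhitneyResult(u_obs, hits / total, "exact")
    res = sps.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), "asymptotic")


def auroc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve via midranks; ties get half credit.

    ``labels`` marks the positive class. Equals the probability that a
    random positive outscores a random negative, counting ties as 1/2.
    """
    scores = np.asarray(scores, np.float64)
    labels = np.asarray(labels, bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be aligned 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUROC undefined: only one class present")
    ranks = sps.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
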