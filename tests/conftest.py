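"""Shared fixtures and independent oracles.

The oracles here recompute MODZ, Mann-Whitney, and AUROC by routes
independent of the package implementation (exact rational arithmetic,
enumeration over label assignments, explicit pair counting) so that tests
compare two derivations rather than a function against itself.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from consensig.signatures import (
    DataLevel,
    Dose,
    GeneSpace,
    PerturbagenType,
    SignatureMatrix,
    SignatureMeta,
)

# Ranks 1..9 permuted so that pairwise Spearman correlations are exactly
# rho(a,b) = rho(a,c) = 0.1 and rho(b,c) = 0.4 (found by enumeration over
# permutations; verify: 1 - 6*sum(d^2)/720 with sum(d^2) = 108, 108, 72).
PERM_A = (1, 2, 3, 4, 5, 6, 7, 8, 9)
PERM_B = (1, 2, 8, 9, 6, 7, 5, 4, 3)
PERM_C = (1, 5, 8, 3, 9, 4, 7, 6, 2)


def make_meta(
    sid: str,
    pert: str = "P0",
    cell: str = "A375",
    time: float = 24.0,
    dose: float | None = 10.0,
    ptype: str = "compound",
    seq: str | None = None,
    tas: float | None = None,
    level: str = "L5",
) -> SignatureMeta:
    return SignatureMeta(
        signature_id=sid,
        perturbagen_id=pert,
        perturbagen_type=PerturbagenType(ptype),
        cell_line=cell,
        time=time,
        dose=None if dose is None else Dose(dose, "uM"),
        shrna_seq=seq,
        data_level=DataLevel(level),
        tas=tas,
    )


def matrix_from_columns(cols, metas=None, gene_ids=None) -> SignatureMatrix:
    """Build a SignatureMatrix from raw column vectors with stub metadata."""
    values = np.column_stack([np.asarray(c, float) for c in cols])
    if gene_ids is None:
        gene_ids = [f"G{i:03d}" for i in range(values.shape[0])]
    if metas is None:
        metas = [make_meta(f"S{j}", pert=f"P{j}") for j in range(values.shape[1])]
    return SignatureMatrix(GeneSpace.all_landmark(gene_ids), values, metas)


# ---------------------------------------------------------------------------
# Exact-arithmetic MODZ oracle
# ---------------------------------------------------------------------------

def frac_ranks(col):
    """Average ranks as exact Fractions."""
    n = len(col)
    order = sorted(range(n), key=lambda i: col[i])
    ranks = [Fraction(0)] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and col[order[j + 1]] == col[order[i]]:
            j += 1
        avg = Fraction(sum(range(i + 1, j + 2)), j - i + 1)
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_spearman(x, y) -> float:
    """Spearman via exact rank arithmetic; only the final sqrt is floating."""
    rx, ry = frac_ranks(list(x)), frac_ranks(list(y))
    n = len(rx)
    mx = sum(rx, Fraction(0)) / n
    my = sum(ry, Fraction(0)) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = sum((a - mx) ** 2 for a in rx)
    dy = sum((b - my) ** 2 for b in ry)
    return float(num) / math.sqrt(float(dx) * float(dy))


def oracle_modz(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force MODZ: floor 0.01 per pairwise term, exact normalization.

    Returns (weights, combined vector). Weight bookkeeping is done in
    Fractions of the (exactly represented) float correlations.
    """
    n = matrix.shape[1]
    if n == 1:
        return np.array([1.0]), matrix[:, 0].astype(float)
    floor = Fraction(1, 100)
    rho = {}
    for i, j in combinations(range(n), 2):
        rho[(i, j)] = rho[(j, i)] = Fraction(oracle_spearman(matrix[:, i], matrix[:, j]))
    raw = [sum(max(rho[(i, j)], floor) for j in range(n) if j != i) for i in range(n)]
    total = sum(raw, Fraction(0))
    weights = [r / total for r in raw]
    combined = [
        float(sum(Fraction(float(matrix[g, i])) * weights[i] for i in range(n)))
        for g in range(matrix.shape[0])
    ]
    return np.array([float(w) for w in weights]), np.array(combined)


def enumerate_modz_cases(n_cases: int, seed: int = 12345):
    """Fixed enumeration of small integer matrices for oracle comparison.

    Sizes cycle over 3..6 genes x 2..5 columns; entries are small integers;
    rank-constant columns are redrawn (Spearman undefined there).
    """
    rng = np.random.default_rng(seed)
    cases = []
    while len(cases) < n_cases:
        n_genes = int(rng.integers(3, 7))
        n_cols = int(rng.integers(2, 6))
        mat = rng.integers(-3, 4, size=(n_genes, n_cols)).astype(float)
        if any(len(set(mat[:, j])) < 2 for j in range(n_cols)):
            continue
        cases.append(mat)
    return cases


# ---------------------------------------------------------------------------
# Rank-statistic oracles
# ---------------------------------------------------------------------------

def oracle_mw_p_greater(x, y) -> float:
    """Exact one-sided Mann-Whitney p via the rank-sum route.

    Enumerates every assignment of the pooled values to the x-group and
    computes U from midranks (U = R_x - m(m+1)/2), a different formulation
    than the implementation's pairwise count.
    """
    from scipy.stats import rankdata

    x = list(map(float, x))
    y = list(map(float, y))
    m = len(x)
    pooled = np.array(x + y)
    ranks = rankdata(pooled)

    def u_of(idx):
        return ranks[list(idx)].sum() - m * (m + 1) / 2

    u_obs = u_of(range(m))
    hits = total = 0
    for idx in combinations(range(len(pooled)), m):
        total += 1
        if u_of(idx) >= u_obs - 1e-12:
            hits += 1
    return hits / total


def oracle_auroc(scores, labels) -> float:
    """AUROC by explicit pair counting with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


@pytest.fixture
def perm_triple_matrix():
    """Three 9-gene signatures with pairwise Spearman (0.1, 0.1, 0.4)."""
    return matrix_from_columns([PERM_A, PERM_B, PERM_C])
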