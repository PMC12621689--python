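"""Moderated Z-score (MODZ) aggregation.

MODZ collapses a set of Z-score signatures of one perturbagen into a single
consensus vector by a weighted mean. Each signature's unnormalized weight is
the sum of its pairwise Spearman correlations to the other signatures, with
every pairwise term floored at 0.01 so that no experiment is silenced:

    alpha_i  proportional to  sum_{j != i} max(rho_ij, 0.01),
    sum_i alpha_i = 1.

Correlations are computed over the landmark-gene rows only (the directly
measured space) and the resulting weights are then applied to all genes,
including imputed ones. MODZ is deliberately a weighted mean, not a
meta-analytic combination: the magnitude of the consensus does not inflate
with the number of inputs, which keeps Z-scores comparable between
perturbagens with very different replication depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import ValidationError
from .signatures import SignatureMatrix

__all__ = ["WeightVector", "pairwise_spearman", "modz_weights", "modz_combine", "modz"]

#: Floor applied to every pairwise correlation term before summation.
CORRELATION_FLOOR = 0.01

_WEIGHT_SUM_TOL = 1e-12


@dataclass(frozen=True)
class WeightVector:
    """Normalized, strictly positive MODZ weights aligned to component ids."""

    weights: tuple[float, ...]
    component_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.weights)
        ids = tuple(str(s) for s in self.component_ids)
        if len(w) != len(ids):
            raise ValidationError("weights and component_ids differ in length")
        if len(w) == 0:
            raise ValidationError("empty weight vector")
        if any(x <= 0 for x in w):
            raise ValidationError(f"non-positive weight in {w}")
        if abs(sum(w) - 1.0) > _WEIGHT_SUM_TOL:
            raise ValidationError(f"weights sum to {sum(w)!r}, not 1")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "component_ids", ids)

    def __len__(self) -> int:
        return len(self.weights)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=np.float64)


def _rank_columns(values: np.ndarray, col_ids: Sequence[str]) -> np.ndarray:
    """Column-wise average ranks; a rank-constant column is an error."""
    ranks = np.apply_along_axis(rankdata, 0, values)
    spread = ranks.max(axis=0) - ranks.min(axis=0)
    flat = np.nonzero(spread == 0)[0]
    if flat.size:
        names = [col_ids[j] for j in flat[:5]]
        raise ValidationError(
            f"constant column(s) {names}: Spearman correlation undefined"
        )
    return ranks


def pairwise_spearman(m: SignatureMatrix | np.ndarray, col_ids=None) -> np.ndarray:
    """All pairwise Spearman correlations between columns.

    Ties receive average ranks. The caller is responsible for restricting
    rows to the landmark space first (see :meth:`SignatureMatrix.lm_view`);
    this function correlates whatever rows it is given.
    """
    if isinstance(m, SignatureMatrix):
        values, col_ids = m.values, m.signature_ids
    else:
        values = np.asarray(m, dtype=np.float64)
        if col_ids is None:
            col_ids = [str(j) for j in range(values.shape[1])]
    if values.shape[1] < 2:
        raise ValidationError("need >= 2 columns for pairwise correlation")
    if values.shape[0] < 3:
        raise ValidationError("need >= 3 rows for a meaningful rank correlation")
    if not np.isfinite(values).all():
        return _pairwise_spearman_pairwise_complete(values, col_ids)
    ranks = _rank_columns(values, col_ids)
    corr = np.corrcoef(ranks, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def _pairwise_spearman_pairwise_complete(values: np.ndarray, col_ids) -> np.ndarray:
    """Pairwise-complete Spearman for matrices with NaN entries (opt-in)."""
    n = values.shape[1]
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.isfinite(values[:, i]) & np.isfinite(values[:, j])
            if mask.sum() < 3:
                raise ValidationError(
                    f"columns {col_ids[i]!r}/{col_ids[j]!r}: fewer than 3 shared "
                    "finite rows"
                )
            xi, xj = rankdata(values[mask, i]), rankdata(values[mask, j])
            if xi.max() == xi.min() or xj.max() == xj.min():
                raise ValidationError(
                    f"constant column among {col_ids[i]!r}, {col_ids[j]!r}"
                )
            corr[i, j] = corr[j, i] = np.clip(np.corrcoef(xi, xj)[0, 1], -1.0, 1.0)
    return corr


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation of two vectors with average-rank ties."""
    x = np.asarray(x, np.float64)
    y = np.asarray(y, np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman expects two aligned 1-D vectors")
    rx, ry = rankdata(x), rankdata(y)
    if rx.max() == rx.min() or ry.max() == ry.min():
        raise ValidationError("constant vector: Spearman undefined")
    return float(np.clip(np.corrcoef(rx, ry)[0, 1], -1.0, 1.0))


def modz_weights(
    corr: np.ndarray, component_ids: Sequence[str] | None = None
) -> WeightVector:
    """MODZ weights from a pairwise correlation matrix.

    Each unnormalized weight sums ``max(rho_ij, 0.01)`` over the other
    components; the floor is applied per pairwise term, before summation. A
    single component receives weight 1 (the pairwise sum is empty).
    """
    corr = np.asarray(corr, dtype=np.float64)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValidationError(f"correlation matrix must be square, got {corr.shape}")
    n = corr.shape[0]
    if component_ids is None:
        component_ids = [str(j) for j in range(n)]
    if n == 0:
        raise ValidationError("empty correlation matrix")
    if n == 1:
        return WeightVector((1.0,), tuple(component_ids))
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValidationError("correlation matrix is not symmetric")
    clipped = np.maximum(corr, CORRELATION_FLOOR)
    np.fill_diagonal(clipped, 0.0)
    raw = clipped.sum(axis=1)
    weights = raw / raw.sum()
    # floor guarantees raw > 0, so normalization is always defined
    return WeightVector(tuple(weights), tuple(component_ids))


def modz_combine(m_full: SignatureMatrix | np.ndarray, w: WeightVector) -> np.ndarray:
    """Weighted per-gene combination over the full gene set.

    ``m_full`` carries all genes (landmark and imputed); the weights must
    have been derived from the landmark-restricted correlations and must be
    aligned to the matrix columns by component id.
    """
    if isinstance(m_full, SignatureMatrix):
        if list(w.component_ids) != m_full.signature_ids:
            raise ValidationError(
                "weight component ids do not align with matrix columns"
            )
        values = m_full.values
    else:
        values = np.asarray(m_full, dtype=np.float64)
        if values.shape[1] != len(w):
            raise ValidationError(
                f"{values.shape[1]} columns vs {len(w)} weights"
            )
    return values @ w.as_array()


def modz(m_full: SignatureMatrix, lm_rows: SignatureMatrix | None = None) -> tuple[
    np.ndarray, WeightVector
]:
    """One-call MODZ: weights from landmark rows, combination over all genes.

    ``lm_rows`` defaults to ``m_full.lm_view()``. For a single column the
    weight is 1 and the input passes through unchanged.
    """
    if m_full.n_signatures == 1:
        w = WeightVector((1.0,), tuple(m_full.signature_ids))
        return m_full.values[:, 0].copy(), w
    if lm_rows is None:
        lm_rows = m_full.lm_view()
    corr = pairwise_spearman(lm_rows)
    w = modz_weights(corr, m_full.signature_ids)
    return modz_combine(m_full, w), w
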