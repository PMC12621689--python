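"""Intra-class similarity and transcriptional-activity diagnostics.

Compounds in the same pharmacological class should look alike. This module
measures how alike, in two settings: pairwise Spearman correlations between
the class members' signatures within one cell line, and between their
cross-context consensus signatures, with a one-sided Mann-Whitney U test of
whether the consensus correlations are stochastically greater.

The transcriptional activity score (TAS) is a per-signature strength metric
consumed as metadata (never computed here); TAS <= 0.2 marks a weak
signature. Diagnostics: the fraction of strong components behind each CS,
the cumulative MODZ weight carried by strong components, and the
within-group correlation of TAS with dose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .modz import spearman
from .pipeline import ConsensusSignature
from .signatures import (
    PerturbagenType,
    PharmClassTable,
    SignatureMatrix,
    SignatureMeta,
)
from .stats import MannWhitneyResult, mannwhitney_greater

logger = logging.getLogger(__name__)

__all__ = [
    "TAS_STRONG_THRESHOLD",
    "ClassSimilarityRecord",
    "intra_class_similarity",
    "class_context_test",
    "strong_weak_profile",
    "cumulative_strong_weight",
    "tas_dose_trend",
]

#: TAS strictly above this marks a strong signature.
TAS_STRONG_THRESHOLD = 0.2


@dataclass(frozen=True)
class ClassSimilarityRecord:
    """Pairwise intra-class correlations in one context."""

    class_name: str
    context: str  # a cell-line id, or "consensus"
    pairwise_rhos: tuple[float, ...]
    mw_p_vs_consensus: float | None = None

    @property
    def mean_rho(self) -> float:
        return float(np.mean(self.pairwise_rhos))

    @property
    def n_pairs(self) -> int:
        return len(self.pairwise_rhos)


def _lm_columns(m: SignatureMatrix) -> tuple[np.ndarray, list[SignatureMeta]]:
    lm = m.lm_view()
    return lm.values, lm.columns


def intra_class_similarity(
    m: SignatureMatrix,
    classes: PharmClassTable,
    context: str,
) -> list[ClassSimilarityRecord]:
    """All intra-class pairwise Spearman values in one context.

    ``context`` is a cell-line id (signatures restricted to that cell; all
    signature pairs between distinct member perturbagens are correlated) or
    ``"consensus"`` (``m`` holds one CS column per perturbagen). Classes
    with fewer than two members having signatures in the context are
    dropped with a logged reason.
    """
    if len(classes) == 0:
        raise ValidationError("empty class table")
    if context == "consensus":
        sub = m
    else:
        ids = [c.signature_id for c in m.columns if c.cell_line == context]
        if not ids:
            logger.info("context %r: no signatures at all", context)
            return []
        sub = m.select_columns(ids)
    values, metas = _lm_columns(sub)
    by_pert: dict[str, list[int]] = {}
    for j, c in enumerate(metas):
        by_pert.setdefault(c.perturbagen_id, []).append(j)
    usable = classes.usable_classes(by_pert)
    dropped = set(classes.classes()) - set(usable)
    for name in sorted(dropped):
        logger.info(
            "class %r dropped in context %r: < 2 members with signatures",
            name,
            context,
        )
    records = []
    for name in sorted(usable):
        rhos: list[float] = []
        for pa, pb in combinations(usable[name], 2):
            for ja in by_pert[pa]:
                for jb in by_pert[pb]:
                    rhos.append(spearman(values[:, ja], values[:, jb]))
        records.append(ClassSimilarityRecord(name, context, tuple(rhos)))
    return records


def class_context_test(
    single_cell_rhos: Sequence[float], consensus_rhos: Sequence[float]
) -> MannWhitneyResult:
    """One-sided Mann-Whitney U: consensus correlations stochastically
    greater than single-cell correlations."""
    if len(single_cell_rhos) == 0 or len(consensus_rhos) == 0:
        raise ValidationError("both correlation lists must be non-empty")
    return mannwhitney_greater(consensus_rhos, single_cell_rhos)


def class_similarity_report(
    m: SignatureMatrix,
    cs_matrix: SignatureMatrix,
    classes: PharmClassTable,
    cell_lines: Sequence[str],
) -> pd.DataFrame:
    """Class x context grid: mean intra-class rho and MW p vs consensus.

    Raw p-values are reported alongside a Benjamini-Hochberg column; the
    gate logic elsewhere uses the raw values.
    """
    cons = {r.class_name: r for r in intra_class_similarity(cs_matrix, classes, "consensus")}
    rows = []
    for cell in cell_lines:
        for rec in intra_class_similarity(m, classes, cell):
            c = cons.get(rec.class_name)
            p = (
                class_context_test(rec.pairwise_rhos, c.pairwise_rhos).p_value
                if c is not None
                else np.nan
            )
            rows.append(
                {
                    "class_name": rec.class_name,
                    "context": cell,
                    "n_pairs": rec.n_pairs,
                    "mean_rho": rec.mean_rho,
                    "consensus_mean_rho": np.nan if c is None else c.mean_rho,
                    "mw_p_consensus_greater": p,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["mw_p_bh"] = _benjamini_hochberg(df["mw_p_consensus_greater"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, np.float64)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    q = p[ok]
    n = q.size
    if n == 0:
        return out
    order = np.argsort(q)
    ranked = q[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(n)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


# ---------------------------------------------------------------------------
# TAS diagnostics
# ---------------------------------------------------------------------------

def _component_tas(
    cs: ConsensusSignature, meta_by_id: Mapping[str, SignatureMeta]
) -> tuple[list[float], list[float], int]:
    """(tas values, aligned weights, n components lacking TAS)."""
    tas, wts, missing = [], [], 0
    for sid, w in zip(cs.component_ids, cs.weights.weights):
        t = meta_by_id[sid].tas
        if t is None:
            missing += 1
        else:
            tas.append(t)
            wts.append(w)
    return tas, wts, missing


def strong_weak_profile(
    consensus_set: Sequence[ConsensusSignature],
    meta: Iterable[SignatureMeta],
) -> tuple[pd.DataFrame, MannWhitneyResult | None]:
    """Per-CS fraction of strong components, compared between gold and
    non-gold consensus signatures.

    Components lacking TAS are excluded from the fraction and counted. The
    second return value is the one-sided Mann-Whitney result (gold fractions
    stochastically greater), or None when either group is empty or no TAS is
    available anywhere.
    """
    meta_by_id = {r.signature_id: r for r in meta}
    rows = []
    for cs in consensus_set:
        tas, _w, missing = _component_tas(cs, meta_by_id)
        rows.append(
            {
                "perturbagen_id": cs.perturbagen_id,
                "is_gold": cs.is_gold,
                "n_components": len(cs.component_ids),
                "n_missing_tas": missing,
                "strong_fraction": (
                    np.nan
                    if not tas
                    else float(np.mean([t > TAS_STRONG_THRESHOLD for t in tas]))
                ),
            }
        )
    df = pd.DataFrame(rows)
    usable = df[np.isfinite(df["strong_fraction"])] if not df.empty else df
    if usable.empty:
        logger.warning("no TAS available on any component; comparison skipped")
        return df, None
    gold = usable.loc[usable["is_gold"], "strong_fraction"].to_numpy()
    nongold = usable.loc[~usable["is_gold"], "strong_fraction"].to_numpy()
    if gold.size == 0 or nongold.size == 0:
        return df, None
    return df, mannwhitney_greater(gold, nongold)


def cumulative_strong_weight(
    cs: ConsensusSignature,
    meta: Iterable[SignatureMeta],
    *,
    missing_tas_is_weak: bool = False,
) -> float:
    """Total MODZ weight carried by strong (TAS > 0.2) components.

    The complementary weak weight is ``1 - result`` exactly, since MODZ
    weights sum to one. A component without TAS is an error unless
    ``missing_tas_is_weak`` declares it weak.
    """
    meta_by_id = {r.signature_id: r for r in meta}
    total = 0.0
    for sid, w in zip(cs.component_ids, cs.weights.weights):
        t = meta_by_id[sid].tas
        if t is None:
            if missing_tas_is_weak:
                continue
            raise ValidationError(f"component {sid!r} lacks TAS")
        if t > TAS_STRONG_THRESHOLD:
            total += w
    return total


def tas_dose_trend(
    meta: Iterable[SignatureMeta], *, min_doses: int = 4
) -> tuple[pd.DataFrame, pd.Series]:
    """Spearman correlation of TAS with dose within (perturbagen, cell, time).

    Only compound signatures with both TAS and a molar dose qualify, and
    only groups with at least ``min_doses`` distinct doses are correlated
    (dose equality after µM normalization). Returns the per-group table and
    a summary of the pooled correlation distribution.
    """
    groups: dict[tuple, list[SignatureMeta]] = {}
    n_excluded = 0
    for r in meta:
        if (
            r.perturbagen_type is not PerturbagenType.COMPOUND
            or r.tas is None
            or r.dose is None
            or r.dose.in_um() is None
        ):
            n_excluded += 1
            continue
        groups.setdefault((r.perturbagen_id, r.cell_line, r.time), []).append(r)
    rows = []
    n_small = 0
    for key in sorted(groups):
        members = groups[key]
        doses = np.array([r.dose.in_um() for r in members])
        if len({r.dose.key() for r in members}) < min_doses:
            n_small += 1
            continue
        tas = np.array([r.tas for r in members])
        try:
            rho = spearman(tas, doses)
        except ValidationError:  # constant TAS across the group
            n_small += 1
            continue
        rows.append(
            {
                "perturbagen_id": key[0],
                "cell_line": key[1],
                "time": key[2],
                "n_signatures": len(members),
                "n_doses": len({r.dose.key() for r in members}),
                "spearman_tas_dose": rho,
            }
        )
    logger.info(
        "tas_dose_trend: %d group(s) below %d doses, %d record(s) non-qualifying",
        n_small,
        min_doses,
        n_excluded,
    )
    df = pd.DataFrame(rows)
    if df.empty:
        return df, pd.Series(dtype=np.float64)
    return df, df["spearman_tas_dose"].describe()
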