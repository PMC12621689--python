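"""Consensus-signature construction and the experiments built on it.

The aggregation hierarchy: Level-5 shRNA signatures sharing a target gene
are first collapsed over shRNA sequences into Level-6 consensus genetic
signatures (CGS), one per (gene, cell, time, dose); Level-5 compound
signatures and Level-6 CGS are then collapsed over all profiled cells,
times, and doses into one consensus perturbagen signature (CS) per
perturbagen. Both steps use MODZ. A CS is *gold* when its components span
at least four distinct cell lines and pass the gold-standard q75 >= 0.2
consistency gate.

Also here: the cell-line subset sweep (how inter-perturbagen similarity
changes as more cell lines are integrated) and the self-knockdown screen
(the Z-score of each knockdown's own target gene within its CS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import EligibilityError, ValidationError
from .modz import WeightVector, modz
from .qc import GOLD_Q75_THRESHOLD, QCRecord, gold_standard_test
from .signatures import (
    DataLevel,
    PerturbagenType,
    SignatureMatrix,
    SignatureMeta,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MIN_CELL_LINES",
    "ConsensusSignature",
    "build_cgs",
    "eligible_perturbagens",
    "build_consensus",
    "build_all_consensus",
    "consensus_matrix",
    "subset_sweep",
    "self_knockdown_screen",
]

#: Minimum distinct cell lines for a perturbagen to receive a CS.
MIN_CELL_LINES = 4

#: Exhaustive subset enumeration cap; beyond this, subsets are sampled.
SUBSET_ENUMERATION_CAP = 2 ** 12


@dataclass(frozen=True)
class ConsensusSignature:
    """A MODZ-aggregated consensus with its provenance and QC verdict."""

    perturbagen_id: str
    values: np.ndarray  # Z-vector over the full gene space
    weights: WeightVector
    component_ids: tuple[str, ...]
    n_cell_lines: int
    qc: QCRecord
    level: DataLevel = DataLevel.CS

    @property
    def is_gold(self) -> bool:
        return self.n_cell_lines >= MIN_CELL_LINES and self.qc.passes_gold


def _modz_group(m: SignatureMatrix) -> tuple[np.ndarray, WeightVector]:
    return modz(m)


def build_cgs(m: SignatureMatrix) -> SignatureMatrix:
    """Collapse Level-5 shRNA signatures over shRNA sequences into CGS.

    One output column per (target gene, cell, time, dose) group; groups of
    one pass through with weight 1. The perturbagen id of an shRNA
    signature is its target gene.
    """
    for c in m.columns:
        if c.perturbagen_type is not PerturbagenType.SHRNA:
            raise ValidationError(
                f"{c.signature_id}: build_cgs expects shRNA signatures only"
            )
    groups: dict[tuple, list[int]] = {}
    for j, c in enumerate(m.columns):
        key = (c.perturbagen_id, c.cell_line, c.time, c.dose_key())
        groups.setdefault(key, []).append(j)
    cols: list[np.ndarray] = []
    metas: list[SignatureMeta] = []
    for key in sorted(groups, key=repr):
        idx = groups[key]
        sub = m.select_columns([m.columns[j].signature_id for j in idx])
        values, _w = _modz_group(sub)
        first = m.columns[idx[0]]
        cols.append(values)
        metas.append(
            SignatureMeta(
                signature_id=f"CGS:{first.perturbagen_id}:{first.cell_line}:{first.time}",
                perturbagen_id=first.perturbagen_id,
                perturbagen_type=PerturbagenType.SHRNA,
                cell_line=first.cell_line,
                time=first.time,
                dose=None,
                shrna_seq=None,
                data_level=DataLevel.L6_CGS,
                tas=None,
                n_components=len(idx),
            )
        )
    return SignatureMatrix(m.gene_space, np.column_stack(cols), metas)


def eligible_perturbagens(meta: Iterable[SignatureMeta]) -> set[str]:
    """Perturbagens whose signatures span >= 4 distinct cell lines.

    Cell lines, not signatures, are counted: many replicates in few cells do
    not qualify.
    """
    cells: dict[str, set[str]] = {}
    for r in meta:
        cells.setdefault(r.perturbagen_id, set()).add(r.cell_line)
    return {p for p, cs in cells.items() if len(cs) >= MIN_CELL_LINES}


def build_consensus(
    m: SignatureMatrix,
    perturbagen_id: str,
    *,
    require_eligibility: bool = True,
    stratify_by_dose: bool = False,
) -> ConsensusSignature:
    """MODZ consensus over all of one perturbagen's signatures.

    All (cell, time, dose) contexts enter one pool by default, so the CS
    captures what is consistent across every profiled condition
    (``stratify_by_dose`` restricts the pool to the modal dose instead). The
    QC record holds the q75 of component pairwise correlations; a failing
    gate still returns the CS, flagged non-gold, so callers can filter.
    """
    comp = m.where(lambda c: c.perturbagen_id == perturbagen_id)
    if comp.n_signatures == 0:
        raise ValidationError(f"no signatures for perturbagen {perturbagen_id!r}")
    n_cells = len({c.cell_line for c in comp.columns})
    if require_eligibility and n_cells < MIN_CELL_LINES:
        raise EligibilityError(
            f"{perturbagen_id}: {n_cells} cell line(s) < required {MIN_CELL_LINES}"
        )
    if stratify_by_dose:
        dose_keys = [c.dose_key() for c in comp.columns]
        modal = max(set(map(repr, dose_keys)), key=[repr(k) for k in dose_keys].count)
        keep = [
            c.signature_id for c, k in zip(comp.columns, dose_keys) if repr(k) == modal
        ]
        comp = comp.select_columns(keep)
    values, w = _modz_group(comp)
    qc = gold_standard_test(
        comp, group_key=(("perturbagen", perturbagen_id),), axis="consensus"
    )
    return ConsensusSignature(
        perturbagen_id=perturbagen_id,
        values=values,
        weights=w,
        component_ids=tuple(comp.signature_ids),
        n_cell_lines=n_cells,
        qc=qc,
    )


def build_all_consensus(
    m: SignatureMatrix, *, gold_only: bool = False
) -> list[ConsensusSignature]:
    """Consensus signatures for every eligible perturbagen in the matrix."""
    eligible = eligible_perturbagens(m.columns)
    out = []
    for pid in sorted(eligible):
        cs = build_consensus(m, pid)
        if gold_only and not cs.is_gold:
            continue
        out.append(cs)
    logger.info(
        "built %d consensus signature(s) from %d eligible perturbagen(s)",
        len(out),
        len(eligible),
    )
    return out


def consensus_matrix(
    cs_list: Sequence[ConsensusSignature],
    gene_space,
    perturbagen_type: PerturbagenType | str = PerturbagenType.COMPOUND,
) -> SignatureMatrix:
    """Stack consensus signatures into a genes x perturbagens matrix.

    Cell line and time lose their meaning at the CS level; the columns carry
    the sentinel context ``cell_line="consensus"``, ``time=0``.
    """
    if not cs_list:
        raise ValidationError("no consensus signatures to stack")
    metas = [
        SignatureMeta(
            signature_id=f"CS:{cs.perturbagen_id}",
            perturbagen_id=cs.perturbagen_id,
            perturbagen_type=PerturbagenType(perturbagen_type),
            cell_line="consensus",
            time=0.0,
            data_level=DataLevel.CS,
            n_components=len(cs.component_ids),
        )
        for cs in cs_list
    ]
    values = np.column_stack([cs.values for cs in cs_list])
    return SignatureMatrix(gene_space, values, metas)


# ---------------------------------------------------------------------------
# Cell-line subset sweep
# ---------------------------------------------------------------------------

def _lm_rank_matrix(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(rankdata, 0, values)


def subset_sweep(
    m: SignatureMatrix,
    perturbagen_ids: Sequence[str],
    cell_lines: Sequence[str],
    *,
    max_subsets: int = SUBSET_ENUMERATION_CAP,
    samples_per_size: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Inter-perturbagen similarity of CS built from cell-line subsets.

    For every non-empty subset of ``cell_lines`` (exhaustive while the
    number of subsets stays within ``max_subsets``, uniformly sampled per
    size beyond that), each perturbagen's CS is rebuilt from only that
    subset's signatures and all inter-perturbagen pairwise Spearman values
    (landmark genes) are collected. Returns one row per subset size with
    mean, sd, and quantiles of the pooled correlation distribution.
    """
    if len(perturbagen_ids) < 2:
        raise ValidationError("subset sweep needs >= 2 perturbagens")
    cells = list(dict.fromkeys(cell_lines))
    have = {
        (c.perturbagen_id, c.cell_line) for c in m.columns
    }
    for pid in perturbagen_ids:
        missing = [cl for cl in cells if (pid, cl) not in have]
        if missing:
            raise ValidationError(
                f"perturbagen {pid!r} lacks signatures in cell line(s) {missing[:3]}"
            )
    k = len(cells)
    rng = np.random.default_rng(seed)
    subsets: list[tuple[str, ...]] = []
    if 2 ** k - 1 <= max_subsets:
        for size in range(1, k + 1):
            subsets.extend(combinations(cells, size))
    else:
        for size in range(1, k + 1):
            seen: set[tuple[str, ...]] = set()
            target = min(samples_per_size, _comb(k, size))
            while len(seen) < target:
                pick = tuple(sorted(rng.choice(cells, size=size, replace=False)))
                seen.add(pick)
            subsets.extend(sorted(seen))

    lm = m.lm_view()
    per_size: dict[int, list[float]] = {}
    for subset in subsets:
        subset_set = set(subset)
        cs_cols = []
        for pid in perturbagen_ids:
            comp = m.where(
                lambda c: c.perturbagen_id == pid and c.cell_line in subset_set
            )
            values, _ = _modz_group(comp)
            cs_cols.append(values)
        cs_vals = np.column_stack(cs_cols)
        lm_idx = m.gene_space.index_of(m.gene_space.lm_ids)
        ranks = _lm_rank_matrix(cs_vals[lm_idx])
        corr = np.corrcoef(ranks, rowvar=False)
        iu = np.triu_indices(len(perturbagen_ids), k=1)
        per_size.setdefault(len(subset), []).extend(corr[iu].tolist())

    rows = []
    for size in sorted(per_size):
        arr = np.asarray(per_size[size])
        rows.append(
            {
                "subset_size": size,
                "n_subsets": sum(1 for s in subsets if len(s) == size),
                "n_correlations": arr.size,
                "mean": arr.mean(),
                "sd": arr.std(ddof=1) if arr.size > 1 else 0.0,
                "q05": np.percentile(arr, 5),
                "q25": np.percentile(arr, 25),
                "median": np.percentile(arr, 50),
                "q75": np.percentile(arr, 75),
                "q95": np.percentile(arr, 95),
            }
        )
    return pd.DataFrame(rows)


def _comb(n: int, k: int) -> int:
    from math import comb as c

    return c(n, k)


# ---------------------------------------------------------------------------
# Self-knockdown screen
# ---------------------------------------------------------------------------

def self_knockdown_screen(
    cs_matrix: SignatureMatrix,
    target_of: Mapping[str, str] | None = None,
    *,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Z-score of each knockdown's own target gene within its consensus.

    Most knockdowns down-regulate their target; a positive, outlying
    self-Z marks a knockdown-resistant gene. The flag compares the target's
    robust z within its own CS column, ``(z - median) / (1.4826 * MAD)``,
    against ``z_threshold`` (default 2), with the direction from the sign.

    ``target_of`` maps perturbagen id -> target gene id; by default each
    knockdown is assumed to target the gene named by its perturbagen id.
    Knockdowns whose target is absent from the gene space are skipped with
    a warning.
    """
    rows = []
    gene_pos = {g: i for i, g in enumerate(cs_matrix.gene_space.gene_ids)}
    for j, c in enumerate(cs_matrix.columns):
        target = (
            target_of.get(c.perturbagen_id) if target_of else c.perturbagen_id
        )
        if target is None or target not in gene_pos:
            logger.warning(
                "%s: target gene %r not in gene space; skipped",
                c.signature_id,
                target,
            )
            continue
        col = cs_matrix.values[:, j]
        self_z = float(col[gene_pos[target]])
        med = float(np.median(col))
        mad = float(np.median(np.abs(col - med)))
        scale = 1.4826 * mad
        robust = (self_z - med) / scale if scale > 0 else np.inf * np.sign(self_z - med)
        if abs(robust) >= z_threshold:
            flag = "up_regulated" if robust > 0 else "down_regulated"
        else:
            flag = "ns"
        rows.append(
            {
                "perturbagen_id": c.perturbagen_id,
                "target_gene": target,
                "self_z": self_z,
                "robust_z": float(robust),
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)
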