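"""Replicate- and cross-context consistency quality control.

The gold-standard consistency rule: a group of signatures is reproducible
when the 75th percentile of its pairwise Spearman correlations (over
landmark genes) is at least 0.2. This module applies that rule within
replicate groups, across cell lines (holding perturbagen, time, dose, and —
for knockdowns — shRNA sequence fixed), and to the component sets of
consensus signatures, and computes how representative a consensus is of its
constituents. No distinctness requirement is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .modz import pairwise_spearman, spearman
from .signatures import PerturbagenType, SignatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GOLD_Q75_THRESHOLD",
    "QCRecord",
    "q75",
    "gold_standard_test",
    "cross_context_consistency",
    "representativeness",
    "qc_report_frame",
]

#: Inclusive threshold on the 75th percentile of pairwise Spearman values.
GOLD_Q75_THRESHOLD = 0.2


@dataclass(frozen=True)
class QCRecord:
    """Consistency verdict for one signature group."""

    group_key: tuple
    n_signatures: int
    q75_spearman: float | None
    passes_gold: bool
    comparison_axis: str  # replicate | cross_cell | cross_dose | cross_time | consensus
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.q75_spearman is not None and not (-1.0 - 1e-12 <= self.q75_spearman <= 1.0 + 1e-12):
            raise ValidationError(f"q75 out of [-1, 1]: {self.q75_spearman}")
        if self.q75_spearman is None and self.passes_gold:
            raise ValidationError("a group with undefined q75 cannot pass")


def q75(values: Sequence[float]) -> float:
    """75th percentile with linear interpolation between order statistics."""
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise ValidationError("q75 of an empty list is undefined")
    return float(np.percentile(arr, 75, method="linear"))


def gold_gate(rhos: Sequence[float]) -> tuple[float, bool]:
    """Apply the gold-standard rule to a list of pairwise correlations."""
    q = q75(rhos)
    return q, q >= GOLD_Q75_THRESHOLD


def gold_standard_test(
    m: SignatureMatrix,
    group_key: tuple = (),
    axis: str = "replicate",
) -> QCRecord:
    """Gold-standard consistency of one group of signatures.

    Correlations are taken over the landmark rows of ``m``. A
    single-signature group yields an undefined q75 and a failing flag — it
    is reported, never silently dropped.
    """
    n = m.n_signatures
    if n < 2:
        logger.warning("group %s has %d signature(s); q75 undefined", group_key, n)
        return QCRecord(group_key, n, None, False, axis, n_pairs=0)
    corr = pairwise_spearman(m.lm_view())
    iu = np.triu_indices(n, k=1)
    rhos = corr[iu]
    q, ok = gold_gate(rhos)
    return QCRecord(group_key, n, q, ok, axis, n_pairs=len(rhos))


def _context_key(meta, control_axes: Sequence[str]) -> tuple:
    parts = []
    for ax in control_axes:
        if ax == "time":
            parts.append(("time", meta.time))
        elif ax == "dose":
            parts.append(("dose", meta.dose_key()))
        elif ax == "sequence":
            parts.append(("sequence", meta.shrna_seq))
        elif ax == "cell_line":
            parts.append(("cell_line", meta.cell_line))
        else:
            raise ValidationError(f"unknown control axis {ax!r}")
    return tuple(parts)


def cross_context_consistency(
    m: SignatureMatrix,
    vary_axis: str = "cell_line",
    control_axes: Sequence[str] | None = None,
) -> tuple[list[QCRecord], int]:
    """Gold-standard test across a varying context, e.g. across cell lines.

    Signatures of each perturbagen are grouped by the controlled coordinates
    (time and dose by default, plus shRNA sequence for knockdown signatures
    below the CGS level); within each group, only pairs differing on the
    varied axis enter the q75. Groups spanning fewer than two values of the
    varied axis are skipped and counted.

    Returns ``(records, n_skipped)``.
    """
    if vary_axis not in ("cell_line", "time", "dose"):
        raise ValidationError(f"unsupported vary axis {vary_axis!r}")
    axis_label = {"cell_line": "cross_cell", "time": "cross_time", "dose": "cross_dose"}[
        vary_axis
    ]
    groups: dict[tuple, list[int]] = {}
    for j, meta in enumerate(m.columns):
        axes = list(control_axes) if control_axes is not None else [
            ax for ax in ("cell_line", "time", "dose") if ax != vary_axis
        ]
        if (
            control_axes is None
            and meta.perturbagen_type is PerturbagenType.SHRNA
            and meta.shrna_seq is not None
        ):
            axes.append("sequence")
        key = (("perturbagen", meta.perturbagen_id),) + _context_key(meta, axes)
        groups.setdefault(key, []).append(j)

    def axis_value(meta):
        if vary_axis == "cell_line":
            return meta.cell_line
        if vary_axis == "time":
            return meta.time
        return meta.dose_key()

    records: list[QCRecord] = []
    skipped = 0
    lm = m.lm_view()
    for key in sorted(groups, key=repr):
        idx = groups[key]
        vals = [axis_value(m.columns[j]) for j in idx]
        if len(set(map(repr, vals))) < 2:
            skipped += 1
            continue
        corr = pairwise_spearman(lm.values[:, idx], [m.columns[j].signature_id for j in idx])
        rhos = [
            corr[a, b]
            for a, b in combinations(range(len(idx)), 2)
            if repr(vals[a]) != repr(vals[b])  # inter-context pairs only
        ]
        q, ok = gold_gate(rhos)
        records.append(
            QCRecord(key, len(idx), q, ok, axis_label, n_pairs=len(rhos))
        )
    if skipped:
        logger.info(
            "%s: skipped %d group(s) with < 2 distinct %s values",
            axis_label,
            skipped,
            vary_axis,
        )
    return records, skipped


def representativeness(cs_values: np.ndarray, components: SignatureMatrix) -> float:
    """Median Spearman correlation between a consensus and its components.

    Both sides are restricted to landmark genes before correlating; the
    caller passes the consensus vector over the same gene space as
    ``components``.
    """
    if components.n_signatures == 0:
        raise ValidationError("no component signatures")
    cs_values = np.asarray(cs_values, dtype=np.float64)
    if cs_values.shape != (components.n_genes,):
        raise ValidationError(
            f"consensus length {cs_values.shape} != gene count {components.n_genes}"
        )
    lm_idx = components.gene_space.index_of(components.gene_space.lm_ids)
    cs_lm = cs_values[lm_idx]
    rhos = [
        spearman(cs_lm, components.values[lm_idx, j])
        for j in range(components.n_signatures)
    ]
    return float(np.median(rhos))


def qc_report_frame(records: Iterable[QCRecord]) -> pd.DataFrame:
    """QC records as a flat table, one row per group (TSV-ready)."""
    rows = []
    for r in records:
        rows.append(
            {
                "group_key": "; ".join(f"{k}={v}" for k, v in r.group_key),
                "n_signatures": r.n_signatures,
                "n_pairs": r.n_pairs,
                "q75_spearman": np.nan if r.q75_spearman is None else r.q75_spearman,
                "passes_gold": r.passes_gold,
                "comparison_axis": r.comparison_axis,
            }
        )
    return pd.DataFrame(rows)
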