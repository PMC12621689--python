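"""Evaluating a consensus signature as a cross-context predictor.

A consensus signature assigns every gene a Z-score whose sign predicts the
direction of regulation and whose magnitude expresses confidence. Given an
external differential-expression table (gene, log2 fold change) from a cell
line the consensus never saw, this module scores the prediction four ways:
Spearman correlation of Z against log2FC, AUROC treating the external
direction as the label and Z as the score, a one-sided Mann-Whitney test of
whether correctly predicted genes carry larger |Z| than incorrect ones, and
Jaccard overlap of regulated gene sets between two external contexts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .modz import spearman
from .signatures import GeneClass, GeneSpace
from .stats import MannWhitneyResult, auroc, mannwhitney_greater

logger = logging.getLogger(__name__)

__all__ = [
    "DETable",
    "read_de_table",
    "match_genes",
    "direction_auroc",
    "split_by_agreement",
    "confidence_test",
    "jaccard",
    "jaccard_from_counts",
    "overlap_report",
    "evaluate_prediction",
]


@dataclass(frozen=True)
class DETable:
    """External differential-expression results for one context.

    ``direction`` is derived from the sign of log2FC; a zero log2FC carries
    no direction and is excluded from direction-based analyses.
    """

    frame: pd.DataFrame  # columns: gene_id, log2fc, significant

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("gene_id", "log2fc"):
            if col not in df.columns:
                raise SchemaError(f"DE table missing column {col!r}")
        if df["gene_id"].duplicated().any():
            dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValidationError(f"duplicate gene ids in DE table: {dupes[:5]}")
        if "significant" not in df.columns:
            df = df.assign(significant=True)
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @property
    def gene_ids(self) -> list[str]:
        return self.frame["gene_id"].tolist()

    def direction_of(self) -> pd.Series:
        """'up', 'down', or None per gene, from the sign of log2FC."""
        fc = self.frame["log2fc"]
        return pd.Series(
            np.where(fc > 0, "up", np.where(fc < 0, "down", None)),
            index=self.frame["gene_id"],
        )

    def regulated(self, direction: str, *, significant_only: bool = True) -> set[str]:
        df = self.frame
        if significant_only:
            df = df[df["significant"].astype(bool)]
        if direction == "up":
            sel = df["log2fc"] > 0
        elif direction == "down":
            sel = df["log2fc"] < 0
        else:
            raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
        return set(df.loc[sel, "gene_id"])


def read_de_table(path: str | Path) -> DETable:
    """TSV with columns gene_id, log2fc, optional significant/padj."""
    df = pd.read_csv(path, sep="\t")
    if "significant" in df.columns:
        df["significant"] = df["significant"].astype(bool)
    elif "padj" in df.columns:
        df["significant"] = df["padj"] < 0.05
    df["gene_id"] = df["gene_id"].astype(str)
    return DETable(df)


def match_genes(
    cs_values: Mapping[str, float] | tuple[np.ndarray, GeneSpace],
    de: DETable,
    subset: GeneClass | str | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Pair consensus Z-scores with external log2FC on shared genes.

    ``cs_values`` is either a gene->Z mapping or ``(vector, gene_space)``.
    ``subset`` optionally restricts to one gene class. Returns the paired
    frame (gene_id, z, log2fc) in DE-table order and counts of unmatched
    genes on each side.
    """
    if isinstance(cs_values, tuple):
        vec, space = cs_values
        vec = np.asarray(vec, np.float64)
        if vec.shape != (len(space),):
            raise ValidationError("consensus vector does not match gene space")
        z_of = dict(zip(space.gene_ids, vec))
        if subset is not None:
            keep = set(space.ids_of_class(GeneClass(subset)))
            z_of = {g: z for g, z in z_of.items() if g in keep}
    else:
        z_of = dict(cs_values)
        if subset is not None:
            raise ValidationError("gene-class subset requires a GeneSpace")
    de_ids = de.gene_ids
    shared = [g for g in de_ids if g in z_of]
    if not shared:
        raise ValidationError("no genes shared between consensus and DE table")
    fc_of = dict(zip(de.frame["gene_id"], de.frame["log2fc"]))
    pairs = pd.DataFrame(
        {
            "gene_id": shared,
            "z": [z_of[g] for g in shared],
            "log2fc": [fc_of[g] for g in shared],
        }
    )
    counts = {
        "n_pairs": len(shared),
        "n_de_unmatched": len(de_ids) - len(shared),
        "n_cs_unmatched": len(z_of) - len(shared),
    }
    return pairs, counts


def direction_auroc(pairs: pd.DataFrame) -> float:
    """AUROC of sign(log2FC) labels predicted by the consensus Z scores.

    Genes with zero log2FC carry no label and are dropped; both directions
    must remain. Tied Z scores get half credit.
    """
    labeled = pairs[pairs["log2fc"] != 0]
    labels = (labeled["log2fc"] > 0).to_numpy()
    if labels.all() or not labels.any():
        raise ValidationError("AUROC undefined: only one regulation direction present")
    return auroc(labeled["z"].to_numpy(), labels)


def split_by_agreement(
    pairs: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split gene pairs by sign agreement between Z and log2FC.

    Returns ``(correct, incorrect, excluded)``; a pair with Z = 0 or
    log2FC = 0 has an undefined sign and goes to excluded.
    """
    z = pairs["z"].to_numpy()
    fc = pairs["log2fc"].to_numpy()
    defined = (z != 0) & (fc != 0)
    agree = np.sign(z) == np.sign(fc)
    correct = pairs[defined & agree]
    incorrect = pairs[defined & ~agree]
    excluded = pairs[~defined]
    return correct, incorrect, excluded


def confidence_test(
    correct_abs_z: Sequence[float], incorrect_abs_z: Sequence[float]
) -> MannWhitneyResult:
    """One-sided Mann-Whitney: |Z| of correct predictions stochastically
    greater than |Z| of incorrect ones (null: correct <= incorrect)."""
    return mannwhitney_greater(correct_abs_z, incorrect_abs_z)


def jaccard(a: set, b: set) -> float:
    """Intersection over union of two sets."""
    if not a and not b:
        raise ValidationError("Jaccard of two empty sets is undefined")
    return len(a & b) / len(a | b)


def jaccard_from_counts(n_a: int, n_b: int, n_shared: int) -> float:
    """Jaccard from set sizes and intersection size."""
    if n_shared > min(n_a, n_b) or min(n_a, n_b, n_shared) < 0:
        raise ValidationError(
            f"inconsistent counts: |A|={n_a}, |B|={n_b}, shared={n_shared}"
        )
    union = n_a + n_b - n_shared
    if union == 0:
        raise ValidationError("Jaccard of two empty sets is undefined")
    return n_shared / union


def overlap_report(
    de1: DETable,
    de2: DETable,
    gene_space: GeneSpace | None = None,
) -> pd.DataFrame:
    """Jaccard overlap of regulated gene sets between two contexts.

    One row per (direction x gene class), plus an 'all' row per direction.
    Directions with no regulated genes in either context yield Jaccard 0
    only when one side is non-empty; the both-empty case is reported NaN.
    """
    classes: list[tuple[str, set[str] | None]] = [("all", None)]
    if gene_space is not None:
        for cls_ in GeneClass:
            classes.append((cls_.value, set(gene_space.ids_of_class(cls_))))
    rows = []
    for direction in ("up", "down"):
        s1 = de1.regulated(direction)
        s2 = de2.regulated(direction)
        for label, keep in classes:
            a = s1 if keep is None else s1 & keep
            b = s2 if keep is None else s2 & keep
            rows.append(
                {
                    "direction": direction,
                    "gene_class": label,
                    "n_context1": len(a),
                    "n_context2": len(b),
                    "n_shared": len(a & b),
                    "jaccard": np.nan if not (a or b) else jaccard(a, b),
                }
            )
    return pd.DataFrame(rows)


def evaluate_prediction(
    cs_vector: np.ndarray,
    gene_space: GeneSpace,
    de: DETable,
    gene_sets: Sequence[str] = ("LM", "BING", "INFERRED"),
) -> pd.DataFrame:
    """Per-gene-class evaluation report: size, Spearman rho, AUROC, MW p.

    Mirrors the structure correlation / classifier / confidence: one row
    per gene class with the number of matched genes, the rank correlation
    of Z with log2FC, the direction AUROC, and the p-value of the
    confidence test, plus agreement counts.
    """
    rows = []
    for label in gene_sets:
        try:
            pairs, counts = match_genes((cs_vector, gene_space), de, subset=label)
        except ValidationError:
            logger.info("gene set %s: no shared genes; skipped", label)
            continue
        correct, incorrect, excluded = split_by_agreement(pairs)
        row = {
            "gene_set": label,
            "n_genes": counts["n_pairs"],
            "spearman_rho": (
                spearman(pairs["z"].to_numpy(), pairs["log2fc"].to_numpy())
                if len(pairs) >= 3
                else np.nan
            ),
            "n_correct": len(correct),
            "n_incorrect": len(incorrect),
            "n_excluded": len(excluded),
        }
        try:
            row["auroc"] = direction_auroc(pairs)
        except ValidationError:
            row["auroc"] = np.nan
        if len(correct) and len(incorrect):
            row["mw_p"] = confidence_test(
                np.abs(correct["z"]), np.abs(incorrect["z"])
            ).p_value
        else:
            row["mw_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
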