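"""Core domain types: gene spaces, signature metadata, and Z-score matrices.

The central container is :class:`SignatureMatrix` — a dense genes x
signatures matrix of differential-expression Z-scores with an aligned
:class:`GeneSpace` (landmark / best-inferred / inferred partition) and one
:class:`SignatureMeta` record per column describing the experimental
coordinates (perturbagen, cell line, time, dose, shRNA sequence, data
level). Every downstream stage (MODZ aggregation, consistency QC, consensus
construction, similarity and prediction analyses) consumes and produces
this container.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "GeneClass",
    "GeneSpace",
    "PerturbagenType",
    "DataLevel",
    "Dose",
    "SignatureMeta",
    "SignatureMatrix",
    "PharmClassTable",
    "subset_genes",
]


class GeneClass(str, enum.Enum):
    """Confidence tier of a gene in an L1000-style assay.

    LM genes are directly measured (the ~978 landmark genes); BING genes are
    imputed with high confidence ("best inferred"); INFERRED covers the
    remaining, lower-confidence imputed genes.
    """

    LM = "LM"
    BING = "BING"
    INFERRED = "INFERRED"


class PerturbagenType(str, enum.Enum):
    COMPOUND = "compound"
    SHRNA = "shRNA"


class DataLevel(str, enum.Enum):
    """Data tier: per-replicate Z-scores (L4), replicate-collapsed signatures
    (L5), consensus genetic signatures over shRNA sequences (L6_CGS), and
    cross-context consensus perturbagen signatures (CS)."""

    L4 = "L4"
    L5 = "L5"
    L6_CGS = "L6_CGS"
    CS = "CS"


@dataclass(frozen=True)
class GeneSpace:
    """Ordered set of gene identifiers with a confidence class per gene."""

    gene_ids: tuple[str, ...]
    class_of: Mapping[str, GeneClass]

    def __post_init__(self) -> None:
        ids = tuple(str(g) for g in self.gene_ids)
        if len(set(ids)) != len(ids):
            dupes = sorted({g for g in ids if list(ids).count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        classes = {str(g): GeneClass(c) for g, c in self.class_of.items()}
        missing = [g for g in ids if g not in classes]
        if missing:
            raise ValidationError(
                f"{len(missing)} gene(s) lack a class assignment, e.g. {missing[:5]}"
            )
        object.__setattr__(self, "gene_ids", ids)
        object.__setattr__(self, "class_of", classes)

    @classmethod
    def all_landmark(cls, gene_ids: Iterable[str]) -> "GeneSpace":
        """Convenience constructor: every gene is a landmark gene."""
        ids = tuple(str(g) for g in gene_ids)
        return cls(ids, {g: GeneClass.LM for g in ids})

    def __len__(self) -> int:
        return len(self.gene_ids)

    def ids_of_class(self, cls_: GeneClass | str) -> tuple[str, ...]:
        cls_ = GeneClass(cls_)
        return tuple(g for g in self.gene_ids if self.class_of[g] is cls_)

    @property
    def lm_ids(self) -> tuple[str, ...]:
        return self.ids_of_class(GeneClass.LM)

    def index_of(self, gene_ids: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise ValidationError(
                f"gene(s) absent from gene space: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        return np.asarray([pos[g] for g in gene_ids], dtype=np.intp)


_DOSE_UNIT_TO_UM = {
    "um": 1.0,
    "µm": 1.0,
    "μm": 1.0,  # micro sign vs greek mu
    "nm": 1e-3,
    "mm": 1e3,
    "m": 1e6,
}

_DOSE_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Zµμ%]*)\s*$")


@dataclass(frozen=True)
class Dose:
    """A numeric dose with its unit, comparable after normalization to µM.

    Two doses compare equal when their µM-normalized values agree within a
    relative tolerance of 1e-6; unit-less doses only compare with other
    unit-less doses of the same value.
    """

    value: float
    unit: str = "uM"

    RTOL = 1e-6

    @classmethod
    def parse(cls, raw: object) -> "Dose":
        if isinstance(raw, Dose):
            return raw
        if isinstance(raw, (int, float)) and not isinstance(raw, bool):
            if not math.isfinite(float(raw)):
                raise ValidationError(f"non-finite dose: {raw!r}")
            return cls(float(raw), "uM")
        m = _DOSE_RE.match(str(raw))
        if m is None:
            raise ValidationError(f"unparseable dose: {raw!r}")
        try:
            value = float(m.group(1))
        except ValueError as exc:
            raise ValidationError(f"unparseable dose: {raw!r}") from exc
        unit = m.group(2) or "uM"
        return cls(value, unit)

    def in_um(self) -> float | None:
        """Value in µM, or None when the unit is not a molar concentration."""
        factor = _DOSE_UNIT_TO_UM.get(self.unit.lower())
        return None if factor is None else self.value * factor

    def matches(self, other: "Dose") -> bool:
        a, b = self.in_um(), other.in_um()
        if a is None or b is None:
            return self.unit.lower() == other.unit.lower() and math.isclose(
                self.value, other.value, rel_tol=self.RTOL, abs_tol=0.0
            )
        return math.isclose(a, b, rel_tol=self.RTOL, abs_tol=0.0)

    def key(self) -> tuple:
        """A hashable grouping key; doses equal under :meth:`matches` share it.

        Rounding the µM value to 6 significant digits realizes the 1e-6
        relative tolerance for grouping purposes.
        """
        um = self.in_um()
        if um is None:
            return (self.unit.lower(), self.value)
        if um == 0.0:
            return ("uM", 0.0)
        exp = math.floor(math.log10(abs(um)))
        return ("uM", round(um, 6 - 1 - exp))


@dataclass(frozen=True)
class SignatureMeta:
    """Experimental coordinates of one signature column."""

    signature_id: str
    perturbagen_id: str
    perturbagen_type: PerturbagenType
    cell_line: str
    time: float  # hours
    dose: Dose | None = None
    shrna_seq: str | None = None
    data_level: DataLevel = DataLevel.L5
    tas: float | None = None
    n_components: int = 1
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "perturbagen_type", PerturbagenType(self.perturbagen_type)
        )
        object.__setattr__(self, "data_level", DataLevel(self.data_level))
        if self.shrna_seq is not None and self.perturbagen_type is not PerturbagenType.SHRNA:
            raise ValidationError(
                f"{self.signature_id}: shrna_seq given for a non-shRNA perturbagen"
            )
        if self.tas is not None and self.tas < 0:
            raise ValidationError(f"{self.signature_id}: negative TAS {self.tas}")
        if self.n_components < 1:
            raise ValidationError(f"{self.signature_id}: n_components < 1")
        if self.data_level is DataLevel.L4 and self.n_components != 1:
            raise ValidationError(
                f"{self.signature_id}: Level-4 records are single replicates"
            )

    def dose_key(self) -> tuple:
        return ("-",) if self.dose is None else self.dose.key()

    def with_(self, **kw) -> "SignatureMeta":
        return replace(self, **kw)


class SignatureMatrix:
    """Dense genes x signatures Z-score matrix with aligned metadata.

    Parameters
    ----------
    gene_space
        Gene identifiers and classes for the rows, in row order.
    values
        2-D float array, shape ``(n_genes, n_signatures)``. Entries must be
        finite unless ``allow_missing`` is set, in which case NaN marks a
        missing value and correlations downstream become pairwise-complete.
    columns
        Metadata records, one per column, in column order.
    """

    def __init__(
        self,
        gene_space: GeneSpace,
        values: np.ndarray,
        columns: Sequence[SignatureMeta],
        *,
        allow_missing: bool = False,
    ) -> None:
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2:
            raise ValidationError(f"values must be 2-D, got shape {values.shape}")
        if values.shape[0] != len(gene_space):
            raise ValidationError(
                f"row count {values.shape[0]} != gene space size {len(gene_space)}"
            )
        columns = list(columns)
        if values.shape[1] != len(columns):
            raise ValidationError(
                f"column count {values.shape[1]} != metadata records {len(columns)}"
            )
        ids = [c.signature_id for c in columns]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate signature ids: {dupes[:5]}")
        if not allow_missing and not np.isfinite(values).all():
            bad = [ids[j] for j in np.unique(np.argwhere(~np.isfinite(values))[:, 1])]
            raise ValidationError(
                f"non-finite entries in column(s) {bad[:5]}; pass allow_missing=True "
                "to opt into pairwise-complete handling"
            )
        self.gene_space = gene_space
        self.values = values
        self.columns = columns
        self.allow_missing = allow_missing
        self._col_index = {c.signature_id: j for j, c in enumerate(columns)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_signatures(self) -> int:
        return self.values.shape[1]

    @property
    def signature_ids(self) -> list[str]:
        return [c.signature_id for c in self.columns]

    def column(self, signature_id: str) -> np.ndarray:
        return self.values[:, self._col_index[signature_id]]

    def meta(self, signature_id: str) -> SignatureMeta:
        return self.columns[self._col_index[signature_id]]

    def meta_frame(self) -> pd.DataFrame:
        """Metadata as a DataFrame (doses reported in their original units)."""
        rows = []
        for c in self.columns:
            rows.append(
                {
                    "signature_id": c.signature_id,
                    "perturbagen_id": c.perturbagen_id,
                    "perturbagen_type": c.perturbagen_type.value,
                    "cell_line": c.cell_line,
                    "time": c.time,
                    "dose": "" if c.dose is None else f"{c.dose.value} {c.dose.unit}",
                    "shrna_seq": c.shrna_seq or "",
                    "data_level": c.data_level.value,
                    "tas": np.nan if c.tas is None else c.tas,
                    "n_components": c.n_components,
                }
            )
        return pd.DataFrame(rows)

    # -- selection -----------------------------------------------------------
    def select_columns(self, signature_ids: Sequence[str]) -> "SignatureMatrix":
        missing = [s for s in signature_ids if s not in self._col_index]
        if missing:
            raise ValidationError(f"unknown signature id(s): {missing[:5]}")
        if not signature_ids:
            raise ValidationError("empty column selection")
        idx = [self._col_index[s] for s in signature_ids]
        return SignatureMatrix(
            self.gene_space,
            self.values[:, idx],
            [self.columns[j] for j in idx],
            allow_missing=self.allow_missing,
        )

    def where(self, predicate) -> "SignatureMatrix":
        ids = [c.signature_id for c in self.columns if predicate(c)]
        return self.select_columns(ids)

    def lm_view(self) -> "SignatureMatrix":
        """Rows restricted to landmark genes (the correlation space)."""
        return subset_genes(self, GeneClass.LM)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SignatureMatrix({self.n_genes} genes x {self.n_signatures} signatures)"
        )


def subset_genes(
    m: SignatureMatrix, selector: GeneClass | str | Iterable[str]
) -> SignatureMatrix:
    """Restrict a matrix to a gene class or an explicit ordered id set.

    Columns are untouched; rows are reordered to the requested order. An
    empty result is a validation error — silently returning a 0-row matrix
    would make downstream correlations meaningless.
    """
    if isinstance(selector, GeneClass) or (
        isinstance(selector, str) and selector in GeneClass.__members__
    ):
        wanted = list(m.gene_space.ids_of_class(GeneClass(selector)))
    elif isinstance(selector, str):
        wanted = [selector]
    else:
        wanted = [str(g) for g in selector]
    if not wanted:
        raise ValidationError(f"gene subset {selector!r} selects no genes")
    idx = m.gene_space.index_of(wanted)
    sub_space = GeneSpace(tuple(wanted), {g: m.gene_space.class_of[g] for g in wanted})
    return SignatureMatrix(
        sub_space, m.values[idx, :], m.columns, allow_missing=m.allow_missing
    )


@dataclass(frozen=True)
class PharmClassTable:
    """Pharmacological class membership: class name -> perturbagen ids."""

    members: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "members",
            {str(k): frozenset(str(p) for p in v) for k, v in self.members.items()},
        )

    def __len__(self) -> int:
        return len(self.members)

    def classes(self) -> list[str]:
        return sorted(self.members)

    def usable_classes(self, available: Iterable[str]) -> dict[str, list[str]]:
        """Classes with >= 2 members among ``available`` perturbagens.

        Classes reduced to fewer than two profiled members carry no pairwise
        information and are dropped (the caller logs the exclusions).
        """
        avail = set(available)
        out: dict[str, list[str]] = {}
        for name, ids in self.members.items():
            present = sorted(ids & avail)
            if len(present) >= 2:
                out[name] = present
        return out
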