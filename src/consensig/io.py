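"""Readers and writers for GCT 1.3 text, GCTX (HDF5), and TSV side tables.

GCT 1.3 text is the reference dialect: a ``#1.3`` version line, a dimension
line ``nrows ncols n_row_meta n_col_meta``, a header row, ``n_col_meta``
column-annotation rows, then one row per gene. GCTX is an optional HDF5
backend storing the matrix at ``/0/DATA/0/matrix`` (signatures x genes, the
cmap convention) with ids under ``/0/META/ROW/id`` and ``/0/META/COL/id``.

Signature metadata travels separately as a TSV whose dialect mirrors LINCS
signature-info tables (one row per signature; required columns
``signature_id, perturbagen_id, perturbagen_type, cell_line, time``).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError
from .signatures import (
    DataLevel,
    Dose,
    GeneClass,
    GeneSpace,
    PerturbagenType,
    PharmClassTable,
    SignatureMatrix,
    SignatureMeta,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_gct",
    "write_gct",
    "read_gctx",
    "write_gctx",
    "read_metadata",
    "write_metadata",
    "read_gene_space",
    "read_class_table",
    "attach_metadata",
]


# ---------------------------------------------------------------------------
# GCT 1.3 text
# ---------------------------------------------------------------------------

def read_gct(path: str | Path, gene_space: GeneSpace | None = None) -> tuple[
    np.ndarray, list[str], list[str]
]:
    """Parse a GCT 1.3 file into ``(values, gene_ids, column_ids)``.

    Row metadata columns and column metadata rows are tolerated and skipped;
    signature metadata is attached separately via :func:`attach_metadata`.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        version = fh.readline().rstrip("\n")
        if not version.startswith("#1.3"):
            raise FormatError(f"{path}: expected '#1.3' version line, got {version!r}")
        dims = fh.readline().rstrip("\n").split("\t")
        if len(dims) not in (2, 4):
            raise FormatError(f"{path}: malformed dimension line {dims!r}")
        try:
            nrow, ncol = int(dims[0]), int(dims[1])
            nrmeta = int(dims[2]) if len(dims) == 4 else 0
            ncmeta = int(dims[3]) if len(dims) == 4 else 0
        except ValueError as exc:
            raise FormatError(f"{path}: malformed dimension line {dims!r}") from exc
        header = fh.readline().rstrip("\n").split("\t")
        expected_header = 1 + nrmeta + ncol
        if len(header) != expected_header:
            raise FormatError(
                f"{path}: header has {len(header)} fields, expected {expected_header}"
            )
        col_ids = header[1 + nrmeta :]
        for _ in range(ncmeta):  # column-annotation rows, not modeled here
            fh.readline()
        gene_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=4 + ncmeta):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != expected_header:
                raise FormatError(
                    f"{path}:{lineno}: {len(parts)} fields, expected {expected_header}"
                )
            gene_ids.append(parts[0])
            try:
                rows.append(np.array(parts[1 + nrmeta :], dtype=np.float64))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from exc
    if len(gene_ids) != nrow:
        raise FormatError(
            f"{path}: dimension line declares {nrow} rows, body has {len(gene_ids)}"
        )
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError(f"{path}: duplicate gene ids")
    if len(set(col_ids)) != len(col_ids):
        raise ValidationError(f"{path}: duplicate column ids")
    values = np.vstack(rows) if rows else np.empty((0, ncol))
    return values, gene_ids, col_ids


def write_gct(
    path: str | Path,
    values: np.ndarray | SignatureMatrix,
    gene_ids: Sequence[str] | None = None,
    col_ids: Sequence[str] | None = None,
) -> None:
    """Write a GCT 1.3 file; floats use ``repr`` so round trips are exact."""
    if isinstance(values, SignatureMatrix):
        gene_ids = list(values.gene_space.gene_ids)
        col_ids = values.signature_ids
        values = values.values
    values = np.asarray(values, dtype=np.float64)
    if gene_ids is None or col_ids is None:
        raise ValidationError("gene_ids and col_ids are required for raw arrays")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#1.3\n")
        fh.write(f"{values.shape[0]}\t{values.shape[1]}\t0\t0\n")
        fh.write("id\t" + "\t".join(col_ids) + "\n")
        for g, row in zip(gene_ids, values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GCTX (HDF5)
# ---------------------------------------------------------------------------

def read_gctx(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a GCTX file (``/0/DATA/0/matrix``, stored signatures x genes)."""
    import h5py

    with h5py.File(path, "r") as f:
        try:
            mat = f["/0/DATA/0/matrix"][:]
            rid = [_decode(x) for x in f["/0/META/ROW/id"][:]]
            cid = [_decode(x) for x in f["/0/META/COL/id"][:]]
        except KeyError as exc:
            raise FormatError(f"{path}: missing GCTX dataset {exc}") from exc
    if mat.shape != (len(cid), len(rid)):
        raise FormatError(
            f"{path}: matrix shape {mat.shape} disagrees with id lengths"
        )
    return np.asarray(mat, dtype=np.float64).T, rid, cid


def write_gctx(
    path: str | Path,
    values: np.ndarray | SignatureMatrix,
    gene_ids: Sequence[str] | None = None,
    col_ids: Sequence[str] | None = None,
) -> None:
    import h5py

    if isinstance(values, SignatureMatrix):
        gene_ids = list(values.gene_space.gene_ids)
        col_ids = values.signature_ids
        values = values.values
    if gene_ids is None or col_ids is None:
        raise ValidationError("gene_ids and col_ids are required for raw arrays")
    with h5py.File(path, "w") as f:
        f.create_dataset("/0/DATA/0/matrix", data=np.asarray(values, np.float64).T)
        f.create_dataset(
            "/0/META/ROW/id", data=np.array(gene_ids, dtype=h5py.string_dtype())
        )
        f.create_dataset(
            "/0/META/COL/id", data=np.array(col_ids, dtype=h5py.string_dtype())
        )


def _decode(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


# ---------------------------------------------------------------------------
# Metadata TSV
# ---------------------------------------------------------------------------

_REQUIRED_META = ["signature_id", "perturbagen_id", "perturbagen_type", "cell_line", "time"]
_KNOWN_META = set(_REQUIRED_META) | {
    "dose",
    "shrna_seq",
    "tas",
    "data_level",
    "n_components",
}

_TIME_SUFFIXES = ("h", "hr", "hrs", "hours")


def _parse_time(raw: object, row: int) -> float:
    s = str(raw).strip()
    for suf in _TIME_SUFFIXES:
        if s.lower().endswith(suf):
            s = s[: -len(suf)].strip()
            break
    try:
        return float(s)
    except ValueError as exc:
        raise SchemaError(f"row {row}: unparseable time {raw!r}") from exc


def read_metadata(path: str | Path) -> list[SignatureMeta]:
    """Read a signature-info TSV into typed :class:`SignatureMeta` records.

    Unknown columns are preserved on each record's ``extra`` mapping. A dose
    on an shRNA row is ignored with a warning (knockdowns carry no dose);
    unparseable time or dose raises a record-level error naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_META if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra_cols = [c for c in df.columns if c not in _KNOWN_META]
    records: list[SignatureMeta] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        d = row._asdict()
        ptype = PerturbagenType(d["perturbagen_type"])
        dose_raw = d.get("dose", "")
        dose = None
        if dose_raw not in ("", "-", "NA"):
            try:
                dose = Dose.parse(dose_raw)
            except ValidationError as exc:
                raise SchemaError(f"row {i}: {exc}") from exc
        shrna = d.get("shrna_seq", "") or None
        if ptype is PerturbagenType.SHRNA and dose is not None:
            warnings.warn(
                f"row {i} ({d['signature_id']}): dose given for an shRNA "
                "signature; ignored",
                stacklevel=2,
            )
            dose = None
        if ptype is not PerturbagenType.SHRNA:
            shrna = None
        tas_raw = d.get("tas", "")
        try:
            tas = float(tas_raw) if tas_raw not in ("", "NA") else None
        except ValueError as exc:
            raise SchemaError(f"row {i}: unparseable tas {tas_raw!r}") from exc
        level = d.get("data_level", "") or "L5"
        ncomp_raw = d.get("n_components", "")
        ncomp = int(ncomp_raw) if ncomp_raw not in ("", "NA") else 1
        records.append(
            SignatureMeta(
                signature_id=d["signature_id"],
                perturbagen_id=d["perturbagen_id"],
                perturbagen_type=ptype,
                cell_line=d["cell_line"],
                time=_parse_time(d["time"], i),
                dose=dose,
                shrna_seq=shrna,
                data_level=DataLevel(level),
                tas=tas,
                n_components=ncomp,
                extra={c: d[c] for c in extra_cols},
            )
        )
    return records


def write_metadata(path: str | Path, records: Iterable[SignatureMeta]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "signature_id": r.signature_id,
                "perturbagen_id": r.perturbagen_id,
                "perturbagen_type": r.perturbagen_type.value,
                "cell_line": r.cell_line,
                "time": repr(r.time),
                "dose": "" if r.dose is None else f"{r.dose.value!r} {r.dose.unit}",
                "shrna_seq": r.shrna_seq or "",
                "data_level": r.data_level.value,
                "tas": "" if r.tas is None else repr(r.tas),
                "n_components": r.n_components,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def attach_metadata(
    values: np.ndarray,
    gene_ids: Sequence[str],
    col_ids: Sequence[str],
    records: Sequence[SignatureMeta],
    gene_space: GeneSpace | None = None,
    *,
    allow_missing: bool = False,
) -> SignatureMatrix:
    """Join a parsed matrix with its metadata records.

    The join is total: a matrix column without a metadata record aborts the
    build with the full list of orphans, never a silent drop.
    """
    by_id = {r.signature_id: r for r in records}
    orphans = [c for c in col_ids if c not in by_id]
    if orphans:
        raise ValidationError(
            f"{len(orphans)} matrix column(s) lack metadata: {orphans[:10]}"
        )
    if gene_space is None:
        gene_space = GeneSpace.all_landmark(gene_ids)
    else:
        gene_space = GeneSpace(
            tuple(gene_ids), {g: gene_space.class_of[g] for g in gene_ids}
        )
    return SignatureMatrix(
        gene_space,
        np.asarray(values, np.float64),
        [by_id[c] for c in col_ids],
        allow_missing=allow_missing,
    )


# ---------------------------------------------------------------------------
# Gene-space and class tables
# ---------------------------------------------------------------------------

def read_gene_space(path: str | Path) -> GeneSpace:
    """Two-column TSV ``gene_id<TAB>class`` with class in {LM, BING, INFERRED}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "class"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    try:
        class_of = {g: GeneClass(c) for g, c in zip(df["gene_id"], df["class"])}
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    return GeneSpace(tuple(df["gene_id"]), class_of)


def read_class_table(path: str | Path) -> PharmClassTable:
    """TSV ``class_name<TAB>perturbagen_id``, one membership per row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("class_name", "perturbagen_id"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    members: dict[str, set[str]] = {}
    for name, pid in zip(df["class_name"], df["perturbagen_id"]):
        members.setdefault(name, set()).add(pid)
    return PharmClassTable({k: frozenset(v) for k, v in members.items()})
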