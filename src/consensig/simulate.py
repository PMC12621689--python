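"""Synthetic compendia and the random-signature null control.

The generator realizes an additive decomposition of a perturbagen
signature: each observed Z-vector is the perturbagen's true consensus
profile plus independent zero-mean normal offsets for the cell line, time
point, and dose it was measured in (plus an shRNA-sequence offset for
knockdowns), plus per-entry observation noise:

    s_p(C, T, D)    = CS_p + eps_c(C) + eps_t(T) + eps_d(D) + eps_obs
    s_g(C, T, D, Q) = CS_g + eps_c(C) + eps_t(T) + eps_d(D) + eps_seq(Q) + eps_obs

Offsets are drawn once per perturbagen x coordinate (a flag shares cell
offsets across perturbagens to emulate cell-line identity effects). True
profiles are standard-normal per gene (signal sd 1), optionally mixed with
a shared class profile. Defaults mirror an L1000-like compendium: 978
landmark genes, the 9 core cell lines, 6 h and 24 h time points, and a
four-point dose range; all noise scales default to half the signal sd.

The null control re-fits per-cell, per-gene normal moments from any
compendium and samples fresh, independent "signatures" from them —
biological content destroyed, marginal structure kept — to verify that
MODZ does not manufacture inter-perturbagen similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pipeline import subset_sweep
from .signatures import (
    DataLevel,
    Dose,
    GeneSpace,
    PerturbagenType,
    SignatureMatrix,
    SignatureMeta,
)

__all__ = [
    "CORE_CELL_LINES",
    "SimConfig",
    "SimTruth",
    "simulate_compendium",
    "fit_context_normals",
    "sample_random_signatures",
    "random_null_sweep",
]

#: The nine core cell lines of the L1000 compendium, used as default labels.
CORE_CELL_LINES = (
    "A375",
    "A549",
    "HA1E",
    "HCC515",
    "HEPG2",
    "HT29",
    "MCF7",
    "PC3",
    "VCAP",
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic compendium.

    Noise scales are in signal-sd units (true profiles have per-gene sd 1).
    ``activity_range`` draws a per-perturbagen amplitude multiplying its
    true profile; the default (1, 1) gives every perturbagen full strength.
    ``class_structure`` maps a class name to (member perturbagen ids,
    shared-signal fraction in [0, 1)).
    """

    n_genes: int = 978
    n_perturbagens: int = 20
    cells: tuple[str, ...] = CORE_CELL_LINES
    times: tuple[float, ...] = (6.0, 24.0)
    doses: tuple[float, ...] = (0.04, 0.37, 3.33, 10.0)  # µM
    perturbagen_type: PerturbagenType = PerturbagenType.COMPOUND
    n_seqs_per_kd: int = 3
    sigma_c: float = 0.5
    sigma_t: float = 0.5
    sigma_d: float = 0.5
    sigma_seq: float = 0.5
    sigma_obs: float = 0.2
    share_cell_offsets: bool = False
    activity_range: tuple[float, float] = (1.0, 1.0)
    simulate_tas: bool = True
    class_structure: Mapping[str, tuple[tuple[str, ...], float]] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_c", "sigma_t", "sigma_d", "sigma_seq", "sigma_obs"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.n_genes < 1 or self.n_perturbagens < 1:
            raise ValidationError("need at least one gene and one perturbagen")
        for name in ("cells", "times", "doses"):
            if len(getattr(self, name)) == 0:
                raise ValidationError(f"{name} must be non-empty")
        object.__setattr__(
            self, "perturbagen_type", PerturbagenType(self.perturbagen_type)
        )


@dataclass(frozen=True)
class SimTruth:
    """Ground truth actually drawn for one simulated compendium."""

    gene_ids: tuple[str, ...]
    perturbagen_ids: tuple[str, ...]
    true_cs: np.ndarray  # genes x perturbagens
    cell_offsets: Mapping[tuple[str, str], np.ndarray]  # (pert, cell) -> vector
    time_offsets: Mapping[tuple[str, float], np.ndarray]
    dose_offsets: Mapping[tuple[str, float], np.ndarray]
    seq_offsets: Mapping[tuple[str, str], np.ndarray]
    activity: Mapping[str, float]

    def true_cs_of(self, perturbagen_id: str) -> np.ndarray:
        j = self.perturbagen_ids.index(perturbagen_id)
        return self.true_cs[:, j]


def _substream(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one run seed."""
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode()) % (2**31)])
    return np.random.default_rng(ss)


def simulate_compendium(cfg: SimConfig) -> tuple[SignatureMatrix, SimTruth]:
    """Draw one compendium under the additive decomposition model.

    One signature per (perturbagen x cell x time x dose [x sequence]);
    regenerating with the same config reproduces the output bit for bit.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2024]))
    genes = tuple(f"G{i:04d}" for i in range(cfg.n_genes))
    perts = tuple(f"P{i:03d}" for i in range(cfg.n_perturbagens))
    is_kd = cfg.perturbagen_type is PerturbagenType.SHRNA

    member_class: dict[str, tuple[str, float]] = {}
    class_signal: dict[str, np.ndarray] = {}
    for cname, (members, frac) in cfg.class_structure.items():
        if not (0.0 <= frac < 1.0):
            raise ValidationError(f"class {cname!r}: shared fraction must be in [0,1)")
        class_signal[cname] = rng.standard_normal(cfg.n_genes)
        for mid in members:
            member_class[mid] = (cname, frac)

    true_cs = np.empty((cfg.n_genes, cfg.n_perturbagens))
    activity: dict[str, float] = {}
    lo, hi = cfg.activity_range
    for j, pid in enumerate(perts):
        own = rng.standard_normal(cfg.n_genes)
        if pid in member_class:
            cname, frac = member_class[pid]
            own = np.sqrt(frac) * class_signal[cname] + np.sqrt(1 - frac) * own
        true_cs[:, j] = own
        activity[pid] = float(rng.uniform(lo, hi))

    cell_off: dict[tuple[str, str], np.ndarray] = {}
    time_off: dict[tuple[str, float], np.ndarray] = {}
    dose_off: dict[tuple[str, float], np.ndarray] = {}
    seq_off: dict[tuple[str, str], np.ndarray] = {}
    shared_cell = {
        c: cfg.sigma_c * rng.standard_normal(cfg.n_genes) for c in cfg.cells
    }
    for pid in perts:
        for c in cfg.cells:
            cell_off[(pid, c)] = (
                shared_cell[c]
                if cfg.share_cell_offsets
                else cfg.sigma_c * rng.standard_normal(cfg.n_genes)
            )
        for t in cfg.times:
            time_off[(pid, t)] = cfg.sigma_t * rng.standard_normal(cfg.n_genes)
        for d in cfg.doses:
            dose_off[(pid, d)] = cfg.sigma_d * rng.standard_normal(cfg.n_genes)
        if is_kd:
            for q in range(cfg.n_seqs_per_kd):
                seq_off[(pid, f"SEQ{q}")] = cfg.sigma_seq * rng.standard_normal(
                    cfg.n_genes
                )

    cols: list[np.ndarray] = []
    metas: list[SignatureMeta] = []
    dose_ranks = {d: i for i, d in enumerate(sorted(set(cfg.doses)))}
    n_dose_levels = max(len(dose_ranks) - 1, 1)
    for j, pid in enumerate(perts):
        base = activity[pid] * true_cs[:, j]
        for c in cfg.cells:
            for t in cfg.times:
                for d in cfg.doses:
                    seqs = [f"SEQ{q}" for q in range(cfg.n_seqs_per_kd)] if is_kd else [None]
                    for q in seqs:
                        sig = (
                            base
                            + cell_off[(pid, c)]
                            + time_off[(pid, t)]
                            + dose_off[(pid, d)]
                        )
                        if q is not None:
                            sig = sig + seq_off[(pid, q)]
                        sig = sig + cfg.sigma_obs * rng.standard_normal(cfg.n_genes)
                        tas = None
                        if cfg.simulate_tas:
                            frac = dose_ranks[d] / n_dose_levels
                            tas = float(
                                np.clip(
                                    activity[pid] * (0.15 + 0.25 * frac)
                                    + rng.normal(0.0, 0.05),
                                    0.0,
                                    1.0,
                                )
                            )
                        sid = f"{pid}:{c}:{t}:{d}" + (f":{q}" if q else "")
                        cols.append(sig)
                        metas.append(
                            SignatureMeta(
                                signature_id=sid,
                                perturbagen_id=pid,
                                perturbagen_type=cfg.perturbagen_type,
                                cell_line=c,
                                time=t,
                                dose=None if is_kd else Dose(d, "uM"),
                                shrna_seq=q,
                                data_level=DataLevel.L5,
                                tas=tas,
                            )
                        )
    matrix = SignatureMatrix(
        GeneSpace.all_landmark(genes), np.column_stack(cols), metas
    )
    truth = SimTruth(
        gene_ids=genes,
        perturbagen_ids=perts,
        true_cs=true_cs,
        cell_offsets=cell_off,
        time_offsets=time_off,
        dose_offsets=dose_off,
        seq_offsets=seq_off,
        activity=activity,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Random-signature null
# ---------------------------------------------------------------------------

def fit_context_normals(m: SignatureMatrix) -> pd.DataFrame:
    """Per-cell-line, per-gene sample mean and sd (unbiased, n-1).

    Cell lines with a single signature carry no variance information and
    are excluded with a warning. Returns a long frame with columns
    cell_line, gene_id, mean, sd.
    """
    import logging

    logger = logging.getLogger(__name__)
    by_cell: dict[str, list[int]] = {}
    for j, c in enumerate(m.columns):
        by_cell.setdefault(c.cell_line, []).append(j)
    rows = []
    for cell in sorted(by_cell):
        idx = by_cell[cell]
        if len(idx) < 2:
            logger.warning("cell line %r has one signature; excluded from fit", cell)
            continue
        sub = m.values[:, idx]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        for g, mu, s in zip(m.gene_space.gene_ids, mean, sd):
            rows.append({"cell_line": cell, "gene_id": g, "mean": mu, "sd": s})
    if not rows:
        raise ValidationError("no cell line has >= 2 signatures to fit")
    return pd.DataFrame(rows)


def sample_random_signatures(
    fits: pd.DataFrame,
    n_per_cell: int,
    seed: int,
    gene_space: GeneSpace | None = None,
) -> SignatureMatrix:
    """Independent normal draws at the fitted per-cell, per-gene moments.

    Columns are labeled with synthetic perturbagen ids ``R000..`` common
    across cells, so the null matrix has the same (perturbagen x cell)
    design as a real compendium but zero shared biology.
    """
    cells = sorted(fits["cell_line"].unique())
    genes = list(fits[fits["cell_line"] == cells[0]]["gene_id"])
    if gene_space is None:
        gene_space = GeneSpace.all_landmark(genes)
    rng = _substream(seed, "random-null")
    cols, metas = [], []
    for cell in cells:
        sub = fits[fits["cell_line"] == cell].set_index("gene_id").loc[genes]
        mu = sub["mean"].to_numpy()
        sd = sub["sd"].to_numpy()
        for i in range(n_per_cell):
            cols.append(mu + sd * rng.standard_normal(len(genes)))
            metas.append(
                SignatureMeta(
                    signature_id=f"R{i:03d}:{cell}",
                    perturbagen_id=f"R{i:03d}",
                    perturbagen_type=PerturbagenType.COMPOUND,
                    cell_line=cell,
                    time=24.0,
                    dose=Dose(10.0, "uM"),
                    data_level=DataLevel.L5,
                )
            )
    return SignatureMatrix(gene_space, np.column_stack(cols), metas)


def random_null_sweep(
    null_matrix: SignatureMatrix,
    cell_lines: Sequence[str] | None = None,
    *,
    seed: int = 0,
    max_subsets: int = 2**12,
    samples_per_size: int = 20,
) -> pd.DataFrame:
    """The cell-line subset sweep applied to a random-signature matrix.

    Under independence, the inter-perturbagen correlation distribution
    should stay centered at zero at every subset size — MODZ must not
    homogenize signatures devoid of biological content.
    """
    if cell_lines is None:
        cell_lines = sorted({c.cell_line for c in null_matrix.columns})
    perts = sorted({c.perturbagen_id for c in null_matrix.columns})
    return subset_sweep(
        null_matrix,
        perts,
        cell_lines,
        seed=seed,
        max_subsets=max_subsets,
        samples_per_size=samples_per_size,
    )
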