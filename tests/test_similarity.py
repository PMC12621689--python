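"""Intra-class similarity, context comparison, TAS diagnostics."""

import numpy as np
import pytest

from consensig.errors import ValidationError
from consensig.modz import WeightVector
from consensig.pipeline import ConsensusSignature, build_all_consensus, consensus_matrix
from consensig.qc import QCRecord
from consensig.signatures import PharmClassTable
from consensig.similarity import (
    class_context_test,
    cumulative_strong_weight,
    intra_class_similarity,
    strong_weak_profile,
    tas_dose_trend,
)
from consensig.simulate import SimConfig, simulate_compendium

from conftest import make_meta, matrix_from_columns


def fake_cs(pid, component_ids, weights, q75=0.5, n_cells=4):
    return ConsensusSignature(
        perturbagen_id=pid,
        values=np.zeros(3),
        weights=WeightVector(tuple(weights), tuple(component_ids)),
        component_ids=tuple(component_ids),
        n_cell_lines=n_cells,
        qc=QCRecord((("perturbagen", pid),), len(component_ids), q75, q75 >= 0.2, "consensus"),
    )


class TestIntraClassSimilarity:
    def test_two_identical_consensus_members(self):
        v = np.array([1.0, 3.0, 2.0, 5.0])
        metas = [make_meta("CS:p1", pert="p1", cell="consensus"),
                 make_meta("CS:p2", pert="p2", cell="consensus")]
        m = matrix_from_columns([v, v], metas=metas)
        recs = intra_class_similarity(m, PharmClassTable({"c": {"p1", "p2"}}), "consensus")
        assert recs[0].mean_rho == pytest.approx(1.0)

    def test_three_members_three_pairs(self):
        rng = np.random.default_rng(0)
        metas = [make_meta(f"CS:p{i}", pert=f"p{i}", cell="consensus") for i in range(3)]
        m = matrix_from_columns([rng.standard_normal(10) for _ in range(3)], metas=metas)
        recs = intra_class_similarity(
            m, PharmClassTable({"c": {"p0", "p1", "p2"}}), "consensus"
        )
        assert recs[0].n_pairs == 3

    def test_small_classes_dropped(self):
        rng = np.random.default_rng(1)
        metas = [make_meta("CS:p0", pert="p0", cell="consensus")]
        m = matrix_from_columns([rng.standard_normal(8)], metas=metas)
        recs = intra_class_similarity(m, PharmClassTable({"c": {"p0", "px"}}), "consensus")
        assert recs == []

    def test_empty_class_table_rejected(self):
        m = matrix_from_columns([[1, 2, 3]])
        with pytest.raises(ValidationError):
            intra_class_similarity(m, PharmClassTable({}), "consensus")

    def test_consensus_amplifies_class_signal(self):
        """When class members share a latent profile, consensus signatures
        show higher intra-class correlation than any single cell line."""
        wins = 0
        n_seeds = 8
        members = ("P000", "P001", "P002")
        classes = PharmClassTable({"shared": set(members)})
        for seed in range(n_seeds):
            cfg = SimConfig(
                n_genes=150,
                n_perturbagens=3,
                cells=("A", "B", "C", "D"),
                times=(24.0,),
                doses=(10.0,),
                sigma_c=1.2,
                sigma_t=0.0,
                sigma_d=0.0,
                sigma_obs=0.3,
                class_structure={"shared": (members, 0.5)},
                seed=700 + seed,
            )
            m, _ = simulate_compendium(cfg)
            cs_list = build_all_consensus(m)
            csm = consensus_matrix(cs_list, m.gene_space)
            cons = intra_class_similarity(csm, classes, "consensus")[0].mean_rho
            single = [
                intra_class_similarity(m, classes, cell)[0].mean_rho
                for cell in ("A", "B", "C", "D")
            ]
            if cons > max(single):
                wins += 1
        assert wins >= n_seeds - 1


class TestClassContextTest:
    def test_minimal_p(self):
        res = class_context_test([0.1, 0.2], [0.9, 0.8])
        assert res.p_value == pytest.approx(1 / 6)

    def test_identical_lists(self):
        assert class_context_test([0.5, 0.6], [0.5, 0.6]).p_value >= 0.5

    def test_wrong_direction(self):
        assert class_context_test([0.9, 0.8], [0.1, 0.2]).p_value >= 0.9


class TestStrongWeakProfile:
    def test_proportions(self):
        meta = [
            make_meta("s1", tas=0.3),
            make_meta("s2", tas=0.1),
            make_meta("s3", tas=0.15),
            make_meta("s4", tas=0.05),
        ]
        cs_gold = fake_cs("g", ("s1", "s2"), (0.5, 0.5), q75=0.8)
        cs_weak = fake_cs("w", ("s3", "s4"), (0.5, 0.5), q75=0.0)
        df, mw = strong_weak_profile([cs_gold, cs_weak], meta)
        by = df.set_index("perturbagen_id")
        assert by.loc["g", "strong_fraction"] == 0.5
        assert by.loc["w", "strong_fraction"] == 0.0
        assert mw is not None

    def test_no_tas_skips_comparison(self):
        meta = [make_meta("s1"), make_meta("s2")]
        df, mw = strong_weak_profile([fake_cs("p", ("s1", "s2"), (0.5, 0.5))], meta)
        assert mw is None
        assert df["n_missing_tas"].iloc[0] == 2


class TestCumulativeStrongWeight:
    def test_hand_sum(self):
        meta = [
            make_meta("s1", tas=0.3),
            make_meta("s2", tas=0.1),
            make_meta("s3", tas=0.25),
        ]
        cs = fake_cs("p", ("s1", "s2", "s3"), (0.5, 0.3, 0.2))
        assert cumulative_strong_weight(cs, meta) == pytest.approx(0.7)

    def test_all_strong_is_one(self):
        meta = [make_meta("s1", tas=0.9), make_meta("s2", tas=0.8)]
        cs = fake_cs("p", ("s1", "s2"), (0.6, 0.4))
        assert cumulative_strong_weight(cs, meta) == pytest.approx(1.0)

    def test_strong_plus_weak_is_one(self):
        meta = [
            make_meta("s1", tas=0.5),
            make_meta("s2", tas=0.1),
            make_meta("s3", tas=0.21),
        ]
        cs = fake_cs("p", ("s1", "s2", "s3"), (0.25, 0.35, 0.4))
        strong = cumulative_strong_weight(cs, meta)
        weak = sum(
            w
            for sid, w in zip(cs.component_ids, cs.weights.weights)
            if dict((r.signature_id, r.tas) for r in meta)[sid] <= 0.2
        )
        assert strong + weak == pytest.approx(1.0, abs=1e-12)

    def test_missing_tas_policy(self):
        meta = [make_meta("s1", tas=0.5), make_meta("s2")]
        cs = fake_cs("p", ("s1", "s2"), (0.7, 0.3))
        with pytest.raises(ValidationError):
            cumulative_strong_weight(cs, meta)
        assert cumulative_strong_weight(cs, meta, missing_tas_is_weak=True) == pytest.approx(0.7)


class TestTasDoseTrend:
    def _group(self, tas_by_dose, pert="p", cell="A", time=24.0):
        return [
            make_meta(f"{pert}:{cell}:{d}", pert=pert, cell=cell, time=time, dose=d, tas=t)
            for d, t in tas_by_dose
        ]

    def test_monotone_group_rho_one(self):
        meta = self._group([(0.1, 0.05), (1.0, 0.2), (3.0, 0.5), (10.0, 0.8)])
        df, _ = tas_dose_trend(meta)
        assert df["spearman_tas_dose"].iloc[0] == pytest.approx(1.0)

    def test_three_dose_group_excluded(self):
        meta = self._group([(0.1, 0.1), (1.0, 0.2), (10.0, 0.3)])
        df, _ = tas_dose_trend(meta)
        assert df.empty

    def test_synthetic_compendium_positive_trend(self):
        """Simulated TAS rises with dose, so the mean group correlation over
        seeded compendia is positive."""
        rhos = []
        for seed in range(5):
            cfg = SimConfig(
                n_genes=10,
                n_perturbagens=4,
                cells=("A",),
                times=(24.0,),
                doses=(0.1, 1.0, 3.0, 10.0),
                seed=900 + seed,
            )
            m, _ = simulate_compendium(cfg)
            df, _ = tas_dose_trend(m.columns)
            rhos.extend(df["spearman_tas_dose"])
        assert len(rhos) >= 20 and np.mean(rhos) > 0
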