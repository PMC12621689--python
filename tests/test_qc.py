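"""Gold-standard consistency gate, cross-context QC, representativeness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consensig.errors import ValidationError
from consensig.qc import (
    cross_context_consistency,
    gold_standard_test,
    q75,
    representativeness,
)
from consensig.simulate import SimConfig, simulate_compendium

from conftest import make_meta, matrix_from_columns


class TestQ75:
    def test_constant_list(self):
        assert q75([0.3, 0.3, 0.3]) == pytest.approx(0.3)

    def test_single_value(self):
        assert q75([0.1]) == pytest.approx(0.1)

    def test_linear_interpolation(self):
        # rank position 0.75 * 3 = 2.25 between 0.2 and 0.3
        assert q75([0.0, 0.1, 0.2, 0.3]) == pytest.approx(0.225)

    def test_empty_is_error(self):
        with pytest.raises(ValidationError):
            q75([])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-1, 1), min_size=1, max_size=12),
        st.integers(0, 11),
        st.floats(0.0, 0.5),
    )
    def test_monotone_in_inputs(self, values, idx, bump):
        """Raising any one value never lowers the 75th percentile."""
        idx = idx % len(values)
        raised = list(values)
        raised[idx] = min(raised[idx] + bump, 1.0)
        assert q75(raised) >= q75(values) - 1e-12


class TestGoldStandardTest:
    def test_identical_pair_passes(self):
        m = matrix_from_columns([[1, 3, 2, 5], [1, 3, 2, 5]])
        rec = gold_standard_test(m)
        assert rec.q75_spearman == pytest.approx(1.0) and rec.passes_gold

    def test_rank_reversed_pair_fails(self):
        m = matrix_from_columns([[1, 2, 3], [3, 2, 1]])
        rec = gold_standard_test(m)
        assert rec.q75_spearman == pytest.approx(-1.0) and not rec.passes_gold

    def test_engineered_rho_triple(self, perm_triple_matrix):
        """Pairwise rho = (0.1, 0.1, 0.4): q75 = 0.25, inclusive pass."""
        rec = gold_standard_test(perm_triple_matrix)
        assert rec.q75_spearman == pytest.approx(0.25)
        assert rec.passes_gold

    def test_threshold_is_inclusive_at_0_2(self):
        from consensig.qc import gold_gate

        q, ok = gold_gate([0.2, 0.2, 0.2])
        assert q == pytest.approx(0.2) and ok

    def test_single_signature_flagged_not_dropped(self):
        m = matrix_from_columns([[1, 2, 3]])
        rec = gold_standard_test(m, group_key=(("perturbagen", "p"),))
        assert rec.q75_spearman is None and not rec.passes_gold
        assert rec.n_signatures == 1

    def test_duplicated_set_always_passes(self):
        rng = np.random.default_rng(5)
        v = rng.standard_normal(12)
        m = matrix_from_columns([v, v, v, v])
        assert gold_standard_test(m).passes_gold


class TestCrossContext:
    def _two_cell_matrix(self, same_time=True):
        v = np.arange(8.0)
        metas = [
            make_meta("s1", pert="p", cell="MCF7", time=24.0),
            make_meta("s2", pert="p", cell="PC3", time=24.0 if same_time else 6.0),
        ]
        return matrix_from_columns([v, v], metas=metas)

    def test_identical_across_two_cells(self):
        records, skipped = cross_context_consistency(self._two_cell_matrix())
        assert len(records) == 1 and skipped == 0
        assert records[0].q75_spearman == pytest.approx(1.0)
        assert records[0].comparison_axis == "cross_cell"

    def test_differing_times_grouped_apart(self):
        records, skipped = cross_context_consistency(self._two_cell_matrix(False))
        assert records == [] and skipped == 2

    def test_within_cell_pairs_excluded(self):
        """Only inter-cell pairs enter the q75 on the cross_cell axis."""
        rng = np.random.default_rng(0)
        v = rng.standard_normal(20)
        w = rng.standard_normal(20)
        metas = [
            make_meta("a1", pert="p", cell="A"),
            make_meta("a2", pert="p", cell="A"),
            make_meta("b1", pert="p", cell="B"),
        ]
        # a1 == a2 (within-cell rho 1.0 must NOT count); both vs b1 random
        m = matrix_from_columns([v, v, w], metas=metas)
        records, _ = cross_context_consistency(m)
        assert records[0].n_pairs == 2  # a1-b1 and a2-b1 only

    def test_zero_noise_compendium_all_pass(self):
        cfg = SimConfig(
            n_genes=50,
            n_perturbagens=3,
            cells=("A", "B", "C"),
            times=(24.0,),
            doses=(10.0,),
            sigma_c=0.0,
            sigma_t=0.0,
            sigma_d=0.0,
            sigma_obs=0.0,
            seed=11,
        )
        m, _ = simulate_compendium(cfg)
        records, _ = cross_context_consistency(m)
        assert records and all(r.passes_gold for r in records)

    def test_pass_fraction_drops_with_cell_noise(self):
        """Large cell-line offsets destroy cross-cell consistency."""
        def pass_rate(sigma_c, seed):
            cfg = SimConfig(
                n_genes=80,
                n_perturbagens=4,
                cells=("A", "B", "C", "D"),
                times=(24.0,),
                doses=(10.0,),
                sigma_c=sigma_c,
                sigma_t=0.0,
                sigma_d=0.0,
                sigma_obs=0.1,
                seed=seed,
            )
            m, _ = simulate_compendium(cfg)
            records, _ = cross_context_consistency(m)
            return np.mean([r.passes_gold for r in records])

        wins = sum(pass_rate(10.0, s) < pass_rate(0.0, s) for s in range(10))
        assert wins >= 9


class TestRepresentativeness:
    def test_identical_components(self):
        v = np.array([1.0, 4.0, 2.0, 3.0])
        m = matrix_from_columns([v, v, v])
        assert representativeness(v, m) == pytest.approx(1.0)

    def test_even_median_of_opposite_ranks(self):
        up = np.array([1.0, 2.0, 3.0, 4.0])
        m = matrix_from_columns([up, up[::-1]])
        assert representativeness(up, m) == pytest.approx(0.0)

    def test_three_component_oracle(self, perm_triple_matrix):
        """Median of hand-computed correlations against the first column."""
        cs = np.asarray(perm_triple_matrix.values[:, 0], float)
        # rho(a, a) = 1, rho(a, b) = 0.1, rho(a, c) = 0.1 -> median 0.1
        got = representativeness(cs, perm_triple_matrix)
        assert got == pytest.approx(0.1)

    def test_empty_components_error(self):
        m = matrix_from_columns([[1, 2, 3]])
        with pytest.raises(ValidationError):
            representativeness(np.zeros(3), m.select_columns([]))
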