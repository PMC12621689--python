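"""Cross-context prediction scoring: matching, AUROC, confidence, overlap."""

import numpy as np
import pandas as pd
import pytest

from consensig.errors import ValidationError
from consensig.prediction import (
    DETable,
    confidence_test,
    direction_auroc,
    evaluate_prediction,
    jaccard,
    jaccard_from_counts,
    match_genes,
    overlap_report,
    read_de_table,
    split_by_agreement,
)
from consensig.signatures import GeneClass, GeneSpace


def de_table(genes, fcs, significant=None):
    df = pd.DataFrame({"gene_id": genes, "log2fc": fcs})
    if significant is not None:
        df["significant"] = significant
    return DETable(df)


class TestMatchGenes:
    def test_full_containment(self):
        z = {"a": 1.0, "b": -2.0, "c": 0.5}
        de = de_table(["a", "b"], [0.5, -1.0])
        pairs, counts = match_genes(z, de)
        assert counts == {"n_pairs": 2, "n_de_unmatched": 0, "n_cs_unmatched": 1}

    def test_disjoint_is_error(self):
        with pytest.raises(ValidationError, match="no genes shared"):
            match_genes({"a": 1.0}, de_table(["x"], [1.0]))

    def test_partial_overlap_counts(self):
        z = {g: 1.0 for g in "abcde"}
        de = de_table(["c", "d", "e", "f", "g"], [1, 1, 1, 1, 1])
        pairs, counts = match_genes(z, de)
        assert len(pairs) == 3
        assert counts["n_de_unmatched"] == 2 and counts["n_cs_unmatched"] == 2

    def test_gene_class_subset(self):
        space = GeneSpace(
            ("a", "b", "c"),
            {"a": GeneClass.LM, "b": GeneClass.BING, "c": GeneClass.LM},
        )
        vec = np.array([1.0, 2.0, 3.0])
        de = de_table(["a", "b", "c"], [1.0, 1.0, 1.0])
        pairs, _ = match_genes((vec, space), de, subset="LM")
        assert list(pairs["gene_id"]) == ["a", "c"]


class TestDirectionAuroc:
    def test_perfect(self):
        pairs = pd.DataFrame({"z": [2, 3, -1, -2], "log2fc": [1, 2, -1, -0.5]})
        assert direction_auroc(pairs) == 1.0

    def test_toy_0_75(self):
        pairs = pd.DataFrame({"z": [3, 1, 2, 0], "log2fc": [1, 1, -1, -1]})
        assert direction_auroc(pairs) == 0.75

    def test_single_direction_rejected(self):
        pairs = pd.DataFrame({"z": [1, 2], "log2fc": [1, 2]})
        with pytest.raises(ValidationError):
            direction_auroc(pairs)

    def test_sign_flip_complements_auroc(self):
        rng = np.random.default_rng(0)
        pairs = pd.DataFrame(
            {"z": rng.standard_normal(20), "log2fc": rng.standard_normal(20)}
        )
        a = direction_auroc(pairs)
        flipped = pairs.assign(z=-pairs["z"])
        assert direction_auroc(flipped) == pytest.approx(1 - a)


class TestSplitByAgreement:
    def test_three_way_split(self):
        pairs = pd.DataFrame(
            {"z": [2.0, -1.0, 0.0, 1.0], "log2fc": [1.0, 0.5, 1.0, 0.0]}
        )
        correct, incorrect, excluded = split_by_agreement(pairs)
        assert list(correct["z"]) == [2.0]
        assert list(incorrect["z"]) == [-1.0]
        assert len(excluded) == 2  # z = 0 and fc = 0

    def test_sign_flip_swaps_sets(self):
        rng = np.random.default_rng(1)
        pairs = pd.DataFrame(
            {"z": rng.standard_normal(15), "log2fc": rng.standard_normal(15)}
        )
        c1, i1, _ = split_by_agreement(pairs)
        c2, i2, _ = split_by_agreement(pairs.assign(z=-pairs["z"]))
        assert set(c1.index) == set(i2.index)
        assert set(i1.index) == set(c2.index)


class TestConfidenceTest:
    def test_minimal_p(self):
        res = confidence_test([3.0, 4.0], [0.1, 0.2])
        assert res.p_value == pytest.approx(1 / 6)

    def test_identical(self):
        assert confidence_test([1.0, 2.0], [1.0, 2.0]).p_value >= 0.5

    def test_wrong_direction(self):
        assert confidence_test([0.1, 0.2], [3.0, 4.0]).p_value >= 0.9


class TestJaccard:
    def test_up_regulated_worked_example(self):
        # 757 and 538 up-regulated genes, 213 shared
        assert jaccard_from_counts(757, 538, 213) == pytest.approx(0.197, abs=5e-4)

    def test_down_regulated_worked_example(self):
        assert jaccard_from_counts(190, 295, 53) == pytest.approx(0.123, abs=5e-4)

    def test_identical_sets(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard_from_counts(5, 5, 5) == 1.0

    def test_disjoint(self):
        assert jaccard_from_counts(10, 20, 0) == 0.0

    def test_empty_undefined(self):
        with pytest.raises(ValidationError):
            jaccard(set(), set())
        with pytest.raises(ValidationError):
            jaccard_from_counts(0, 0, 0)

    def test_inconsistent_counts(self):
        with pytest.raises(ValidationError):
            jaccard_from_counts(3, 4, 5)


class TestOverlapReport:
    def test_identical_tables(self):
        de = de_table(["a", "b", "c"], [1.0, -1.0, 2.0])
        rep = overlap_report(de, de).set_index(["direction", "gene_class"])
        assert rep.loc[("up", "all"), "jaccard"] == 1.0
        assert rep.loc[("down", "all"), "jaccard"] == 1.0

    def test_disjoint_sets(self):
        d1 = de_table(["a", "b"], [1.0, 1.0])
        d2 = de_table(["c", "d"], [1.0, 1.0])
        rep = overlap_report(d1, d2).set_index(["direction", "gene_class"])
        assert rep.loc[("up", "all"), "jaccard"] == 0.0

    def test_counts_match_set_arithmetic(self):
        d1 = de_table(["a", "b", "c", "d"], [1, 1, -1, -1])
        d2 = de_table(["b", "c", "d", "e"], [1, -1, 1, -1])
        rep = overlap_report(d1, d2).set_index(["direction", "gene_class"])
        up = rep.loc[("up", "all")]
        assert up["n_shared"] == 1  # only b
        assert up["jaccard"] == pytest.approx(jaccard_from_counts(2, 2, 1))


class TestEvaluatePrediction:
    def test_report_structure_and_recovery(self):
        """A consensus that equals the scaled true log2FC scores near-perfectly."""
        rng = np.random.default_rng(5)
        genes = tuple(f"g{i}" for i in range(60))
        classes = {g: (GeneClass.LM if i < 40 else GeneClass.BING) for i, g in enumerate(genes)}
        space = GeneSpace(genes, classes)
        fc = rng.standard_normal(60)
        z = 2.0 * fc + 0.01 * rng.standard_normal(60)
        de = de_table(list(genes), fc)
        rep = evaluate_prediction(z, space, de).set_index("gene_set")
        assert rep.loc["LM", "n_genes"] == 40
        assert rep.loc["LM", "auroc"] > 0.95
        assert rep.loc["LM", "spearman_rho"] > 0.9


def test_read_de_table_padj(tmp_path):
    p = tmp_path / "de.tsv"
    p.write_text("gene_id\tlog2fc\tpadj\nA\t1.5\t0.01\nB\t-0.5\t0.5\n")
    de = read_de_table(p)
    assert de.regulated("up") == {"A"}
    assert de.regulated("down") == set()  # B not significant
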