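import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcindex import (apply_cutoff, background_composition, collapse_duplicates,
                     compute_epsilon, read_interactions)
from mcindex.interactions import FormatError, GeneticInteraction

from conftest import make_iset


class TestComputeEpsilon:
    @pytest.mark.parametrize("phi_ab,phi_a,phi_b,expected", [
        (0.5, 1.0, 0.5, 0.0),
        (0.2, 0.8, 0.5, -0.2),
        (1.0, 0.9, 0.9, 0.19),
    ])
    def test_multiplicative_deviation(self, phi_ab, phi_a, phi_b, expected):
        assert compute_epsilon(phi_ab, phi_a, phi_b) == pytest.approx(expected)

    def test_negative_fitness_rejected(self):
        with pytest.raises(ValueError):
            compute_epsilon(0.5, -0.1, 0.5)

    def test_vectorized(self):
        out = compute_epsilon([0.5, 1.0], [1.0, 0.9], [0.5, 0.9])
        assert out == pytest.approx([0.0, 0.19])


class TestGeneticInteraction:
    def test_sign_follows_epsilon(self):
        assert GeneticInteraction("A", "B", 0.3, 0.01).sign == 1
        assert GeneticInteraction("A", "B", -0.3, 0.01).sign == -1

    @pytest.mark.parametrize("kwargs", [
        dict(gene_a="A", gene_b="A", epsilon=0.1, p_value=0.1),  # self pair
        dict(gene_a="A", gene_b="B", epsilon=0.0, p_value=0.1),  # no sign
        dict(gene_a="A", gene_b="B", epsilon=0.1, p_value=1.5),  # bad p
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneticInteraction(**kwargs)


class TestReadInteractions:
    def write(self, tmp_path, text, name="t.tsv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    def test_reads_valid_rows(self, tmp_path):
        path = self.write(tmp_path,
                          "gene_a\tgene_b\tepsilon\tp_value\n"
                          "YAL001C\tYBR001W\t0.2\t0.01\n"
                          "YAL002W\tYBR002C\t-0.1\t0.02\n"
                          "YAL003W\tYBR003C\t0.3\t0.5\n")
        iset = read_interactions(path)
        assert len(iset) == 3
        assert iset.cutoff_level == "raw"

    def test_drops_missing_self_and_zero(self, tmp_path):
        path = self.write(tmp_path,
                          "gene_a\tgene_b\tepsilon\tp_value\n"
                          "A\tB\t\t0.01\n"          # missing epsilon
                          "YAL001C\tYAL001C\t0.2\t0.01\n"  # self pair
                          "C\tD\t0.0\t0.01\n"        # sign undefined
                          "E\tF\t0.2\t0.01\n")
        iset = read_interactions(path)
        assert len(iset) == 1
        assert iset.frame.iloc[0]["gene_a"] == "E"

    def test_column_map_and_missing_column(self, tmp_path):
        path = self.write(tmp_path,
                          "query\tarray\tscore\tpval\nA\tB\t0.2\t0.01\n")
        iset = read_interactions(path, column_map={
            "gene_a": "query", "gene_b": "array",
            "epsilon": "score", "p_value": "pval"})
        assert len(iset) == 1
        with pytest.raises(FormatError, match="epsilon"):
            read_interactions(path)

    def test_gene_names_normalized(self, tmp_path):
        path = self.write(tmp_path,
                          "gene_a\tgene_b\tepsilon\tp_value\n"
                          " yal001c \tYBR001W\t0.2\t0.01\n")
        iset = read_interactions(path)
        assert iset.frame.iloc[0]["gene_a"] == "YAL001C"


class TestApplyCutoff:
    @pytest.mark.parametrize("eps,p,kept_by", [
        (0.10, 0.01, {"lenient", "intermediate"}),
        (-0.13, 0.04, {"lenient", "intermediate", "stringent"}),
        (0.17, 0.06, set()),
    ])
    def test_threshold_rules(self, eps, p, kept_by):
        iset = make_iset([("A", "B", eps, p)])
        for level in ("lenient", "intermediate", "stringent"):
            out = apply_cutoff(iset, level)
            assert (len(out) == 1) == (level in kept_by), level

    def test_unknown_level(self):
        with pytest.raises(ValueError):
            apply_cutoff(make_iset([("A", "B", 0.1, 0.01)]), "strict")

    def test_requires_raw_input(self):
        filtered = apply_cutoff(make_iset([("A", "B", 0.1, 0.01)]), "lenient")
        with pytest.raises(ValueError):
            apply_cutoff(filtered, "lenient")

    def test_nesting_on_generated_data(self, default_sim):
        _, _, iset, _ = default_sim
        pairs = {}
        for level in ("lenient", "intermediate", "stringent"):
            out = apply_cutoff(iset, level)
            pairs[level] = set(map(tuple, out.frame[["gene_a", "gene_b"]].values))
        assert pairs["stringent"] <= pairs["intermediate"] <= pairs["lenient"]


class TestCollapseDuplicates:
    def test_concordant_merged(self):
        iset = make_iset([("A", "B", 0.2, 0.02), ("B", "A", 0.4, 0.01)])
        out = collapse_duplicates(iset)
        assert len(out) == 1
        row = out.frame.iloc[0]
        assert row["epsilon"] == pytest.approx(0.3)
        assert row["p_value"] == pytest.approx(0.01)
        assert out.pair_policy == "unordered-collapsed"

    def test_discordant_removed(self):
        iset = make_iset([("A", "B", 0.2, 0.02), ("B", "A", -0.2, 0.01)])
        assert len(collapse_duplicates(iset)) == 0

    def test_no_duplicates_identity_and_idempotence(self):
        iset = make_iset([("A", "B", 0.2, 0.02), ("C", "D", -0.1, 0.01)])
        once = collapse_duplicates(iset)
        twice = collapse_duplicates(once)
        pd.testing.assert_frame_equal(once.frame, iset.frame)
        pd.testing.assert_frame_equal(twice.frame, once.frame)

    def test_output_never_larger(self, default_sim):
        _, _, iset, _ = default_sim
        assert len(collapse_duplicates(iset)) <= len(iset)


class TestBackgroundComposition:
    def test_counts_and_ratios(self):
        iset = make_iset([("A", f"B{i}", 0.1, 0.01) for i in range(10)]
                         + [("C", f"D{i}", -0.1, 0.01) for i in range(90)])
        bg = background_composition(iset)
        assert bg.f_positive == pytest.approx(0.1)
        assert bg.alpha == pytest.approx(-0.8)

    def test_boundaries(self):
        all_pos = make_iset([("A", "B", 0.1, 0.01), ("C", "D", 0.2, 0.01)])
        bg = background_composition(all_pos)
        assert (bg.alpha, bg.f_positive) == (1.0, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            background_composition(make_iset([]))

    @settings(derandomize=True, max_examples=50)
    @given(n_pos=st.integers(0, 50), n_neg=st.integers(0, 50))
    def test_alpha_identity(self, n_pos, n_neg):
        if n_pos + n_neg == 0:
            return
        rows = [("A", f"P{i}", 0.1, 0.01) for i in range(n_pos)] + \
               [("A", f"N{i}", -0.1, 0.01) for i in range(n_neg)]
        bg = background_composition(make_iset(rows))
        assert bg.n_positive + bg.n_negative == n_pos + n_neg
        assert bg.alpha == pytest.approx(2 * bg.f_positive - 1)
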