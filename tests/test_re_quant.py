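import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retroce.annotation_io import RELocus
from retroce.re_quant import (
    SampleLibrary,
    count_reads,
    differential_expression,
    rpkm,
    size_expression_filter,
)

from oracles import oracle_count_sam, welch_p


def _expr(values: dict, samples) -> pd.DataFrame:
    return pd.DataFrame(values, index=samples).T


class TestRpkm:
    def _one(self, count, length, total):
        loci = [RELocus("c", 0, length, "+")]
        counts = pd.DataFrame({"s1": [count]}, index=[loci[0].locus_id])
        lib = [SampleLibrary("s1", "normal", total)]
        return float(rpkm(counts, loci, lib).iloc[0, 0])

    @pytest.mark.parametrize(
        "count,length,total,expected",
        [(10, 1000, 1_000_000, 10.0), (0, 1000, 1_000_000, 0.0), (7, 350, 2_500_000, 8.0)],
    )
    def test_formula(self, count, length, total, expected):
        assert self._one(count, length, total) == pytest.approx(expected)

    @given(
        count=st.integers(0, 10_000),
        length=st.integers(1, 100_000),
        total=st.integers(1, 10**8),
        k=st.integers(1, 1000),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_invariant_under_joint_scaling_of_counts_and_depth(self, count, length, total, k):
        assert self._one(count * k, length, total * k) == pytest.approx(
            self._one(count, length, total), rel=1e-9
        )

    def test_zero_length_locus_cannot_exist(self):
        with pytest.raises(ValueError):
            RELocus("c", 5, 5, "+")


class TestCountReads:
    def test_counts_match_manifest_and_brute_force(self, sam_corpus):
        manifest, paths, expected, totals, _ = sam_corpus
        loci = manifest.re_loci()
        for sample, path in paths.items():
            col, total = count_reads(path, loci)
            assert (col == expected[sample]).all()
            assert total == totals[sample]
            assert col.to_dict() == oracle_count_sam(path, loci)

    def test_straddling_and_antisense_reads_not_counted(self, sam_corpus):
        # the plan emits ~30% extra labelled reads per locus; all must be ignored
        manifest, paths, expected, totals, _ = sam_corpus
        sample = next(iter(paths))
        col, total = count_reads(paths[sample], manifest.re_loci())
        assert total > col.sum()  # the extras are mapped but not attributable

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            count_reads(tmp_path / "absent.sam", [])


class TestSizeExpressionFilter:
    def test_length_threshold_inclusive(self):
        loci = [RELocus("c", i * 1000, i * 1000 + n, "+") for i, n in enumerate((150, 200, 500))]
        expr = pd.DataFrame(
            {"s1": [5.0, 5.0, 5.0], "s2": [5.0, 5.0, 5.0]},
            index=[l.locus_id for l in loci],
        )
        kept = size_expression_filter(expr, loci, min_length_bp=200, min_rpkm=1, min_samples=1)
        assert len(kept) == 2

    def test_expression_threshold_needs_min_samples(self):
        loci = [RELocus("c", 0, 500, "+")]
        expr = pd.DataFrame([[0.5, 0.9, 0.2]], index=[loci[0].locus_id], columns=list("abc"))
        kept = size_expression_filter(expr, loci, min_length_bp=0, min_rpkm=1, min_samples=2)
        assert len(kept) == 0

    def test_disjoint_failure_modes_compose(self):
        # 10 loci: 4 fail length, 2 others fail expression -> 4 survive
        loci = [RELocus("c", i * 1000, i * 1000 + (100 if i < 4 else 500), "+") for i in range(10)]
        vals = [[5.0]] * 4 + [[0.1], [0.1]] + [[5.0]] * 4
        expr = pd.DataFrame(vals, index=[l.locus_id for l in loci], columns=["s1"])
        kept = size_expression_filter(expr, loci, min_length_bp=200, min_rpkm=1, min_samples=1)
        assert len(kept) == 4


class TestDifferentialExpression:
    GROUPS = {"n1": "normal", "n2": "normal", "n3": "normal",
              "t1": "tumor", "t2": "tumor", "t3": "tumor"}

    def test_identical_groups_give_zero_fc_and_no_calls(self):
        expr = pd.DataFrame([[3.0] * 6], index=["x"], columns=self.GROUPS)
        table = differential_expression(expr, self.GROUPS)
        assert table.loc["x", "log2fc"] == 0
        assert table.loc["x", "p_value"] == 1.0  # zero variance, equal means
        assert not table.loc["x", "significant"]

    def test_label_swap_negates_log2fc_keeps_p(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.lognormal(2, 1, size=(20, 6)), columns=list(self.GROUPS))
        fwd = differential_expression(expr, self.GROUPS)
        swapped = {s: ("tumor" if g == "normal" else "normal") for s, g in self.GROUPS.items()}
        rev = differential_expression(expr, swapped)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"].reindex(fwd.index))
        assert np.allclose(fwd["p_value"], rev["p_value"].reindex(fwd.index))

    def test_hand_computed_fold_change_and_welch_p(self):
        normal, tumor = [1.0, 1.0, 1.0], [4.0, 4.0, 4.00001]
        expr = pd.DataFrame([normal + tumor], index=["x"], columns=list(self.GROUPS))
        table = differential_expression(expr, self.GROUPS, pseudocount=0.25)
        expected_fc = math.log2((sum(tumor) / 3 + 0.25) / (sum(normal) / 3 + 0.25))
        assert table.loc["x", "log2fc"] == pytest.approx(expected_fc)
        assert table.loc["x", "log2fc"] == pytest.approx(1.766, abs=5e-4)
        hand_p = welch_p(
            [math.log2(v + 0.25) for v in tumor], [math.log2(v + 0.25) for v in normal]
        )
        assert table.loc["x", "p_value"] == pytest.approx(hand_p, rel=1e-6)

    def test_p_values_match_textbook_welch_on_random_data(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.lognormal(3, 1, size=(30, 6)), columns=list(self.GROUPS))
        table = differential_expression(expr, self.GROUPS, pseudocount=0.25)
        logged = np.log2(expr + 0.25)
        for locus in table.index:
            hand = welch_p(
                list(logged.loc[locus, ["t1", "t2", "t3"]]),
                list(logged.loc[locus, ["n1", "n2", "n3"]]),
            )
            assert table.loc[locus, "p_value"] == pytest.approx(hand, rel=1e-9)

    def test_significance_reproducible_from_own_columns(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.lognormal(2, 2, size=(50, 6)), columns=list(self.GROUPS))
        table = differential_expression(expr, self.GROUPS, alpha=0.05, fc_threshold=1.0)
        recomputed = (table["p_value"] < 0.05) & (table["log2fc"].abs() > 1.0)
        assert (table["significant"] == recomputed).all()

    def test_sorted_by_p_then_abs_fc(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.lognormal(2, 1, size=(25, 6)), columns=list(self.GROUPS))
        table = differential_expression(expr, self.GROUPS)
        assert table["p_value"].is_monotonic_increasing

    def test_single_sample_group_rejected(self):
        groups = {"n1": "normal", "t1": "tumor", "t2": "tumor"}
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["x"], columns=list(groups))
        with pytest.raises(ValueError, match="2 samples per group"):
            differential_expression(expr, groups)
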