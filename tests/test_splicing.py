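"""Exon skipping: read counting, ratio statistics, calling, rescue scoring."""

import math

import numpy as np
import pandas as pd
import pytest

from phosplice.splicing import test_exon as exon_fisher_test
from phosplice.splicing import (
    GeneModel,
    SplicedAlignment,
    adjusted_log2_ratio,
    analyze_counts,
    call_significant,
    count_all_exons,
    count_inclusion_skipping,
    overlap_significant,
    recovery_analysis,
    rpkm,
)
from phosplice.simulate import SplicingSimConfig, simulate_spliced_reads

from _oracles import fisher_two_sided_oracle

MODEL = GeneModel("g1", ((0, 100), (200, 300), (400, 500)))


def results_frame(rows):
    """(gene, exon, significant[, tested]) rows -> minimal results table."""
    out = pd.DataFrame(rows, columns=["gene", "exon", "significant"])
    out["tested"] = True
    return out


class TestCounting:
    def test_inclusion_and_skipping_by_construction(self):
        reads = [
            SplicedAlignment("r1", ((50, 100), (400, 450))),  # skips exon 1
            SplicedAlignment("r2", ((220, 280),)),  # inside exon 1
        ]
        assert count_inclusion_skipping(MODEL, reads, 1) == (1, 1)

    def test_no_reads(self):
        assert count_inclusion_skipping(MODEL, [], 1) == (0, 0)

    def test_boundary_mismatch_not_skipping(self):
        # junction (100, 399): acceptor misses the annotated start 400
        reads = [SplicedAlignment("r1", ((50, 100), (399, 450)))]
        inc, skp = count_inclusion_skipping(MODEL, reads, 1)
        assert skp == 0

    def test_junction_tolerance_rescues_near_miss(self):
        reads = [SplicedAlignment("r1", ((50, 100), (399, 450)))]
        _, skp = count_inclusion_skipping(MODEL, reads, 1, junction_tolerance=1)
        assert skp == 1

    @pytest.mark.parametrize("index", [0, 2, 5])
    def test_non_internal_exon_rejected(self, index):
        with pytest.raises(ValueError):
            count_inclusion_skipping(MODEL, [], index)

    def test_read_counted_once_per_category(self):
        # two blocks both overlap exon 1: still one inclusion read
        reads = [SplicedAlignment("r1", ((210, 220), (250, 260)))]
        assert count_inclusion_skipping(MODEL, reads, 1) == (1, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_simulated_reads_match_ground_truth_exactly(self, seed):
        cfg = SplicingSimConfig(
            n_genes=3, exons_per_gene=5, depth=15.0, psi=0.7, seed=seed
        )
        sim = simulate_spliced_reads(cfg)
        counted = pd.concat(
            [count_all_exons(sim.models[g], sim.alignments) for g in sorted(sim.models)],
            ignore_index=True,
        )
        pd.testing.assert_frame_equal(counted, sim.truth)


class TestRatioAndTest:
    @pytest.mark.parametrize(
        "counts,expected",
        [((10, 10, 5, 10), 1.0), ((3, 6, 4, 8), 0.0), ((1, 8, 1, 2), -2.0)],
    )
    def test_adjusted_log2(self, counts, expected):
        assert adjusted_log2_ratio(*counts) == pytest.approx(expected)

    def test_adjusted_log2_zero_count_sentinel(self):
        assert math.isnan(adjusted_log2_ratio(0, 10, 5, 10))

    def test_adjusted_log2_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            s1, i1, s2, i2 = (int(x) for x in rng.integers(1, 100, size=4))
            assert adjusted_log2_ratio(s1, i1, s2, i2) == pytest.approx(
                -adjusted_log2_ratio(s2, i2, s1, i1)
            )

    def test_positive_integer_rule(self):
        res = exon_fisher_test(0, 50, 5, 45)
        assert not res["tested"] and math.isnan(res["p"])

    def test_balanced_table_p_one(self):
        assert exon_fisher_test(1, 1, 1, 1)["p"] == 1.0

    def test_p_matches_enumeration_oracle(self):
        assert exon_fisher_test(10, 1, 1, 10)["p"] == pytest.approx(
            fisher_two_sided_oracle(10, 1, 1, 10), rel=1e-9
        )

    def test_p_invariant_under_group_swap(self):
        a = exon_fisher_test(12, 4, 3, 9)["p"]
        b = exon_fisher_test(3, 9, 12, 4)["p"]
        assert a == pytest.approx(b, rel=1e-12)


class TestCalling:
    def test_single_tested_exon(self):
        res = pd.DataFrame(
            [{"gene": "g", "exon": 1, "p": 0.04, "tested": True}]
        )
        out = call_significant(res, q_threshold=0.05)
        assert out["q"].iloc[0] == pytest.approx(0.04)
        assert out["significant"].iloc[0]

    def test_all_p_one_none_significant(self):
        res = pd.DataFrame(
            [{"gene": "g", "exon": i, "p": 1.0, "tested": True} for i in range(5)]
        )
        assert not call_significant(res)["significant"].any()

    def test_untested_exons_excluded_from_family(self):
        res = pd.DataFrame(
            [
                {"gene": "g", "exon": 1, "p": 0.03, "tested": True},
                {"gene": "g", "exon": 2, "p": math.nan, "tested": False},
            ]
        )
        out = call_significant(res)
        assert out.loc[out["exon"] == 1, "q"].iloc[0] == pytest.approx(0.03)
        assert math.isnan(out.loc[out["exon"] == 2, "q"].iloc[0])
        assert not out.loc[out["exon"] == 2, "significant"].iloc[0]

    def test_replicates_summed_within_group(self):
        counts = pd.DataFrame(
            [
                ["g", 1, "case", 0, 5, 10],
                ["g", 1, "case", 1, 5, 10],
                ["g", 1, "control", 0, 10, 5],
                ["g", 1, "control", 1, 10, 5],
            ],
            columns=["gene", "exon", "group", "replicate", "inclusion", "skipping"],
        )
        out = analyze_counts(counts, "case", "control")
        row = out.iloc[0]
        assert (row["S_case"], row["I_case"], row["S_ctrl"], row["I_ctrl"]) == (20, 10, 10, 20)
        assert row["adjusted_log2"] == pytest.approx(2.0)


class TestRpkm:
    @pytest.mark.parametrize(
        "args,expected",
        [((10, 1000, 1_000_000), 10.0), ((0, 500, 10), 0.0), ((100, 500, 2_000_000), 100.0)],
    )
    def test_values(self, args, expected):
        assert rpkm(*args) == pytest.approx(expected)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)


class TestOverlapAndRecovery:
    def test_disjoint_significant_sets(self):
        a = results_frame([["g1", 1, True], ["g2", 1, False]])
        b = results_frame([["g1", 1, False], ["g2", 1, True]])
        shared, n_genes = overlap_significant(a, b)
        assert shared == [] and n_genes == 0

    def test_identical_significant_sets(self):
        rows = [["g1", 1, True], ["g1", 2, True], ["g2", 1, True], ["g2", 3, True], ["g3", 1, True]]
        shared, n_genes = overlap_significant(results_frame(rows), results_frame(rows))
        assert len(shared) == 5 and n_genes == 3

    def test_full_rescue(self):
        disease = results_frame([["g1", 1, True], ["g2", 1, True]])
        treated = results_frame([["g1", 1, False], ["g2", 1, False]])
        shared = [("g1", 1), ("g2", 1)]
        recovered, frac = recovery_analysis(disease, treated, shared)
        assert frac == 1.0 and len(recovered) == 2

    def test_no_rescue_when_treated_mirrors_disease(self):
        disease = results_frame([["g1", 1, True], ["g2", 1, True]])
        recovered, frac = recovery_analysis(disease, disease, [("g1", 1), ("g2", 1)])
        assert frac == 0.0 and recovered == []

    def test_empty_shared_set_sentinel(self):
        disease = results_frame([["g1", 1, True]])
        _, frac = recovery_analysis(disease, disease, [])
        assert math.isnan(frac)

    def test_unknown_shared_exon_rejected(self):
        disease = results_frame([["g1", 1, True]])
        with pytest.raises(ValueError):
            recovery_analysis(disease, disease, [("gX", 9)])
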