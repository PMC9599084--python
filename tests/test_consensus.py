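"""Harmonization arithmetic, tensor conservation, filter oracles."""

import numpy as np
import pandas as pd
import pytest

from cerna_icb.consensus import (
    CircConsensus,
    build_call_tensor,
    consensus_counts,
    harmonize_calls,
    high_confidence_filter,
    summarize_genome,
)
from conftest import brute_force_filter, random_call_fixture


def make_calls(rows):
    return pd.DataFrame(
        rows,
        columns=["caller_id", "sample_id", "chrom", "start", "end", "strand",
                 "bsj_reads"],
    )


class TestHarmonize:
    def test_one_based_closed_convention_shifts_to_bed(self):
        calls = make_calls([("CIRI", "s1", "chr1", 101, 200, "+", 5)])
        out = harmonize_calls(calls)  # CIRI profile is (-1, 0)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (100, 200)
        assert out.loc[0, "circ_id"] == "chr1:100-200:+"

    def test_different_conventions_reach_one_key(self):
        calls = make_calls(
            [
                ("CIRI", "s1", "chr1", 101, 200, "+", 5),
                ("CIRCexplorer2", "s1", "chr1", 100, 200, "+", 3),
            ]
        )
        out = harmonize_calls(calls)
        assert out["circ_id"].nunique() == 1

    def test_unknown_caller_lists_known_profiles(self):
        calls = make_calls([("mystery", "s1", "chr1", 1, 2, "+", 1)])
        with pytest.raises(ValueError, match="CIRCexplorer2"):
            harmonize_calls(calls)

    def test_degenerate_interval_rejected_with_reason(self):
        calls = make_calls(
            [
                ("CIRI", "s1", "chr1", 200, 200, "+", 5),  # start>=end after shift? 199<200 ok
                ("CIRCexplorer2", "s1", "chr1", 300, 300, "+", 5),
            ]
        )
        out, rejected = harmonize_calls(calls, return_rejected=True)
        assert len(rejected) == 1
        assert rejected.loc[0, "reject_reason"] == "start >= end after shift"
        assert len(out) == 1

    def test_jittered_fixture_maps_back_to_registry(self, sim, small_config):
        """Every synthetic call, harmonized, lands on its true locus key —
        checked against a brute-force per-caller offset reversal."""
        out = harmonize_calls(sim.calls)
        registry = set(sim.truth["registry"]["circ_id"])
        assert set(out["circ_id"]) <= registry
        # brute-force reversal, record by record
        profiles = small_config.caller_offset_profile
        for rec in sim.calls.sample(50, random_state=0).itertuples():
            ds, de = profiles[rec.caller_id]
            key = f"{rec.chrom}:{rec.start + ds}-{rec.end + de}:{rec.strand}"
            assert key in registry


class TestTensor:
    def test_single_record_single_cell(self):
        h = harmonize_calls(make_calls(
            [("CIRCexplorer2", "s1", "chr1", 10, 20, "+", 4)]
        ))
        t = build_call_tensor(h)
        assert t.values.sum() == 4
        assert (t.values > 0).sum() == 1

    def test_duplicate_cells_are_summed(self):
        h = harmonize_calls(make_calls(
            [
                ("CIRCexplorer2", "s1", "chr1", 10, 20, "+", 2),
                ("CIRCexplorer2", "s1", "chr1", 10, 20, "+", 3),
            ]
        ))
        t = build_call_tensor(h)
        assert t.values.max() == 5

    def test_marginal_totals_conserve_input_reads(self):
        rng = np.random.default_rng(0)
        calls = random_call_fixture(rng)
        t = build_call_tensor(calls)
        assert t.total_reads() == calls["bsj_reads"].sum()
        by_sample = calls.groupby("sample_id")["bsj_reads"].sum()
        for j, s in enumerate(t.sample_ids):
            assert t.values[:, j, :].sum() == by_sample[s]


class TestConsensusCounts:
    def test_single_caller_passthrough(self):
        h = harmonize_calls(make_calls(
            [("CIRCexplorer2", "s1", "chr1", 10, 20, "+", 4)]
        ))
        cm = consensus_counts(build_call_tensor(h))
        assert cm.counts.iloc[0, 0] == 4

    def test_median_of_three_callers(self):
        h = harmonize_calls(make_calls(
            [
                ("CIRCexplorer2", "s1", "chr1", 10, 20, "+", 2),
                ("CIRI", "s1", "chr1", 11, 20, "+", 4),
                ("DCC", "s1", "chr1", 11, 20, "+", 6),
            ]
        ))
        cm = consensus_counts(build_call_tensor(h))
        assert cm.counts.iloc[0, 0] == 4

    def test_matches_brute_force_median_over_support(self):
        rng = np.random.default_rng(1)
        calls = random_call_fixture(rng, n_circ=40)
        t = build_call_tensor(calls)
        cm = consensus_counts(t)
        for i, cid in enumerate(t.circ_ids):
            support = [k for k in range(len(t.caller_ids))
                       if t.values[i, :, k].sum() > 0]
            for j in range(len(t.sample_ids)):
                if not support:
                    expected = 0
                else:
                    expected = int(np.round(np.median(
                        [t.values[i, j, k] for k in support]
                    )))
                assert cm.counts.iloc[i, j] == expected


class TestHighConfidenceFilter:
    def _tensor(self, cells):
        """cells: list of (circ, sample, caller, reads)."""
        rows = [
            (k, s, c.rsplit(":", 2)[0],
             int(c.rsplit(":", 2)[1].split("-")[0]),
             int(c.rsplit(":", 2)[1].split("-")[1]), c.rsplit(":", 2)[2], r)
            for (c, s, k, r) in cells
        ]
        calls = make_calls(rows)
        calls["circ_id"] = [c for (c, _, _, _) in cells]
        return build_call_tensor(calls)

    def test_three_callers_two_good_samples_retained(self):
        t = self._tensor(
            [
                ("chr1:1-9:+", "s1", "A", 3), ("chr1:1-9:+", "s2", "A", 2),
                ("chr1:1-9:+", "s1", "B", 3), ("chr1:1-9:+", "s2", "B", 2),
                ("chr1:1-9:+", "s1", "C", 3), ("chr1:1-9:+", "s2", "C", 2),
            ]
        )
        assert high_confidence_filter(t) == ["chr1:1-9:+"]

    def test_two_caller_support_rejected(self):
        t = self._tensor(
            [
                ("chr1:1-9:+", "s1", "A", 9), ("chr1:1-9:+", "s2", "A", 9),
                ("chr1:1-9:+", "s1", "B", 9), ("chr1:1-9:+", "s2", "B", 9),
                ("chr2:1-9:+", "s1", "C", 1),
            ]
        )
        assert "chr1:1-9:+" not in high_confidence_filter(t)

    def test_single_qualifying_sample_rejected(self):
        t = self._tensor(
            [
                ("chr1:1-9:+", "s1", "A", 5),
                ("chr1:1-9:+", "s1", "B", 5),
                ("chr1:1-9:+", "s1", "C", 5),
                ("chr1:1-9:+", "s2", "A", 1),
            ]
        )
        assert high_confidence_filter(t) == []

    def test_min_callers_beyond_panel_errors(self):
        t = self._tensor([("chr1:1-9:+", "s1", "A", 5)])
        with pytest.raises(ValueError, match="min_callers"):
            high_confidence_filter(t, min_callers=3)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("scope", ["merged", "per_caller"])
    def test_matches_brute_force_oracle(self, seed, scope):
        rng = np.random.default_rng(seed)
        t = build_call_tensor(random_call_fixture(rng))
        got = high_confidence_filter(t, reads_scope=scope)
        assert got == brute_force_filter(t, reads_scope=scope)

    def test_monotone_under_added_reads_and_callers(self):
        rng = np.random.default_rng(42)
        t = build_call_tensor(random_call_fixture(rng, n_circ=40))
        base = set(high_confidence_filter(t))
        for _ in range(100):
            t2 = build_call_tensor(
                random_call_fixture(np.random.default_rng(42), n_circ=40)
            )
            i = rng.integers(t2.values.shape[0])
            j = rng.integers(t2.values.shape[1])
            k = rng.integers(t2.values.shape[2])
            t2.values[i, j, k] += int(rng.integers(1, 5))
            assert base <= set(high_confidence_filter(t2))

    def test_invariant_to_input_row_order(self):
        rng = np.random.default_rng(9)
        calls = random_call_fixture(rng, n_circ=30)
        shuffled = calls.sample(frac=1.0, random_state=1).reset_index(
            drop=True
        )
        a = CircConsensus(offset_profiles={f"caller{k}": (0, 0)
                                           for k in range(5)}).fit(calls)
        b = CircConsensus(offset_profiles={f"caller{k}": (0, 0)
                                           for k in range(5)}).fit(shuffled)
        assert a.retained_keys_ == b.retained_keys_
        pd.testing.assert_frame_equal(a.matrix_, b.matrix_)


class TestSummaries:
    def test_single_chromosome_carries_all_reads(self):
        counts = pd.DataFrame(
            {"s1": [3, 4], "s2": [1, 0]},
            index=["chr5:1-9:+", "chr5:10-19:-"],
        )
        from cerna_icb.consensus import ConsensusMatrix

        cm = ConsensusMatrix(counts, pd.Series([frozenset(["A"])] * 2,
                                               index=counts.index))
        groups = pd.Series({"s1": "responder", "s2": "non-responder"})
        out = summarize_genome(cm, None, groups)
        per_chrom = out["per_chromosome"]
        assert list(per_chrom["chrom"]) == ["chr5"]
        assert per_chrom["total_reads"].iloc[0] == 8

    def test_empty_annotation_means_all_novel(self):
        counts = pd.DataFrame({"s1": [3]}, index=["chr5:1-9:+"])
        from cerna_icb.consensus import ConsensusMatrix

        cm = ConsensusMatrix(counts, pd.Series([frozenset(["A"])],
                                               index=counts.index))
        out = summarize_genome(cm, pd.DataFrame(), pd.Series({"s1": "r"}))
        assert len(out["host_gene_ranking"]) == 0

    def test_totals_match_generator_truth(self, sim):
        cc = CircConsensus().fit(
            sim.calls, sample_ids=list(sim.samples["sample_id"])
        )
        groups = sim.samples.set_index("sample_id")["response"]
        out = cc.summarize(None, groups)
        per_chrom = out["per_chromosome"].set_index("chrom")
        # brute-force: sum retained consensus counts by registry chromosome
        expected = {}
        for cid in cc.retained_keys_:
            chrom = cid.rsplit(":", 2)[0]
            expected[chrom] = expected.get(chrom, 0) + int(
                cc.matrix_.loc[cid].sum()
            )
        for chrom, total in expected.items():
            assert per_chrom.loc[chrom, "total_reads"] == total

    def test_host_gene_ranking_orders_by_reads(self):
        counts = pd.DataFrame(
            {"s1": [10, 1, 5]},
            index=["chr1:1-9:+", "chr1:20-29:+", "chr2:1-9:+"],
        )
        from cerna_icb.consensus import ConsensusMatrix

        cm = ConsensusMatrix(
            counts, pd.Series([frozenset(["A"])] * 3, index=counts.index)
        )
        ann = pd.DataFrame(
            {
                "circ_id": ["chr1:1-9:+", "chr2:1-9:+"],
                "host_gene": ["CDR1", "HIPK3"],
            }
        )
        out = summarize_genome(cm, ann, pd.Series({"s1": "r"}))
        ranking = out["host_gene_ranking"]
        assert list(ranking["host_gene"]) == ["CDR1", "HIPK3"]
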