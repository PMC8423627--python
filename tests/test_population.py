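"""Population merging, filtering, cohort statistics and the priority-based
gene-family count, on constructed fixtures with known answers."""
import itertools

import numpy as np
import pandas as pd
import pytest

import anchorsv as asv
from anchorsv.population import (SVCall, acquired_svs, consistency_support,
                                 introgression_overlap, matrix_to_calls,
                                 merge_calls, population_filter,
                                 priority_gene_count, subgenome_summary)


def _call(acc, start, typ="DEL", chrom="c1", length=50, depth=10,
          genotype="present"):
    return SVCall(acc, typ, chrom, start, start + length, length, depth,
                  genotype)


class TestMerge:
    def test_nearby_same_type_calls_merge(self):
        calls = [_call("a1", 1000, length=50), _call("a2", 1005, length=52)]
        m = merge_calls(calls, min_support=2)
        assert len(m.loci) == 1
        assert m.loci["support"].iloc[0] == 2
        assert m.states.iloc[0].tolist() == ["present", "present"]

    def test_min_support_threshold(self):
        calls = [_call(f"a{i}", 1000 + i) for i in range(9)]
        m = merge_calls(calls, min_support=10)
        assert len(m.loci) == 0 and m.dropped_low_support == 1
        calls.append(_call("a9", 1009))
        m = merge_calls(calls, min_support=10)
        assert len(m.loci) == 1

    def test_conflicting_types_not_merged(self):
        calls = [_call("a1", 1000, typ="DEL"), _call("a2", 1000, typ="INS")]
        m = merge_calls(calls, min_support=1)
        assert len(m.loci) == 2

    def test_single_linkage_chain(self):
        """A chain of calls each within tolerance of the next merges into
        one cluster even when the ends are far apart; verified against an
        exhaustive partition oracle."""
        calls = [_call(f"a{i}", 1000 + 80 * i) for i in range(6)]
        m = merge_calls(calls, pos_tol=100, min_support=1)
        assert len(m.loci) == 1
        # oracle: the transitive closure over pairwise compatibility
        def compatible(a, b):
            return abs(a.start - b.start) <= 100 and \
                abs(a.end - b.end) <= 100 and \
                abs(a.length - b.length) <= 0.2 * max(a.length, b.length)
        n = len(calls)
        parent = list(range(n))
        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i
        for i, j in itertools.combinations(range(n), 2):
            if compatible(calls[i], calls[j]):
                parent[find(j)] = find(i)
        assert len({find(i) for i in range(n)}) == 1

    def test_merge_idempotent(self):
        rng = np.random.default_rng(0)
        calls = []
        for locus in range(5):
            base = 10_000 * (locus + 1)
            for i in range(12):
                calls.append(_call(f"a{i}", base + int(rng.integers(0, 40)),
                                   length=int(rng.integers(45, 55))))
        m1 = merge_calls(calls)
        m2 = merge_calls(matrix_to_calls(m1))
        pd.testing.assert_frame_equal(m1.loci, m2.loci)
        pd.testing.assert_frame_equal(m1.states, m2.states)

    def test_order_invariance(self):
        calls = [_call(f"a{i}", 1000 + 7 * i) for i in range(12)]
        m1 = merge_calls(calls)
        m2 = merge_calls(calls[::-1])
        pd.testing.assert_frame_equal(m1.loci, m2.loci)


class TestFilters:
    def test_maf_removes_rare_locus(self):
        states = ["present"] * 4 + ["absent"] * 96
        m = _make_matrix(states, [10] * 100)
        filtered, rep = population_filter(m)
        assert rep == {"retained": 0, "removed": 1}

    def test_missing_ratio_removes_locus(self):
        states = ["present"] * 40 + ["absent"] * 35 + ["missing"] * 25
        m = _make_matrix(states, [10] * 100)
        filtered, _ = population_filter(m)
        assert len(filtered.loci) == 0

    def test_common_well_covered_locus_retained(self):
        states = ["present"] * 50 + ["absent"] * 45 + ["missing"] * 5
        m = _make_matrix(states, [10] * 100)
        filtered, rep = population_filter(m)
        assert rep["retained"] == 1

    def test_low_depth_becomes_missing(self):
        states = ["present"] * 100
        depths = [2] * 30 + [10] * 70
        m = _make_matrix(states, depths)
        filtered, _ = population_filter(m)
        assert len(filtered.loci) == 0  # missing ratio 0.3 > 0.2


def _make_matrix(states, depths):
    accs = [f"a{i}" for i in range(len(states))]
    loci = pd.DataFrame([("L1", "DEL", "c1", 100, 150, 50,
                          states.count("present"))],
                        columns=["locus_id", "type", "chrom", "start", "end",
                                 "length", "support"]).set_index("locus_id")
    st = pd.DataFrame([states], index=loci.index, columns=accs)
    dp = pd.DataFrame([depths], index=loci.index, columns=accs)
    from anchorsv.population import SVPresenceMatrix
    return SVPresenceMatrix(loci, st, dp)


class TestAcquired:
    def _cohort_matrix(self, n_acquired=25, n_shared=10, n_rare=5):
        """100 early + 100 modern accessions; the acquired loci are at 60%
        in modern and 10% in early."""
        early = [f"e{i}" for i in range(100)]
        modern = [f"m{i}" for i in range(100)]
        calls = []
        pos = 10_000
        for k in range(n_acquired):
            for a in modern[:60]:
                calls.append(_call(a, pos, chrom="cA" if k % 2 else "cD"))
            for a in early[:10]:
                calls.append(_call(a, pos, chrom="cA" if k % 2 else "cD"))
            pos += 10_000
        for _ in range(n_shared):  # high everywhere -> not acquired
            for a in modern[:60] + early[:60]:
                calls.append(_call(a, pos))
            pos += 10_000
        for _ in range(n_rare):  # low everywhere
            for a in modern[:20] + early[:5]:
                calls.append(_call(a, pos))
            pos += 10_000
        m = merge_calls(calls, accessions=early + modern)
        return m, early, modern

    def test_exactly_constructed_loci_returned(self):
        m, early, modern = self._cohort_matrix()
        got = acquired_svs(m, early, modern)
        assert len(got) == 25

    def test_shared_high_frequency_not_acquired(self):
        m, early, modern = self._cohort_matrix(n_acquired=0, n_shared=8)
        assert acquired_svs(m, early, modern) == []

    def test_cohort_overlap_rejected(self):
        m, early, modern = self._cohort_matrix(5, 0, 0)
        with pytest.raises(ValueError):
            acquired_svs(m, early, early[:50] + modern[:50])

    def test_direction_disjoint(self):
        m, early, modern = self._cohort_matrix()
        fwd = set(acquired_svs(m, early, modern))
        rev = set(acquired_svs(m, modern, early))
        assert not fwd & rev

    def test_subgenome_summary_densities(self):
        m, early, modern = self._cohort_matrix()
        got = acquired_svs(m, early, modern)
        table = [("cA", 1_000_000, "A"), ("cD", 500_000, "D")]
        df = subgenome_summary(m, got, table).set_index("subgenome")
        assert df.loc["A", "count"] + df.loc["D", "count"] == 25
        assert df.loc["D", "density_per_kb"] == pytest.approx(
            df.loc["D", "count"] / 500.0)


class TestIntrogression:
    def _sv(self, pos, typ="DEL", length=100, chrom="c1"):
        return asv.StructuralVariant(typ, chrom, pos, pos + length,
                                     length=length)

    def test_trio_recovers_exactly_donor_transferred(self):
        rng = np.random.default_rng(2)
        donor = [self._sv(int(p)) for p in
                 rng.choice(np.arange(100, 10_000) * 50, size=60,
                            replace=False)]
        transferred = donor[:40]
        private = [self._sv(10_000_000 + i * 5_000) for i in range(10)]
        line = transferred + private
        got = introgression_overlap(line, donor)
        assert len(got) == 40
        assert all(sv in transferred for sv in got)

    def test_identical_record_reported(self):
        sv = self._sv(500)
        assert introgression_overlap([sv], [self._sv(500)]) == [sv]

    def test_unrelated_not_reported(self):
        assert introgression_overlap([self._sv(500)],
                                     [self._sv(50_000)]) == []


class TestPriorityCount:
    def test_tie_broken_by_priority(self):
        table = pd.DataFrame({"A": [3], "B": [3], "C": [1]}, index=["f1"])
        df, total = priority_gene_count(table, ["A", "B", "C"])
        assert total == 3
        assert df.iloc[0]["source"] == "A"
        df, _ = priority_gene_count(table, ["B", "A", "C"])
        assert df.iloc[0]["source"] == "B"

    def test_single_source_sums(self):
        table = pd.DataFrame({"A": [2, 5]}, index=["f1", "f2"])
        _, total = priority_gene_count(table, ["A"])
        assert total == 7

    def test_random_tables_match_bruteforce(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.integers(0, 20, size=(50, 4)),
                             columns=list("ABCD"))
        df, total = priority_gene_count(table, ["C", "A", "D", "B"])
        # brute-force oracle
        want = int(sum(max(row) for _, row in table.iterrows()))
        assert total == want
        for (_, row), (_, res) in zip(table.iterrows(), df.iterrows()):
            assert row[res["source"]] == row.max()
            better = [s for s in ["C", "A", "D", "B"]
                      if row[s] == row.max()]
            assert res["source"] == better[0]

    def test_total_invariant_to_column_order(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.integers(0, 9, size=(20, 3)),
                             columns=list("ABC"))
        _, t1 = priority_gene_count(table, ["A", "B", "C"])
        _, t2 = priority_gene_count(table[["C", "B", "A"]], ["A", "B", "C"])
        assert t1 == t2

    def test_empty_table(self):
        assert priority_gene_count(pd.DataFrame(), ["A"])[1] == 0


class TestConsistency:
    def test_supported_pairwise_sv_retained_with_count(self):
        calls = [_call(f"a{i}", 1000, length=50) for i in range(500)]
        m = merge_calls(calls)
        sv = asv.StructuralVariant("DEL", "c1", 1000, 1050, length=50)
        got = consistency_support([sv], m)
        assert got == [(sv, 500)]

    def test_unsupported_pairwise_sv_excluded(self):
        calls = [_call(f"a{i}", 1000, length=50) for i in range(500)]
        m = merge_calls(calls)
        sv = asv.StructuralVariant("DEL", "c1", 90_000, 90_050, length=50)
        assert consistency_support([sv], m) == []

    def test_constructed_mixture_counts(self):
        """30 of 100 pairwise SVs also segregate in >= 10 accessions."""
        rng = np.random.default_rng(5)
        positions = (rng.choice(np.arange(200, 50_000), size=100,
                                replace=False) * 40).tolist()
        pairwise = [asv.StructuralVariant("DEL", "c1", p, p + 50, length=50)
                    for p in positions]
        calls = []
        for p in positions[:30]:
            for i in range(12):
                calls.append(_call(f"a{i}", p, length=50))
        for p in positions[30:40]:  # below support threshold
            for i in range(5):
                calls.append(_call(f"a{i}", p, length=50))
        m = merge_calls(calls, accessions=[f"a{i}" for i in range(12)])
        got = consistency_support(pairwise, m)
        assert len(got) == 30
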