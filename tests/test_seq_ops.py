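import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from deepcomm import synthetic
from deepcomm.seq_ops import (
    AlignedSequenceSet,
    SequenceRecord,
    cluster_otus,
    contaminant_screen,
    dereplicate,
    distance_matrix,
    kmismatch_map,
    pairwise_distance,
    precluster,
    read_fasta,
    reverse_complement,
    shared_otus,
    write_fasta,
)
from deepcomm.tables_io import CommunityTable


def rec(rid, seq, ab=1):
    return SequenceRecord(id=rid, seq=seq, abundance=ab)


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT")) for _ in range(length))


class TestFastaIO:
    def test_size_annotation_roundtrip(self, tmp_path):
        records = [rec("a", "ACGT", 7), rec("b", "GGCC", 1)]
        path = tmp_path / "x.fa"
        write_fasta(records, path)
        back = read_fasta(path)
        assert [(r.id, r.seq, r.abundance) for r in back] == [
            ("a", "ACGT", 7),
            ("b", "GGCC", 1),
        ]


class TestDereplicate:
    def test_exact_duplicates_merged(self):
        out = dereplicate([rec("a", "ACGT"), rec("b", "ACGT"), rec("c", "ACGT")])
        assert len(out) == 1 and out[0].abundance == 3

    def test_prefix_folds_into_longer(self):
        out = dereplicate([rec("a", "ACGT"), rec("b", "ACGTTT")], mode="prefix")
        assert len(out) == 1
        assert out[0].seq == "ACGTTT" and out[0].abundance == 2

    def test_full_mode_keeps_prefix_distinct(self):
        out = dereplicate([rec("a", "ACGT"), rec("b", "ACGTTT")], mode="full")
        assert len(out) == 2

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(0)
        pool = [random_seq(rng, rng.integers(8, 14)) for _ in range(12)]
        records = [
            rec(f"r{i}", pool[rng.integers(len(pool))][: rng.integers(6, 15)] or "A")
            for i in range(50)
        ]
        records = [r for r in records if r.seq]
        out = dereplicate(records, mode="prefix")
        # oracle: total abundance conserved and no retained sequence is a
        # prefix of another retained sequence
        assert sum(r.abundance for r in out) == sum(r.abundance for r in records)
        for x, y in itertools.permutations(out, 2):
            assert not y.seq.startswith(x.seq)

    def test_abundance_conserved_property(self):
        rng = np.random.default_rng(1)
        records = [rec(f"r{i}", random_seq(rng, 6), int(rng.integers(1, 9))) for i in range(30)]
        for mode in ("full", "prefix"):
            out = dereplicate(records, mode=mode)
            assert sum(r.abundance for r in out) == sum(r.abundance for r in records)


class TestPairwiseDistance:
    def test_identical(self):
        assert pairwise_distance("ACGT", "ACGT") == 0.0

    def test_terminal_gaps_ignored(self):
        assert pairwise_distance("--ACGT", "TTACGT") == 0.0
        assert pairwise_distance("ACGT--", "ACGTTT") == 0.0

    def test_internal_gap_counts_one(self):
        assert pairwise_distance("ACG-T", "ACGAT") == pytest.approx(1 / 5)

    def test_gap_gap_column_excluded(self):
        # span covers 4 columns, one of which is gap/gap -> 3 compared
        assert pairwise_distance("A-GT", "A-CT") == pytest.approx(1 / 3)

    def test_symmetric_and_zero_iff_identical_span(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            s1 = random_seq(rng, 20)
            s2 = random_seq(rng, 20)
            assert pairwise_distance(s1, s2) == pairwise_distance(s2, s1)
            assert (pairwise_distance(s1, s2) == 0.0) == (s1 == s2)

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance("AC----", "----GT")


class TestPrecluster:
    def test_identical_records_merge(self):
        out = precluster([rec("a", "ACGT", 3), rec("b", "ACGT", 2)], max_diffs=2)
        assert len(out) == 1 and out[0].abundance == 5

    def test_rare_variant_absorbed_by_abundant(self):
        out = precluster([rec("big", "ACGTACGT", 100), rec("small", "ACGTACGA", 1)], max_diffs=2)
        assert len(out) == 1
        assert out[0].id == "big" and out[0].abundance == 101

    def test_greedy_chain_is_not_single_linkage(self):
        # A-B-C each 1 apart; B joins A, C is 2 from A so stays (max_diffs=1)
        out = precluster(
            [rec("A", "AAAAAAAA", 10), rec("B", "AAAAAAAT", 5), rec("C", "AAAAAATT", 3)],
            max_diffs=1,
        )
        ids = sorted(r.id for r in out)
        assert ids == ["A", "C"]
        assert {r.id: r.abundance for r in out}["A"] == 15


def partition_signature(clusters):
    return sorted(tuple(sorted(c)) for c in clusters)


class TestClusterOtus:
    def test_identical_set_single_otu(self):
        aligned = AlignedSequenceSet([rec("a", "ACGT"), rec("b", "ACGT")])
        assert cluster_otus(aligned).n_otus == 1

    def test_distant_pair_splits(self):
        aligned = AlignedSequenceSet([rec("a", "AAAAAAAAAA"), rec("b", "AAAAAAAATT")])
        # distance 0.2 > 0.03
        assert cluster_otus(aligned, threshold=0.03).n_otus == 2

    def test_representative_is_most_abundant(self):
        aligned = AlignedSequenceSet([rec("a", "ACGT", 2), rec("b", "ACGT", 9)])
        otus = cluster_otus(aligned)
        assert otus.representatives == ["b"]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        base = random_seq(rng, 40)
        records = []
        for i in range(12):
            seq = list(base)
            for pos in rng.choice(40, size=rng.integers(0, 6), replace=False):
                seq[pos] = "ACGT"[rng.integers(4)]
            records.append(rec(f"r{i}", "".join(seq)))
        aligned = AlignedSequenceSet(records)
        n_prev = None
        for t in (0.0, 0.02, 0.05, 0.1, 1.0):
            n = cluster_otus(aligned, threshold=t).n_otus
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n
        assert cluster_otus(aligned, threshold=1.0).n_otus == 1

    def test_threshold_zero_groups_only_identical(self):
        aligned = AlignedSequenceSet(
            [rec("a", "ACGT"), rec("b", "ACGT"), rec("c", "ACGA")]
        )
        otus = cluster_otus(aligned, threshold=0.0)
        assert partition_signature(otus.clusters) == [("a", "b"), ("c",)]

    def test_matches_scipy_average_linkage_on_generic_distances(self):
        # random continuous-ish distances (no ties): partitions agree with an
        # independent implementation cut at the same threshold
        rng = np.random.default_rng(4)
        for _ in range(10):
            records = [rec(f"r{i}", random_seq(rng, 60)) for i in range(10)]
            aligned = AlignedSequenceSet(records)
            d = distance_matrix(aligned)
            t = float(rng.uniform(0.1, 0.8))
            ours = cluster_otus(aligned, threshold=t)
            z = hierarchy.linkage(d[np.triu_indices(10, 1)], method="average")
            flat = hierarchy.fcluster(z, t=t, criterion="distance")
            scipy_clusters: dict[int, list[str]] = {}
            for idx, c in enumerate(flat):
                scipy_clusters.setdefault(c, []).append(f"r{idx}")
            assert partition_signature(ours.clusters) == partition_signature(
                scipy_clusters.values()
            )


class TestSharedOtus:
    def build(self, site_seqs):
        site_otus, site_records = {}, {}
        for site, seqs in site_seqs.items():
            records = [rec(f"{site}_{i}", s, ab) for i, (s, ab) in enumerate(seqs)]
            aligned = AlignedSequenceSet(records)
            site_otus[site] = cluster_otus(aligned, threshold=0.03)
            site_records[site] = records
        return site_otus, site_records

    def test_identical_representatives_span_both_sites(self):
        seqs = [("ACGTACGTACGT", 5), ("TTTTACGTCCCC", 2)]
        otus, records = self.build({"s1": seqs, "s2": seqs})
        shared = shared_otus(otus, records)
        assert all(c.sites == {"s1", "s2"} for c in shared)

    def test_distant_representatives_share_nothing(self):
        otus, records = self.build(
            {"s1": [("AAAAAAAAAAAA", 3)], "s2": [("GGGGGGGGGGGG", 3)]}
        )
        shared = shared_otus(otus, records)
        assert all(len(c.sites) == 1 for c in shared)

    def test_planted_shared_and_private_mix(self):
        rng = np.random.default_rng(5)
        common = [random_seq(rng, 61) for _ in range(5)]
        priv1 = [random_seq(rng, 61) for _ in range(5)]
        priv2 = [random_seq(rng, 61) for _ in range(5)]
        otus, records = self.build(
            {
                "s1": [(s, 4) for s in common + priv1],
                "s2": [(s, 4) for s in common + priv2],
            }
        )
        shared = shared_otus(otus, records)
        spanning = [c for c in shared if c.sites == {"s1", "s2"}]
        assert len(spanning) == 5


class TestKmismatchMap:
    def test_exact_substring_hit(self):
        hits = kmismatch_map([rec("q", "ACGTAC")], [rec("r", "TTACGTACTT")], 0)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].offset == 2 and fwd[0].mismatches == 0

    def test_three_mismatches_not_reported_at_two(self):
        # best placement on either strand differs at 3 positions
        hits = kmismatch_map([rec("q", "AAAA")], [rec("r", "ACCCCA")], 2)
        assert hits == []

    def test_reverse_complement_strand(self):
        q = rec("q", "ACGT")
        hits = kmismatch_map([q], [rec("r", reverse_complement("ACGT") + "GGGG")], 0)
        assert any(h.strand == "-" and h.offset == 0 for h in hits)

    def test_two_mismatch_hits_superset_of_exact(self):
        rng = np.random.default_rng(6)
        queries = [rec(f"q{i}", random_seq(rng, 8)) for i in range(10)]
        refs = [rec(f"r{i}", random_seq(rng, 60)) for i in range(3)]
        h0 = {(h.query_id, h.reference_id, h.offset, h.strand) for h in kmismatch_map(queries, refs, 0)}
        h2 = {(h.query_id, h.reference_id, h.offset, h.strand) for h in kmismatch_map(queries, refs, 2)}
        assert h0 <= h2

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(7)
        queries = [rec(f"q{i}", random_seq(rng, 6)) for i in range(20)]
        refs = [rec(f"r{i}", random_seq(rng, 40)) for i in range(5)]
        got = {
            (h.query_id, h.reference_id, h.offset, h.mismatches, h.strand)
            for h in kmismatch_map(queries, refs, 2)
        }
        expected = set()
        for q in queries:
            for strand, qs in (("+", q.seq), ("-", reverse_complement(q.seq))):
                for r in refs:
                    for off in range(len(r.seq) - len(qs) + 1):
                        mm = sum(
                            1 for a, b in zip(qs, r.seq[off : off + len(qs)]) if a != b
                        )
                        if mm <= 2:
                            expected.add((q.id, r.id, off, mm, strand))
        assert got == expected


class TestContaminantScreen:
    def make_table(self):
        counts = pd.DataFrame(
            [[95, 3, 2, 0], [50, 0, 0, 50]],
            index=["s1", "s2"],
            columns=["Bacillus", "Rheinheimera", "Delftia", "Clostridium"],
        )
        return CommunityTable(counts)

    def test_empty_list(self):
        out = contaminant_screen(self.make_table(), [])
        assert (out["contaminant_genera_observed"] == 0).all()
        assert (out["contaminant_relative_abundance"] == 0.0).all()

    def test_all_genera_listed(self):
        table = self.make_table()
        out = contaminant_screen(table, table.taxa)
        assert np.allclose(out["contaminant_relative_abundance"], 1.0)

    def test_planted_five_percent(self):
        out = contaminant_screen(self.make_table(), ["Rheinheimera", "Delftia", "Absent"])
        assert out.loc["s1", "contaminant_genera_observed"] == 2
        assert out.loc["s1", "contaminant_relative_abundance"] == pytest.approx(0.05)
        assert out.loc["s2", "contaminant_genera_observed"] == 0
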