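"""Greedy identity clustering, distances and cluster enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aptastack.clustering import (
    Cluster,
    NeighborIndex,
    cluster_enrichment,
    cluster_stats,
    greedy_cluster,
    minimal_enrichment_threshold,
    normalized_edit_distance,
    read_cluster_tsv,
    strip_primers,
    write_cluster_tsv,
)
from aptastack.datasets import s15_filtered_totals
from aptastack.selex_io import SequencePool
from aptastack.template import expected_insert
from oracles import levenshtein

DNA = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestNormalizedEditDistance:
    def test_identity(self):
        assert normalized_edit_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_single_substitution(self):
        assert normalized_edit_distance("ACGT", "ACGA") == 0.25

    def test_ten_substitutions_in_100nt_is_90pct_identity(self, rng):
        s1 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
        s2 = list(s1)
        pos = rng.choice(100, size=10, replace=False)
        for p in pos:
            s2[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s2[p]]
        assert normalized_edit_distance(s1, "".join(s2)) == pytest.approx(0.10)

    def test_empty_string_raises(self):
        with pytest.raises(ValueError):
            normalized_edit_distance("", "ACGT")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(DNA, DNA)
    def test_matches_dp_oracle_and_is_symmetric(self, s1, s2):
        d = normalized_edit_distance(s1, s2)
        assert d == pytest.approx(levenshtein(s1, s2) / max(len(s1), len(s2)))
        assert d == normalized_edit_distance(s2, s1)
        assert 0.0 <= d <= 1.0
        assert (d == 0.0) == (s1 == s2)


def _pool(seq_counts, round_label="11"):
    pool = SequencePool(round=round_label)
    for seq, n in seq_counts.items():
        pool.add(seq, n)
    return pool


def _mutate(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestGreedyCluster:
    def test_single_sequence_single_cluster(self):
        (cl,) = greedy_cluster(_pool({expected_insert("A" * 30): 3}))
        assert cl.size == 1 and cl.seed == expected_insert("A" * 30)

    def test_close_variants_join_seed(self, rng):
        seed = expected_insert(
            "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
        )
        counts = {seed: 10}
        for i in range(9):
            counts[_mutate(seed, [20 + i], rng)] = 1
        clusters = greedy_cluster(_pool(counts), identity_threshold=0.85)
        assert len(clusters) == 1
        assert clusters[0].seed == seed  # most abundant founds the cluster
        assert clusters[0].size == 10

    def test_dissimilar_sequences_stay_apart(self):
        a = expected_insert("A" * 30)
        b = expected_insert("GC" * 15)
        clusters = greedy_cluster(_pool({a: 2, b: 1}), identity_threshold=0.85)
        assert len(clusters) == 2

    def test_empty_input(self):
        assert greedy_cluster([]) == []

    def test_partition_and_threshold_invariants(self, rng):
        # random sequences plus two planted families
        counts = {}
        bases = np.array(list("ACGT"))
        for _ in range(60):
            counts[expected_insert("".join(bases[rng.integers(0, 4, 30)]))] = 1
        for _ in range(2):
            fam = expected_insert("".join(bases[rng.integers(0, 4, 30)]))
            counts[fam] = 5
            for k in range(6):
                counts[_mutate(fam, rng.choice(30, size=2, replace=False), rng)] = 1
        clusters = greedy_cluster(_pool(counts), identity_threshold=0.85)
        members = [s for c in clusters for s in c.members]
        assert sorted(members) == sorted(counts)  # every sequence exactly once
        for c in clusters:
            for m in c.members:
                d = normalized_edit_distance(strip_primers(m), strip_primers(c.seed))
                assert d <= 0.15 + 1e-12

    def test_matches_bruteforce_greedy_reference(self, rng):
        """The neighbor-graph formulation equals a direct first-fit scan."""
        import edlib

        counts = {}
        bases = np.array(list("ACGT"))
        for _ in range(25):
            counts[expected_insert("".join(bases[rng.integers(0, 4, 30)]))] = int(
                rng.integers(1, 6)
            )
        fam = expected_insert("".join(bases[rng.integers(0, 4, 30)]))
        counts[fam] = 9
        for k in range(8):
            counts[_mutate(fam, rng.choice(30, size=int(rng.integers(1, 4)),
                                           replace=False), rng)] = 1
        # short-fragment variant exercises unequal core lengths
        counts[fam[:40] + fam[48:]] = 2

        for order_seed in (0, 1):
            got = greedy_cluster(_pool(counts), 0.85, order_seed=order_seed)
            # reference: visit in the same order, scan clusters first-fit
            seqs = sorted(counts)
            rng2 = np.random.default_rng(order_seed)
            tie = rng2.permutation(len(seqs))
            order = sorted(range(len(seqs)),
                           key=lambda i: (-counts[seqs[i]], tie[i]))
            ref_clusters = []
            for i in order:
                core = strip_primers(seqs[i])
                for cl in ref_clusters:
                    seed_core = strip_primers(cl[0])
                    dmax = int(np.floor(0.15 * max(len(core), len(seed_core))))
                    d = edlib.align(core, seed_core, mode="NW",
                                    task="distance")["editDistance"]
                    if d <= dmax:
                        cl[1].append(seqs[i])
                        break
                else:
                    ref_clusters.append((seqs[i], [seqs[i]]))
            assert [set(c.members) for c in got] == [set(m) for _, m in ref_clusters]

    def test_reclustering_stability_on_clean_families(self, rng):
        """With unambiguous families, every visiting order yields the same
        partition (the documented tie-breaking only permutes cluster ids)."""
        counts = {}
        bases = np.array(list("ACGT"))
        for _ in range(5):
            fam = expected_insert("".join(bases[rng.integers(0, 4, 30)]))
            counts[fam] = 8
            for k in range(5):
                counts[_mutate(fam, [k], rng)] = 1
        partitions = []
        for order_seed in range(3):
            cls = greedy_cluster(_pool(counts), 0.85, order_seed=order_seed)
            partitions.append({frozenset(c.members) for c in cls})
        assert partitions[0] == partitions[1] == partitions[2]


class TestClusterStats:
    def test_singleton_identity_one(self):
        seq = expected_insert("A" * 30)
        cl = Cluster(0, seq, {seq: {"4": 1}})
        assert cluster_stats(cl) == (1, 1.0)

    def test_mean_identity_arithmetic(self, rng):
        seed = expected_insert("".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)]))
        # member at ~0.105 core distance: 6 substitutions over 57-nt core
        member = _mutate(seed, [16, 18, 20, 22, 24, 26], rng)
        cl = Cluster(0, seed, {seed: {"4": 1}, member: {"4": 1}})
        expected = np.mean([1.0, 1.0 - 6 / 57])
        assert cluster_stats(cl)[1] == pytest.approx(expected)

    def test_high_frequency_cluster_selection_rule(self, rng):
        """>100 distinct sequences and >90% mean identity select the
        planted qualifying cluster only."""
        seed = expected_insert("".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)]))
        big = {seed: {"4": 1}}
        while len(big) < 111:  # 110 distinct single/double mutants
            p = [15 + int(x) for x in  # variable-region positions only
                 rng.choice(30, size=int(rng.integers(1, 3)), replace=False)]
            big[_mutate(seed, p, rng)] = {"4": 1}
        qualifying = Cluster(0, seed, big)
        small = Cluster(1, seed, {seed: {"4": 1}})
        chosen = [
            c for c in (qualifying, small)
            if c.size > 100 and c.mean_identity_to_seed > 0.90
        ]
        assert chosen == [qualifying]


class TestClusterEnrichment:
    totals = s15_filtered_totals()

    def _cluster(self, late, early, n_late, n_early):
        return Cluster(0, "SEED", {"SEED": {late: n_late, early: n_early}})

    def test_two_sequence_cluster_round11_vs_4(self):
        cl = self._cluster("11", "4", 1, 1)
        enr = cluster_enrichment(cl, "11", "4", self.totals)
        assert round(enr.ratio, 2) == 7.61

    def test_two_sequence_cluster_round10_vs_9(self):
        cl = self._cluster("10", "9", 1, 1)
        enr = cluster_enrichment(cl, "10", "9", self.totals)
        assert round(enr.ratio, 4) == 0.8451

    def test_equal_normalized_frequency_gives_one(self):
        totals = {"11": 1000, "4": 2000}
        cl = self._cluster("11", "4", 1, 2)
        assert cluster_enrichment(cl, "11", "4", totals).ratio == pytest.approx(1.0)

    def test_missing_round_excluded_not_infinite(self):
        cl = Cluster(0, "SEED", {"SEED": {"11": 3}})
        enr = cluster_enrichment(cl, "11", "4", self.totals)
        assert enr.label == "excluded" and np.isnan(enr.ratio)


class TestMinimalEnrichmentThreshold:
    totals = s15_filtered_totals()

    @pytest.mark.parametrize(
        "late,early,decimals,expected",
        [("11", "4", 2, 7.61), ("11", "9", 4, 0.7468),
         ("10", "4", 2, 8.61), ("10", "9", 4, 0.8451)],
    )
    def test_printed_thresholds(self, late, early, decimals, expected):
        got = minimal_enrichment_threshold(late, early, self.totals)
        assert round(got, decimals) == expected

    def test_equal_totals_give_one(self):
        assert minimal_enrichment_threshold("a", "b", {"a": 5, "b": 5}) == 1.0

    def test_reciprocal_product_is_one(self):
        f = minimal_enrichment_threshold
        for late, early in [("11", "4"), ("10", "9"), ("11", "9")]:
            assert f(late, early, self.totals) * f(early, late, self.totals) == (
                pytest.approx(1.0)
            )


def test_cluster_tsv_round_trip(tmp_path, rng):
    counts = {}
    bases = np.array(list("ACGT"))
    for r in ("4", "11"):
        for _ in range(10):
            seq = expected_insert("".join(bases[rng.integers(0, 4, 30)]))
            counts.setdefault(seq, {})[r] = int(rng.integers(1, 4))
    pools = [
        _pool({s: c[r] for s, c in counts.items() if r in c}, r)
        for r in ("4", "11")
    ]
    clusters = greedy_cluster(pools)
    path = tmp_path / "clusters.tsv"
    write_cluster_tsv(clusters, path)
    back = read_cluster_tsv(path)
    assert [(c.cluster_id, c.seed, dict(c.members)) for c in clusters] == [
        (c.cluster_id, c.seed, {s: dict(v) for s, v in c.members.items()})
        for c in back
    ]


def test_neighbor_index_rejects_mismatched_pools(small_pool):
    other = SequencePool(round="4")
    other.add(expected_insert("G" * 30))
    index = NeighborIndex(sorted(small_pool.counts), 0.85)
    with pytest.raises(ValueError, match="does not match"):
        greedy_cluster(other, neighbors=index)
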