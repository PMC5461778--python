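"""Greedy identity clustering of aptamer pools and cluster enrichment.

Sequences are grouped CD-HIT style: visited in descending total-count
order (ties broken by a seeded shuffle), each sequence joins the first
existing cluster whose seed lies within ``1 - identity_threshold``
normalized Levenshtein distance, otherwise it founds a new cluster.
Distances are computed on primer-stripped cores, since the primers are
identical across all filtered inserts.

A k-mer count filter prunes candidate seeds before any edit-distance
call: if edit_distance(q, s) <= d then q and s share at least
``len(q) - k + 1 - d*k`` k-mer occurrences, so seeds below that bound
cannot match.  The filter is exact (never discards a true match).

Cluster enrichment between a late round X and an early round Y is the
ratio of the cluster's normalized frequencies:

    enrichment = (cluster count in X / total X) / (cluster count in Y / total Y)

The minimal attainable enrichment for a two-sequence cluster (one read
per compared round) is therefore total_Y / total_X; a cluster must exceed
it strictly to count as enriched.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from .template import PRIMER_3, PRIMER_5

__all__ = [
    "Cluster",
    "ClusterEnrichment",
    "normalized_edit_distance",
    "strip_primers",
    "greedy_cluster",
    "cluster_stats",
    "cluster_enrichment",
    "minimal_enrichment_threshold",
    "write_cluster_tsv",
    "read_cluster_tsv",
]


def normalized_edit_distance(s1: str, s2: str) -> float:
    """Levenshtein distance divided by the longer length, in [0, 1]."""
    if not s1 or not s2:
        raise ValueError("normalized edit distance is undefined for empty strings")
    if s1 == s2:
        return 0.0
    d = edlib.align(s1, s2, mode="NW", task="distance")["editDistance"]
    return d / max(len(s1), len(s2))


def strip_primers(insert: str) -> str:
    """Remove the flanking primers from an insert when present."""
    core = insert
    if core.startswith(PRIMER_5):
        core = core[len(PRIMER_5):]
    if core.endswith(PRIMER_3):
        core = core[: -len(PRIMER_3)]
    return core


@dataclass
class Cluster:
    """One greedy cluster: seed (most abundant member) plus members with
    per-round counts."""

    cluster_id: int
    seed: str
    members: dict[str, Counter] = field(default_factory=dict)

    @property
    def size(self) -> int:
        """Number of distinct member sequences."""
        return len(self.members)

    @property
    def total_count(self) -> int:
        return sum(sum(c.values()) for c in self.members.values())

    def round_count(self, round_label: str) -> int:
        return sum(c.get(round_label, 0) for c in self.members.values())

    @property
    def mean_identity_to_seed(self) -> float:
        core_seed = strip_primers(self.seed)
        idents = [
            1.0 - normalized_edit_distance(strip_primers(m), core_seed)
            if strip_primers(m) != core_seed
            else 1.0
            for m in self.members
        ]
        return float(np.mean(idents))


@dataclass(frozen=True)
class ClusterEnrichment:
    cluster_id: int
    round_late: str
    round_early: str
    ratio: float  # nan when excluded
    label: str  # "enriched" | "depleted" | "excluded"


_CODE = {b: i for i, b in enumerate("ACGT")}


def _encode_cores(cores: list[str]):
    max_len = max(len(c) for c in cores)
    enc = np.zeros((len(cores), max_len), dtype=np.uint8)
    lens = np.empty(len(cores), dtype=np.int64)
    for r, core in enumerate(cores):
        lens[r] = len(core)
        for p, b in enumerate(core):
            code = _CODE.get(b)
            if code is None:
                raise ValueError(f"non-ACGT base {b!r} in sequence core")
            enc[r, p] = code
    return enc, lens


class NeighborIndex:
    """Exact sparse graph of sequence pairs within a distance threshold.

    Greedy clustering only ever joins a sequence to a seed within the
    threshold, so the graph contains every pair any visiting order could
    join; building it once makes reclustering with different orders cheap.
    Sequences are keyed by their sorted order, so the same pools can be
    reclustered against the same index.
    """

    def __init__(self, sequences: list[str], identity_threshold: float):
        from ._cluster_kernel import build_edges

        self.sequences = sorted(sequences)
        self.identity_threshold = identity_threshold
        cores = [strip_primers(s) for s in self.sequences]
        enc, lens = _encode_cores(cores)
        ei, ej = build_edges(enc, lens, 1.0 - identity_threshold)
        self.neighbors: dict[int, list[int]] = defaultdict(list)
        for a, b in zip(ei, ej):
            self.neighbors[int(a)].append(int(b))
            self.neighbors[int(b)].append(int(a))


def greedy_cluster(pools, identity_threshold: float = 0.85,
                   order_seed: int = 0,
                   neighbors: NeighborIndex | None = None) -> list[Cluster]:
    """Abundance-ordered greedy seed clustering on normalized edit distance.

    Parameters
    ----------
    pools : SequencePool or iterable of SequencePool
        Per-round pools; counts are aggregated across rounds per sequence.
    identity_threshold : float
        Sequences join a cluster when their primer-stripped core is within
        ``1 - identity_threshold`` normalized distance of the seed's core.
    order_seed : int
        Seed for the shuffle that breaks abundance ties.
    """
    if not 0.5 <= identity_threshold < 1:
        raise ValueError("identity_threshold must be in [0.5, 1)")
    if hasattr(pools, "counts"):
        pools = [pools]
    per_round: dict[str, Counter] = defaultdict(Counter)
    totals: Counter = Counter()
    for pool in pools:
        for seq, cnt in pool.counts.items():
            per_round[seq][pool.round] += cnt
            totals[seq] += cnt
    if not totals:
        return []

    seqs = sorted(totals)
    if neighbors is None:
        neighbors = NeighborIndex(seqs, identity_threshold)
    elif (neighbors.sequences != seqs
          or neighbors.identity_threshold != identity_threshold):
        raise ValueError("NeighborIndex does not match these pools")
    rng = np.random.default_rng(order_seed)
    tie = rng.permutation(len(seqs))
    order = sorted(range(len(seqs)), key=lambda i: (-totals[seqs[i]], tie[i]))

    founded_at: dict[int, int] = {}  # sequence index -> cluster id of its seed
    clusters: list[Cluster] = []
    for i in order:
        seq = seqs[i]
        best_cluster = None
        for nb in neighbors.neighbors.get(i, ()):
            cid = founded_at.get(nb)
            if cid is not None and (best_cluster is None or cid < best_cluster):
                best_cluster = cid
        if best_cluster is None:
            cid = len(clusters)
            clusters.append(Cluster(cluster_id=cid, seed=seq))
            founded_at[i] = cid
            clusters[cid].members[seq] = per_round[seq]
        else:
            clusters[best_cluster].members[seq] = per_round[seq]
    return clusters


def cluster_stats(cluster: Cluster) -> tuple[int, float]:
    """(distinct-sequence size, mean identity of members to the seed)."""
    if not cluster.members:
        raise ValueError("empty cluster")
    return cluster.size, cluster.mean_identity_to_seed


def minimal_enrichment_threshold(round_late: str, round_early: str,
                                 round_totals: dict[str, int]) -> float:
    """Enrichment of a two-sequence cluster with one read per compared
    round: total_early / total_late."""
    late, early = round_totals[str(round_late)], round_totals[str(round_early)]
    if late <= 0 or early <= 0:
        raise ValueError("round totals must be positive")
    return early / late


def cluster_enrichment(cluster: Cluster, round_late: str, round_early: str,
                       round_totals: dict[str, int]) -> ClusterEnrichment:
    """Eq-style enrichment ratio of a cluster between two rounds.

    Clusters missing reads in either compared round are labeled
    ``excluded`` (never an infinite ratio).
    """
    round_late, round_early = str(round_late), str(round_early)
    n_late = cluster.round_count(round_late)
    n_early = cluster.round_count(round_early)
    if n_late == 0 or n_early == 0:
        return ClusterEnrichment(
            cluster.cluster_id, round_late, round_early, float("nan"), "excluded"
        )
    total_late = round_totals[round_late]
    total_early = round_totals[round_early]
    if total_late <= 0 or total_early <= 0:
        raise ValueError("round totals must be positive")
    ratio = (n_late / total_late) / (n_early / total_early)
    threshold = minimal_enrichment_threshold(round_late, round_early, round_totals)
    if ratio > threshold:
        label = "enriched"
    elif ratio < 1.0:
        label = "depleted"
    else:
        label = "excluded"
    return ClusterEnrichment(cluster.cluster_id, round_late, round_early, ratio, label)


def write_cluster_tsv(clusters, path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tseed\tsequence\tround\tcount\n")
        for cl in clusters:
            for seq in sorted(cl.members):
                counts = cl.members[seq]
                for rnd in sorted(counts):
                    fh.write(f"{cl.cluster_id}\t{cl.seed}\t{seq}\t{rnd}\t{counts[rnd]}\n")


def read_cluster_tsv(path) -> list[Cluster]:
    clusters: dict[int, Cluster] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["cluster_id", "seed", "sequence", "round", "count"]:
            raise ValueError(f"unexpected cluster TSV header in {path}")
        for line in fh:
            cid_s, seed, seq, rnd, count = line.rstrip("\n").split("\t")
            cid = int(cid_s)
            cl = clusters.setdefault(cid, Cluster(cluster_id=cid, seed=seed))
            cl.members.setdefault(seq, Counter())[rnd] += int(count)
    return [clusters[c] for c in sorted(clusters)]
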