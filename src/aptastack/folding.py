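"""Secondary-structure prediction and ensemble comparison.

Two backends provide the same API:

* :class:`ReferenceBackend` — the built-in pair-maximization model
  (canonical pairs, minimum hairpin loop 3, one stability unit per pair,
  Boltzmann ensemble at unit temperature).  Deterministic, dependency-free
  and exactly verifiable against exhaustive structure enumeration.
* :class:`ViennaBackend` — the ViennaRNA thermodynamic model, used when the
  ``RNA`` python bindings are importable.

Downstream modules (NCM extraction, ensemble distances) are backend
agnostic: they consume dot-bracket strings and pairing-probability
matrices only.

The ensemble distance between two equal-length sequences A and B is

    d(A, B) = (1/|A|) * sum_{i<j} (P_ij^A - P_ij^B)^2

where P_ij is the probability that positions i and j pair and |A| is the
sequence length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import _nussinov

__all__ = [
    "SecondaryStructure",
    "PairProbabilityMatrix",
    "ReferenceBackend",
    "ViennaBackend",
    "get_backend",
    "fold",
    "pair_probabilities",
    "ensemble_distance",
    "intra_cluster_distances",
    "inter_cluster_distances",
    "intra_inter_cluster_distance",
    "pair_table_to_dot_bracket",
    "dot_bracket_to_pairs",
]


@dataclass(frozen=True)
class SecondaryStructure:
    """A single predicted structure for one sequence."""

    sequence: str
    dot_bracket: str
    representation: str  # "mfe" | "centroid"
    energy: float  # backend units (reference: -1 per pair)

    def __post_init__(self):
        if len(self.dot_bracket) != len(self.sequence):
            raise ValueError("dot-bracket length must match sequence length")

    @property
    def pairs(self) -> frozenset[tuple[int, int]]:
        """Base pairs as 0-based (i, j) with i < j."""
        return frozenset(dot_bracket_to_pairs(self.dot_bracket))


@dataclass
class PairProbabilityMatrix:
    """Symmetric matrix of base-pairing probabilities for one sequence."""

    matrix: np.ndarray  # (n, n) symmetric, zero diagonal

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("pair-probability matrix must be square")
        self.matrix = m

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def prob(self, i: int, j: int) -> float:
        """P(i pairs j), 0-based symmetric access."""
        return float(self.matrix[i, j])


def dot_bracket_to_pairs(db: str) -> list[tuple[int, int]]:
    pairs, stack = [], []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"unexpected symbol {c!r} in dot-bracket")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return sorted(pairs)


def pair_table_to_dot_bracket(pt) -> str:
    out = []
    for i, p in enumerate(pt):
        if p < 0:
            out.append(".")
        elif p > i:
            out.append("(")
        else:
            out.append(")")
    return "".join(out)


def _normalize(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid bases {sorted(bad)} in sequence")
    return seq


class ReferenceBackend:
    """Built-in pair-maximization folding model.

    MFE traceback is deterministic: on ties the pairing branch is preferred
    and the 5'-most partner chosen.  Results are memoized per sequence, so
    repeated folds of pool sequences across resamples are free.
    """

    name = "reference"

    def __init__(self, cache: bool = True):
        self._mfe_cache: dict[str, list[int]] | None = {} if cache else None
        self._bppm_cache: dict[str, np.ndarray] | None = {} if cache else None

    def mfe_pair_table(self, sequence: str) -> list[int]:
        """Optimal pair table (0-based partner, -1 unpaired)."""
        seq = _normalize(sequence)
        if self._mfe_cache is not None and seq in self._mfe_cache:
            return self._mfe_cache[seq]
        pt = _nussinov.mfe_pair_table(_nussinov.encode(seq)).tolist()
        if self._mfe_cache is not None:
            self._mfe_cache[seq] = pt
        return pt

    def mfe(self, sequence: str) -> SecondaryStructure:
        seq = _normalize(sequence)
        pt = self.mfe_pair_table(seq)
        db = pair_table_to_dot_bracket(pt)
        energy = -float(db.count("("))
        return SecondaryStructure(seq, db, "mfe", energy)

    def pair_probabilities(self, sequence: str) -> PairProbabilityMatrix:
        seq = _normalize(sequence)
        if self._bppm_cache is not None and seq in self._bppm_cache:
            m = self._bppm_cache[seq]
        else:
            m = _nussinov.pair_probability_matrix(_nussinov.encode(seq))
            if self._bppm_cache is not None:
                self._bppm_cache[seq] = m
        return PairProbabilityMatrix(m)

    def centroid(self, sequence: str) -> SecondaryStructure:
        m = self.pair_probabilities(sequence).matrix
        seq = _normalize(sequence)
        n = len(seq)
        pt = np.full(n, -1, dtype=int)
        ii, jj = np.nonzero(np.triu(m) > 0.5)
        for i, j in zip(ii, jj):
            pt[i], pt[j] = j, i
        db = pair_table_to_dot_bracket(pt)
        return SecondaryStructure(seq, db, "centroid", -float(len(ii)))


class ViennaBackend:
    """Thermodynamic folding through the ViennaRNA python bindings."""

    name = "vienna"

    def __init__(self, cache: bool = True):
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "ViennaRNA python bindings are required for the vienna "
                "backend; install the 'vienna' extra or use the reference "
                "backend"
            ) from exc
        self._RNA = RNA
        self._mfe_cache: dict[str, tuple[str, float]] | None = {} if cache else None

    def mfe(self, sequence: str) -> SecondaryStructure:
        seq = _normalize(sequence)
        if self._mfe_cache is not None and seq in self._mfe_cache:
            db, e = self._mfe_cache[seq]
        else:
            db, e = self._RNA.fold_compound(seq).mfe()
            if self._mfe_cache is not None:
                self._mfe_cache[seq] = (db, e)
        return SecondaryStructure(seq, db, "mfe", float(e))

    def pair_probabilities(self, sequence: str) -> PairProbabilityMatrix:
        seq = _normalize(sequence)
        fc = self._RNA.fold_compound(seq)
        fc.pf()
        bpp = np.asarray(fc.bpp())[1:, 1:]  # 1-based upper triangle
        m = bpp + bpp.T
        return PairProbabilityMatrix(m)

    def centroid(self, sequence: str) -> SecondaryStructure:
        seq = _normalize(sequence)
        fc = self._RNA.fold_compound(seq)
        fc.pf()
        db, dist = fc.centroid()
        return SecondaryStructure(seq, db, "centroid", float(dist))


def get_backend(name: str = "reference", cache: bool = True):
    if name == "reference":
        return ReferenceBackend(cache=cache)
    if name == "vienna":
        return ViennaBackend(cache=cache)
    raise ValueError(f"unknown folding backend {name!r}")


def fold(sequence: str, representation: str = "mfe", backend=None) -> SecondaryStructure:
    """Predict the MFE or centroid structure of one sequence."""
    backend = backend or ReferenceBackend()
    if representation == "mfe":
        return backend.mfe(sequence)
    if representation == "centroid":
        return backend.centroid(sequence)
    raise ValueError(f"unknown representation {representation!r}")


def pair_probabilities(sequence: str, backend=None) -> PairProbabilityMatrix:
    backend = backend or ReferenceBackend()
    return backend.pair_probabilities(sequence)


def ensemble_distance(a: PairProbabilityMatrix, b: PairProbabilityMatrix) -> float:
    """Mean squared base-pair probability difference between two ensembles.

    Both sequences must have the same length; the sum runs over all i < j
    cells present in either matrix and is normalized by the length.
    """
    if a.length != b.length:
        raise ValueError(
            f"ensemble distance requires equal lengths ({a.length} != {b.length})"
        )
    n = a.length
    if n == 0:
        raise ValueError("empty matrices")
    iu = np.triu_indices(n, k=1)
    diff = a.matrix[iu] - b.matrix[iu]
    return float(np.sum(diff * diff) / n)


def _pairwise_distances(mats_a, mats_b=None):
    """All-against-all ensemble distances; equal-length pairs only."""
    dists, skipped = [], 0
    if mats_b is None:
        for x, y in itertools.combinations(mats_a, 2):
            if x.length == y.length:
                dists.append(ensemble_distance(x, y))
            else:
                skipped += 1
    else:
        for x in mats_a:
            for y in mats_b:
                if x.length == y.length:
                    dists.append(ensemble_distance(x, y))
                else:
                    skipped += 1
    return np.asarray(dists), skipped


@dataclass
class DistanceDistribution:
    """Summary of a within- or between-cluster distance distribution."""

    kind: str  # "intra" | "inter"
    cluster_a: int
    cluster_b: int | None
    distances: np.ndarray
    skipped_unequal_length: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def median(self) -> float:
        return float(np.median(self.distances)) if self.distances.size else float("nan")

    @property
    def first_quartile(self) -> float:
        return (
            float(np.percentile(self.distances, 25))
            if self.distances.size
            else float("nan")
        )


def intra_cluster_distances(cluster, backend=None, max_sequences: int = 1000,
                            seed: int = 0) -> DistanceDistribution:
    """Pairwise ensemble distances among up to ``max_sequences`` distinct
    members of one cluster (folded over the full insert)."""
    backend = backend or ReferenceBackend()
    seqs = sorted(cluster.members)
    if len(seqs) > max_sequences:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(seqs), size=max_sequences, replace=False)
        seqs = [seqs[i] for i in sorted(idx)]
    mats = [backend.pair_probabilities(s) for s in seqs]
    d, skipped = _pairwise_distances(mats)
    dist = DistanceDistribution("intra", cluster.cluster_id, None, d, skipped)
    if d.size == 0:
        dist.warnings.append("no equal-length pairs within cluster")
    return dist


def intra_inter_cluster_distance(clusters, backend=None, n_sample: int = 1000,
                                 top_n: int = 100, min_size: int = 100,
                                 min_identity: float = 0.90, seed: int = 0):
    """Distance distributions for all qualifying cluster pairs.

    Clusters qualify with more than ``min_size`` distinct sequences and a
    mean member identity to the seed above ``min_identity``.  Returns
    (intra, inter): per-cluster within distributions (up to ``n_sample``
    members) and per-pair between distributions (top ``top_n`` members
    each, equal-length pairs only).
    """
    backend = backend or ReferenceBackend()
    selected = [
        c for c in clusters
        if c.size > min_size and c.mean_identity_to_seed > min_identity
    ]
    intra = {
        c.cluster_id: intra_cluster_distances(c, backend, n_sample, seed)
        for c in selected
    }
    inter = {}
    for a, b in itertools.combinations(selected, 2):
        inter[(a.cluster_id, b.cluster_id)] = inter_cluster_distances(
            a, b, backend, top_n
        )
    return intra, inter


def inter_cluster_distances(cluster_a, cluster_b, backend=None,
                            top_n: int = 100) -> DistanceDistribution:
    """Ensemble distances between the top ``top_n`` most frequent members
    of two clusters, all-against-all, equal-length pairs only."""
    backend = backend or ReferenceBackend()

    def top(cluster):
        ranked = sorted(
            cluster.members.items(),
            key=lambda kv: (-sum(kv[1].values()), kv[0]),
        )
        return [s for s, _ in ranked[:top_n]]

    mats_a = [backend.pair_probabilities(s) for s in top(cluster_a)]
    mats_b = [backend.pair_probabilities(s) for s in top(cluster_b)]
    d, skipped = _pairwise_distances(mats_a, mats_b)
    dist = DistanceDistribution(
        "inter", cluster_a.cluster_id, cluster_b.cluster_id, d, skipped
    )
    if d.size == 0:
        dist.warnings.append("no equal-length pairs between clusters")
    return dist
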