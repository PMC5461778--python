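"""Synthetic SELEX round generator with ground truth.

The generator emulates the sequenced selection experiment: four sequenced
rounds over an 87-nt template (15-nt primers, 30-nt randomized region,
27-nt constant region), round-over-round enrichment of sequences whose
variable regions fold into planted base-pair stacks, and the library's
read artifacts (rapid amplifiers carrying a duplicated T7 promoter,
~79-nt short fragments from an 8-nt variable-region deletion, low-quality
reads).

Selection acts on whole sequences: between sequenced rounds the frequency
of founder i is updated as f(i) <- f(i) * s(i) (renormalized), where s(i)
is the product of the selection coefficients of the planted motifs the
founder carries; reads are then drawn multinomially to the round's pool
size.  Everything is deterministic under the master seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import numpy as np

from . import selex_io
from .background import MutationModel, _mutate_constant
from .folding import ReferenceBackend
from .ncm import extract_ncms
from .template import (
    CONSTANT_REGION,
    PRIMER_3,
    PRIMER_5,
    T7_PROMOTER,
    VARIABLE_LENGTH,
    expected_insert,
)

__all__ = [
    "PlantedMotif",
    "RoundSpec",
    "SimConfig",
    "Scaffold",
    "GroundTruth",
    "make_scaffold",
    "simulate_rounds",
    "write_fastq",
    "pools_from_reads",
    "end_to_end_recovery",
]

_PAIRS = ("AU", "UA", "GC", "CG", "GU", "UG")

#: Default helix-extension pairs: strong (G-C) plus wobble (G-U) pairs, so
#: planted stems are stable under the folding model and the selected pool
#: acquires the G/C/U-skewed composition characteristic of structured
#: selections.
STEM_EXTENSION_PAIRS = ("GC", "CG", "GU", "UG")


@dataclass(frozen=True)
class PlantedMotif:
    """A base-pair-stack motif under selection."""

    motif_id: str
    stacks: tuple[str, ...]  # 2_2 labels, e.g. ("CG/GU",)
    selection_coefficient: float = 1.0
    n_families: int = 1  # independent scaffold lineages carrying the motif
    variants_per_family: int = 1  # distinct founders per lineage
    initial_weight: float = 1.0  # founder weight relative to background
    extension_pairs: tuple[str, ...] = STEM_EXTENSION_PAIRS
    pad_bases: str = "AC"  # unstructured filler around the stem-loop block

    def __post_init__(self):
        if self.selection_coefficient <= 0:
            raise ValueError("selection coefficients must be > 0")
        if self.initial_weight <= 0:
            raise ValueError("initial weights must be > 0")


@dataclass(frozen=True)
class RoundSpec:
    label: str
    pool_size: int


@dataclass
class SimConfig:
    rounds: list[RoundSpec]
    planted: list[PlantedMotif] = field(default_factory=list)
    n_background_founders: int = 1000
    neutral_families: int = 0  # structured lineages with s = 1
    variants_per_neutral_family: int = 1
    neutral_initial_weight: float = 1.0
    # neutral stems avoid wobble pairs so unselected lineages do not carry
    # the wobble-containing stacks typically planted as selected motifs
    neutral_extension_pairs: tuple[str, ...] = ("GC", "CG", "AU", "UA")
    neutral_pad_bases: str = "AC"
    mutation_model: MutationModel | None = None
    rapid_amplifier_rate: float = 0.0
    short_fragment_rate: float = 0.0
    low_quality_rate: float = 0.0
    master_seed: int = 0

    def __post_init__(self):
        for r in (self.rapid_amplifier_rate, self.short_fragment_rate,
                  self.low_quality_rate):
            if not 0 <= r <= 1:
                raise ValueError("artifact rates must be in [0, 1]")


@dataclass(frozen=True)
class Scaffold:
    """A designed insert whose MFE structure contains requested stacks."""

    insert: str
    variable_region: str
    stem_start: int  # within the variable region
    stem_length: int  # pairs
    loop_length: int
    labels: tuple[str, ...]

    @property
    def mutable_positions(self) -> list[int]:
        """Variable-region positions outside the stem/loop block."""
        span = 2 * self.stem_length + self.loop_length
        return [
            p for p in range(VARIABLE_LENGTH)
            if not self.stem_start <= p < self.stem_start + span
        ]


def _chain_stacks(stacks: tuple[str, ...]) -> list[str]:
    """Order 2_2 labels into a contiguous helix; raises if impossible."""
    parsed = []
    for lab in stacks:
        parts = lab.split("/")
        if len(parts) != 2 or any(p not in _PAIRS for p in parts):
            raise ValueError(f"invalid 2_2 label {lab!r}")
        parsed.append(tuple(parts))
    for perm in permutations(parsed):
        chain = list(perm[0])
        ok = True
        for first, second in perm[1:]:
            if first == chain[-1]:
                chain.append(second)
            else:
                ok = False
                break
        if ok:
            return chain
    raise ValueError(
        f"stacks {stacks} cannot be chained into a single helix "
        "(adjacent pairs are incompatible)"
    )


def make_scaffold(stacks, seed: int, stem_length: int = 8, loop_length: int = 4,
                  backend=None, max_tries: int = 100,
                  extension_pairs: tuple[str, ...] = STEM_EXTENSION_PAIRS,
                  pad_bases: str = "AC") -> Scaffold:
    """Design an aptamer whose folded insert contains the requested stacks.

    The requested 2_2 labels are chained into a contiguous run of base
    pairs, extended with random canonical pairs to ``stem_length``, closed
    by a loop and embedded at a random offset in the 30-nt variable
    region.  The candidate is accepted only once the reference backend's
    MFE structure of the full insert contains every requested label.
    """
    backend = backend or ReferenceBackend()
    chain = _chain_stacks(tuple(stacks))
    if stem_length < len(chain):
        raise ValueError("stem_length shorter than the requested chain")
    span = 2 * stem_length + loop_length
    if span > VARIABLE_LENGTH:
        raise ValueError("stem + loop exceeds the variable region")
    rng = np.random.default_rng(seed)
    want = Counter(stacks)
    for _ in range(max_tries):
        pairs = list(chain)
        while len(pairs) < stem_length:
            if rng.random() < 0.5:
                pairs.insert(0, extension_pairs[rng.integers(len(extension_pairs))])
            else:
                pairs.append(extension_pairs[rng.integers(len(extension_pairs))])
        loop = "".join(rng.choice(list(pad_bases), size=loop_length))
        stem5 = "".join(p[0] for p in pairs)
        stem3 = "".join(p[1] for p in reversed(pairs))
        block = stem5 + loop + stem3
        start = int(rng.integers(0, VARIABLE_LENGTH - span + 1))
        pad = "".join(rng.choice(list(pad_bases), size=VARIABLE_LENGTH - span))
        var = (pad[:start] + block + pad[start:]).replace("U", "T")
        insert = expected_insert(var)
        found = extract_ncms(insert, backend.mfe(insert))
        if all(found.get(lab, 0) >= cnt for lab, cnt in want.items()):
            return Scaffold(
                insert=insert,
                variable_region=var,
                stem_start=start,
                stem_length=stem_length,
                loop_length=loop_length,
                labels=tuple(stacks),
            )
    raise RuntimeError(
        f"could not realize stacks {tuple(stacks)} in the MFE structure "
        f"after {max_tries} tries"
    )


@dataclass
class GroundTruth:
    """Provenance and expectations for every emitted read."""

    founders: list[str]  # full inserts
    provenance: list[str | None]  # motif_id, "neutral-family", or None
    selection: np.ndarray  # per-founder selection coefficient
    expected_freqs: dict[str, np.ndarray]  # round label -> founder freqs
    planted_labels: dict[str, tuple[str, ...]]  # motif_id -> 2_2 labels
    artifact_counts: dict[str, Counter] = field(default_factory=dict)


_HIGH_Q = 38
_LOW_Q = 10


def _rapid_amplifier_read(rng: np.random.Generator) -> str:
    # promoter/primer-only artifact carrying a duplicated T7 promoter;
    # filler keeps the primer-delimited insert inside the accepted length
    # band so the duplicated promoter is what rejects the read
    filler = "".join(rng.choice(list("ACGT"), size=32))
    return T7_PROMOTER + PRIMER_5 + filler + T7_PROMOTER + PRIMER_5 + PRIMER_3


def _delete_variable(insert: str, rng: np.random.Generator, k: int = 8) -> str:
    var_start = len(PRIMER_5)
    pos = int(rng.integers(0, VARIABLE_LENGTH - k + 1))
    i = var_start + pos
    return insert[:i] + insert[i + k:]


def _mutate_variable(var: str, positions, rng: np.random.Generator,
                     n_mut: int) -> str:
    pos = rng.choice(len(positions), size=min(n_mut, len(positions)),
                     replace=False)
    out = list(var)
    for p in pos:
        i = positions[int(p)]
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def _build_founders(config: SimConfig, rng: np.random.Generator, backend):
    founders: list[str] = []
    provenance: list[str | None] = []
    selection: list[float] = []
    weights: list[float] = []
    planted_labels: dict[str, tuple[str, ...]] = {}
    for motif in config.planted:
        planted_labels[motif.motif_id] = motif.stacks
        for fam in range(motif.n_families):
            scaffold = make_scaffold(
                motif.stacks, seed=int(rng.integers(2**31)), backend=backend,
                extension_pairs=motif.extension_pairs,
                pad_bases=motif.pad_bases,
            )
            variants = {scaffold.variable_region}
            while len(variants) < motif.variants_per_family:
                variants.add(
                    _mutate_variable(
                        scaffold.variable_region, scaffold.mutable_positions,
                        rng, n_mut=int(rng.integers(1, 3)),
                    )
                )
            for var in sorted(variants):
                founders.append(expected_insert(var))
                provenance.append(motif.motif_id)
                selection.append(motif.selection_coefficient)
                weights.append(motif.initial_weight)
    for fam in range(config.neutral_families):
        scaffold_seed = int(rng.integers(2**31))
        # a structured but unselected lineage: random stem, no fixed label
        ext = config.neutral_extension_pairs
        pair = ext[int(rng.integers(len(ext)))]
        try:
            scaffold = make_scaffold((pair + "/" + pair,), seed=scaffold_seed,
                                     backend=backend, extension_pairs=ext,
                                     pad_bases=config.neutral_pad_bases)
        except RuntimeError:  # pragma: no cover - extremely unlikely
            continue
        variants = {scaffold.variable_region}
        while len(variants) < config.variants_per_neutral_family:
            variants.add(
                _mutate_variable(
                    scaffold.variable_region, scaffold.mutable_positions,
                    rng, n_mut=int(rng.integers(1, 3)),
                )
            )
        for var in sorted(variants):
            founders.append(expected_insert(var))
            provenance.append("neutral-family")
            selection.append(1.0)
            weights.append(config.neutral_initial_weight)
    n_bg = config.n_background_founders
    if n_bg:
        base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
        codes = rng.integers(0, 4, size=(n_bg, VARIABLE_LENGTH))
        raw = base_bytes[codes].tobytes()
        L = VARIABLE_LENGTH
        for i in range(n_bg):
            founders.append(expected_insert(raw[i * L : (i + 1) * L].decode()))
            provenance.append(None)
            selection.append(1.0)
            weights.append(1.0)
    return founders, provenance, np.asarray(selection), np.asarray(weights)


def simulate_rounds(config: SimConfig, backend=None):
    """Simulate per-round reads; returns ({round: [ReadRecord]}, GroundTruth)."""
    backend = backend or ReferenceBackend()
    rng = np.random.default_rng(config.master_seed)
    founders, provenance, selection, weights = _build_founders(config, rng, backend)
    n = len(founders)
    if n == 0:
        raise ValueError("no founders configured")
    freqs = weights / weights.sum()
    qual_cache: dict[int, tuple[int, ...]] = {}

    def high_quals(length: int) -> tuple[int, ...]:
        q = qual_cache.get(length)
        if q is None:
            q = tuple([_HIGH_Q] * length)
            qual_cache[length] = q
        return q

    reads: dict[str, list[selex_io.ReadRecord]] = {}
    expected: dict[str, np.ndarray] = {}
    artifacts: dict[str, Counter] = {}
    for ridx, spec in enumerate(config.rounds):
        if ridx > 0:
            freqs = freqs * selection
            freqs = freqs / freqs.sum()
        expected[spec.label] = freqs.copy()
        counts = rng.multinomial(spec.pool_size, freqs)
        founder_idx = np.repeat(np.arange(n), counts)
        n_reads = founder_idx.size
        u = rng.random(n_reads)
        rapid = u < config.rapid_amplifier_rate
        short = (~rapid) & (
            u < config.rapid_amplifier_rate + config.short_fragment_rate
        )
        lowq = rng.random(n_reads) < config.low_quality_rate
        emit_order = rng.permutation(n_reads)
        mutate = config.mutation_model and config.mutation_model.rate > 0
        art = Counter()
        round_reads = []
        for read_no, ri in enumerate(emit_order, start=1):
            seq = founders[founder_idx[ri]]
            if rapid[ri]:
                seq = _rapid_amplifier_read(rng)
                art["rapid amplifier"] += 1
            elif short[ri]:
                seq = _delete_variable(seq, rng)
                art["short fragment"] += 1
            if mutate:
                const = _mutate_constant(rng, config.mutation_model)
                if const != CONSTANT_REGION:
                    seq = seq.replace(CONSTANT_REGION, const, 1)
                    art["constant mutation"] += 1
            if lowq[ri]:
                quals = [_HIGH_Q] * len(seq)
                quals[int(rng.integers(len(quals)))] = _LOW_Q
                quals = tuple(quals)
                art["low quality"] += 1
            else:
                quals = high_quals(len(seq))
            round_reads.append(
                selex_io.ReadRecord(
                    identifier=f"r{spec.label}_{read_no}",
                    sequence=seq,
                    qualities=quals,
                    round=spec.label,
                )
            )
        reads[spec.label] = round_reads
        artifacts[spec.label] = art
    truth = GroundTruth(
        founders=founders,
        provenance=provenance,
        selection=selection,
        expected_freqs=expected,
        planted_labels={m.motif_id: m.stacks for m in config.planted},
        artifact_counts=artifacts,
    )
    return reads, truth


def write_fastq(reads, path) -> None:
    """Write simulated reads as Sanger PHRED+33 FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.identifier}\n{r.sequence}\n+\n{qual}\n")


def pools_from_reads(reads_by_round, quality_min: int = 20):
    """Filter simulated reads through the standard read filters."""
    pools, reports = {}, {}
    for label, reads in reads_by_round.items():
        pool = selex_io.SequencePool(round=label)
        report = selex_io.FilterReport()
        for r in reads:
            ok, reason = selex_io.filter_read(r, quality_min=quality_min)
            if ok:
                report.accepted += 1
                pool.add(selex_io.extract_insert(r))
            else:
                report.rejected[reason] += 1
        pools[label], reports[label] = pool, report
    return pools, reports


def end_to_end_recovery(config: SimConfig, sample_size: int = 5000,
                        n_resamples: int = 11, alpha: float = 0.001,
                        run_lasso: bool = True, min_cluster_size: int = 5,
                        identity_threshold: float = 0.85,
                        n_reclusterings: int = 5, stability_min: int = 3,
                        p_max: float = 0.01, bg_size: int | None = None,
                        backend=None) -> dict:
    """Run the full pipeline on a simulated experiment and score it
    against the ground truth.

    Compares the last configured round against the first.  The background
    is simulated in sampled mode from the late round and regenerated with
    a distinct derived seed for every resample, so background ratios carry
    generation noise and the enrichment test stays calibrated.  Returns a
    report with the enrichment calls, the retained regression predictors
    and hit/false-positive summaries for the planted labels.
    """
    from . import background as bg_mod
    from .ncm import enrichment_report, ncm_frequencies
    from .regression import stable_predictors

    backend = backend or ReferenceBackend()
    reads, truth = simulate_rounds(config, backend=backend)
    pools, reports = pools_from_reads(reads)
    labels = [r.label for r in config.rounds]
    early, late = labels[0], labels[-1]
    seed0 = config.master_seed
    bg_size = bg_size or sample_size

    base_freqs = bg_mod.estimate_base_distribution(pools[late])
    model = bg_mod.estimate_mutation_model(pools[late])

    def resamples(pool):
        return [
            ncm_frequencies(pool, sample_size, resample_seed=seed0 + 1000 + i,
                            backend=backend)
            for i in range(n_resamples)
        ]

    bg_vectors = []
    for i in range(n_resamples):
        bg = bg_mod.simulate_background(
            bg_size, "sampled", model, seed=seed0 + 777 + i,
            base_freqs=base_freqs,
        )
        bg_pool = selex_io.SequencePool(round="background")
        for s in bg.sequences:
            bg_pool.add(s)
        bg_vectors.append(
            ncm_frequencies(bg_pool, bg_size, resample_seed=seed0 + 777 + i,
                            backend=backend)
        )

    records = enrichment_report(
        resamples(pools[late]), resamples(pools[early]), bg_vectors,
        alpha=alpha,
    )
    enriched = {r.label for r in records if r.status == "enriched"}
    depleted = {r.label for r in records if r.status == "depleted"}

    planted = set()
    for m in config.planted:
        planted.update(m.stacks)
    planted_enriched = {
        lab for m in config.planted if m.selection_coefficient > 1
        for lab in m.stacks
    }
    planted_depleted = {
        lab for m in config.planted if m.selection_coefficient < 1
        for lab in m.stacks
    }

    report = {
        "round_late": late,
        "round_early": early,
        "filter_reports": {k: v.as_dict() for k, v in reports.items()},
        "enriched_calls": sorted(enriched),
        "depleted_calls": sorted(depleted),
        "planted_enriched": sorted(planted_enriched),
        "planted_depleted": sorted(planted_depleted),
        "planted_enriched_recovered": sorted(planted_enriched & enriched),
        "planted_depleted_recovered": sorted(planted_depleted & depleted),
        "records": records,
    }
    if run_lasso and config.planted:
        round_totals = {k: p.total_usable for k, p in pools.items()}
        selected = stable_predictors(
            list(pools.values()), round_late=late, round_early=early,
            round_totals=round_totals, backend=backend,
            n_reclusterings=n_reclusterings, stability_min=stability_min,
            p_max=p_max, min_cluster_size=min_cluster_size,
            identity_threshold=identity_threshold, seed=seed0 + 5000,
        )
        retained = {p.label for p in selected}
        report["lasso_retained"] = sorted(retained)
        report["planted_lasso_retained"] = sorted(planted_enriched & retained)
    return report
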