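"""Simulated background pools (BG_uni / BG_samp) with an empirical
constant-region mutation model.

Background aptamers are assembled as 5' primer + simulated 30-nt variable
region + simulated constant region + 3' primer.  The variable region is
drawn with uniform base probabilities (``uniform`` mode) or with the base
distribution observed in the pool's variable regions (``sampled`` mode).
The constant region starts from the 27-nt reference and receives a
Poisson-distributed number of mutation events whose per-site rate,
point/insertion/deletion mix and substitution outcomes are estimated from
the final-round pool.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np

from .clustering import strip_primers
from .template import (
    CONSTANT_REGION,
    PRIMER_3,
    PRIMER_5,
    VARIABLE_LENGTH,
)

__all__ = [
    "MutationModel",
    "BackgroundSet",
    "locate_variable_region",
    "estimate_base_distribution",
    "estimate_mutation_model",
    "simulate_background",
]

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class MutationModel:
    """Per-site constant-region mutation process.

    ``rate`` is events per reference site per sequence.  ``category_probs``
    orders (point, insertion, deletion).  ``substitution`` maps each
    original base to its replacement distribution over the other bases.
    ``insertion_probs`` is the base distribution of inserted nucleotides.
    """

    rate: float
    category_probs: tuple[float, float, float]
    substitution: dict[str, dict[str, float]]
    insertion_probs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("mutation rate must be non-negative")
        if self.rate > 0 and abs(sum(self.category_probs) - 1.0) > 1e-9:
            raise ValueError("category probabilities must sum to 1")
        if not self.insertion_probs:
            # default: marginal of the substitution outcomes
            marg = Counter()
            for dist in self.substitution.values():
                for b, p in dist.items():
                    marg[b] += p
            total = sum(marg.values())
            if total > 0:
                self.insertion_probs = {b: marg.get(b, 0) / total for b in _BASES}
            else:
                self.insertion_probs = {b: 0.25 for b in _BASES}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "rate": self.rate,
                    "category_probs": list(self.category_probs),
                    "substitution": self.substitution,
                    "insertion_probs": self.insertion_probs,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "MutationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            rate=d["rate"],
            category_probs=tuple(d["category_probs"]),
            substitution=d["substitution"],
            insertion_probs=d.get("insertion_probs", {}),
        )


@dataclass
class BackgroundSet:
    mode: str  # "uniform" | "sampled"
    sequences: list[str]
    seed: int


from functools import lru_cache


@lru_cache(maxsize=1 << 18)
def _locate_core(core: str, window: int) -> int:
    """Leftmost window start minimizing distance to the constant reference."""
    best_start, best_dist = 0, None
    for start in range(len(core) - window + 1):
        win = core[start : start + window]
        d = edlib.align(win, CONSTANT_REGION, mode="NW", task="distance")[
            "editDistance"
        ]
        if best_dist is None or d < best_dist:
            best_start, best_dist = start, d
    return best_start


def locate_variable_region(insert: str, window: int = 20) -> tuple[slice, slice]:
    """Locate the variable / constant regions of a primer-delimited insert.

    Slides a window of ``window`` nt along the primer-stripped core and
    picks the start minimizing the Levenshtein distance to the 27-nt
    constant reference (leftmost on ties).  Returns (variable_span,
    constant_span) as slices on the insert.
    """
    core = strip_primers(insert)
    if len(core) < window:
        raise ValueError(
            f"insert core ({len(core)} nt) shorter than window ({window} nt)"
        )
    best_start = _locate_core(core, window)
    p5 = len(PRIMER_5)
    return (
        slice(p5, p5 + best_start),
        slice(p5 + best_start, len(insert) - len(PRIMER_3)),
    )


def estimate_base_distribution(pools) -> dict[str, float]:
    """Base frequencies of the located variable regions, count-weighted.

    The variable region ends where the infix-aligned constant reference
    begins (see :func:`_align_constant`).
    """
    counts = Counter()
    if hasattr(pools, "counts"):
        pools = [pools]
    for pool in pools:
        for seq, n in pool.counts.items():
            start, _ = _align_constant(strip_primers(seq))
            for b in strip_primers(seq)[:start]:
                counts[b] += n
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no variable-region bases located")
    return {b: counts.get(b, 0) / total for b in _BASES}


@lru_cache(maxsize=1 << 18)
def _align_constant(core: str) -> tuple[int, tuple]:
    """Locate the constant region and read off its mutation events.

    The 27-nt reference is first infix-aligned into the primer-stripped
    core to find a candidate start.  Because the library's variable region
    is 30 nt by design, a start within a few bases of 30 is snapped to 30:
    this removes the boundary ambiguity where a mutated head base could
    otherwise be pushed into the free flank and mis-read as a deletion.
    A start far from 30 (a variable-region indel, e.g. a short fragment)
    is kept as located.  Returns (start, events) with events as
    (kind, ref_base, obs_base).
    """
    res = edlib.align(CONSTANT_REGION, core, mode="HW", task="locations")
    start = res["locations"][0][0]
    if abs(start - VARIABLE_LENGTH) <= 4:
        start = min(VARIABLE_LENGTH, len(core))
    observed = core[start:]
    path = edlib.align(observed, CONSTANT_REGION, mode="NW", task="path")
    events = []
    i = 0  # observed position
    j = 0  # reference position
    for length, op in _parse_cigar(path["cigar"]):
        if op == "=":
            i += length
            j += length
        elif op == "X":
            for _ in range(length):
                events.append(("point", CONSTANT_REGION[j], observed[i]))
                i += 1
                j += 1
        elif op == "I":  # extra observed base
            for _ in range(length):
                events.append(("insertion", None, observed[i]))
                i += 1
        elif op == "D":  # reference base absent from the observed core
            for _ in range(length):
                events.append(("deletion", CONSTANT_REGION[j], None))
                j += 1
    return start, tuple(events)


def _parse_cigar(cigar: str):
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            yield int(num), c
            num = ""


def estimate_mutation_model(pool) -> MutationModel:
    """Estimate the constant-region mutation model from a (final-round)
    pool by infix-aligning each core against the constant reference.

    The per-site rate uses all aligned events.  Category and outcome
    distributions are tallied from single-event sequences only: in
    multi-event sequences a minimum-cost alignment can merge adjacent
    events (a substitution next to a deletion reads as one deletion),
    which biases the category mix; lone events are unambiguous and,
    since events are independent, an unbiased sample of the mix.
    """
    n_seqs = 0
    n_all_events = 0
    cat = Counter()
    subs: dict[str, Counter] = {b: Counter() for b in _BASES}
    ins = Counter()
    for seq, n in pool.counts.items():
        n_seqs += n
        _, events = _align_constant(strip_primers(seq))
        n_all_events += n * len(events)
        if len(events) != 1:
            continue
        for kind, ref_b, obs_b in events:
            cat[kind] += n
            if kind == "point" and ref_b in subs and obs_b in _BASE_IDX:
                subs[ref_b][obs_b] += n
            elif kind == "insertion" and obs_b in _BASE_IDX:
                ins[obs_b] += n
    if n_seqs == 0:
        raise ValueError("no constant regions located")
    rate = n_all_events / (n_seqs * len(CONSTANT_REGION))
    total_events = sum(cat.values())
    if total_events == 0:
        return MutationModel(rate, (1.0, 0.0, 0.0), {})
    probs = (
        cat["point"] / total_events,
        cat["insertion"] / total_events,
        cat["deletion"] / total_events,
    )
    substitution = {}
    for b, c in subs.items():
        t = sum(c.values())
        if t:
            substitution[b] = {o: c[o] / t for o in sorted(c)}
    ins_total = sum(ins.values())
    ins_probs = (
        {b: ins.get(b, 0) / ins_total for b in _BASES} if ins_total else {}
    )
    return MutationModel(rate, probs, substitution, ins_probs)


def _mutate_constant(rng: np.random.Generator, model: MutationModel) -> str:
    ref = CONSTANT_REGION
    n_sites = len(ref)
    k = min(int(rng.poisson(model.rate * n_sites)), n_sites)
    if k == 0:
        return ref
    sites = np.sort(rng.choice(n_sites, size=k, replace=False))
    cats = rng.choice(3, size=k, p=model.category_probs)
    out = []
    prev = 0
    for site, cat in zip(sites, cats):
        out.append(ref[prev:site])
        base = ref[site]
        if cat == 0:  # point mutation
            dist = model.substitution.get(base)
            if dist:
                opts = sorted(dist)
                probs = np.array([dist[o] for o in opts])
                new = opts[rng.choice(len(opts), p=probs / probs.sum())]
            else:
                new = _BASES[(_BASE_IDX[base] + 1 + rng.integers(3)) % 4]
            out.append(new)
        elif cat == 1:  # insertion after the site
            opts = sorted(model.insertion_probs)
            probs = np.array([model.insertion_probs[o] for o in opts])
            ins = opts[rng.choice(len(opts), p=probs / probs.sum())]
            out.append(base + ins)
        else:  # deletion of the site's base
            pass
        prev = site + 1
    out.append(ref[prev:])
    return "".join(out)


def simulate_background(n: int, mode: str, mutation_model: MutationModel,
                        seed: int, base_freqs: dict[str, float] | None = None
                        ) -> BackgroundSet:
    """Simulate ``n`` full-length background aptamers.

    ``mode`` selects uniform or sampled variable-region base composition;
    the sampled mode requires ``base_freqs`` (from
    :func:`estimate_base_distribution`).  Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("uniform", "sampled"):
        raise ValueError(f"unknown background mode {mode!r}")
    if mode == "sampled":
        if base_freqs is None:
            raise ValueError("sampled mode requires base_freqs")
        p = np.array([base_freqs[b] for b in _BASES], dtype=float)
        p = p / p.sum()
    else:
        p = np.full(4, 0.25)
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=(n, VARIABLE_LENGTH), p=p)
    bases = np.array(list(_BASES))
    sequences = []
    for row in codes:
        var = "".join(bases[row])
        const = (
            _mutate_constant(rng, mutation_model)
            if mutation_model.rate > 0
            else CONSTANT_REGION
        )
        sequences.append(PRIMER_5 + var + const + PRIMER_3)
    return BackgroundSet(mode=mode, sequences=sequences, seed=seed)
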