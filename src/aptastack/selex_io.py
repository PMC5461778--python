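"""Read filtering and per-round sequence pools.

Reads are accepted when all of the following hold, checked in a fixed
order so that every rejected read is attributed to exactly one (first
failing) filter:

1. *pattern* — the read contains the 5' primer followed, after zero or
   more bases, by the 3' primer (forward strand only);
2. *alphabet* — only A/C/G/T between and including the primers;
3. *quality* — every base's PHRED score (Sanger +33) is >= ``quality_min``
   (default 20);
4. *length* — the primer-delimited insert is 79-100 nt;
5. *rapid amplifier* — at most one occurrence of the T7 promoter 17-mer
   anywhere in the read (duplicated-promoter artifacts carry two or more).

Accepted inserts (between and including the primers) are tallied into a
:class:`SequencePool`; counts are normalized to the round's usable total
when frequencies are needed.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .template import (
    MAX_INSERT_LENGTH,
    MIN_INSERT_LENGTH,
    PRIMER_3,
    PRIMER_5,
    T7_PROMOTER,
)

__all__ = [
    "ReadRecord",
    "SequencePool",
    "FilterReport",
    "FilterError",
    "filter_read",
    "extract_insert",
    "build_pool",
    "normalized_frequency",
    "write_pool_tsv",
    "read_pool_tsv",
]

_REJECT_REASONS = ("pattern", "alphabet", "quality", "length", "rapid amplifier")

_INSERT_RE = re.compile(
    re.escape(PRIMER_5) + r"[ACGTN]*?" + re.escape(PRIMER_3)
)
_STANDARD = set("ACGT")


class FilterError(ValueError):
    """Malformed input record."""


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with per-base PHRED qualities."""

    identifier: str
    sequence: str
    qualities: tuple[int, ...]
    round: str = ""

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise FilterError(
                f"record {self.identifier!r}: sequence length "
                f"{len(self.sequence)} != quality length {len(self.qualities)}"
            )
        if self.qualities and min(self.qualities) < 0:
            raise FilterError(f"record {self.identifier!r}: negative quality")


@dataclass
class SequencePool:
    """Multiset of filtered inserts for one selection round."""

    round: str
    counts: Counter = field(default_factory=Counter)

    @property
    def total_usable(self) -> int:
        return sum(self.counts.values())

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    def add(self, insert: str, count: int = 1) -> None:
        self.counts[insert] += count


@dataclass
class FilterReport:
    """Per-filter rejection tallies; partitions the input reads."""

    accepted: int = 0
    rejected: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return self.accepted + sum(self.rejected.values())

    def as_dict(self) -> dict:
        return {
            "accepted": self.accepted,
            "rejected": {r: self.rejected.get(r, 0) for r in _REJECT_REASONS},
            "total": self.total,
        }


def _find_insert(sequence: str) -> re.Match | None:
    return _INSERT_RE.search(sequence)


def filter_read(read: ReadRecord, quality_min: int = 20) -> tuple[bool, str | None]:
    """Apply the read filters; returns (accepted, rejection reason)."""
    m = _find_insert(read.sequence)
    if m is None:
        return False, "pattern"
    insert = m.group(0)
    if not set(insert) <= _STANDARD:
        return False, "alphabet"
    if read.qualities and min(read.qualities) < quality_min:
        return False, "quality"
    if not MIN_INSERT_LENGTH <= len(insert) <= MAX_INSERT_LENGTH:
        return False, "length"
    if read.sequence.count(T7_PROMOTER) >= 2:
        return False, "rapid amplifier"
    return True, None


def extract_insert(read: ReadRecord) -> str:
    """Primer-delimited insert (inclusive of both primers).

    Contract: the read must already have passed :func:`filter_read`.
    """
    m = _find_insert(read.sequence)
    if m is None:
        raise ValueError(
            f"record {read.identifier!r} has no primer-delimited insert; "
            "filter_read must precede extract_insert"
        )
    return m.group(0)


def _quality_ok_fast(qual_str: str, min_char: str) -> bool:
    return min(qual_str) >= min_char if qual_str else True


def build_pool(fastq_path, round_label: str,
               quality_min: int = 20) -> tuple[SequencePool, FilterReport]:
    """Stream a Sanger-PHRED+33 FASTQ file into a filtered pool."""
    pool = SequencePool(round=str(round_label))
    report = FilterReport()
    min_char = chr(quality_min + 33)
    path = Path(fastq_path)
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                seq = seq.upper()
                m = _find_insert(seq)
                if m is None:
                    report.rejected["pattern"] += 1
                    continue
                insert = m.group(0)
                if not set(insert) <= _STANDARD:
                    report.rejected["alphabet"] += 1
                    continue
                if not _quality_ok_fast(qual, min_char):
                    report.rejected["quality"] += 1
                    continue
                if not MIN_INSERT_LENGTH <= len(insert) <= MAX_INSERT_LENGTH:
                    report.rejected["length"] += 1
                    continue
                if seq.count(T7_PROMOTER) >= 2:
                    report.rejected["rapid amplifier"] += 1
                    continue
                report.accepted += 1
                pool.add(insert)
        except ValueError as exc:
            raise FilterError(f"invalid FASTQ {path}: {exc}") from exc
    return pool, report


def normalized_frequency(pool: SequencePool, sequence: str) -> float:
    """Count of ``sequence`` divided by the round's usable total."""
    total = pool.total_usable
    if total == 0:
        raise ValueError(f"round {pool.round!r}: no usable reads")
    return pool.counts.get(sequence, 0) / total


def write_pool_tsv(pools, path) -> None:
    """Write one or more pools as TSV (round, sequence, count)."""
    if isinstance(pools, SequencePool):
        pools = [pools]
    with open(path, "w") as fh:
        fh.write("round\tsequence\tcount\n")
        for pool in pools:
            for seq in sorted(pool.counts):
                fh.write(f"{pool.round}\t{seq}\t{pool.counts[seq]}\n")


def read_pool_tsv(path) -> list[SequencePool]:
    """Read pools back from the TSV written by :func:`write_pool_tsv`."""
    pools: dict[str, SequencePool] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["round", "sequence", "count"]:
            raise FilterError(f"unexpected pool TSV header in {path}: {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FilterError(f"{path}:{lineno}: expected 3 columns")
            rnd, seq, count = parts
            pools.setdefault(rnd, SequencePool(round=rnd)).add(seq, int(count))
    return [pools[r] for r in sorted(pools)]
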