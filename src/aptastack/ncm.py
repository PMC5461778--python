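"""Base-pair-stack (nucleotide cyclic motif) extraction and enrichment.

A 2_2 NCM is a stack of two adjacent base pairs — both strand segments
have length exactly two, so stacks interrupted by bulges or internal
loops are not counted.  Labels name the stacked pairs from the 5' end,
each pair written 5'-base then 3'-base: the duplex 5'-AGG-3' paired with
5'-CCU-3' contains AU/GC and GC/GC.  A 3_3 NCM is three consecutive
stacked pairs; windows overlap, mirroring the 2_2 sharing rule.

Per-round NCM frequencies are computed by resampling distinct sequences
without replacement, folding each, normalizing each sequence's NCM counts
to its own total (sequences with no stacks contribute a zero vector but
stay in the denominator), and averaging over the sample.  Enrichment is
the per-resample log2 ratio of frequencies between a late round and an
early round (or a simulated background pool); significance uses the
one-sided Wilcoxon rank-sum test of the late-vs-early ratios against the
late-vs-background ratios.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .folding import ReferenceBackend, SecondaryStructure, fold

__all__ = [
    "extract_ncms",
    "NCMFrequencyVector",
    "EnrichmentRecord",
    "ncm_frequencies",
    "ncm_enrichment",
    "significance_test",
    "enrichment_report",
    "ncm_cooccurrence",
    "sequence_ncm_profile",
]

_RNA = str.maketrans("Tt", "Uu")


def extract_ncms(sequence: str, structure: SecondaryStructure | str,
                 order: str = "2_2") -> Counter:
    """Multiset of NCM labels in one structure.

    ``structure`` may be a :class:`SecondaryStructure` or a raw dot-bracket
    string.  Unpaired structures yield an empty multiset.
    """
    db = structure.dot_bracket if hasattr(structure, "dot_bracket") else structure
    seq = sequence.upper().translate(_RNA)
    if len(db) != len(seq):
        raise ValueError("structure length must match sequence length")
    n = len(seq)
    pt = [-1] * n
    stack = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pt[j], pt[i] = i, j
    return _ncms_from_pair_table(seq, pt, order)


def _ncms_from_pair_table(seq: str, pt: list[int], order: str) -> Counter:
    if order == "2_2":
        depth = 2
    elif order == "3_3":
        depth = 3
    else:
        raise ValueError(f"unknown NCM order {order!r}")
    n = len(seq)
    labels: Counter = Counter()
    for i in range(n):
        j = pt[i]
        if j <= i:
            continue
        # stack of `depth` consecutive pairs starting at (i, j)
        ok = True
        for d in range(1, depth):
            if i + d >= n or pt[i + d] != j - d or j - d <= i + d:
                ok = False
                break
        if ok:
            label = "/".join(seq[i + d] + seq[j - d] for d in range(depth))
            labels[label] += 1
    return labels


def sequence_ncm_profile(sequence: str, backend=None, representation: str = "mfe",
                         order: str = "2_2", normalize: bool = True) -> dict[str, float]:
    """Per-sequence NCM frequency (or raw count) vector.

    Results are memoized on the backend instance, so pool sequences shared
    between resamples and design rows are profiled once.
    """
    backend = backend or ReferenceBackend()
    cache = getattr(backend, "_ncm_profile_cache", None)
    if cache is None:
        cache = {}
        try:
            backend._ncm_profile_cache = cache
        except AttributeError:  # pragma: no cover - exotic backend
            cache = None
    key = (sequence, representation, order, normalize)
    if cache is not None and key in cache:
        return cache[key]
    if representation == "mfe" and hasattr(backend, "mfe_pair_table"):
        seq = sequence.upper().translate(_RNA)
        counts = _ncms_from_pair_table(seq, backend.mfe_pair_table(seq), order)
    else:
        struct = fold(sequence, representation, backend)
        counts = extract_ncms(sequence, struct, order)
    if normalize:
        total = sum(counts.values())
        result = (
            {lab: c / total for lab, c in counts.items()} if total else {}
        )
    else:
        result = dict(counts)
    if cache is not None:
        cache[key] = result
    return result


@dataclass
class NCMFrequencyVector:
    """Mean per-sequence NCM fractions for one resample of one round."""

    round: str
    resample_seed: int
    sample_size: int
    freq: dict[str, float]
    #: pseudo-frequency assigned to labels absent from this resample:
    #: half the smallest nonzero per-sequence contribution observed.
    zero_floor: float = 0.0

    def get(self, label: str) -> tuple[float, bool]:
        """(frequency, used_pseudo_floor) for one label."""
        f = self.freq.get(label, 0.0)
        if f > 0.0:
            return f, False
        return self.zero_floor, True


def ncm_frequencies(pool, sample_size: int, resample_seed: int,
                    representation: str = "mfe", backend=None,
                    order: str = "2_2") -> NCMFrequencyVector:
    """Resampled NCM frequencies for one round's pool.

    Samples ``sample_size`` distinct sequences without replacement (capped
    at the pool's distinct-sequence count), folds each, and averages the
    per-sequence normalized NCM count vectors.
    """
    backend = backend or ReferenceBackend()
    seqs = sorted(pool.counts) if hasattr(pool, "counts") else sorted(pool)
    if not seqs:
        raise ValueError("empty pool")
    n = min(sample_size, len(seqs))
    rng = np.random.default_rng(resample_seed)
    idx = rng.choice(len(seqs), size=n, replace=False)
    acc: Counter = Counter()
    min_contrib = np.inf
    for i in idx:
        profile = sequence_ncm_profile(seqs[i], backend, representation, order)
        for lab, f in profile.items():
            acc[lab] += f
            if f < min_contrib:
                min_contrib = f
    freq = {lab: v / n for lab, v in acc.items()}
    floor = 0.0 if not np.isfinite(min_contrib) else 0.5 * min_contrib / n
    rnd = getattr(pool, "round", "")
    return NCMFrequencyVector(rnd, resample_seed, n, freq, floor)


def ncm_enrichment(late: list[NCMFrequencyVector],
                   early: list[NCMFrequencyVector]) -> dict[str, dict]:
    """Per-label log2 frequency ratios, paired by resample index.

    Returns label -> {"ratios", "mean", "stderr", "pseudo_used"}.
    Labels absent from both sides of every resample are omitted; a label
    with zero frequency on one side of a resample gets that resample's
    pseudo-floor and is flagged.
    """
    if len(late) != len(early) or not late:
        raise ValueError("late and early must be equal-length, non-empty lists")
    labels = set()
    for v in (*late, *early):
        labels.update(v.freq)
    out: dict[str, dict] = {}
    for lab in sorted(labels):
        ratios, pseudo = [], False
        for lv, ev in zip(late, early):
            fl, pl = lv.get(lab)
            fe, pe = ev.get(lab)
            if fl == 0.0 or fe == 0.0:
                # pool so unstructured that no floor exists; skip resample
                continue
            pseudo = pseudo or pl or pe
            ratios.append(np.log2(fl / fe))
        if not ratios:
            continue
        arr = np.asarray(ratios)
        out[lab] = {
            "ratios": arr,
            "mean": float(arr.mean()),
            "stderr": float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0,
            "pseudo_used": pseudo,
        }
    return out


def significance_test(ratios_vs_early, ratios_vs_background,
                      alpha: float = 0.001,
                      spurious_min: float = 1.0) -> tuple[float, str]:
    """Wilcoxon rank-sum comparison of enrichment against expectation.

    Enriched: the late-vs-early log2 ratios exceed the late-vs-background
    ratios (one-sided, p < alpha).  Depleted: the opposite one-sided test.
    Spurious: a nominally large mean ratio (>= ``spurious_min`` log2 units)
    that is not significant against background.  Returns (p, status) where
    p is the smaller one-sided p-value.
    """
    x = np.asarray(ratios_vs_early, dtype=float)
    y = np.asarray(ratios_vs_background, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("insufficient resamples (need >= 3 per side)")
    p_greater = stats.mannwhitneyu(x, y, alternative="greater", method="exact").pvalue
    p_less = stats.mannwhitneyu(x, y, alternative="less", method="exact").pvalue
    if p_greater < alpha and x.mean() > y.mean():
        return float(p_greater), "enriched"
    if p_less < alpha and x.mean() < y.mean():
        return float(p_less), "depleted"
    if x.mean() >= spurious_min:
        return float(p_greater), "spurious"
    return float(min(p_greater, p_less)), "unchanged"


@dataclass
class EnrichmentRecord:
    label: str
    mean_log2_vs_early: float
    mean_log2_vs_background: float
    stderr: float
    p_value: float
    status: str
    pseudo_used: bool = False


def enrichment_report(late: list[NCMFrequencyVector],
                      early: list[NCMFrequencyVector],
                      background: list[NCMFrequencyVector],
                      alpha: float = 0.001) -> list[EnrichmentRecord]:
    """Full per-label enrichment report of a late round against an early
    round, with the late-vs-background comparison as expectation."""
    vs_early = ncm_enrichment(late, early)
    vs_bg = ncm_enrichment(late, background)
    records = []
    for lab in sorted(set(vs_early) & set(vs_bg)):
        e, b = vs_early[lab], vs_bg[lab]
        p, status = significance_test(e["ratios"], b["ratios"], alpha=alpha)
        records.append(
            EnrichmentRecord(
                label=lab,
                mean_log2_vs_early=e["mean"],
                mean_log2_vs_background=b["mean"],
                stderr=e["stderr"],
                p_value=p,
                status=status,
                pseudo_used=e["pseudo_used"] or b["pseudo_used"],
            )
        )
    return records


def ncm_cooccurrence(sequences, backend=None, representation: str = "mfe",
                     order: str = "2_2"):
    """Spearman rank correlation between per-sequence NCM count profiles.

    Returns (labels, rho matrix); correlations undefined for constant
    profiles are reported as NaN.
    """
    sequences = list(sequences)
    if len(sequences) < 10:
        raise ValueError("need >= 10 sequences for co-occurrence analysis")
    backend = backend or ReferenceBackend()
    profiles = [
        sequence_ncm_profile(s, backend, representation, order, normalize=False)
        for s in sequences
    ]
    labels = sorted(set().union(*[set(p) for p in profiles]) or set())
    if not labels:
        return [], np.empty((0, 0))
    mat = np.zeros((len(sequences), len(labels)))
    for r, p in enumerate(profiles):
        for c, lab in enumerate(labels):
            mat[r, c] = p.get(lab, 0)
    if len(labels) == 1:
        return labels, np.ones((1, 1))
    with np.errstate(invalid="ignore"):
        rho = stats.spearmanr(mat).statistic
    if np.ndim(rho) == 0:  # scipy collapses the two-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    const = mat.std(axis=0) == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    return labels, rho
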