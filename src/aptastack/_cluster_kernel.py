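"""Numba kernels for greedy seed clustering.

Clustering at 85% identity on primer-stripped cores is dominated by
distance tests: the 27-nt constant region is shared by essentially every
core, so k-mer count filters cannot prune candidate pairs and each
sequence must be tested against many seeds.  Instead, an exact sparse
neighbor graph (all pairs within the distance threshold) is built once
per sequence set with a bit-parallel Levenshtein distance (Myers'
algorithm, early-abandoned once the score cannot return below the
threshold); each greedy (re)clustering then only walks a sequence's
neighbor list.  Both steps are exact: the graph contains every pair that
any visiting order could join.
"""

import numpy as np
from numba import njit

_INF = np.int32(1 << 30)


@njit(cache=True)
def banded_levenshtein(a, la, b, lb, d):
    """Levenshtein distance if <= d, else -1 (band half-width d)."""
    if la - lb > d or lb - la > d:
        return -1
    w = 2 * d + 1
    prev = np.full(w, _INF, dtype=np.int32)
    cur = np.full(w, _INF, dtype=np.int32)
    prev[d] = 0
    for j in range(1, min(lb, d) + 1):
        prev[d + j] = j
    for i in range(1, la + 1):
        for t in range(w):
            cur[t] = _INF
        lo = i - d if i - d > 0 else 0
        hi = i + d if i + d < lb else lb
        row_min = _INF
        for j in range(lo, hi + 1):
            off = j - i + d
            if j == 0:
                cur[off] = i
                if i < row_min:
                    row_min = i
                continue
            best = _INF
            if off - 1 >= 0 and cur[off - 1] != _INF and cur[off - 1] + 1 < best:
                best = cur[off - 1] + 1
            if off + 1 < w and prev[off + 1] != _INF and prev[off + 1] + 1 < best:
                best = prev[off + 1] + 1
            if prev[off] != _INF:
                c = 0 if a[i - 1] == b[j - 1] else 1
                if prev[off] + c < best:
                    best = prev[off] + c
            cur[off] = best
            if best < row_min:
                row_min = best
        if row_min > d:
            return -1
        tmp = prev
        prev = cur
        cur = tmp
    dd = prev[lb - la + d]
    return dd if dd <= d else -1


@njit(cache=True)
def _build_peq(enc, lens):
    """Per-sequence 4-letter bitmasks for Myers' algorithm (length <= 63)."""
    n = enc.shape[0]
    peq = np.zeros((n, 4), dtype=np.uint64)
    one = np.uint64(1)
    for i in range(n):
        if lens[i] > 63:
            continue
        for p in range(lens[i]):
            peq[i, enc[i, p]] |= one << np.uint64(p)
    return peq


@njit(cache=True, inline="always")
def _myers_bounded(peq_row, sh, la, enc_b, off, lb, d):
    """Levenshtein(a[sh:sh+la], b[off:off+lb]) if <= d else -1; la <= 63."""
    one = np.uint64(1)
    mask = (one << np.uint64(la)) - one
    vp = mask
    vn = np.uint64(0)
    score = la
    top = one << np.uint64(la - 1)
    for j in range(lb):
        eq = (peq_row[enc_b[off + j]] >> sh) & mask
        xv = eq | vn
        xh = (((eq & vp) + vp) ^ vp) | eq
        hp = vn | ~(xh | vp)
        hn = vp & xh
        if hp & top:
            score += 1
        elif hn & top:
            score -= 1
        if score - (lb - 1 - j) > d:
            return -1
        hp = ((hp << one) | one) & mask
        hn = (hn << one) & mask
        vp = (hn | ~(xv | hp)) & mask
        vn = hp & xv
    return score if score <= d else -1


@njit(cache=True)
def pair_distance_bounded(enc_a, la, peq_a, enc_b, lb, d):
    """Bounded Levenshtein; strips common prefix/suffix (exact for unit
    costs) before the bit-parallel DP."""
    if la - lb > d or lb - la > d:
        return -1
    lim = la if la < lb else lb
    p = 0
    while p < lim and enc_a[p] == enc_b[p]:
        p += 1
    s = 0
    while s < lim - p and enc_a[la - 1 - s] == enc_b[lb - 1 - s]:
        s += 1
    la2 = la - p - s
    lb2 = lb - p - s
    if la2 == 0 or lb2 == 0:
        dd = la2 + lb2
        return dd if dd <= d else -1
    if la <= 63:  # bitmasks exist only for patterns that fit one word
        return _myers_bounded(peq_a, np.uint64(p), la2, enc_b, p, lb2, d)
    res = banded_levenshtein(enc_a[p : p + la2], la2, enc_b[p : p + lb2], lb2, d)
    return res


@njit(cache=True)
def build_edges(enc, lens, max_frac):
    """All (i, j) pairs (i < j) within the normalized distance threshold."""
    n = enc.shape[0]
    peq = _build_peq(enc, lens)
    cap = 4 * n + 16
    ei = np.empty(cap, dtype=np.int64)
    ej = np.empty(cap, dtype=np.int64)
    m = 0
    for i in range(n):
        li = lens[i]
        for j in range(i + 1, n):
            lj = lens[j]
            lmax = li if li > lj else lj
            d = int(np.floor(max_frac * lmax))
            if pair_distance_bounded(enc[i], li, peq[i], enc[j], lj, d) != -1:
                if m >= cap:
                    cap *= 2
                    nei = np.empty(cap, dtype=np.int64)
                    nej = np.empty(cap, dtype=np.int64)
                    nei[:m] = ei[:m]
                    nej[:m] = ej[:m]
                    ei = nei
                    ej = nej
                ei[m] = i
                ej[m] = j
                m += 1
    return ei[:m], ej[:m]
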