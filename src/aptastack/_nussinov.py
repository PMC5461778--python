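"""Numba kernels for the built-in pair-maximization folding model.

Model: canonical pairs {AU, UA, GC, CG, GU, UG}, minimum hairpin loop of 3
unpaired bases, every pair contributes one unit of stability.  The ensemble
weights a structure by exp(#pairs) (unit temperature), so the partition
function and pairing probabilities follow from inside/outside recursions on
the same recursion tree as the optimal-structure fill.
"""

import numpy as np
from numba import njit

MIN_LOOP = 3
_W = float(np.e)  # Boltzmann weight per base pair at unit temperature

# base encoding: A=0, C=1, G=2, U/T=3
_CAN = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in ((0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)):
    _CAN[_a, _b] = True

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGU"):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i
_ENC[ord("T")] = 3
_ENC[ord("t")] = 3


def encode(sequence: str) -> np.ndarray:
    """Encode an RNA/DNA string to uint8 codes; raises on other symbols."""
    arr = _ENC[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        bad = sequence[int(np.argmax(arr == 255))]
        raise ValueError(f"invalid base {bad!r} in sequence")
    return arr


_N_PARTNERS = np.array([1, 1, 2, 2], dtype=np.int64)
_PARTNER_CODES = np.array([[3, 0], [2, 0], [1, 3], [0, 2]], dtype=np.int64)


@njit(cache=True)
def _fill(enc, can):
    # N padded to (n+1, n+1): empty/inverted intervals read as 0, which
    # removes the interval guards from the inner loop.  The k loop visits
    # only positions holding a canonical partner of base i (CSR position
    # lists per base code).
    n = enc.shape[0]
    N = np.zeros((n + 1, n + 1), dtype=np.int32)
    counts = np.zeros(4, dtype=np.int64)
    for p in range(n):
        counts[enc[p]] += 1
    offs = np.zeros(5, dtype=np.int64)
    for c in range(4):
        offs[c + 1] = offs[c] + counts[c]
    pos = np.empty(n, dtype=np.int64)
    fill_ptr = offs[:4].copy()
    for p in range(n):
        c = enc[p]
        pos[fill_ptr[c]] = p
        fill_ptr[c] += 1
    # first partner-list index with position >= i + MIN_LOOP + 1, per (i, code)
    start = np.empty((n, 4), dtype=np.int64)
    for c in range(4):
        idx = offs[c]
        hi = offs[c + 1]
        for i in range(n):
            lo = i + MIN_LOOP + 1
            while idx < hi and pos[idx] < lo:
                idx += 1
            start[i, c] = idx
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1, j]
            bi = enc[i]
            for t in range(_N_PARTNERS[bi]):
                pc = _PARTNER_CODES[bi, t]
                hi = offs[pc + 1]
                for idx in range(start[i, pc], hi):
                    k = pos[idx]
                    if k > j:
                        break
                    v = 1 + N[i + 1, k - 1] + N[k + 1, j]
                    if v > best:
                        best = v
            N[i, j] = best
    return N


@njit(cache=True)
def _traceback(enc, can, N):
    n = enc.shape[0]
    pt = np.full(n, -1, dtype=np.int16)
    # explicit interval stack; ties prefer the pairing branch, 5'-most partner
    stack_i = np.empty(2 * n + 2, dtype=np.int64)
    stack_j = np.empty(2 * n + 2, dtype=np.int64)
    top = 0
    stack_i[0] = 0
    stack_j[0] = n - 1
    top = 1
    while top > 0:
        top -= 1
        i = stack_i[top]
        j = stack_j[top]
        while i < j:
            if j - i <= MIN_LOOP:
                break
            target = N[i, j]
            if target == 0:
                break
            paired = False
            crow = can[enc[i]]
            for k in range(i + MIN_LOOP + 1, j + 1):
                v = (1 + N[i + 1, k - 1] + N[k + 1, j]) * crow[enc[k]]
                if v == target:
                    pt[i] = k
                    pt[k] = i
                    if k + 1 <= j:
                        stack_i[top] = k + 1
                        stack_j[top] = j
                        top += 1
                    j = k - 1
                    i = i + 1
                    paired = True
                    break
            if not paired:
                i = i + 1
    return pt


@njit(cache=True)
def _inside(enc, can):
    n = enc.shape[0]
    Q = np.ones((n, n), dtype=np.float64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            acc = Q[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if can[enc[i], enc[k]]:
                    v = _W
                    if k - 1 >= i + 1:
                        v *= Q[i + 1, k - 1]
                    if k + 1 <= j:
                        v *= Q[k + 1, j]
                    acc += v
            Q[i, j] = acc
    return Q


@njit(cache=True)
def _pair_probs(enc, can, Q):
    n = enc.shape[0]
    P = np.zeros((n, n), dtype=np.float64)
    if n <= MIN_LOOP + 1:
        return P
    E = np.zeros((n, n), dtype=np.float64)
    # R[k, jj] = sum over processed pairs (k, l) with l > jj of
    #            W * E[k, l] * Q(jj+1, l-1)
    R = np.zeros((n, n), dtype=np.float64)
    Z = Q[0, n - 1]
    for span in range(n - 1, MIN_LOOP, -1):
        for i in range(n - span):
            j = i + span
            if not can[enc[i], enc[j]]:
                continue
            ql = 1.0 if i == 0 else Q[0, i - 1]
            qr = 1.0 if j == n - 1 else Q[j + 1, n - 1]
            acc = ql * qr
            for k in range(i):
                qk = 1.0 if k + 1 > i - 1 else Q[k + 1, i - 1]
                acc += qk * R[k, j]
            E[i, j] = acc
            m = _W * acc
            for jj in range(j):
                qj = 1.0 if jj + 1 > j - 1 else Q[jj + 1, j - 1]
                R[i, jj] += m * qj
            qin = 1.0 if i + 1 > j - 1 else Q[i + 1, j - 1]
            p = _W * qin * acc / Z
            P[i, j] = p
            P[j, i] = p
    return P


def fill_matrix(enc: np.ndarray) -> np.ndarray:
    return _fill(enc, _CAN)


def mfe_pair_table(enc: np.ndarray) -> np.ndarray:
    """Optimal pair table (partner index, -1 if unpaired), deterministic."""
    return _traceback(enc, _CAN, _fill(enc, _CAN))


def pair_probability_matrix(enc: np.ndarray) -> np.ndarray:
    """Symmetric matrix of ensemble pairing probabilities."""
    return _pair_probs(enc, _CAN, _inside(enc, _CAN))


def partition_function(enc: np.ndarray) -> float:
    return float(_inside(enc, _CAN)[0, -1]) if enc.size else 1.0
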