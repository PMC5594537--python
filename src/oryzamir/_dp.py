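"""Numba dynamic-programming kernels shared by the search, MSA and folding code.

Conventions:
- sequences are int8 arrays over A=0, C=1, G=2, T/U=3 (N=4 never matches);
- gap penalties are positive costs; opening a gap of length k costs
  ``gap_open + k * gap_extend``;
- the folding kernel works on the single-hairpin structure class only
  (stacks, bulges, internal loops, one terminal loop; no multiloops).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e18
POS = 1.0e18


def encode(seq: str) -> np.ndarray:
    """Encode a DNA/RNA string as int8 (A0 C1 G2 T/U3, anything else 4)."""
    table = np.full(256, 4, dtype=np.int8)
    for i, c in enumerate("ACGT"):
        table[ord(c)] = i
        table[ord(c.lower())] = i
    table[ord("U")] = 3
    table[ord("u")] = 3
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def sw_affine(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover - numba
    """Smith–Waterman local alignment with affine gaps.

    Returns (score, a_start, a_end, b_start, b_end, ops) where ops is an
    int8 array over {0: diagonal, 1: gap in b (consume a), 2: gap in a}.
    """
    n, m = len(a), len(b)
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 start, 1 M, 2 Ix, 3 Iy
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # gap states
            ox = M[i - 1, j] - gap_open - gap_extend
            ex = Ix[i - 1, j] - gap_extend
            if ox >= ex:
                Ix[i, j] = ox
                pX[i, j] = 1
            else:
                Ix[i, j] = ex
                pX[i, j] = 2
            oy = M[i, j - 1] - gap_open - gap_extend
            ey = Iy[i, j - 1] - gap_extend
            if oy >= ey:
                Iy[i, j] = oy
                pY[i, j] = 1
            else:
                Iy[i, j] = ey
                pY[i, j] = 3
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else mismatch
            vm = M[i - 1, j - 1]
            vx = Ix[i - 1, j - 1]
            vy = Iy[i - 1, j - 1]
            v = vm
            p = 1
            if vx > v:
                v = vx
                p = 2
            if vy > v:
                v = vy
                p = 3
            v = v + s
            if v < 0.0:
                v = 0.0
                p = 0
            M[i, j] = v
            pM[i, j] = p
            if v > best:
                best = v
                bi = i
                bj = j
    # traceback from (bi, bj) in state M
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = bi, bj
    state = 1
    while i > 0 and j > 0:
        if state == 1:
            p = pM[i, j]
            if p == 0 and M[i, j] == 0.0 and k > 0:
                break
            ops[k] = 0
            k += 1
            i -= 1
            j -= 1
            if p == 0:
                break
            state = p
        elif state == 2:
            p = pX[i, j]
            ops[k] = 1
            k += 1
            i -= 1
            state = p
        else:
            p = pY[i, j]
            ops[k] = 2
            k += 1
            j -= 1
            state = p
    return best, i, bi, j, bj, ops[:k][::-1].copy()


@njit(cache=True)
def profile_nw(pa, pb, sub, gap_open, gap_extend):  # pragma: no cover - numba
    """Global profile–profile alignment with affine gaps (Needleman–Wunsch).

    pa, pb: (L, 5) float count profiles over A,C,G,T,gap. sub: 5x5 score
    matrix. Returns (score, ops) with ops over {0 diag, 1 gap in pb, 2 gap in pa}.
    """
    n, m = pa.shape[0], pb.shape[0]
    na = 0.0
    for x in range(5):
        na += pa[0, x]
    nb = 0.0
    for x in range(5):
        nb += pb[0, x]
    scale = 1.0 / (na * nb)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -gap_open - gap_extend * i
        pX[i, 0] = 2 if i > 1 else 1
    for j in range(1, m + 1):
        Iy[0, j] = -gap_open - gap_extend * j
        pY[0, j] = 3 if j > 1 else 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            ox = max(M[i - 1, j], Iy[i - 1, j]) - gap_open - gap_extend
            ex = Ix[i - 1, j] - gap_extend
            if ox >= ex:
                Ix[i, j] = ox
                pX[i, j] = 1 if M[i - 1, j] >= Iy[i - 1, j] else 3
            else:
                Ix[i, j] = ex
                pX[i, j] = 2
            oy = max(M[i, j - 1], Ix[i, j - 1]) - gap_open - gap_extend
            ey = Iy[i, j - 1] - gap_extend
            if oy >= ey:
                Iy[i, j] = oy
                pY[i, j] = 1 if M[i, j - 1] >= Ix[i, j - 1] else 2
            else:
                Iy[i, j] = ey
                pY[i, j] = 3
            s = 0.0
            for x in range(5):
                ax = pa[i - 1, x]
                if ax == 0.0:
                    continue
                for y in range(5):
                    by = pb[j - 1, y]
                    if by != 0.0:
                        s += ax * by * sub[x, y]
            s *= scale
            vm = M[i - 1, j - 1]
            vx = Ix[i - 1, j - 1]
            vy = Iy[i - 1, j - 1]
            v = vm
            p = 1
            if vx > v:
                v = vx
                p = 2
            if vy > v:
                v = vy
                p = 3
            M[i, j] = v + s
            pM[i, j] = p
    # choose best final state
    vm, vx, vy = M[n, m], Ix[n, m], Iy[n, m]
    state = 1
    score = vm
    if vx > score:
        score = vx
        state = 2
    if vy > score:
        score = vy
        state = 3
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 1:
            ops[k] = 0
            k += 1
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 2:
            ops[k] = 1
            k += 1
            state = pX[i, j]
            i -= 1
        else:
            ops[k] = 2
            k += 1
            state = pY[i, j]
            j -= 1
    return score, ops[:k][::-1].copy()


@njit(cache=True)
def fold_fill(pair_type, stack, hpen, lpen, max_loop):  # pragma: no cover - numba
    """Fill the single-hairpin folding DP.

    pair_type[i, j]: 0..5 pair-type index or -1 if (i, j) cannot pair.
    stack: 6x6 nearest-neighbor stack energies; hpen[k]: terminal hairpin-loop
    penalty for k unpaired; lpen[a, b]: bulge/internal-loop penalty for a and b
    unpaired nucleotides on the two sides (a + b >= 1). Returns (E, NP) where
    E[i, j] is the best energy of a hairpin closed by pair (i, j) and NP the
    pair count of that optimum.
    """
    n = pair_type.shape[0]
    E = np.full((n, n), POS)
    NP = np.zeros((n, n), dtype=np.int32)
    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            if pair_type[i, j] < 0:
                continue
            loop = j - i - 1
            best = hpen[loop] if loop < hpen.shape[0] else hpen[hpen.shape[0] - 1]
            bnp = 1
            amax = min(max_loop, j - i - 2)
            for a in range(0, amax + 1):
                k = i + 1 + a
                bmax = min(max_loop, j - k - 2)
                for b in range(0, bmax + 1):
                    l = j - 1 - b
                    if l - k < 4:
                        continue
                    if pair_type[k, l] < 0 or E[k, l] >= POS:
                        continue
                    if a == 0 and b == 0:
                        cost = stack[pair_type[i, j], pair_type[k, l]]
                    else:
                        cost = lpen[a, b]
                    v = cost + E[k, l]
                    if v < best - 1e-9 or (v < best + 1e-9 and NP[k, l] + 1 > bnp):
                        best = v
                        bnp = NP[k, l] + 1
            E[i, j] = best
            NP[i, j] = bnp
    return E, NP
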