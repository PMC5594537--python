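"""Independent global-alignment oracle used by the cluster identity tests.

Plain-Python affine-gap Needleman-Wunsch with the same scoring as the
cluster module's aligner (match +2, mismatch -1, gap open -5 on the first
gap residue, -1 per extension), with a diagonal-first traceback.
"""

NEG = float("-inf")
MATCH, MISMATCH, OPEN, EXTEND = 2.0, -1.0, -5.0, -1.0


def nw_identity_oracle(a: str, b: str) -> float:
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = OPEN + EXTEND * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = OPEN + EXTEND * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + OPEN, X[i - 1][j] + EXTEND, Y[i - 1][j] + OPEN)
            Y[i][j] = max(M[i][j - 1] + OPEN, X[i][j - 1] + OPEN, Y[i][j - 1] + EXTEND)
    # diagonal-first traceback
    i, j = n, m
    state = max((M[i][j], "M"), (X[i][j], "X"), (Y[i][j], "Y"))[1]
    matches = cols = 0
    while i > 0 or j > 0:
        cols += 1
        if state == "M":
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            matches += a[i - 1] == b[j - 1]
            prev = M[i][j] - s
            if prev == M[i - 1][j - 1]:
                state = "M"
            elif prev == X[i - 1][j - 1]:
                state = "X"
            else:
                state = "Y"
            i -= 1
            j -= 1
        elif state == "X":
            v = X[i][j]
            if v == M[i - 1][j] + OPEN:
                state = "M"
            elif v == X[i - 1][j] + EXTEND:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:
            v = Y[i][j]
            if v == M[i][j - 1] + OPEN:
                state = "M"
            elif v == X[i][j - 1] + OPEN:
                state = "X"
            else:
                state = "Y"
            j -= 1
    return matches / cols * 100.0
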