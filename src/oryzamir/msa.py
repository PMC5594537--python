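"""Progressive multiple sequence alignment for short precursor ortholog sets.

Pipeline: all-pairs global alignment (affine-gap Needleman-Wunsch) ->
Jukes-Cantor distances -> neighbor-joining guide order -> profile-profile
progressive alignment. Deterministic given the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dp import encode, profile_nw
from .phylo import DistanceMatrix, nj_joins


@dataclass
class AlignParams:
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = 4.0
    gap_extend: float = 1.0

    def submat(self) -> np.ndarray:
        """5x5 profile scoring matrix over A,C,G,T,gap (gap column scores 0)."""
        m = np.full((5, 5), self.mismatch)
        np.fill_diagonal(m, self.match)
        m[4, :] = 0.0
        m[:, 4] = 0.0
        return m


@dataclass
class MSA:
    """Equal-length gapped rows plus optional region annotations
    (alignment-coordinate intervals, e.g. mature/star/loop)."""

    ids: list[str]
    rows: list[str]
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def map_interval(self, row_idx: int, interval: tuple[int, int]) -> tuple[int, int]:
        """Map an ungapped-sequence interval of one row to alignment columns."""
        s, e = interval
        cols = [c for c, ch in enumerate(self.rows[row_idx]) if ch != "-"]
        if e > len(cols) or s >= e:
            raise ValueError("interval outside ungapped row")
        return cols[s], cols[e - 1] + 1

    def column(self, c: int) -> str:
        return "".join(r[c] for r in self.rows)

    def subset(self, indices: list[int]) -> "MSA":
        return MSA(
            ids=[self.ids[i] for i in indices], rows=[self.rows[i] for i in indices],
            regions=dict(self.regions),
        )


def _profile(rows: list[str]) -> np.ndarray:
    codes = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    prof = np.zeros((len(rows[0]), 5))
    for row in rows:
        for i, ch in enumerate(row):
            prof[i, codes.get(ch, 4)] += 1.0
    return prof


def pairwise_global(a: str, b: str, params: AlignParams | None = None) -> tuple[float, str, str]:
    """Affine-gap global alignment of two sequences; returns (score, row_a, row_b)."""
    params = params or AlignParams()
    ra, rb = _merge([a.upper().replace("U", "T")], [b.upper().replace("U", "T")], params)
    score, _ = profile_nw(
        _profile([a.upper().replace("U", "T")]),
        _profile([b.upper().replace("U", "T")]),
        params.submat(),
        params.gap_open,
        params.gap_extend,
    )
    return score, ra[0], rb[0]


def _merge(rows_a: list[str], rows_b: list[str], params: AlignParams) -> tuple[list[str], list[str]]:
    sub = params.submat()
    _, ops = profile_nw(_profile(rows_a), _profile(rows_b), sub, params.gap_open, params.gap_extend)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for op in ops:
        if op == 0:
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i])
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j])
            i += 1
            j += 1
        elif op == 1:
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i])
            for k in range(len(rows_b)):
                out_b[k].append("-")
            i += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append("-")
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j])
            j += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _pdistance(row_a: str, row_b: str) -> float:
    pairs = [(x, y) for x, y in zip(row_a, row_b) if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def align_progressive(
    seqs: list[tuple[str, str]], params: AlignParams | None = None
) -> MSA:
    """Progressive MSA of (id, sequence) pairs.

    Guide order comes from neighbor joining on Jukes-Cantor pairwise
    distances (p-distances where the JC correction is undefined).
    """
    params = params or AlignParams()
    for sid, s in seqs:
        if len(s) == 0:
            raise ValueError(f"{sid}: empty sequence")
    norm = [(sid, s.upper().replace("U", "T")) for sid, s in seqs]
    if len(norm) == 1:
        return MSA(ids=[norm[0][0]], rows=[norm[0][1]])
    if len(norm) == 2:
        ra, rb = _merge([norm[0][1]], [norm[1][1]], params)
        return MSA(ids=[norm[0][0], norm[1][0]], rows=[ra[0], rb[0]])

    n = len(norm)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, ra, rb = pairwise_global(norm[i][1], norm[j][1], params)
            p = _pdistance(ra, rb)
            d = p if p >= 0.75 else -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = d
    joins = nj_joins(DistanceMatrix(taxa=[sid for sid, _ in norm], matrix=D))

    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([sid], [s]) for i, (sid, s) in enumerate(norm)
    }
    next_internal = n
    for ia, ib, new, _, _ in joins[:-2]:
        ids_a, rows_a = clusters.pop(ia)
        ids_b, rows_b = clusters.pop(ib)
        ra, rb = _merge(rows_a, rows_b, params)
        clusters[new] = (ids_a + ids_b, ra + rb)
        next_internal = new + 1
    # final three-way join: merge remaining clusters pairwise, largest first
    remaining = sorted(clusters, key=lambda k: (-len(clusters[k][0]), k))
    ids_a, rows_a = clusters[remaining[0]]
    for k in remaining[1:]:
        ids_b, rows_b = clusters[k]
        rows_a, rb = _merge(rows_a, rows_b, params)
        ids_a = ids_a + ids_b
        rows_a = rows_a + rb
    # restore input order
    order = {sid: i for i, (sid, _) in enumerate(norm)}
    packed = sorted(zip(ids_a, rows_a), key=lambda t: order[t[0]])
    return MSA(ids=[sid for sid, _ in packed], rows=[r for _, r in packed])
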