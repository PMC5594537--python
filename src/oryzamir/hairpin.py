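"""Single-hairpin RNA secondary structure prediction and structure metrics.

Pre-miRNA candidates are expected to fold back on themselves into one
stem-loop, so the structure class is restricted to a single hairpin: a chain
of nested base pairs (Watson-Crick + GU) separated by stacks, bulges and
internal loops, closed by one terminal loop of >= 3 nt. This keeps the
dynamic program quadratic and the energy model auditable.

The energy model is a minimal nearest-neighbor table: Turner-style stacking
energies for the 16 WC/GU stacks plus log-extrapolated loop penalties.
Absolute minimum-free-energy values therefore differ from full-featured
folders such as RNAfold (no dangles, no coaxial stacking, no sequence-
dependent loop terms); the acceptance threshold on MFE is a configurable
filter parameter, and an external-backend adapter is provided for users who
want RNAfold-exact energies.
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np

from ._dp import POS, encode, fold_fill

#: pair-type index order used throughout: AU, CG, GC, UA, GU, UG
PAIR_STRINGS = ("AU", "CG", "GC", "UA", "GU", "UG")

# nearest-neighbor stacking energies, kcal/mol at 37C; rows = outer pair
# (5' side), cols = inner pair. WC + wobble only.
STACK_ENERGY = np.array(
    [
        # AU     CG     GC     UA     GU     UG
        [-0.9, -2.2, -2.1, -1.1, -0.6, -1.4],  # AU
        [-2.1, -3.3, -2.4, -2.1, -1.4, -2.1],  # CG
        [-2.4, -3.4, -3.3, -2.2, -1.5, -2.5],  # GC
        [-1.3, -2.4, -2.1, -0.9, -1.0, -1.3],  # UA
        [-1.3, -2.5, -2.1, -1.4, -0.5, +1.3],  # GU
        [-1.0, -1.5, -1.4, -0.6, +0.3, -0.5],  # UG
    ]
)

_HAIRPIN_TAB = [math.inf, math.inf, math.inf, 5.4, 5.6, 5.7, 5.4, 6.0, 5.5, 6.4]
_BULGE_TAB = [0.0, 3.8, 2.8, 3.2, 3.6, 4.0, 4.4]
_RT_EXTRAP = 1.08  # 1.75 * RT at 37C, for Jacobson-Stockmayer log extrapolation


def _hairpin_penalties(max_len: int) -> np.ndarray:
    pen = np.empty(max_len + 1)
    for n in range(max_len + 1):
        if n < len(_HAIRPIN_TAB):
            pen[n] = _HAIRPIN_TAB[n]
        else:
            pen[n] = _HAIRPIN_TAB[-1] + _RT_EXTRAP * math.log(n / (len(_HAIRPIN_TAB) - 1))
    return pen


def _loop_penalties(max_loop: int) -> np.ndarray:
    """lpen[a, b] for a, b unpaired nt on the two stem sides (bulge/internal)."""

    def bulge(n: int) -> float:
        if n < len(_BULGE_TAB):
            return _BULGE_TAB[n]
        return _BULGE_TAB[-1] + _RT_EXTRAP * math.log(n / (len(_BULGE_TAB) - 1))

    def internal(n: int) -> float:
        tab = {2: 1.7, 3: 1.8, 4: 2.0, 5: 2.2, 6: 2.5}
        if n in tab:
            return tab[n]
        return tab[6] + _RT_EXTRAP * math.log(n / 6)

    pen = np.full((max_loop + 1, max_loop + 1), POS)
    for a in range(max_loop + 1):
        for b in range(max_loop + 1):
            if a == 0 and b == 0:
                continue
            if a == 0 or b == 0:
                pen[a, b] = bulge(a + b)
            else:
                pen[a, b] = internal(a + b) + min(0.6 * abs(a - b), 3.0)
    return pen


@dataclass
class EnergyModel:
    """Tunable hairpin energy tables (kcal/mol)."""

    stack: np.ndarray = field(default_factory=lambda: STACK_ENERGY.copy())
    max_loop: int = 15  # max unpaired nt per stem side in one bulge/internal loop
    max_hairpin_tab: int = 1024

    def tables(self) -> tuple[np.ndarray, np.ndarray]:
        return _hairpin_penalties(self.max_hairpin_tab), _loop_penalties(self.max_loop)


DEFAULT_MODEL = EnergyModel()


def pair_type_matrix(codes: np.ndarray) -> np.ndarray:
    """(i, j) -> pair-type index 0..5 or -1 if the bases cannot pair."""
    lut = np.full((5, 5), -1, dtype=np.int8)
    idx = {"A": 0, "C": 1, "G": 2, "U": 3}
    for t, (x, y) in enumerate(PAIR_STRINGS):
        lut[idx[x], idx[y]] = t
    n = len(codes)
    pt = np.full((n, n), -1, dtype=np.int8)
    safe = np.minimum(codes, 4)
    for i in range(n):
        ci = safe[i]
        if ci >= 4:
            continue
        row = lut[ci, np.minimum(safe, 4)]
        pt[i, :] = row
    # never pair a base with itself or closer than the minimum loop
    tri = np.tril_indices(n)
    pt[tri] = -1
    return pt


@dataclass
class HairpinStructure:
    """A folded candidate precursor.

    pairing[i] is the partner index of position i, or -1 if unpaired. The
    pairing is a single nested chain; ``arm5``/``arm3`` span the outermost to
    innermost paired positions on each strand and ``loop`` is the terminal
    loop interval (0-based half-open).
    """

    sequence: str
    pairing: list[int]
    mfe: float

    @property
    def n_pairs(self) -> int:
        return sum(1 for p in self.pairing if p >= 0) // 2

    @property
    def pair_chain(self) -> list[tuple[int, int]]:
        """Nested pairs (i, j) with i < j, outermost first."""
        chain = [(i, p) for i, p in enumerate(self.pairing) if p > i]
        chain.sort()
        return chain

    @property
    def arm5(self) -> tuple[int, int]:
        ch = self.pair_chain
        if not ch:
            return (0, 0)
        return (ch[0][0], ch[-1][0] + 1)

    @property
    def arm3(self) -> tuple[int, int]:
        ch = self.pair_chain
        if not ch:
            return (0, 0)
        return (ch[-1][1], ch[0][1] + 1)

    @property
    def loop(self) -> tuple[int, int]:
        ch = self.pair_chain
        if not ch:
            return (0, len(self.sequence))
        return (ch[-1][0] + 1, ch[-1][1])

    @property
    def dot_bracket(self) -> str:
        out = []
        for i, p in enumerate(self.pairing):
            out.append("." if p < 0 else ("(" if p > i else ")"))
        return "".join(out)

    @property
    def is_hairpin(self) -> bool:
        """True iff the structure has at least one pair (a stem exists)."""
        return self.n_pairs >= 1


class FoldError(ValueError):
    pass


def fold_hairpin(seq: str, model: EnergyModel | None = None, min_len: int = 10) -> HairpinStructure:
    """Minimum-free-energy single-hairpin structure of ``seq``.

    DNA input is read as RNA (T -> U). Ties are broken deterministically:
    prefer more pairs, then the first optimum in scan order (outermost pair
    with the smallest coordinates, inner loops enumerated smallest-first).
    The open chain (no pairs) has energy 0; the reported MFE is <= 0.
    """
    model = model or DEFAULT_MODEL
    if len(seq) < min_len:
        raise FoldError(f"sequence too short to fold ({len(seq)} < {min_len} nt)")
    codes = encode(seq)
    if np.all(codes >= 4):
        raise FoldError("sequence contains no foldable (non-N) bases")
    pt = pair_type_matrix(codes)
    hpen, lpen = model.tables()
    E, NP = fold_fill(pt, model.stack, hpen, lpen, model.max_loop)

    n = len(seq)
    best = 0.0
    bnp = 0
    bij = None
    for i in range(n):
        for j in range(i + 4, n):
            if E[i, j] >= POS:
                continue
            v = E[i, j]
            if v < best - 1e-9 or (v < best + 1e-9 and NP[i, j] > bnp):
                best = v
                bnp = NP[i, j]
                bij = (i, j)
    pairing = [-1] * n
    if bij is not None:
        i, j = bij
        while True:
            pairing[i], pairing[j] = j, i
            loop = j - i - 1
            hp = hpen[loop] if loop < len(hpen) else hpen[-1]
            if abs(E[i, j] - hp) < 1e-9 and NP[i, j] == 1:
                break
            found = False
            amax = min(model.max_loop, j - i - 2)
            for a in range(amax + 1):
                k = i + 1 + a
                bmax = min(model.max_loop, j - k - 2)
                for b in range(bmax + 1):
                    l = j - 1 - b
                    if l - k < 4 or pt[k, l] < 0 or E[k, l] >= POS:
                        continue
                    cost = model.stack[pt[i, j], pt[k, l]] if (a == 0 and b == 0) else lpen[a, b]
                    if abs(cost + E[k, l] - E[i, j]) < 1e-9 and NP[k, l] + 1 == NP[i, j]:
                        i, j = k, l
                        found = True
                        break
                if found:
                    break
            if not found:  # numerical corner: stop at current pair
                break
    return HairpinStructure(sequence=seq, pairing=pairing, mfe=min(0.0, best))


def max_bulge(structure: HairpinStructure) -> int:
    """Largest number of unpaired nt on a single side of any bulge or internal
    loop within the stem (terminal loop excluded)."""
    chain = structure.pair_chain
    worst = 0
    for (i1, j1), (i2, j2) in zip(chain, chain[1:]):
        worst = max(worst, i2 - i1 - 1, j1 - j2 - 1)
    return worst


class MatureInLoopError(ValueError):
    """The mature interval spans the terminal loop: no miRNA/miRNA* duplex."""


def duplex_mismatches(
    structure: HairpinStructure, mature_interval: tuple[int, int]
) -> tuple[int, tuple[int, int]]:
    """Count mature positions not paired in the folded structure and infer the
    star interval by the canonical 2-nt 3'-overhang duplex rule.

    Returns (mismatch_count, star_interval). Raises MatureInLoopError when the
    mature interval overlaps the terminal loop (the candidate is not a valid
    hairpin precursor for this mature).
    """
    ms, me = mature_interval
    n = len(structure.sequence)
    if not (0 <= ms < me <= n):
        raise ValueError("mature interval outside sequence")
    if structure.n_pairs == 0:
        raise MatureInLoopError("structure has no stem")
    ls, le = structure.loop
    a5s, a5e = structure.arm5
    a3s, a3e = structure.arm3
    on5 = min(me, a5e) - max(ms, a5s) > 0
    on3 = min(me, a3e) - max(ms, a3s) > 0
    if on5 and on3:
        raise MatureInLoopError("mature interval spans the terminal loop")
    if not on5 and not on3:
        raise MatureInLoopError("mature interval lies outside the stem")
    # positions falling in the terminal loop (or otherwise unpaired) count as
    # duplex mismatches; a mature may shade a base or two into the loop
    mism = sum(1 for i in range(ms, me) if structure.pairing[i] < 0)
    partners = [structure.pairing[i] for i in range(ms, me) if structure.pairing[i] >= 0]
    if not partners:
        raise MatureInLoopError("mature interval entirely unpaired")
    q_lo, q_hi = min(partners), max(partners)
    on_5prime_arm = q_lo > me - 1
    if on_5prime_arm:
        # star lies downstream; shift +2 gives the star its 2-nt 3' overhang
        star = (min(q_lo + 2, n), min(q_hi + 3, n))
    else:
        star = (max(q_lo - 2, 0), max(q_hi - 1, 0))
    return mism, star


def parse_dot_bracket(db: str) -> list[int]:
    """Pairing table from a dot-bracket string (nested brackets only)."""
    pairing = [-1] * len(db)
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairing[i], pairing[j] = j, i
        elif c != ".":
            raise ValueError(f"unsupported dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced '(' in dot-bracket")
    return pairing


def structure_from_dot_bracket(seq: str, db: str, energy: float) -> HairpinStructure:
    """Adapter for external folding backends emitting dot-bracket + energy.

    The downstream metrics (max_bulge, duplex_mismatches) apply unchanged as
    long as the structure is a single nested chain; branched (multiloop)
    structures are accepted here but walk only the outermost chain.
    """
    return HairpinStructure(sequence=seq, pairing=parse_dot_bracket(db), mfe=energy)


def fold_with_rnafold(seq: str) -> HairpinStructure:
    """Optional plug-in backend calling an installed ``RNAfold`` executable."""
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold not found on PATH")
    out = subprocess.run(
        [exe, "--noPS"], input=seq + "\n", capture_output=True, text=True, check=True
    ).stdout.splitlines()
    db_line = out[1]
    db = db_line.split()[0]
    energy = float(db_line[db_line.rindex("(") + 1 : db_line.rindex(")")])
    return structure_from_dot_bracket(seq, db, energy)
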