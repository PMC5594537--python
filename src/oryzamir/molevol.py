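"""Substitution-rate, transition/transversion, conservation and composition
analyses on precursor ortholog alignments.

Gap handling follows common practice for these statistics: pairwise deletion
for distances (each pair of rows compared at their mutually ungapped sites),
complete-case columns for substitution patterns and conservation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .msa import MSA

BASES = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class RateConfig:
    """Divergence-time scaling for absolute substitution rates.

    ``divergence_time_years`` is the time separating the two most distant
    lineages of the panel (15 million years for the Oryza radiation); with a
    mean of N substitutions/site between lineages, the per-year rate is
    R = N / (2 T).
    """

    divergence_time_years: float = 1.5e7

    def __post_init__(self) -> None:
        if self.divergence_time_years <= 0:
            raise ValueError("divergence time must be positive")


def jc_distance(row_a: str, row_b: str) -> tuple[float, float]:
    """Jukes-Cantor distance between two (gapped) rows.

    Returns (p, N): observed proportion of differing sites over pairwise
    complete sites, and N = -(3/4) ln(1 - 4p/3) expected substitutions/site.
    N is NaN when p >= 0.75 (JC singularity; excluded from averages).
    """
    pairs = [
        (x, y)
        for x, y in zip(row_a.upper(), row_b.upper())
        if x in BASES and y in BASES
    ]
    if not pairs:
        raise ValueError("no pairwise-complete sites")
    p = sum(1 for x, y in pairs if x != y) / len(pairs)
    if p >= 0.75:
        return p, math.nan
    return p, -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def mean_pairwise_jc(msa: MSA, region: tuple[int, int] | None = None) -> float:
    """Mean JC substitutions/site over all row pairs (NaN pairs dropped with
    a warning-equivalent exclusion)."""
    lo, hi = region if region is not None else (0, msa.n_cols)
    vals = []
    for i, j in combinations(range(len(msa.rows)), 2):
        _, n = jc_distance(msa.rows[i][lo:hi], msa.rows[j][lo:hi])
        if not math.isnan(n):
            vals.append(n)
    if not vals:
        return math.nan
    return float(np.mean(vals))


def substitution_rate(mean_n: float, rate_config: RateConfig | None = None) -> float:
    """Absolute substitution rate R = N / (2 T) in substitutions/site/year."""
    if mean_n < 0:
        raise ValueError("mean substitutions/site must be >= 0")
    cfg = rate_config or RateConfig()
    return mean_n / (2.0 * cfg.divergence_time_years)


@dataclass
class SubstitutionSummary:
    p: float
    N: float
    R: float
    ti_count: float
    tv_count: float
    titv_ratio: float
    ti_fraction: float
    pattern: np.ndarray  # 4x4 from->to percentages, off-diagonal sums to 100


def titv_summary(msa: MSA, region: tuple[int, int] | None = None):
    """Transition/transversion counts, ratio and directional pattern.

    Counts are over all row pairs at mutually complete column pairs. The
    ratio is the raw count ratio ti/tv, whose no-bias expectation is 0.5
    (one transition vs two transversion types per site); the transition
    fraction ti/(ti+tv) is reported alongside. The 4x4 pattern assigns
    direction by column consensus (majority state; ties split equally) over
    complete-case columns and is expressed as percentages of all observed
    substitutions.
    """
    lo, hi = region if region is not None else (0, msa.n_cols)
    ti = tv = 0
    for i, j in combinations(range(len(msa.rows)), 2):
        for x, y in zip(msa.rows[i][lo:hi], msa.rows[j][lo:hi]):
            if x in BASES and y in BASES and x != y:
                if (x, y) in _TRANSITIONS:
                    ti += 1
                else:
                    tv += 1
    ratio = ti / tv if tv else math.nan
    frac = ti / (ti + tv) if (ti + tv) else math.nan

    idx = {b: k for k, b in enumerate(BASES)}
    pattern = np.zeros((4, 4))
    for c in range(lo, hi):
        col = msa.column(c)
        if any(ch not in BASES for ch in col):
            continue
        counts = {b: col.count(b) for b in BASES if col.count(b)}
        if len(counts) < 2:
            continue
        top = max(counts.values())
        modes = [b for b, k in counts.items() if k == top]
        w = 1.0 / len(modes)
        for consensus in modes:
            for b, k in counts.items():
                if b != consensus:
                    pattern[idx[consensus], idx[b]] += w * k
    total = pattern.sum()
    if total > 0:
        pattern = pattern / total * 100.0
    return ti, tv, ratio, frac, pattern


def regional_conservation(
    msa: MSA, region: tuple[int, int], parts: int = 3
) -> list[float]:
    """Proportion of fully conserved columns in `parts` contiguous blocks of
    the region (remainder distributed left-first; a 21-nt region -> 7/7/7).

    A column is conserved iff all taxa share one non-gap base.
    """
    lo, hi = region
    length = hi - lo
    if length < parts:
        raise ValueError(f"region of {length} columns cannot be split into {parts} parts")
    base = length // parts
    rem = length % parts
    sizes = [base + (1 if k < rem else 0) for k in range(parts)]
    out = []
    pos = lo
    for size in sizes:
        conserved = 0
        for c in range(pos, pos + size):
            col = msa.column(c)
            if all(ch in BASES for ch in col) and len(set(col)) == 1:
                conserved += 1
        out.append(conserved / size)
        pos += size
    return out


def base_composition(seq: str) -> tuple[float, float]:
    """(AT, GC) fractions of a sequence or region; N and gaps excluded from
    the denominator. Returns (nan, nan) when nothing is countable."""
    s = seq.upper().replace("U", "T")
    at = sum(1 for c in s if c in "AT")
    gc = sum(1 for c in s if c in "GC")
    tot = at + gc
    if tot == 0:
        return math.nan, math.nan
    return at / tot, gc / tot


def substitution_summary(
    msa: MSA,
    rate_config: RateConfig | None = None,
    region: tuple[int, int] | None = None,
) -> SubstitutionSummary:
    """Bundle the per-alignment substitution analyses for one region."""
    lo, hi = region if region is not None else (0, msa.n_cols)
    ps = []
    for i, j in combinations(range(len(msa.rows)), 2):
        p, _ = jc_distance(msa.rows[i][lo:hi], msa.rows[j][lo:hi])
        ps.append(p)
    mean_n = mean_pairwise_jc(msa, region)
    ti, tv, ratio, frac, pattern = titv_summary(msa, region)
    return SubstitutionSummary(
        p=float(np.mean(ps)),
        N=mean_n,
        R=substitution_rate(mean_n, rate_config) if not math.isnan(mean_n) else math.nan,
        ti_count=ti,
        tv_count=tv,
        titv_ratio=ratio,
        ti_fraction=frac,
        pattern=pattern,
    )
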