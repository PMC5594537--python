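"""Per-locus diversity and neutrality statistics with coalescent nulls.

Tajima's D contrasts mean pairwise differences with the segregating-site
estimate of theta; Fu & Li's F (outgroup) and F* (singleton) statistics
contrast pairwise diversity with external-branch / singleton mutations.
All statistics use complete deletion (columns containing a gap or N are
dropped), the convention of the standard desktop tools for these tests.
Significance is assessed against a fixed-S neutral coalescent null
(constant population size, no recombination): genealogies are simulated
with msprime and the observed number of mutations is dropped uniformly on
total branch length.

The species panel analysed here is a cross-species sample rather than a
within-population one; the statistics are computed exactly as in standard
practice for such panels, and the interpretation caveat is documented in
the methods note.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import msprime
import numpy as np

from .msa import MSA

BASES = "ACGT"

#: default split of the panel for the domestication diversity-loss summary
CULTIVATED_DEFAULT = ("O_sativa_indica", "O_glaberrima")


@dataclass
class NeutralityConstants:
    """Sample-size constants of the Tajima and Fu & Li statistics."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    c_n: float
    u_F: float
    v_F: float
    u_Fstar: float
    v_Fstar: float

    @classmethod
    def for_n(cls, n: int) -> "NeutralityConstants":
        if n < 3:
            raise ValueError("neutrality statistics need n >= 3 sequences")
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        c_n = 2.0 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
        an1 = a1 + 1.0 / n  # a_{n+1}
        v_F = (c_n + 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)) / (
            a1**2 + a2
        )
        u_F = (
            1.0
            + (n + 1) / (3.0 * (n - 1))
            - 4.0 * (n + 1) / (n - 1) ** 2 * (an1 - 2.0 * n / (n + 1))
        ) / a1 - v_F
        v_Fs = (
            (2.0 * n**3 + 110.0 * n**2 - 255.0 * n + 153.0) / (9.0 * n**2 * (n - 1))
            + 2.0 * (n - 1) * a1 / n**2
            - 8.0 * a2 / n
        ) / (a1**2 + a2)
        u_Fs = ((4.0 * n**2 + 19.0 * n + 3.0 - 12.0 * (n + 1) * an1) / (3.0 * n * (n - 1))) / a1 - v_Fs
        return cls(
            n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2,
            c_n=c_n, u_F=u_F, v_F=v_F, u_Fstar=u_Fs, v_Fstar=v_Fs,
        )


def complete_columns(msa: MSA) -> list[str]:
    """Columns with no gap/N in any row (complete deletion)."""
    cols = []
    for c in range(msa.n_cols):
        col = msa.column(c)
        if all(ch in BASES for ch in col.upper()):
            cols.append(col.upper())
    return cols


def segregating_sites(msa: MSA) -> tuple[int, int, int]:
    """(S, eta, singletons) over complete columns.

    S counts polymorphic columns; eta counts mutations (k alleles -> k-1);
    singletons are mutations carried by exactly one sequence (a column with
    two alleles both of count 1 contributes one singleton).
    """
    cols = complete_columns(msa)
    if not cols:
        raise ValueError("no complete columns")
    S = eta = singles = 0
    for col in cols:
        counts = {b: col.count(b) for b in set(col)}
        k = len(counts)
        if k < 2:
            continue
        S += 1
        eta += k - 1
        ones = sum(1 for v in counts.values() if v == 1)
        singles += min(ones, k - 1)
    return S, eta, singles


def pairwise_differences(msa: MSA) -> tuple[float, int]:
    """(mean pairwise differences over complete columns, number of complete
    columns)."""
    cols = complete_columns(msa)
    if not cols:
        raise ValueError("no complete columns")
    n = len(msa.rows)
    total = 0
    for col in cols:
        for i, j in combinations(range(n), 2):
            if col[i] != col[j]:
                total += 1
    npairs = n * (n - 1) // 2
    return total / npairs, len(cols)


def nucleotide_diversity(msa: MSA) -> float:
    """pi per site: mean over sequence pairs of differences / complete columns."""
    pi_total, ncols = pairwise_differences(msa)
    return pi_total / ncols


def watterson_theta(msa: MSA) -> float:
    """Watterson's estimator per site: S / (a1 * L complete columns)."""
    S, _, _ = segregating_sites(msa)
    _, ncols = pairwise_differences(msa)
    k = NeutralityConstants.for_n(len(msa.rows))
    return S / (k.a1 * ncols)


def tajimas_d(msa: MSA) -> float:
    """Tajima's D; NaN when S = 0 (undefined, excluded from distributions)."""
    S, _, _ = segregating_sites(msa)
    if S == 0:
        return math.nan
    k = NeutralityConstants.for_n(len(msa.rows))
    pi_total, _ = pairwise_differences(msa)
    var = k.e1 * S + k.e2 * S * (S - 1)
    if var <= 0:  # degenerate (e.g. n = 3, S = 1): D undefined
        return math.nan
    return (pi_total - S / k.a1) / math.sqrt(var)


def _fu_li_f_from_counts(n: int, eta: int, pi_total: float, eta_e: int) -> float:
    k = NeutralityConstants.for_n(n)
    var = k.u_F * eta + k.v_F * eta**2
    if var <= 0:
        return math.nan
    return (pi_total - eta_e) / math.sqrt(var)


def _fu_li_fstar_from_counts(n: int, eta: int, pi_total: float, eta_s: int) -> float:
    k = NeutralityConstants.for_n(n)
    var = k.u_Fstar * eta + k.v_Fstar * eta**2
    if var <= 0:
        return math.nan
    return (pi_total - (n - 1) / n * eta_s) / math.sqrt(var)


def fu_li_f(msa: MSA, outgroup_id: str | None = None) -> tuple[float, str]:
    """Fu & Li's F (with an outgroup row polarizing external mutations) or
    F* (singleton variant) when no outgroup is supplied.

    Returns (statistic, variant_flag) with variant in {"F_with_outgroup",
    "F_star"}; NaN when S = 0.
    """
    if outgroup_id is None:
        S, eta, eta_s = segregating_sites(msa)
        if S == 0:
            return math.nan, "F_star"
        pi_total, _ = pairwise_differences(msa)
        return _fu_li_fstar_from_counts(len(msa.rows), eta, pi_total, eta_s), "F_star"

    if outgroup_id not in msa.ids:
        raise ValueError(f"outgroup {outgroup_id!r} not in alignment")
    out_idx = msa.ids.index(outgroup_id)
    in_rows = [r for i, r in enumerate(msa.rows) if i != out_idx]
    out_row = msa.rows[out_idx]
    n = len(in_rows)
    # complete over ingroup + outgroup so every column is polarizable
    eta = eta_e = 0
    diffs_total = 0
    ncols = 0
    for c in range(msa.n_cols):
        col = "".join(r[c] for r in in_rows).upper()
        anc = out_row[c].upper()
        if anc not in BASES or any(ch not in BASES for ch in col):
            continue
        ncols += 1
        counts = {b: col.count(b) for b in set(col)}
        eta += max(len(counts | {anc: 0}) - 1, len(counts) - 1)
        for b, cnt in counts.items():
            if b != anc and cnt == 1:
                eta_e += 1
        for i, j in combinations(range(n), 2):
            if col[i] != col[j]:
                diffs_total += 1
    if ncols == 0:
        raise ValueError("no complete columns")
    if eta == 0:
        return math.nan, "F_with_outgroup"
    npairs = n * (n - 1) // 2
    pi_total = diffs_total / npairs
    return _fu_li_f_from_counts(n, eta, pi_total, eta_e), "F_with_outgroup"


@dataclass
class NeutralityResult:
    locus_id: str
    n: int
    sites: int
    S: int
    eta: int
    singletons: int
    pi: float  # per site
    theta_w: float  # per site
    tajima_d: float
    fu_li_f: float
    variant_flag: str
    p_tajima: float = math.nan
    p_fu_li: float = math.nan
    significant: bool = False


@dataclass
class CoalescentNull:
    """Empirical fixed-S null distributions for D and F*/F at sample size n."""

    n: int
    S: int
    d_values: np.ndarray
    f_values: np.ndarray
    variant: str

    def p_value(self, observed: float, stat: str = "d") -> float:
        """Two-sided empirical p: 2 * min(P(null <= obs), P(null >= obs))."""
        null = self.d_values if stat == "d" else self.f_values
        if math.isnan(observed):
            return math.nan
        lo = float(np.mean(null <= observed))
        hi = float(np.mean(null >= observed))
        return min(1.0, 2.0 * min(lo, hi))


def coalescent_null(
    n: int,
    S_obs: int,
    reps: int = 10000,
    seed: int = 1,
    variant: str = "F_star",
) -> CoalescentNull:
    """Neutral constant-size no-recombination coalescent null conditioned on S.

    Genealogies are simulated with msprime; S_obs mutations are dropped on
    branches with probability proportional to branch length; D and F*/F are
    computed per replicate from the resulting allele counts.
    """
    if n < 3:
        raise ValueError("n >= 3 required")
    if S_obs < 1:
        raise ValueError("S_obs >= 1 required")
    if reps < 100:
        warnings.warn("fewer than 100 replicates: p-value resolution is poor")
    rng = np.random.default_rng(seed)
    ms_seed = int(rng.integers(1, 2**31 - 1))
    reps_iter = msprime.sim_ancestry(
        samples=n, ploidy=1, population_size=1.0, num_replicates=reps,
        random_seed=ms_seed,
    )
    npairs = n * (n - 1) / 2.0
    d_out = np.empty(reps)
    f_out = np.empty(reps)
    for k, ts in enumerate(reps_iter):
        tree = ts.first()
        lengths = []
        below = []
        for u in tree.nodes():
            if tree.parent(u) != -1:
                lengths.append(tree.branch_length(u))
                below.append(tree.num_samples(u))
        lengths = np.asarray(lengths)
        below = np.asarray(below)
        counts = rng.multinomial(S_obs, lengths / lengths.sum())
        pi_total = float(np.sum(counts * below * (n - below)) / npairs)
        d_out[k] = _tajima_from_counts(n, S_obs, pi_total)
        if variant == "F_star":
            eta_s = int(np.sum(counts[(below == 1) | (below == n - 1)]))
            f_out[k] = _fu_li_fstar_from_counts(n, S_obs, pi_total, eta_s)
        else:
            eta_e = int(np.sum(counts[below == 1]))
            f_out[k] = _fu_li_f_from_counts(n, S_obs, pi_total, eta_e)
    return CoalescentNull(n=n, S=S_obs, d_values=d_out, f_values=f_out, variant=variant)


def _tajima_from_counts(n: int, S: int, pi_total: float) -> float:
    k = NeutralityConstants.for_n(n)
    var = k.e1 * S + k.e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi_total - S / k.a1) / math.sqrt(var)


def analyze_locus(
    msa: MSA,
    locus_id: str,
    outgroup_id: str | None = None,
    reps: int = 2000,
    seed: int = 1,
    alpha: float = 0.05,
) -> NeutralityResult:
    """Full per-locus neutrality analysis with simulated p-values."""
    S, eta, singles = segregating_sites(msa)
    pi_total, ncols = pairwise_differences(msa)
    n = len(msa.rows) - (1 if outgroup_id else 0)
    if S == 0:
        return NeutralityResult(
            locus_id=locus_id, n=n, sites=ncols, S=0, eta=0, singletons=0,
            pi=0.0, theta_w=0.0, tajima_d=math.nan, fu_li_f=math.nan,
            variant_flag="F_star" if outgroup_id is None else "F_with_outgroup",
        )
    d = tajimas_d(msa if outgroup_id is None else msa.subset(
        [i for i, t in enumerate(msa.ids) if t != outgroup_id]))
    f, variant = fu_li_f(msa, outgroup_id)
    null = coalescent_null(n, S, reps=reps, seed=seed, variant=variant)
    p_d = null.p_value(d, "d")
    p_f = null.p_value(f, "f")
    res = NeutralityResult(
        locus_id=locus_id, n=n, sites=ncols, S=S, eta=eta, singletons=singles,
        pi=pi_total / ncols, theta_w=watterson_theta(msa), tajima_d=d, fu_li_f=f,
        variant_flag=variant, p_tajima=p_d, p_fu_li=p_f,
        significant=bool(p_d < alpha and p_f < alpha),
    )
    return res


def diversity_loss(
    msas: dict[str, MSA],
    cultivated_ids: tuple[str, ...] = CULTIVATED_DEFAULT,
    wild_ids: tuple[str, ...] | None = None,
    locus_subset: list[str] | None = None,
) -> tuple[float, float]:
    """Diversity retained in the cultivated group relative to the wild group.

    retained = mean over loci of pi(cultivated) / mean over loci of pi(wild);
    loss = 1 - retained. ``wild_ids`` defaults to all non-cultivated taxa.
    """
    loci = locus_subset if locus_subset is not None else sorted(msas)
    pis_c, pis_w = [], []
    for locus in loci:
        msa = msas[locus]
        cid = [i for i, t in enumerate(msa.ids) if t in cultivated_ids]
        wid = (
            [i for i, t in enumerate(msa.ids) if t in wild_ids]
            if wild_ids is not None
            else [i for i, t in enumerate(msa.ids) if t not in cultivated_ids]
        )
        if len(cid) < 2 or len(wid) < 2:
            raise ValueError(f"{locus}: both groups need >= 2 members")
        pis_c.append(nucleotide_diversity(msa.subset(cid)))
        pis_w.append(nucleotide_diversity(msa.subset(wid)))
    mean_w = float(np.mean(pis_w))
    if mean_w == 0:
        raise ValueError("wild-group diversity is zero: retained fraction undefined")
    retained = float(np.mean(pis_c)) / mean_w
    return retained, 1.0 - retained
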