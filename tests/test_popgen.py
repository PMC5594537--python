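import math
from itertools import combinations

import msprime
import numpy as np
import pytest
from scipy.stats import kstest

from oryzamir.msa import MSA
from oryzamir.popgen import (
    NeutralityConstants,
    analyze_locus,
    coalescent_null,
    diversity_loss,
    fu_li_f,
    nucleotide_diversity,
    segregating_sites,
    tajimas_d,
    watterson_theta,
)

# ---------------------------------------------------------------------------
# independent straight-from-formula oracles (explicit loops, no shared code)
# ---------------------------------------------------------------------------


def _complete_cols(rows):
    return [
        "".join(r[c] for r in rows)
        for c in range(len(rows[0]))
        if all(r[c] in "ACGT" for r in rows)
    ]


def oracle_pi_total(rows):
    cols = _complete_cols(rows)
    n = len(rows)
    total = sum(
        1 for col in cols for i, j in combinations(range(n), 2) if col[i] != col[j]
    )
    return total / (n * (n - 1) / 2)


def oracle_tajima_d(rows):
    cols = _complete_cols(rows)
    n = len(rows)
    S = sum(1 for col in cols if len(set(col)) > 1)
    if S == 0:
        return math.nan
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (oracle_pi_total(rows) - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def oracle_fu_li_fstar(rows):
    cols = _complete_cols(rows)
    n = len(rows)
    eta = eta_s = 0
    for col in cols:
        counts = {b: col.count(b) for b in set(col)}
        if len(counts) < 2:
            continue
        eta += len(counts) - 1
        eta_s += min(sum(1 for v in counts.values() if v == 1), len(counts) - 1)
    if eta == 0:
        return math.nan
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    an1 = a1 + 1 / n
    vF = (
        (2 * n**3 + 110 * n**2 - 255 * n + 153) / (9 * n**2 * (n - 1))
        + 2 * (n - 1) * a1 / n**2
        - 8 * a2 / n
    ) / (a1**2 + a2)
    uF = ((4 * n**2 + 19 * n + 3 - 12 * (n + 1) * an1) / (3 * n * (n - 1))) / a1 - vF
    pi = oracle_pi_total(rows)
    return (pi - (n - 1) / n * eta_s) / math.sqrt(uF * eta + vF * eta**2)


def oracle_fu_li_f_outgroup(in_rows, out_row):
    n = len(in_rows)
    eta = eta_e = 0
    diffs = 0
    for c in range(len(out_row)):
        col = "".join(r[c] for r in in_rows)
        anc = out_row[c]
        if anc not in "ACGT" or any(ch not in "ACGT" for ch in col):
            continue
        alleles = set(col)
        eta += len(alleles | {anc}) - 1
        for b in alleles:
            if b != anc and col.count(b) == 1:
                eta_e += 1
        for i, j in combinations(range(n), 2):
            if col[i] != col[j]:
                diffs += 1
    if eta == 0:
        return math.nan
    pi = diffs / (n * (n - 1) / 2)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    an1 = a1 + 1 / n
    c_n = 2 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    vF = (c_n + 2 * (n**2 + n + 3) / (9 * n * (n - 1)) - 2 / (n - 1)) / (a1**2 + a2)
    uF = (
        1 + (n + 1) / (3 * (n - 1)) - 4 * (n + 1) / (n - 1) ** 2 * (an1 - 2 * n / (n + 1))
    ) / a1 - vF
    return (pi - eta_e) / math.sqrt(uF * eta + vF * eta**2)


def random_msa(rng, n=None, L=None):
    n = n or int(rng.integers(4, 12))
    L = L or int(rng.integers(30, 80))
    base = rng.choice(list("ACGT"), size=L)
    rows = []
    for _ in range(n):
        row = base.copy()
        for _ in range(int(rng.integers(1, 10))):
            row[int(rng.integers(L))] = "ACGT"[int(rng.integers(4))]
        rows.append("".join(row))
    return MSA(ids=[f"t{i}" for i in range(n)], rows=rows)


class TestSegregatingSites:
    def test_identical_rows(self):
        msa = MSA(ids=list("abcd"), rows=["ACGT"] * 4)
        assert segregating_sites(msa) == (0, 0, 0)

    def test_single_singleton_column(self):
        msa = MSA(ids=list("abcd"), rows=["A", "A", "A", "G"])
        assert segregating_sites(msa) == (1, 1, 1)

    def test_three_allele_column(self):
        msa = MSA(ids=list("abcd"), rows=["A", "A", "C", "G"])
        S, eta, singles = segregating_sites(msa)
        assert (S, eta, singles) == (1, 2, 2)

    def test_matches_exhaustive_column_scan(self, rng):
        for _ in range(100):
            msa = random_msa(rng)
            S, eta, _ = segregating_sites(msa)
            cols = _complete_cols(msa.rows)
            assert S == sum(1 for c in cols if len(set(c)) > 1)
            assert eta == sum(len(set(c)) - 1 for c in cols)

    def test_gap_columns_excluded(self):
        msa = MSA(ids=list("ab"), rows=["A-G", "AAG"])
        assert segregating_sites(msa)[0] == 0


class TestDiversity:
    def test_two_rows_one_difference_in_100(self):
        rows = ["A" * 100, "C" + "A" * 99]
        assert nucleotide_diversity(MSA(ids=list("ab"), rows=rows)) == pytest.approx(0.01)

    def test_identical_rows_zero(self):
        assert nucleotide_diversity(MSA(ids=list("ab"), rows=["ACGT"] * 2)) == 0.0

    def test_equals_brute_force_all_pairs(self, rng):
        for _ in range(50):
            msa = random_msa(rng)
            cols = _complete_cols(msa.rows)
            expected = oracle_pi_total(msa.rows) / len(cols)
            assert nucleotide_diversity(msa) == pytest.approx(expected, abs=1e-12)


class TestOracleAgreement:
    """Dual-implementation check: statistics match independently coded
    textbook formulas to 1e-12 on random small alignments."""

    def test_d_f_fstar_pi_theta(self, rng):
        checked = 0
        for _ in range(50):
            msa = random_msa(rng)
            S, _, _ = segregating_sites(msa)
            if S == 0:
                continue
            checked += 1
            assert tajimas_d(msa) == pytest.approx(oracle_tajima_d(msa.rows), abs=1e-12)
            f_star, flag = fu_li_f(msa)
            assert flag == "F_star"
            assert f_star == pytest.approx(oracle_fu_li_fstar(msa.rows), abs=1e-12)
            n = len(msa.rows)
            cols = _complete_cols(msa.rows)
            a1 = sum(1 / i for i in range(1, n))
            assert watterson_theta(msa) == pytest.approx(S / (a1 * len(cols)), abs=1e-12)
        assert checked >= 40

    def test_f_with_outgroup(self, rng):
        checked = 0
        for _ in range(30):
            msa = random_msa(rng, n=8)
            S, _, _ = segregating_sites(msa)
            if S == 0:
                continue
            checked += 1
            f, flag = fu_li_f(msa, outgroup_id="t7")
            assert flag == "F_with_outgroup"
            expected = oracle_fu_li_f_outgroup(msa.rows[:7], msa.rows[7])
            assert f == pytest.approx(expected, abs=1e-12)
        assert checked >= 20

    def test_row_and_column_order_invariance(self, rng):
        msa = random_msa(rng, n=8, L=60)
        d0 = tajimas_d(msa)
        f0, _ = fu_li_f(msa)
        perm = list(rng.permutation(8))
        shuffled = msa.subset(perm)
        cols = list(rng.permutation(msa.n_cols))
        shuffled = MSA(
            ids=shuffled.ids,
            rows=["".join(r[c] for c in cols) for r in shuffled.rows],
        )
        assert tajimas_d(shuffled) == pytest.approx(d0, abs=1e-12)
        assert fu_li_f(shuffled)[0] == pytest.approx(f0, abs=1e-12)


def test_tajimas_d_matches_tskit_on_simulated_data():
    """Independent-library cross-check on coalescent-simulated sequences."""
    ts = msprime.sim_ancestry(samples=8, ploidy=1, sequence_length=500,
                              population_size=1e4, random_seed=42)
    ts = msprime.sim_mutations(ts, rate=2e-7, random_seed=43, discrete_genome=False)
    rows = ["".join("AG"[int(v)] for v in hap) for hap in
            ts.genotype_matrix().T]
    L = ts.num_sites
    msa = MSA(ids=[f"s{i}" for i in range(8)], rows=rows)
    assert len(rows[0]) == L
    assert tajimas_d(msa) == pytest.approx(float(ts.Tajimas_D()), abs=1e-9)
    pi_total = nucleotide_diversity(msa) * L
    assert pi_total == pytest.approx(
        float(ts.diversity(span_normalise=False)), abs=1e-9
    )


class TestUndefinedCases:
    def test_s_zero_is_nan(self):
        msa = MSA(ids=list("abc"), rows=["ACGT"] * 3)
        assert math.isnan(tajimas_d(msa))
        f, _ = fu_li_f(msa)
        assert math.isnan(f)

    def test_no_complete_columns_rejected(self):
        msa = MSA(ids=list("ab"), rows=["A-", "-A"])
        with pytest.raises(ValueError):
            segregating_sites(msa)


class TestCoalescentNull:
    def test_observed_at_null_median_gives_p_near_one(self):
        null = coalescent_null(10, 20, reps=2000, seed=5)
        med = float(np.median(null.d_values))
        assert null.p_value(med, "d") > 0.9

    def test_extreme_observation_gives_small_p(self):
        null = coalescent_null(10, 20, reps=2000, seed=5)
        assert null.p_value(-5.0, "d") < 0.01
        assert null.p_value(-5.0, "f") < 0.01

    def test_few_reps_warns(self):
        with pytest.warns(UserWarning, match="resolution"):
            coalescent_null(5, 3, reps=50, seed=1)

    def test_reproducible_given_seed(self):
        a = coalescent_null(6, 10, reps=500, seed=9)
        b = coalescent_null(6, 10, reps=500, seed=9)
        assert np.array_equal(a.d_values, b.d_values)


class TestDiversityLoss:
    def _msa(self, rows):
        return MSA(ids=[f"t{i}" for i in range(len(rows))], rows=rows)

    def test_identical_groups_retain_everything(self):
        rows = ["AAGT", "ACGT", "AAGT", "ACGT"]
        msas = {"L1": MSA(ids=["c1", "c2", "w1", "w2"], rows=rows)}
        retained, loss = diversity_loss(msas, cultivated_ids=("c1", "c2"),
                                        wild_ids=("w1", "w2"))
        assert retained == pytest.approx(1.0)
        assert loss == pytest.approx(0.0)

    def test_monomorphic_cultivated_loses_everything(self):
        rows = ["ACGT", "ACGT", "AAGT", "ACTT"]
        msas = {"L1": MSA(ids=["c1", "c2", "w1", "w2"], rows=rows)}
        retained, loss = diversity_loss(msas, cultivated_ids=("c1", "c2"),
                                        wild_ids=("w1", "w2"))
        assert (retained, loss) == (0.0, 1.0)

    def test_configured_retention_recovered_in_simulation(self, rng):
        # plant loci whose cultivated-group diversity is a known fraction of
        # the wild-group diversity and recover that fraction
        msas = {}
        for k in range(40):
            L = 200
            base = rng.choice(list("ACGT"), size=L)
            def variants(n_mut, n_rows):
                rows = []
                for _ in range(n_rows):
                    r = base.copy()
                    for _ in range(n_mut):
                        r[int(rng.integers(L))] = "ACGT"[int(rng.integers(4))]
                    rows.append("".join(r))
                return rows
            rows = variants(1, 3) + variants(8, 3)
            msas[f"L{k}"] = MSA(
                ids=["c1", "c2", "c3", "w1", "w2", "w3"], rows=rows
            )
        retained, _ = diversity_loss(
            msas, cultivated_ids=("c1", "c2", "c3"), wild_ids=("w1", "w2", "w3")
        )
        # expected pairwise diffs scale with mutations per row: ~2 vs ~16
        assert retained == pytest.approx(2 / 16, rel=0.35)

    def test_degenerate_groups_rejected(self):
        msas = {"L1": MSA(ids=["c1", "w1", "w2"], rows=["ACGT"] * 3)}
        with pytest.raises(ValueError, match=">= 2 members"):
            diversity_loss(msas, cultivated_ids=("c1",), wild_ids=("w1", "w2"))


def test_analyze_locus_end_to_end(rng):
    msa = random_msa(rng, n=10, L=60)
    res = analyze_locus(msa, "locusX", reps=500, seed=3)
    assert res.locus_id == "locusX"
    assert res.S >= 0 and res.pi >= 0
    if res.S > 0:
        assert 0 <= res.p_tajima <= 1 and 0 <= res.p_fu_li <= 1
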