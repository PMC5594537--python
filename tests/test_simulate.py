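import numpy as np
import pytest
from scipy.stats import chi2_contingency

from oryzamir.molevol import jc_distance, regional_conservation
from oryzamir.msa import MSA
from oryzamir.simulate import (
    DEFAULT_SPECIES_TREE,
    SimulationConfig,
    build_ancestor,
    evolve_precursor_family,
    simulate,
)

STAR10 = "(" + ",".join(f"t{i}:15.0" for i in range(10)) + ");"


class TestEvolve:
    def test_zero_mature_rate_keeps_mature_identical(self, rng):
        cfg = SimulationConfig(
            species_tree=STAR10, query_species="t0",
            r_mature=0.0, r_star=1e-9, r_loop=5e-9, seed=1,
        )
        anc = build_ancestor(rng, cfg)
        leaves = evolve_precursor_family(anc, STAR10, cfg, rng)
        mats = {p.seq[p.mature[0]: p.mature[1]] for p in leaves.values()}
        assert mats == {anc.seq[anc.mature[0]: anc.mature[1]]}

    def test_infinite_kappa_yields_only_transitions(self, rng):
        cfg = SimulationConfig(
            species_tree="(t0:0.0,t1:50.0);", query_species="t0",
            r_mature=2e-9, r_star=2e-9, r_loop=2e-9, kappa=float("inf"),
            indel_rate=0.0, seed=1,
        )
        anc = build_ancestor(rng, cfg)
        leaves = evolve_precursor_family(anc, cfg.species_tree, cfg, rng)
        ti = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        changes = [
            (x, y) for x, y in zip(leaves["t0"].seq, leaves["t1"].seq) if x != y
        ]
        assert changes and all(c in ti for c in changes)

    def test_zero_length_branch_leaf_equals_parent(self, rng):
        cfg = SimulationConfig(species_tree="(t0:0.0,t1:1.0);", query_species="t0", seed=1)
        anc = build_ancestor(rng, cfg)
        leaves = evolve_precursor_family(anc, cfg.species_tree, cfg, rng)
        assert leaves["t0"].seq == anc.seq

    def test_indels_confined_to_loop(self, rng):
        cfg = SimulationConfig(
            species_tree=STAR10, query_species="t0",
            indel_rate=5e-9, seed=2,
        )
        anc = build_ancestor(rng, cfg)
        leaves = evolve_precursor_family(anc, STAR10, cfg, rng)
        for p in leaves.values():
            assert p.mature == anc.mature  # coordinates exact by construction
            assert p.star[1] - p.star[0] == anc.star[1] - anc.star[0]

    def test_rate_recovery_within_15_percent(self, rng):
        """Parameter recovery: families evolved at the panel divergence depth
        re-estimate the mature rate via JC + R = N/2T."""
        from oryzamir.molevol import RateConfig, substitution_rate
        from itertools import combinations

        cfg = SimulationConfig(species_tree=STAR10, query_species="t0", seed=3)
        ns = []
        for _ in range(200):
            anc = build_ancestor(rng, cfg)
            leaves = evolve_precursor_family(anc, STAR10, cfg, rng)
            mats = [p.seq[p.mature[0]: p.mature[1]] for p in leaves.values()]
            for a, b in combinations(mats, 2):
                n = jc_distance(a, b)[1]
                if not np.isnan(n):
                    ns.append(n)
        r_hat = substitution_rate(float(np.mean(ns)), RateConfig(1.5e7))
        assert abs(r_hat - cfg.r_mature) / cfg.r_mature < 0.15


class TestPlantGenome:
    def test_reproducible_given_seed(self):
        cfg = SimulationConfig(n_families=3, seed=7)
        g1, f1, t1, o1, truth1 = simulate(cfg)
        g2, f2, t2, o2, truth2 = simulate(cfg)
        assert [r.sequence for sp in sorted(g1) for r in g1[sp]] == [
            r.sequence for sp in sorted(g2) for r in g2[sp]
        ]
        assert [(l.chrom, l.start, l.strand) for l in truth1.loci] == [
            (l.chrom, l.start, l.strand) for l in truth2.loci
        ]

    def test_every_planted_locus_lies_within_its_genome(self, small_cohort):
        genomes = small_cohort["genomes"]
        for l in small_cohort["truth"].loci:
            rec = next(r for r in genomes[l.species] if r.chrom_id == l.chrom)
            assert 0 <= l.start < l.end <= len(rec.sequence)
            # the oriented genome slice equals the planted precursor
            seq = rec.sequence[l.start:l.end]
            if l.strand == "-":
                from oryzamir.formats import revcomp
                seq = revcomp(seq)
            prec = small_cohort["ortholog_sets"][l.family][l.species]
            if l.cluster_member != 1 and l.family != "famCL":
                assert seq == prec.seq

    def test_zero_te_probability_means_no_te_calls(self):
        from oryzamir.homology import scan_te_overlap

        cfg = SimulationConfig(n_families=4, te_insert_prob=0.0, seed=5)
        genomes, _, te_lib, osets, truth = simulate(cfg)
        assert truth.te_families == {}
        # decoy-only library: no planted locus should match a TE
        sp = cfg.query_species
        for l in truth.species_loci(sp)[:6]:
            rec = next(r for r in genomes[sp] if r.chrom_id == l.chrom)
            calls = scan_te_overlap(rec.sequence[l.start:l.end], te_lib)
            assert calls == []

    def test_te_families_carry_exact_fragment(self, small_cohort):
        truth = small_cohort["truth"]
        te_lib = small_cohort["te_library"]
        osets = small_cohort["ortholog_sets"]
        cfg = small_cohort["cfg"]
        for fam, label in truth.te_families.items():
            anc_seq = osets[fam][cfg.query_species].seq
            entries = [r for r in te_lib if r.chrom_id.startswith(label)]
            assert any(
                any(e.sequence[i:i + 50] in anc_seq for i in range(len(e.sequence) - 50))
                for e in entries
            )

    def test_cluster_truth_has_expected_spacers(self, small_cohort):
        truth = small_cohort["truth"]
        cfg = small_cohort["cfg"]
        n_two = sum(1 for n, _, _ in cfg.cluster_spec if n == 2)
        for sp in sorted(small_cohort["genomes"]):
            clusters = truth.clusters(sp)
            assert len(clusters) == len(cfg.cluster_spec)
            two = [m for m in clusters.values() if len(m) == 2]
            assert len(two) == n_two
            for members in two:
                spacer = members[1].start - members[0].end
                assert abs(spacer - 100) <= 10

    def test_intragenic_fraction_generates_gene_features(self, small_cohort):
        feats = small_cohort["features"]
        assert any(f.feature_kind == "gene" for sp in feats for f in feats[sp])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="conservation ordering"):
            SimulationConfig(r_mature=1e-8, r_star=1e-9, r_loop=1e-9)
        with pytest.raises(ValueError, match="in \\[0, 1\\]"):
            SimulationConfig(duplication_prob=1.5)


def test_equal_rates_make_regions_indistinguishable(rng):
    """Under r_mature = r_star = r_loop the conserved-site proportions of the
    three regions are statistically indistinguishable (chi-square over
    replicate families)."""
    cfg = SimulationConfig(
        species_tree=STAR10, query_species="t0",
        r_mature=2e-9, r_star=2e-9, r_loop=2e-9, indel_rate=0.0, seed=6,
    )
    table = np.zeros((3, 2))  # region x (conserved, variable)
    for _ in range(100):
        anc = build_ancestor(rng, cfg)
        leaves = evolve_precursor_family(anc, STAR10, cfg, rng)
        aln = MSA(ids=sorted(leaves), rows=[leaves[t].seq for t in sorted(leaves)])
        regions = {0: anc.mature, 1: anc.star, 2: anc.loop}
        for k, region in regions.items():
            props = regional_conservation(aln, region, parts=1)
            length = region[1] - region[0]
            conserved = round(props[0] * length)
            table[k, 0] += conserved
            table[k, 1] += length - conserved
    _, p, _, _ = chi2_contingency(table)
    assert p > 0.01
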