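"""Synthetic ortholog sets and genomes with planted miRNA loci.

The generator emulates the statistical structure the comparative analyses
assume: precursor families diverge along a 10-taxon species tree with
region-specific substitution rates (mature <= star <= loop), a K80-style
transition bias, loop-confined indels, lineage duplications that copy a
locus to another chromosome, TE-derived families sharing a >= 50-nt exact
fragment with a TE library entry, and tandem two-member clusters bridged by
a ~100-nt spacer with a 22-nt deletion immediately downstream of the mature
in the second member. A truth table records every planted locus for recall
and parameter-recovery testing.

Branch lengths are in million years; a branch of length t at per-year rate
r contributes an expected r * 1e6 * t substitutions per site (per-site
Poisson event counts, jump-chain K80 moves).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .formats import FeatureRecord, GenomeRecord, revcomp

#: Oryza-like ultrametric default species tree, branch lengths in MY.
#: The FF genome (O. brachyantha) splits 15 MYA, the BB genome
#: (O. punctata) 9.11 MYA, the AA crown radiates within ~2.93 MY.
DEFAULT_SPECIES_TREE = (
    "((((((((O_sativa_indica:0.75,O_nivara:0.75):0.45,O_rufipogon:1.2):0.6,"
    "(O_barthii:0.6,O_glaberrima:0.6):1.2):0.4,O_glumaepatula:2.2):0.3,"
    "O_meridionalis:2.5):0.43,O_longistaminata:2.93):6.18,O_punctata:9.11):5.89,"
    "O_brachyantha:15.0);"
)

TE_FAMILY_LABELS = ("STOWAWAY", "GYPSY", "COPIA", "MUDR")

_BASES = "ACGT"
_TI = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


def _default_cluster_spec() -> list[tuple[int, int, int]]:
    # nine clusters: five 2-membered (~100-nt spacer, 22-nt deletion in the
    # second member), four 1-membered — the miR1861-style organization
    return [
        (1, 0, 0), (2, 100, 22), (2, 100, 22), (2, 100, 22), (1, 0, 0),
        (1, 0, 0), (2, 100, 22), (2, 100, 22), (1, 0, 0),
    ]


@dataclass
class SimulationConfig:
    species_tree: str = DEFAULT_SPECIES_TREE
    n_families: int = 50
    mature_len: int = 21
    loop_len: int = 15
    flank_len: int = 20
    cluster_loop_len: int = 30  # cluster-family loop, long enough to absorb the deletion
    r_mature: float = 3.2e-10  # substitutions/site/year
    r_star: float = 8.0e-10
    r_loop: float = 2.0e-9
    kappa: float = 2.0  # transition/transversion rate ratio
    seed_rate_factor: float = 1.0  # multiplier on r_mature at mature positions 2-7
    indel_rate: float = 1.0e-10  # loop-only, events/site/year
    mean_indel_len: float = 3.0
    duplication_prob: float = 0.3  # per lineage per locus
    te_insert_prob: float = 0.29  # per family
    cluster_spec: list[tuple[int, int, int]] = field(default_factory=_default_cluster_spec)
    background_gc: float = 0.44
    genome_len: int = 90000
    n_chromosomes: int = 3
    fraction_intragenic: float = 0.3
    query_species: str = "O_sativa_indica"
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("r_mature", "r_star", "r_loop", "indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("duplication_prob", "te_insert_prob", "background_gc", "fraction_intragenic"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.r_mature <= self.r_star <= self.r_loop:
            raise ValueError("expected conservation ordering r_mature <= r_star <= r_loop")


@dataclass
class AnnotatedPrecursor:
    """A precursor sequence with mature/star intervals (0-based half-open)."""

    seq: str
    mature: tuple[int, int]
    star: tuple[int, int]

    @property
    def loop(self) -> tuple[int, int]:
        return (self.mature[1], self.star[0])


@dataclass
class PlantedLocus:
    species: str
    family: str
    gene: str
    paralogue_index: int
    chrom: str
    start: int
    end: int
    strand: str
    origin: str  # ancestral | duplication | te
    mature: tuple[int, int]  # relative to the oriented (5'->3') locus sequence
    divergence_from_query: float = math.nan
    cluster_id: str | None = None
    cluster_member: int | None = None

    @property
    def locus_id(self) -> str:
        return f"{self.species}:{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass
class SimulationTruth:
    loci: list[PlantedLocus]
    te_families: dict[str, str]  # family -> TE label
    rates: dict[str, float]
    seed: int

    def species_loci(self, species: str) -> list[PlantedLocus]:
        return [l for l in self.loci if l.species == species]

    def clusters(self, species: str) -> dict[str, list[PlantedLocus]]:
        out: dict[str, list[PlantedLocus]] = {}
        for l in self.species_loci(species):
            if l.cluster_id:
                out.setdefault(l.cluster_id, []).append(l)
        for members in out.values():
            members.sort(key=lambda l: l.start)
        return out


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[i] for i in rng.choice(4, size=length, p=p))


def _loop_seq(rng: np.random.Generator, length: int) -> str:
    # AU-rich loops, as in real plant pre-miRNA terminal loops
    return random_seq(rng, length, gc=0.35)


def build_ancestor(
    rng: np.random.Generator, cfg: SimulationConfig, loop_len: int | None = None
) -> AnnotatedPrecursor:
    """An ancestral precursor: flank + mature + loop + revcomp(mature) +
    revcomp(flank), rejection-sampled so the planted hairpin genuinely passes
    the precursor filters with margin (a real pre-miRNA does by definition:
    stable stem, no large bulge, mature on the arm and well-paired)."""
    from . import hairpin as hp

    loop_len = loop_len if loop_len is not None else cfg.loop_len
    ms = cfg.flank_len
    me = ms + cfg.mature_len
    for _ in range(200):
        mature = random_seq(rng, cfg.mature_len, gc=0.55)
        loop = _loop_seq(rng, loop_len)
        flank = random_seq(rng, cfg.flank_len, gc=0.55)
        seq = flank + mature + loop + revcomp(mature) + revcomp(flank)
        structure = hp.fold_hairpin(seq)
        if structure.mfe > -20 or hp.max_bulge(structure) > 8:
            continue
        try:
            mism, _ = hp.duplex_mismatches(structure, (ms, me))
        except hp.MatureInLoopError:
            continue
        if mism > 2:
            continue
        ss = me + loop_len
        return AnnotatedPrecursor(seq=seq, mature=(ms, me), star=(ss, ss + cfg.mature_len))
    raise RuntimeError("could not sample a filter-passing ancestral precursor")


def _site_rates(prec: AnnotatedPrecursor, cfg: SimulationConfig) -> np.ndarray:
    rates = np.full(len(prec.seq), cfg.r_loop)
    ms, me = prec.mature
    ss, se = prec.star
    rates[ms:me] = cfg.r_mature
    # seed-like block: 2nd-7th nt of the mature
    rates[ms + 1 : min(ms + 7, me)] *= cfg.seed_rate_factor
    rates[ss:se] = cfg.r_star
    return rates


def _mutate_branch(
    prec: AnnotatedPrecursor, t_my: float, cfg: SimulationConfig, rng: np.random.Generator
) -> AnnotatedPrecursor:
    """Evolve a precursor along one branch of t_my million years."""
    if t_my <= 0:
        return replace(prec)
    seq = np.array([_BASES.index(c) for c in prec.seq])
    rates = _site_rates(prec, cfg)
    mu = rates * 1e6 * t_my
    nev = rng.poisson(mu)
    p_ti = cfg.kappa / (cfg.kappa + 2.0) if math.isfinite(cfg.kappa) else 1.0
    for i in np.nonzero(nev)[0]:
        base = seq[i]
        for _ in range(nev[i]):
            if rng.random() < p_ti:
                base = _TI[base]
            else:
                # one of the two transversions
                choices = [b for b in range(4) if b != base and _TI[base] != b]
                base = choices[rng.integers(2)]
        seq[i] = base
    out = "".join(_BASES[b] for b in seq)
    ms, me = prec.mature
    ss, se = prec.star

    # loop-confined indels
    loop_start, loop_end = me, ss
    loop_len = loop_end - loop_start
    n_indel = rng.poisson(cfg.indel_rate * 1e6 * t_my * max(loop_len, 0))
    for _ in range(n_indel):
        loop_len = loop_end - loop_start
        length = int(1 + rng.geometric(1.0 / cfg.mean_indel_len) - 1)
        length = max(1, length)
        if rng.random() < 0.5 and loop_len - length >= 4:  # deletion, keep a foldable loop
            pos = loop_start + int(rng.integers(0, loop_len - length + 1))
            out = out[:pos] + out[pos + length :]
            loop_end -= length
            ss -= length
            se -= length
        else:  # insertion
            pos = loop_start + int(rng.integers(0, loop_len + 1))
            out = out[:pos] + _loop_seq(rng, length) + out[pos:]
            loop_end += length
            ss += length
            se += length
    return AnnotatedPrecursor(seq=out, mature=(ms, me), star=(ss, se))


def evolve_precursor_family(
    ancestor: AnnotatedPrecursor,
    tree: str | dendropy.Tree,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, AnnotatedPrecursor]:
    """Evolve an annotated ancestor along the species tree.

    Returns taxon -> leaf precursor with updated mature/star coordinates.
    Substitutions follow a per-site Poisson K80 jump chain with the rate of
    the site's region; indels occur only in the terminal loop, so mature and
    star intervals stay exact by construction.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("species tree needs >= 2 leaves")
    states: dict[int, AnnotatedPrecursor] = {id(tree.seed_node): ancestor}
    out: dict[str, AnnotatedPrecursor] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        child = _mutate_branch(parent_state, t, cfg, rng)
        states[id(node)] = child
        if node.is_leaf():
            out[node.taxon.label] = child
    return out


def _passes_precursor_filters(prec: AnnotatedPrecursor) -> bool:
    """Whether a precursor passes the structural acceptance filters (stable
    hairpin, bulge <= 12, mature on one arm with <= 6 unpaired positions)."""
    from . import hairpin as hp

    try:
        s = hp.fold_hairpin(prec.seq)
    except hp.FoldError:
        return False
    if s.mfe > -15.0 or hp.max_bulge(s) > 12:
        return False
    try:
        mism, _ = hp.duplex_mismatches(s, prec.mature)
    except hp.MatureInLoopError:
        return False
    return mism <= 6


class PlacementError(RuntimeError):
    pass


def _place(
    occupied: dict[str, list[tuple[int, int]]],
    chrom_lens: dict[str, int],
    length: int,
    rng: np.random.Generator,
    chrom: str | None = None,
    exclude_chrom: str | None = None,
    retries: int = 200,
    margin: int = 50,
) -> tuple[str, int]:
    chroms = [c for c in chrom_lens if c != exclude_chrom] if chrom is None else [chrom]
    for _ in range(retries):
        c = chroms[rng.integers(len(chroms))]
        limit = chrom_lens[c] - length
        if limit <= 0:
            continue
        s = int(rng.integers(0, limit))
        if all(not (s < e0 + margin and s0 < s + length + margin) for s0, e0 in occupied[c]):
            occupied[c].append((s, s + length))
            return c, s
    raise PlacementError(f"could not place a {length}-nt locus after {retries} retries")


def simulate(
    cfg: SimulationConfig,
) -> tuple[
    dict[str, list[GenomeRecord]],
    dict[str, list[FeatureRecord]],
    list[GenomeRecord],
    dict[str, dict[str, AnnotatedPrecursor]],
    SimulationTruth,
]:
    """Run the full generator.

    Returns (genomes, features, te_library, ortholog_sets, truth) where
    ortholog_sets maps family -> taxon -> annotated precursor. Deterministic
    for a given config (all randomness from cfg.seed).
    """
    rng = np.random.default_rng(cfg.seed)
    tree = dendropy.Tree.get(data=cfg.species_tree, schema="newick", preserve_underscores=True)
    taxa = [leaf.taxon.label for leaf in tree.leaf_nodes()]
    if cfg.query_species not in taxa:
        raise ValueError(f"query species {cfg.query_species} not a tree leaf")

    families = [f"fam{k:03d}" for k in range(cfg.n_families)]
    cluster_family = "famCL" if cfg.cluster_spec else None

    # TE library: entries are built to share an exact >= 50-nt fragment with
    # the ancestors of TE-derived families (the detectable signature of TE
    # origin); extra decoy entries carry no planted fragment.
    te_families: dict[str, str] = {}
    ancestors: dict[str, AnnotatedPrecursor] = {}
    te_library: list[GenomeRecord] = []
    te_counter = 0
    for fam in families:
        anc = build_ancestor(rng, cfg)
        ancestors[fam] = anc
        if rng.random() < cfg.te_insert_prob:
            label = TE_FAMILY_LABELS[te_counter % len(TE_FAMILY_LABELS)]
            te_counter += 1
            te_families[fam] = label
            frag_len = 70
            start = int(rng.integers(0, len(anc.seq) - frag_len + 1))
            entry = (
                random_seq(rng, 120, gc=cfg.background_gc)
                + anc.seq[start : start + frag_len]
                + random_seq(rng, 120, gc=cfg.background_gc)
            )
            te_library.append(GenomeRecord(f"{label}_{te_counter}", entry))
    for k in range(3):  # decoys
        label = TE_FAMILY_LABELS[k % len(TE_FAMILY_LABELS)]
        te_library.append(
            GenomeRecord(f"{label}_d{k}", random_seq(rng, 300, gc=cfg.background_gc))
        )

    ortholog_sets: dict[str, dict[str, AnnotatedPrecursor]] = {}
    for fam in families:
        ortholog_sets[fam] = evolve_precursor_family(ancestors[fam], tree, cfg, rng)
    if cluster_family:
        # the cluster family evolves without loop indels so the planted
        # 22-nt deletion signature stays exact in every lineage, and the
        # whole ortholog set (including the shortened second members) is
        # conditioned on staying a valid precursor family in every species —
        # as the real tandem family, which is detected across the panel, is
        cfg_cl = replace(cfg, indel_rate=0.0)
        del_lens = {d for (n, _, d) in cfg.cluster_spec if n == 2 and d > 0}
        for _ in range(50):
            anc_cl = build_ancestor(rng, cfg, loop_len=cfg.cluster_loop_len)
            leaves = evolve_precursor_family(anc_cl, tree, cfg_cl, rng)
            ok = True
            for prec in leaves.values():
                variants = [prec] + [
                    AnnotatedPrecursor(
                        seq=prec.seq[: prec.mature[1]] + prec.seq[prec.mature[1] + d :],
                        mature=prec.mature,
                        star=(prec.star[0] - d, prec.star[1] - d),
                    )
                    for d in sorted(del_lens)
                ]
                if not all(_passes_precursor_filters(v) for v in variants):
                    ok = False
                    break
            if ok:
                break
        else:
            raise RuntimeError("could not sample a panel-wide valid cluster family")
        ancestors[cluster_family] = anc_cl
        ortholog_sets[cluster_family] = leaves

    # genomes
    chrom_len = cfg.genome_len // cfg.n_chromosomes
    genomes: dict[str, list[GenomeRecord]] = {}
    features: dict[str, list[FeatureRecord]] = {}
    loci: list[PlantedLocus] = []
    for sp in taxa:
        chroms = {f"{sp}_chr{i + 1}": chrom_len for i in range(cfg.n_chromosomes)}
        seqs = {c: list(random_seq(rng, n, gc=cfg.background_gc)) for c, n in chroms.items()}
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        feats: list[FeatureRecord] = []

        def plant(
            fam: str,
            prec: AnnotatedPrecursor,
            origin: str,
            paralogue_index: int,
            cluster_id: str | None = None,
            cluster_member: int | None = None,
            forced: tuple[str, int, str] | None = None,
            exclude_chrom: str | None = None,
            ref_seq: str | None = None,
        ) -> PlantedLocus:
            if forced is None:
                strand = "+" if rng.random() < 0.5 else "-"
                chrom, start = _place(occupied, chroms, len(prec.seq), rng, exclude_chrom=exclude_chrom)
            else:
                chrom, start, strand = forced
                occupied[chrom].append((start, start + len(prec.seq)))
            insert = prec.seq if strand == "+" else revcomp(prec.seq)
            seqs[chrom][start : start + len(prec.seq)] = list(insert)
            qprec = ortholog_sets.get(fam, {}).get(cfg.query_species)
            ref = ref_seq if ref_seq is not None else (qprec.seq if qprec else None)
            div = math.nan
            if ref is not None:
                import edlib

                div = edlib.align(prec.seq, ref, mode="NW", task="distance")[
                    "editDistance"
                ] / max(len(prec.seq), len(ref))
            locus = PlantedLocus(
                species=sp, family=fam, gene=f"{fam}.g1", paralogue_index=paralogue_index,
                chrom=chrom, start=start, end=start + len(prec.seq), strand=strand,
                origin=origin, mature=prec.mature, divergence_from_query=div,
                cluster_id=cluster_id, cluster_member=cluster_member,
            )
            loci.append(locus)
            return locus

        # clusters first: their wide (> max detection gap) exclusion margins
        # are easiest to satisfy on an empty genome
        if cluster_family:
            prec = ortholog_sets[cluster_family][sp]
            qcl = ortholog_sets[cluster_family][cfg.query_species]
            for ci, (n_members, spacer_len, del_len) in enumerate(cfg.cluster_spec):
                cid = f"cluster{ci + 1}"
                if n_members == 1:
                    strand = "+" if rng.random() < 0.5 else "-"
                    chrom, start = _place(occupied, chroms, len(prec.seq), rng, margin=1200)
                    plant(cluster_family, prec, "ancestral", ci, cluster_id=cid,
                          cluster_member=0, forced=(chrom, start, strand))
                    continue
                spacer = spacer_len + int(rng.integers(-5, 6))
                member2 = AnnotatedPrecursor(
                    seq=prec.seq[: prec.mature[1]] + prec.seq[prec.mature[1] + del_len :],
                    mature=prec.mature,
                    star=(prec.star[0] - del_len, prec.star[1] - del_len),
                )
                ref2 = qcl.seq[: qcl.mature[1]] + qcl.seq[qcl.mature[1] + del_len :]
                total = len(prec.seq) + spacer + len(member2.seq)
                strand = "+" if rng.random() < 0.5 else "-"
                # clusters are planted well apart (>1 kb) so distinct planted
                # clusters cannot chain into one detected cluster
                chrom, start = _place(occupied, chroms, total, rng, margin=1200)
                if strand == "+":
                    plant(cluster_family, prec, "ancestral", ci, cluster_id=cid,
                          cluster_member=0, forced=(chrom, start, "+"))
                    plant(cluster_family, member2, "ancestral", ci, cluster_id=cid,
                          cluster_member=1, ref_seq=ref2,
                          forced=(chrom, start + len(prec.seq) + spacer, "+"))
                else:
                    # genomic order reversed so 5'->3' order on the minus strand
                    # is member1, spacer, member2
                    plant(cluster_family, member2, "ancestral", ci, cluster_id=cid,
                          cluster_member=1, ref_seq=ref2, forced=(chrom, start, "-"))
                    plant(cluster_family, prec, "ancestral", ci, cluster_id=cid,
                          cluster_member=0, forced=(chrom, start + len(member2.seq) + spacer, "-"))

        for fam in families:
            prec = ortholog_sets[fam][sp]
            origin = "te" if fam in te_families else "ancestral"
            base = plant(fam, prec, origin, 0)
            if rng.random() < cfg.duplication_prob:
                plant(fam, prec, "duplication", 1, exclude_chrom=base.chrom)

        # gene annotations: a configured fraction of loci become intragenic
        gi = 0
        for locus in [l for l in loci if l.species == sp]:
            if rng.random() >= cfg.fraction_intragenic or locus.cluster_id:
                continue
            gs = max(0, locus.start - 200)
            ge = min(chroms[locus.chrom], locus.end + 200)
            gid = f"{sp}_gene{gi}"
            gi += 1
            feats.append(FeatureRecord(locus.chrom, gs, ge, "+", "gene", gid))
            if rng.random() < 0.5 and locus.start - gs >= 100 and ge - locus.end >= 100:
                # exon-intron-exon: the locus lands in the intron
                feats.append(FeatureRecord(locus.chrom, gs, locus.start - 50, "+", "exon", f"{gid}.e1"))
                feats.append(FeatureRecord(locus.chrom, locus.end + 50, ge, "+", "exon", f"{gid}.e2"))
            else:
                feats.append(FeatureRecord(locus.chrom, gs, ge, "+", "exon", f"{gid}.e1"))

        genomes[sp] = [GenomeRecord(c, "".join(seqs[c]), species_id=sp) for c in chroms]
        features[sp] = feats

    truth = SimulationTruth(
        loci=loci,
        te_families=te_families,
        rates={"mature": cfg.r_mature, "star": cfg.r_star, "loop": cfg.r_loop},
        seed=cfg.seed,
    )
    for locus in truth.loci:
        g = genomes[locus.species]
        assert any(r.chrom_id == locus.chrom and locus.end <= len(r.sequence) for r in g)
    return genomes, features, te_library, ortholog_sets, truth


def queries_from_simulation(
    ortholog_sets: dict[str, dict[str, AnnotatedPrecursor]],
    query_species: str,
    cluster_spec: list[tuple[int, int, int]] | None = None,
    cluster_family: str = "famCL",
):
    """PrecursorQuery objects for the designated query taxon's leaf sequences.

    When the cluster family has two-member clusters, the shortened second
    member of the query taxon is an additional query (as each member of a
    tandem family is its own reference precursor)."""
    from .homology import PrecursorQuery

    out = []
    for fam, leaves in sorted(ortholog_sets.items()):
        prec = leaves[query_species]
        out.append(
            PrecursorQuery(
                id=f"{fam}.g1", family=fam, sequence=prec.seq,
                mature_interval=prec.mature, star_interval=prec.star,
            )
        )
        if fam == cluster_family and cluster_spec:
            del_lens = {d for (n, _, d) in cluster_spec if n == 2 and d > 0}
            for k, del_len in enumerate(sorted(del_lens)):
                out.append(
                    PrecursorQuery(
                        id=f"{fam}.g{k + 2}", family=fam,
                        sequence=prec.seq[: prec.mature[1]] + prec.seq[prec.mature[1] + del_len :],
                        mature_interval=prec.mature,
                        star_interval=(prec.star[0] - del_len, prec.star[1] - del_len),
                    )
                )
    return out
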