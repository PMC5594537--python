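"""End-to-end pipeline drivers and census-style reporting.

`run_pipeline` chains the stages on a synthetic cohort: simulate ->
annotate (search + six-criterion filters + paralogues/context/TE) ->
substitution-rate analyses -> neutrality tests -> phylogeny -> tandem
clusters -> summary reports. All outputs are TSV/JSON; everything is
deterministic for a given config (every random stream is seeded from the
config seed).
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusters as cl
from . import molevol, msa, phylo, popgen
from .config import RunConfig
from .formats import FeatureRecord, GenomeRecord, extract_sequence
from .homology import (
    CandidateVerdict,
    GenomeIndex,
    classify_context,
    evaluate_candidate,
    group_paralogues,
    scan_te_overlap,
    search_homologs,
    species_summary,
)
from .simulate import queries_from_simulation, simulate


def load_census() -> pd.DataFrame:
    """The packaged per-species census of miRNA families/genes/paralogues."""
    with importlib.resources.files("oryzamir.data").joinpath(
        "oryza_mirna_census.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def summarize_census(df: pd.DataFrame) -> dict[str, float]:
    """Panel-wide averages of a census table (means over species)."""
    return {
        "mean_genes": float(df["genes"].mean()),
        "mean_genes_per_family": float(df["genes_per_family"].mean()),
        "mean_paralogues_per_gene": float(df["paralogues_per_gene"].mean()),
        "mean_te_families": float(df["te_families"].mean()),
        "mean_families": float(df["families"].mean()),
        "mean_hits": float(df["hits"].mean()),
    }


def annotate_species(
    genome: list[GenomeRecord],
    queries,
    config: RunConfig,
    te_library: list[GenomeRecord] | None = None,
    features: list[FeatureRecord] | None = None,
) -> list[CandidateVerdict]:
    """Search all queries against one genome and apply the full filter chain,
    paralogue grouping, context classification and TE screening."""
    index = GenomeIndex(genome, config.scoring.word_size)
    genome_dict = {r.chrom_id: r.sequence for r in genome}
    verdicts: list[CandidateVerdict] = []
    for query in queries:
        hits = search_homologs(
            query, genome, scoring=config.scoring, e_max=config.e_max, index=index
        )
        for hit in hits:
            verdicts.append(
                evaluate_candidate(hit, query, genome_dict, thresholds=config.thresholds)
            )
    group_paralogues(verdicts, min_locus_gap=config.min_locus_gap)
    for v in verdicts:
        if not v.accepted:
            continue
        if features is not None:
            v.context = classify_context((v.hit.chrom, v.hit.start, v.hit.end), features)
        if te_library:
            cand = extract_sequence(
                genome_dict, v.hit.chrom, v.hit.start, v.hit.end, v.hit.strand
            )
            v.te_families = scan_te_overlap(
                cand, te_library,
                min_identity=config.te_min_identity, min_overlap=config.te_min_overlap,
            )
    return verdicts


def verdict_frame(verdicts: list[CandidateVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        rows.append(
            {
                "query_id": v.hit.query_id,
                "family": v.family,
                "chrom": v.hit.chrom,
                "strand": v.hit.strand,
                # user-facing coordinates are 1-based inclusive
                "start": v.hit.start + 1,
                "end": v.hit.end,
                "e_value": v.hit.e_value,
                "identity": round(v.hit.identity, 4),
                "c1_length": v.c1,
                "c2_mature": v.c2,
                "c3_hairpin": v.c3,
                "c4_mfe": v.c4,
                "c5_bulge": v.c5,
                "c6_duplex": v.c6,
                "accepted": v.accepted,
                "mfe": None if v.mfe is None else round(v.mfe, 2),
                "paralogue_group": v.paralogue_group,
                "context": v.context,
                "te_families": ",".join(v.te_families),
            }
        )
    return pd.DataFrame(rows)


def family_msas(ortholog_sets, families=None) -> dict[str, msa.MSA]:
    """Progressive MSAs of the per-family precursor ortholog sets, with
    mature/star region annotations mapped from the first row."""
    out = {}
    for fam in sorted(families if families is not None else ortholog_sets):
        leaves = ortholog_sets[fam]
        seqs = [(taxon, prec.seq) for taxon, prec in sorted(leaves.items())]
        aln = msa.align_progressive(seqs)
        first = aln.ids[0]
        prec = leaves[first]
        idx = aln.ids.index(first)
        aln.regions["mature"] = aln.map_interval(idx, prec.mature)
        aln.regions["star"] = aln.map_interval(idx, prec.star)
        out[fam] = aln
    return out


def molevol_report(msas: dict[str, msa.MSA], config: RunConfig) -> pd.DataFrame:
    rows = []
    for fam, aln in sorted(msas.items()):
        for region_name in (None, "mature", "star"):
            region = aln.regions.get(region_name) if region_name else None
            if region_name and region is None:
                continue
            s = molevol.substitution_summary(aln, config.rate, region)
            rows.append(
                {
                    "family": fam,
                    "region": region_name or "precursor",
                    "p": s.p,
                    "N": s.N,
                    "R": s.R,
                    "ti": s.ti_count,
                    "tv": s.tv_count,
                    "titv_ratio": s.titv_ratio,
                    "ti_fraction": s.ti_fraction,
                }
            )
    return pd.DataFrame(rows)


def neutrality_report(
    msas: dict[str, msa.MSA], config: RunConfig
) -> tuple[pd.DataFrame, dict]:
    rng = np.random.default_rng(config.seed + 7)
    results = []
    for fam, aln in sorted(msas.items()):
        res = popgen.analyze_locus(
            aln, fam, reps=config.neutrality_reps, seed=int(rng.integers(1, 2**31 - 1))
        )
        results.append(res)
    df = pd.DataFrame([asdict(r) for r in results])
    sig = [r.locus_id for r in results if r.significant]
    subset = sig if sig else sorted(msas)
    summary = {
        "n_loci": len(results),
        "n_significant_both": len(sig),
        "loss_locus_subset": "significant" if sig else "all",
    }
    try:
        retained, loss = popgen.diversity_loss(msas, locus_subset=subset)
        summary.update({"diversity_retained": retained, "diversity_loss": loss})
    except ValueError as exc:  # panel lacks the cultivated/wild split
        summary["diversity_loss_note"] = str(exc)
    return df, summary


def cluster_report(
    verdicts: list[CandidateVerdict],
    genome: list[GenomeRecord],
    family: str,
    config: RunConfig,
) -> list[cl.ClusterRecord]:
    genome_dict = {r.chrom_id: r.sequence for r in genome}
    loci = []
    for v in verdicts:
        if not v.accepted or v.family != family:
            continue
        seq = extract_sequence(genome_dict, v.hit.chrom, v.hit.start, v.hit.end, v.hit.strand)
        loci.append(
            cl.ClusterLocus(
                locus_id=f"{v.hit.chrom}:{v.hit.start}-{v.hit.end}({v.hit.strand})",
                chrom=v.hit.chrom,
                start=v.hit.start,
                end=v.hit.end,
                strand=v.hit.strand,
                sequence=seq,
                mature=v.mature_interval,
            )
        )
    records = cl.detect_clusters(loci, max_gap=config.cluster_max_gap)
    return cl.characterize_clusters(records, expected_del_len=config.cluster_expected_deletion)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage on a synthetic cohort and write the report bundle.

    Emits per-stage TSV/JSON files under ``outdir`` and returns the summary
    dict. Deterministic given the config.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        genomes, features, te_library, ortholog_sets, truth = simulate(config.simulation)
        queries = queries_from_simulation(
            ortholog_sets,
            config.simulation.query_species,
            cluster_spec=config.simulation.cluster_spec,
        )
        truth_df = pd.DataFrame(
            [
                {**{k: v for k, v in asdict(l).items() if k not in ("mature",)},
                 "mature_start": l.mature[0], "mature_end": l.mature[1]}
                for l in truth.loci
            ]
        )
        truth_df.to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)

        stage = "annotate"
        all_verdicts: dict[str, list[CandidateVerdict]] = {}
        census_rows = []
        for sp in sorted(genomes):
            verdicts = annotate_species(
                genomes[sp], queries, config, te_library=te_library, features=features[sp]
            )
            all_verdicts[sp] = verdicts
            row = {"species": sp, **species_summary(verdicts)}
            ctx = {"intergenic": 0, "exonic": 0, "intronic": 0, "intron_exon": 0}
            for v in verdicts:
                if v.accepted and v.context:
                    ctx[v.context] += 1
            row.update({f"ctx_{k}": n for k, n in ctx.items()})
            census_rows.append(row)
        census = pd.DataFrame(census_rows)
        census.to_csv(outdir / "species_census.tsv", sep="\t", index=False)
        pd.concat(
            [verdict_frame(v).assign(species=sp) for sp, v in sorted(all_verdicts.items())],
            ignore_index=True,
        ).to_csv(outdir / "verdicts.tsv", sep="\t", index=False)

        stage = "molevol"
        msas = family_msas(ortholog_sets)
        mol = molevol_report(msas, config)
        mol.to_csv(outdir / "molevol.tsv", sep="\t", index=False)

        n_taxa = len(genomes)
        stage = "neutrality"
        if n_taxa >= 3:
            neut_df, neut_summary = neutrality_report(msas, config)
        else:
            neut_df = pd.DataFrame()
            neut_summary = {"n_loci": 0, "note": "panel has < 3 taxa; neutrality skipped"}
        neut_df.to_csv(outdir / "neutrality.tsv", sep="\t", index=False)

        stage = "tree"
        fam0 = sorted(msas)[0]
        if n_taxa >= 3:
            aln = msas[fam0]
            n = len(aln.ids)
            D = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    _, d = molevol.jc_distance(aln.rows[i], aln.rows[j])
                    if math.isnan(d):
                        d = 0.75
                    D[i, j] = D[j, i] = d
            tree = phylo.neighbor_joining(
                phylo.DistanceMatrix(taxa=list(aln.ids), matrix=D), clamp_negative=True
            )
            phylo.write_newick(tree, outdir / f"{fam0}_nj.nwk")

        stage = "clusters"
        cluster_records = {}
        cluster_rows = []
        for sp in sorted(genomes):
            recs = cluster_report(all_verdicts[sp], genomes[sp], "famCL", config)
            cluster_records[sp] = recs
            for r in recs:
                cluster_rows.append(
                    {
                        "species": sp,
                        "cluster_id": r.cluster_id,
                        "n_members": len(r.members),
                        "chrom": r.members[0].chrom,
                        "strand": r.members[0].strand,
                        "spacers": ",".join(map(str, r.spacers)),
                        "deletions": ",".join(
                            f"{d.length}@+{d.offset_from_mature_end}" for d in r.deletions
                        ),
                    }
                )
        pd.DataFrame(cluster_rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)

        stage = "report"
        summary = {
            "n_species": len(genomes),
            "n_queries": len(queries),
            "census": census.to_dict(orient="records"),
            "neutrality": neut_summary,
            "planted_loci": len(truth.loci),
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        return {
            "summary": summary,
            "truth": truth,
            "verdicts": all_verdicts,
            "msas": msas,
            "clusters": cluster_records,
            "census": census,
        }
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
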