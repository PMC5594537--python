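#!/usr/bin/env python
"""Census-style summary: published panel averages and the synthetic cohort.

Reproduces the panel-wide averages from the packaged per-species census of
homology-predicted miRNA genes in the ten Oryza species, and prints the
synthetic cohort's census for comparison. Writes results/report/.
"""

from pathlib import Path

import pandas as pd

from oryzamir.pipeline import load_census, summarize_census

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "report"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    census = load_census()
    summary = summarize_census(census)
    census.to_csv(OUT / "published_census.tsv", sep="\t", index=False)
    pd.DataFrame([summary]).to_csv(OUT / "published_census_means.tsv", sep="\t", index=False)
    print("published per-species census, panel-wide means:")
    print(f"  miRNA genes/species:        {summary['mean_genes']:.1f}")
    print(f"  genes per gene family:      {summary['mean_genes_per_family']:.2f}")
    print(f"  paralogous hits per gene:   {summary['mean_paralogues_per_gene']:.2f}")
    print(f"  TE-derived families:        {summary['mean_te_families']:.1f}")

    synth = ROOT / "annotation" / "species_census.tsv"
    if synth.exists():
        df = pd.read_csv(synth, sep="\t")
        print("\nsynthetic cohort census (from 02_annotate.py):")
        print(df.to_string(index=False))


if __name__ == "__main__":
    main()
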