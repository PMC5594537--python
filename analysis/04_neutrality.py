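#!/usr/bin/env python
"""Per-locus neutrality tests across the synthetic species panel.

Computes S, pi, Watterson's theta, Tajima's D and Fu & Li's F* for every
family alignment, with p-values from a fixed-S neutral coalescent null, and
the cultivated-vs-wild diversity-retention summary. Writes
results/neutrality/.
"""

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from oryzamir.config import RunConfig
from oryzamir.pipeline import family_msas, neutrality_report
from oryzamir.simulate import simulate

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "neutrality"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = RunConfig.from_yaml(ROOT / "simulation" / "config.yaml")
    _, _, _, ortholog_sets, _ = simulate(config.simulation)
    msas = family_msas(ortholog_sets)

    df, summary = neutrality_report(msas, config)
    df.to_csv(OUT / "neutrality.tsv", sep="\t", index=False)
    with open(OUT / "diversity_loss.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    defined = df.dropna(subset=["tajima_d"])
    print(f"{len(df)} loci analysed; {len(defined)} with S >= 1")
    print(f"mean Tajima's D = {defined.tajima_d.mean():+.3f}, "
          f"mean Fu & Li's F* = {defined.fu_li_f.mean():+.3f}")
    print("(a species panel is one fixed, unbalanced genealogy, not a "
          "population sample: long outgroup branches concentrate variants on "
          "few lineages, so negative values arise without selection)")
    print(f"significant for both tests at alpha = 0.05: "
          f"{summary['n_significant_both']} loci")
    if "diversity_retained" in summary:
        print(f"diversity retained in the cultivated pair vs wild species: "
              f"{100 * summary['diversity_retained']:.1f}% "
              f"(loss {100 * summary['diversity_loss']:.1f}%) over "
              f"{summary['loss_locus_subset']} loci")


if __name__ == "__main__":
    main()
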