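#!/usr/bin/env python
"""Neighbor-joining trees from precursor ortholog alignments.

Builds per-family NJ trees from Jukes-Cantor distances, roots them on the
distant outgroup, and checks whether the two outgroup species attach
basally — the qualitative expectation for this panel. Writes newick files
under results/phylogeny/.
"""

import math
from pathlib import Path

import numpy as np

from oryzamir.config import RunConfig
from oryzamir.molevol import jc_distance
from oryzamir.phylo import DistanceMatrix, neighbor_joining, root_tree, write_newick
from oryzamir.pipeline import family_msas
from oryzamir.simulate import simulate

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "phylogeny"
OUTGROUPS = ("O_brachyantha", "O_punctata")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = RunConfig.from_yaml(ROOT / "simulation" / "config.yaml")
    _, _, _, ortholog_sets, _ = simulate(config.simulation)
    msas = family_msas(ortholog_sets)

    basal = 0
    built = 0
    for fam, aln in sorted(msas.items()):
        n = len(aln.ids)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                _, d = jc_distance(aln.rows[i], aln.rows[j])
                D[i, j] = D[j, i] = 0.75 if math.isnan(d) else d
        tree = neighbor_joining(DistanceMatrix(list(aln.ids), D), clamp_negative=True)
        write_newick(tree, OUT / f"{fam}_nj.nwk")
        built += 1
        try:
            rooted = root_tree(tree, ["O_brachyantha"])
            # is O_punctata the next-deepest split inside the ingroup?
            ingroup = next(
                c for c in rooted.seed_node.child_nodes()
                if {l.taxon.label for l in c.leaf_iter()} != {"O_brachyantha"}
            )
            splits = [
                frozenset(l.taxon.label for l in c.leaf_iter())
                for c in ingroup.child_nodes()
            ]
            basal += frozenset({"O_punctata"}) in splits
        except ValueError:
            pass

    print(f"built {built} NJ trees; in {basal} of them the two distant "
          f"genomes ({', '.join(OUTGROUPS)}) attach basally in order")


if __name__ == "__main__":
    main()
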