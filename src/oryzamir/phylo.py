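"""Distance-based tree inference: neighbor-joining with outgroup rooting.

The Saitou-Nei algorithm is implemented directly (standard Q-criterion,
two-point branch-length formulas, deterministic lowest-index tie-break) and
returns dendropy trees, which handle newick serialization and rerooting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite distances (resolve undefined JC distances upstream)")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if np.any(m < -1e-12):
            raise ValueError("negative distances")
        if not np.allclose(np.diag(m), 0.0, atol=1e-9):
            raise ValueError("nonzero diagonal")
        self.matrix = m

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.taxa) + "\n")
            for t, row in zip(self.taxa, self.matrix):
                fh.write(t + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [line.rstrip("\n").split("\t")[1:] for line in fh if line.strip()]
        return cls(taxa=header, matrix=np.array(rows, dtype=float))


def nj_joins(dm: DistanceMatrix) -> list[tuple[int, int, int, float, float]]:
    """Neighbor-joining join order.

    Returns tuples (i, j, new, L_i, L_j) over node indices (0..n-1 are the
    input taxa; internal nodes are numbered onward). The final entry joins
    the last three clusters and is encoded as three consecutive 2-way records
    ending at the trifurcating root; callers wanting the tree should use
    :func:`neighbor_joining`.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa for neighbor joining")
    D = dm.matrix.copy()
    active = list(range(n))
    index_of = {k: k for k in active}  # node id -> row in D
    joins: list[tuple[int, int, int, float, float]] = []
    next_id = n
    while len(active) > 3:
        r = len(active)
        rows = [index_of[k] for k in active]
        sub = D[np.ix_(rows, rows)]
        totals = sub.sum(axis=1)
        Q = (r - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        # deterministic: smallest Q, ties -> lowest (i, j) node-id pair
        best = None
        for a in range(r):
            for b in range(a + 1, r):
                key = (Q[a, b], active[a], active[b])
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dij = sub[a, b]
        li = 0.5 * dij + (totals[a] - totals[b]) / (2.0 * (r - 2))
        lj = dij - li
        # distances to the new node
        newd = 0.5 * (sub[a, :] + sub[b, :] - dij)
        ia, ib = active[a], active[b]
        joins.append((ia, ib, next_id, li, lj))
        # overwrite row of a with the new node, drop b
        ra = index_of[ia]
        for c in range(r):
            rc = index_of[active[c]]
            D[ra, rc] = D[rc, ra] = newd[c]
        D[ra, ra] = 0.0
        index_of[next_id] = ra
        active = [k for k in active if k not in (ia, ib)] + [next_id]
        next_id += 1
    # terminal three-way join
    x, y, z = active
    rx, ry, rz = index_of[x], index_of[y], index_of[z]
    dxy, dxz, dyz = D[rx, ry], D[rx, rz], D[ry, rz]
    lx = 0.5 * (dxy + dxz - dyz)
    ly = 0.5 * (dxy + dyz - dxz)
    lz = 0.5 * (dxz + dyz - dxy)
    joins.append((x, y, -1, lx, ly))
    joins.append((z, -1, -1, lz, 0.0))
    return joins


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = False) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree with a
    trifurcating seed node.

    With ``clamp_negative`` (MEGA-compatible practice), negative estimated
    branch lengths are clamped to 0 and the deficit moved to the sibling.
    """
    joins = nj_joins(dm)
    nodes: dict[int, dendropy.Node] = {}
    tns = dendropy.TaxonNamespace()
    for i, t in enumerate(dm.taxa):
        nodes[i] = dendropy.Node(taxon=tns.new_taxon(t))

    def lengths(li: float, lj: float) -> tuple[float, float]:
        if clamp_negative:
            if li < 0:
                lj += li
                li = 0.0
            if lj < 0:
                li += lj
                lj = 0.0
            li, lj = max(li, 0.0), max(lj, 0.0)
        return li, lj

    for ia, ib, new, li, lj in joins[:-2]:
        parent = dendropy.Node()
        li, lj = lengths(li, lj)
        parent.add_child(nodes[ia])
        nodes[ia].edge.length = li
        parent.add_child(nodes[ib])
        nodes[ib].edge.length = lj
        nodes[new] = parent
    (x, y, _, lx, ly), (z, _, _, lz, _) = joins[-2:]
    root = dendropy.Node()
    for node_id, length in ((x, lx), (y, ly), (z, lz)):
        root.add_child(nodes[node_id])
        nodes[node_id].edge.length = max(length, 0.0) if clamp_negative else length
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


class NonMonophyleticOutgroup(ValueError):
    pass


def root_tree(tree: dendropy.Tree, outgroup_taxa: list[str]) -> dendropy.Tree:
    """Root on the branch separating the outgroup from the ingroup, at its
    midpoint. The outgroup must form a clade of the unrooted tree."""
    tree = tree.clone(depth=1)
    out = set(outgroup_taxa)
    all_taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = out - all_taxa
    if missing:
        raise ValueError(f"outgroup taxa not in tree: {sorted(missing)}")
    target = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if below == out or below == all_taxa - out:
            target = node
            break
    if target is None:
        raise NonMonophyleticOutgroup(
            f"outgroup {sorted(out)} does not form a clade of the unrooted tree"
        )
    edge = target.edge
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half)
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True, real_value_format_specifier=".10g")


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks and
    simulation oracles)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted((t.label for t in tree.taxon_namespace), key=str)
    lookup = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(lookup[taxa[i]], lookup[taxa[j]])
            m[i, j] = m[j, i] = d
    return DistanceMatrix(taxa=taxa, matrix=m)
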