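"""Neighbor-joining phylogenetics of repeats and precursor proteins.

Distances are 1 - fractional identity from pairwise global alignment (see
:mod:`orbimine.align`).  The NJ agglomeration is the standard Saitou-Nei
procedure: for an additive distance matrix it recovers the generating
topology and branch lengths exactly.  Negative branch estimates are clamped
to zero with the deficit transferred to the sibling branch, so the joined
pair's path length is preserved.  Trees are dendropy objects; midpoint
rooting and Newick output come from dendropy.  Bootstrap support resamples
alignment columns with replacement and reports, per internal bipartition of
the reference tree, the percentage of replicates containing it.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np

from .align import AlignmentParams, DEFAULT_PARAMS, DistanceMatrix, distance_matrix


class PhyloInputError(ValueError):
    pass


def _pair_branches(dij: float, li: float) -> tuple[float, float]:
    """Clamp negative NJ estimates; the deficit moves to the sibling."""
    lj = dij - li
    if li < 0:
        return 0.0, dij
    if lj < 0:
        return dij, 0.0
    return li, lj


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree."""
    n = len(dm)
    if n < 2:
        raise PhyloInputError("neighbor joining needs >= 2 taxa")
    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    d = dm.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        li, lj = _pair_branches(dij, li)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new node
        new_row = 0.5 * (d[i, active] + d[j, active] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = new_row
        d[active, k] = new_row
        d[k, k] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [k]

    center = dendropy.Node()
    if len(active) == 2:
        i, j = active
        half = d[i, j] / 2.0
        for node in (nodes[i], nodes[j]):
            center.add_child(node)
            node.edge.length = half
    else:
        i, j, k = active
        li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
        lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
        lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
            center.add_child(node)
            node.edge.length = max(length, 0.0)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def tree_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.edges())


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path (on a clone)."""
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise PhyloInputError("midpoint rooting needs >= 2 leaves")
    rooted = tree.clone(depth=1)
    if tree_length(rooted) == 0.0:
        warnings.warn("zero-length tree: midpoint is arbitrary; rooting in place")
        rooted.is_rooted = True
        return rooted
    if len(leaves) == 2:
        # the midpoint sits on the single leaf-to-leaf path; rebalance it
        a, b = list(rooted.leaf_node_iter())
        total = (a.edge.length or 0.0) + (b.edge.length or 0.0)
        a.edge.length = b.edge.length = total / 2.0
        rooted.is_rooted = True
        return rooted
    rooted.reroot_at_midpoint(update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def _aligned_identity(a: np.ndarray, b: np.ndarray, gap: int) -> float:
    both_gap = (a == gap) & (b == gap)
    denom = int((~both_gap).sum())
    if denom == 0:
        return 0.0
    return int(((a == b) & ~both_gap).sum()) / denom


def alignment_distances(rows: list[tuple[str, str]],
                        columns: np.ndarray | None = None) -> DistanceMatrix:
    """p-distances (1 - identity) between aligned rows, optionally on a
    resampled column index vector."""
    ids = [name for name, _ in rows]
    mat = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for _, r in rows])
    if columns is not None:
        mat = mat[:, columns]
    gap = ord("-")
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - _aligned_identity(mat[i], mat[j], gap)
    return DistanceMatrix(ids, d)


def _bipartitions(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    """Nontrivial bipartitions, keyed by the leaf side not containing the
    alphabetically first taxon."""
    all_labels = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = min(all_labels)
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = all_labels - side
        if 2 <= len(side) <= len(all_labels) - 2:
            out[side] = node
    return out


def bootstrap_support(aligned: list[tuple[str, str]], n_reps: int, seed: int,
                      params: AlignmentParams = DEFAULT_PARAMS) -> dendropy.Tree:
    """NJ tree of aligned repeats with bootstrap support on internal nodes.

    Columns are resampled with replacement ``n_reps`` times; support is the
    percentage of replicate NJ trees containing each internal bipartition of
    the reference tree (built from the full alignment).  Deterministic for a
    fixed seed.  Internal node labels carry the support values.
    """
    if len(aligned) < 3:
        raise PhyloInputError("bootstrap needs >= 3 aligned rows")
    if n_reps < 1:
        raise PhyloInputError("n_reps must be >= 1")
    widths = {len(r) for _, r in aligned}
    if len(widths) != 1:
        raise PhyloInputError("rows must be aligned to equal length")
    (width,) = widths
    rng = np.random.default_rng(seed)
    reference = neighbor_joining(alignment_distances(aligned))
    ref_biparts = _bipartitions(reference)
    counts = {side: 0 for side in ref_biparts}
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        rep_tree = neighbor_joining(alignment_distances(aligned, cols))
        rep_sides = set(_bipartitions(rep_tree))
        for side in counts:
            if side in rep_sides:
                counts[side] += 1
    for side, node in ref_biparts.items():
        node.label = f"{100.0 * counts[side] / n_reps:g}"
    return reference


def nj_tree_from_sequences(seqs: list[tuple[str, str]],
                           params: AlignmentParams = DEFAULT_PARAMS
                           ) -> dendropy.Tree:
    """Convenience: pairwise-alignment distances -> NJ tree."""
    return neighbor_joining(distance_matrix(seqs, params))
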