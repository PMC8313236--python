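"""Taxonomy-derived phylogenies and the species correlation matrix.

The meta-regression needs a species-by-species correlation matrix
describing shared ancestry.  In the absence of a dated molecular tree,
a topology is built from ranked taxonomic classifications (species
sharing a genus form a clade nested inside the family clade, and so
on), branch lengths are assigned with Grafen's method (node height a
power of the number of descendant tips, giving an ultrametric tree),
and the correlation between two species is the fraction of the
root-to-tip path they share.

Trees are :class:`dendropy.Tree` objects throughout, so Newick I/O and
standard tree manipulations come for free.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "tree_from_taxonomy",
    "grafen_lengths",
    "phylo_correlation",
    "read_taxonomy",
    "write_newick",
    "read_newick",
]

ULTRAMETRIC_TOL = 1e-9


def read_taxonomy(path, rank_columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a ranked-lineage table (CSV, one row per species).

    Columns are ordered from the broadest rank to the species
    identifier (last column).  ``rank_columns`` selects and orders a
    subset; by default all columns are used in file order.
    """
    df = pd.read_csv(path, dtype=str)
    if rank_columns is not None:
        df = df[list(rank_columns)]
    return df


def tree_from_taxonomy(taxonomy: pd.DataFrame) -> dendropy.Tree:
    """Build a rooted topology from a ranked-lineage table.

    Each row is one species; columns run broadest rank -> species id
    (last column).  Species sharing a prefix of their lineage are
    nested accordingly.  Ranks that are constant across every species
    and unary internal nodes are collapsed, so the result has no
    single-child chains; polytomies are kept as-is.

    Raises ``ValueError`` on duplicate species or an inconsistent
    lineage (the same taxon name appearing under two different parents),
    reporting the offending rows.
    """
    tax = taxonomy.astype(str)
    if tax.shape[0] < 2:
        raise ValueError("need at least 2 species to build a tree")
    if tax.isin(["", "nan"]).any().any():
        raise ValueError("taxonomy entries must be non-empty")
    species = tax.iloc[:, -1]
    dup = species[species.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate species identifiers: {dup}")
    # a taxon name must always sit under the same parent chain
    for col in range(1, tax.shape[1]):
        parent_of = {}
        for row_i, row in enumerate(tax.itertuples(index=False)):
            name, parent = row[col], row[col - 1]
            if parent_of.setdefault(name, (parent, row_i))[0] != parent:
                first_row = parent_of[name][1]
                raise ValueError(
                    f"inconsistent lineage: {name!r} under both "
                    f"{parent_of[name][0]!r} (row {first_row}) and "
                    f"{parent!r} (row {row_i})"
                )
    internal_names = set(tax.iloc[:, :-1].to_numpy().ravel())
    clash = internal_names & set(species)
    # a species id may legitimately repeat its own genus-level name only
    # if it is the same lineage; any cross-lineage reuse is an error
    for name in clash:
        rows_as_tip = set(np.where(species == name)[0])
        rows_as_internal = set(np.where((tax.iloc[:, :-1] == name).any(axis=1))[0])
        if rows_as_internal - rows_as_tip:
            raise ValueError(
                f"rank entry {name!r} collides with a species id of "
                f"another lineage"
            )

    taxa = dendropy.TaxonNamespace(species.tolist())
    tree = dendropy.Tree(taxon_namespace=taxa)
    node_at = {(): tree.seed_node}
    for row in tax.itertuples(index=False):
        path = ()
        for depth, name in enumerate(row):
            parent = node_at[path]
            path = path + (name,)
            if path not in node_at:
                child = dendropy.Node(label=name)
                parent.add_child(child)
                node_at[path] = child
        tip = node_at[path]
        tip.taxon = taxa.get_taxon(path[-1])
    tree.is_rooted = True
    tree.suppress_unifurcations()
    return tree


def grafen_lengths(tree: dendropy.Tree, power: float = 1.0) -> dendropy.Tree:
    """Assign Grafen branch lengths in place and return the tree.

    Each internal node gets height ``((k - 1)/(S - 1))^power`` where
    ``k`` is its number of descendant tips and ``S`` the total tip
    count; tips have height 0.  A branch's length is the height drop
    from parent to child, so the tree is ultrametric with depth 1
    (root height 1 by construction).
    """
    if power <= 0:
        raise ValueError("power must be positive")
    tips = tree.leaf_nodes()
    S = len(tips)
    if S < 2:
        raise ValueError("need at least 2 tips")
    heights = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._n_tips = 1
            heights[node] = 0.0
        else:
            node._n_tips = sum(ch._n_tips for ch in node.child_nodes())
            heights[node] = ((node._n_tips - 1) / (S - 1)) ** power
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
        else:
            node.edge.length = heights[node.parent_node] - heights[node]
    return tree


def _tip_depths(tree: dendropy.Tree) -> dict:
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    return depth


def phylo_correlation(tree: dendropy.Tree) -> pd.DataFrame:
    """Species correlation matrix from an ultrametric tree.

    Entry (i, j) is the root-to-MRCA path length of the pair divided by
    the total tree depth — the fraction of evolutionary history the two
    species share.  The diagonal is 1; a star tree gives the identity.
    Raises on non-ultrametric input (tip depths differing by more than
    ``1e-9`` relative to the depth).
    """
    depth = _tip_depths(tree)
    tips = tree.leaf_nodes()
    tip_depths = np.array([depth[t] for t in tips])
    total = tip_depths.mean()
    if total <= 0:
        raise ValueError("tree has zero depth; assign branch lengths first")
    if np.ptp(tip_depths) > ULTRAMETRIC_TOL * max(1.0, total):
        raise ValueError("tree is not ultrametric; Grafen lengths required")
    labels = [t.taxon.label for t in tips]
    index = {t: i for i, t in enumerate(tips)}
    S = len(tips)
    corr = np.eye(S)
    for node in tree.postorder_internal_node_iter():
        share = depth[node] / total
        groups = [
            [index[t] for t in ch.leaf_iter()] for ch in node.child_nodes()
        ]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia = np.asarray(groups[a])[:, None]
                ib = np.asarray(groups[b])[None, :]
                corr[ia, ib] = share
                corr[ib.T, ia.T] = share
    return pd.DataFrame(corr, index=labels, columns=labels)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = True
    return tree
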