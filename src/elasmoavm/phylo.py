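"""Phylogenetic trees and the Brownian-motion correlation matrix.

Species-level random effects in the meta-regression are correlated according
to shared evolutionary history: under Brownian trait evolution on a rooted
tree, cov(u_i, u_j) is proportional to the root-to-MRCA path length shared by
tips i and j. Normalising by the root-to-tip depths gives the correlation
matrix ``C`` used by the model. For an ultrametric tree this reduces to
shared-path / total-depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

#: diagonal jitter applied before any Cholesky factorization downstream
CHOLESKY_JITTER = 1e-8


class TreeError(ValueError):
    pass


@dataclass
class PhyloTree:
    """A rooted tree with tip labels and non-negative branch lengths."""

    tree: dendropy.Tree

    def __post_init__(self):
        labels = self.tip_labels
        if len(labels) < 2:
            raise TreeError("tree must have at least 2 tips")
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dups}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeError("negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def depths(self) -> dict[str, float]:
        """Root-to-tip path lengths."""
        out: dict[str, float] = {}
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        for lf in self.tree.leaf_node_iter():
            out[lf.taxon.label] = float(lf.root_distance)
        return out


@dataclass
class CorrMatrix:
    """Species-by-species Brownian correlation matrix over an ordered list."""

    values: np.ndarray
    species: list[str]

    def __post_init__(self):
        c = np.asarray(self.values, dtype=float)
        if c.shape != (len(self.species), len(self.species)):
            raise ValueError("matrix shape does not match species list")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if c.min() < -1e-12 or c.max() > 1 + 1e-12:
            raise ValueError("correlations must lie in [0, 1]")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")
        self.values = c

    def cholesky(self, jitter: float = CHOLESKY_JITTER) -> np.ndarray:
        return np.linalg.cholesky(self.values + jitter * np.eye(len(self.species)))

    def reorder(self, species: list[str]) -> "CorrMatrix":
        idx = [self.species.index(s) for s in species]
        return CorrMatrix(self.values[np.ix_(idx, idx)], list(species))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.species)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def identity(cls, species: list[str]) -> "CorrMatrix":
        return cls(np.eye(len(species)), list(species))


def parse_tree(path, schema: str = "newick", tree_index: int = 0) -> PhyloTree:
    """Parse one rooted tree from a Newick or NEXUS file.

    ``tree_index`` selects from a multi-tree file (e.g. a posterior sample of
    trees); sensitivity reruns can sweep it.
    """
    if schema not in ("newick", "nexus"):
        raise ValueError("schema must be 'newick' or 'nexus'")
    try:
        trees = dendropy.TreeList.get(path=str(path), schema=schema)
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"failed to parse {path} as {schema}: {exc}") from exc
    if not len(trees):
        raise TreeError(f"no trees found in {path}")
    if not (0 <= tree_index < len(trees)):
        raise TreeError(f"tree_index {tree_index} out of range (file has {len(trees)})")
    tree = trees[tree_index]
    tree.is_rooted = True
    return PhyloTree(tree)


def parse_tree_string(newick: str) -> PhyloTree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise TreeError(f"failed to parse newick string: {exc}") from exc
    tree.is_rooted = True
    return PhyloTree(tree)


def count_trees(path, schema: str = "newick") -> int:
    return len(dendropy.TreeList.get(path=str(path), schema=schema))


def select_tree(path, index: int, schema: str = "nexus") -> PhyloTree:
    """Retrieve tree ``index`` from a multi-tree file (posterior tree set)."""
    return parse_tree(path, schema=schema, tree_index=index)


def random_tree_index(n_trees: int, seed: int) -> int:
    """Seeded random choice of a tree from a posterior set."""
    return int(np.random.default_rng(seed).integers(0, n_trees))


def prune_to_species(t: PhyloTree, species: list[str]) -> PhyloTree:
    """Induced subtree on the requested tips.

    Unifurcations created by pruning are suppressed with their branch lengths
    summed, so patristic distances among retained tips are preserved.
    """
    have = set(t.tip_labels)
    missing = [s for s in species if s not in have]
    if missing:
        raise TreeError(f"species absent from tree: {missing}")
    clone = dendropy.Tree(t.tree)
    taxa = [tx for tx in clone.taxon_namespace if tx.label in set(species)]
    clone.retain_taxa(taxa, suppress_unifurcations=True)
    return PhyloTree(clone)


def write_newick(t: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(t.as_newick() + "\n")


def brownian_correlation(t: PhyloTree, species_order: list[str] | None = None) -> CorrMatrix:
    """Brownian-motion correlation matrix for the tree's tips.

    ``C[i, j] = shared root-to-MRCA path length / sqrt(depth_i * depth_j)``;
    the sqrt-depth normalisation makes the matrix a valid correlation matrix
    for non-ultrametric trees as well and reduces to shared/total depth when
    the tree is ultrametric.
    """
    species_order = list(species_order) if species_order is not None else sorted(t.tip_labels)
    have = set(t.tip_labels)
    missing = [s for s in species_order if s not in have]
    if missing:
        raise TreeError(f"species absent from tree: {missing}")
    sub = prune_to_species(t, species_order) if set(species_order) != have else t

    tree = sub.tree
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    depths = {lbl: float(node.root_distance) for lbl, node in leaves.items()}
    zero = [s for s, d in depths.items() if d <= 0]
    if zero:
        raise TreeError(f"tips at zero root-to-tip depth (correlation undefined): {zero}")

    n = len(species_order)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_tree(tree)
    c = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = leaves[species_order[i]].taxon, leaves[species_order[j]].taxon
            mrca = pdm.mrca(ti, tj)
            mrca_depth = float(mrca.root_distance)
            c[i, j] = c[j, i] = mrca_depth / np.sqrt(depths[species_order[i]] * depths[species_order[j]])
    return CorrMatrix(c, species_order)
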