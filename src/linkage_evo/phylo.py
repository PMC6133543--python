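"""Tree and trait I/O plus the phylogenetic covariance machinery.

Trees are rooted, time-calibrated phylogenies read from Newick (via
dendropy).  Under Brownian motion with unit rate, the among-species
covariance of a trait is the matrix of shared root-to-MRCA path lengths,
``C_ij = depth(MRCA(i, j))`` with ``C_ii`` the root-to-tip depth; every
statistical module in this package is built on that matrix.  Pagel's
lambda rescales its off-diagonal entries to measure how strongly
phylogeny structures regression residuals (lambda = 0: star phylogeny /
OLS; lambda = 1: full Brownian covariance).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    EmptyOverlap,
    LambdaOutOfRange,
    MissingBranchLength,
    ParseError,
)

__all__ = [
    "Phylogeny",
    "TraitTable",
    "BranchTable",
    "read_newick",
    "prune_to_overlap",
    "phylo_vcv",
    "lambda_transform",
]


@dataclass(frozen=True)
class BranchTable:
    """Flat arrays describing every branch (edge above a non-root node).

    Branch ``i`` runs from absolute time ``t_start[i]`` (its parent node's
    depth) to ``t_end[i]`` (its child node's depth).  ``parent[i]`` is the
    branch index of the parent edge, or -1 for branches hanging off the
    root.  ``tip_mask[i]`` flags the tips descending from the branch and
    ``is_terminal[i]`` marks terminal (tip) branches.  Indices follow a
    preorder traversal, so a parent branch always precedes its children.
    """

    t_start: np.ndarray
    t_end: np.ndarray
    parent: np.ndarray
    tip_mask: np.ndarray
    is_terminal: np.ndarray

    @property
    def n_branches(self) -> int:
        return self.t_start.shape[0]

    @property
    def lengths(self) -> np.ndarray:
        return self.t_end - self.t_start


class Phylogeny:
    """A rooted tree with branch lengths and a stable tip ordering.

    Wraps a :class:`dendropy.Tree`; tip order (and hence the row order of
    every covariance matrix and trait vector) is the leaf order of the
    underlying tree, exposed as :attr:`tip_labels`.
    """

    def __init__(self, tree: dendropy.Tree):
        if tree.seed_node is None or len(tree.leaf_nodes()) < 2:
            raise ParseError("tree must be rooted with at least two tips")
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ParseError("every tip must carry a label")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ParseError(f"duplicate tip labels: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise MissingBranchLength(
                    f"edge above {edge.head_node!r} lacks a branch length"
                )
            if edge.length < 0:
                raise ParseError("negative branch length")
        self._tree = tree
        self._labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}

    # -- constructors -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse exceptions
            raise ParseError(str(exc)) from exc
        return cls(tree)

    # -- basic structure ----------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return list(self._labels)

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", unquoted_underscores=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")

    # -- depths and covariance ----------------------------------------
    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths, in tip order."""
        depths = np.empty(self.n_tips)
        node_depth = {self._tree.seed_node: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            node_depth[node] = node_depth[node.parent_node] + (node.edge.length or 0.0)
            if node.is_leaf():
                depths[self._index[node.taxon.label]] = node_depth[node]
        return depths

    def depth(self) -> float:
        return float(self.tip_depths().max())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.tip_depths()
        return float(d.max() - d.min()) <= rel_tol * float(d.max())

    def check_ultrametric(self, rel_tol: float = 1e-6) -> None:
        if not self.is_ultrametric(rel_tol):
            d = self.tip_depths()
            warnings.warn(
                "tree is not ultrametric (root-to-tip depth spread "
                f"{d.max() - d.min():.3g} over depth {d.max():.3g})",
                stacklevel=2,
            )

    def vcv(self) -> np.ndarray:
        """Brownian-motion covariance: C_ij = depth of MRCA(i, j).

        Accumulated in one postorder pass: each internal node contributes
        its depth to all tip pairs split between different children.
        """
        n = self.n_tips
        C = np.zeros((n, n))
        node_depth: dict = {self._tree.seed_node: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is not self._tree.seed_node:
                node_depth[node] = node_depth[node.parent_node] + (node.edge.length or 0.0)
        tips_below: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                idx = np.array([self._index[node.taxon.label]])
                C[idx[0], idx[0]] = node_depth[node]
                tips_below[node] = idx
            else:
                child_sets = [tips_below.pop(ch) for ch in node.child_nodes()]
                d = node_depth[node]
                for a in range(len(child_sets)):
                    for b in range(a + 1, len(child_sets)):
                        C[np.ix_(child_sets[a], child_sets[b])] = d
                        C[np.ix_(child_sets[b], child_sets[a])] = d
                tips_below[node] = np.concatenate(child_sets)
        return C

    # -- branch bookkeeping -------------------------------------------
    def branch_table(self) -> BranchTable:
        """Enumerate branches with stable preorder ids (root edge excluded)."""
        n = self.n_tips
        t_start, t_end, parent, masks, term = [], [], [], [], []
        branch_of_node: dict = {}
        node_depth: dict = {self._tree.seed_node: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            depth = node_depth[node.parent_node] + (node.edge.length or 0.0)
            node_depth[node] = depth
            branch_of_node[node] = len(t_start)
            t_start.append(node_depth[node.parent_node])
            t_end.append(depth)
            parent.append(branch_of_node.get(node.parent_node, -1))
            masks.append(np.zeros(n, dtype=bool))
            term.append(node.is_leaf())
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                i = self._index[node.taxon.label]
                anc = node
                while anc is not self._tree.seed_node:
                    masks[branch_of_node[anc]][i] = True
                    anc = anc.parent_node
        return BranchTable(
            t_start=np.array(t_start),
            t_end=np.array(t_end),
            parent=np.array(parent, dtype=int),
            tip_mask=np.array(masks),
            is_terminal=np.array(term, dtype=bool),
        )

    # -- pruning -------------------------------------------------------
    def pruned_to(self, labels: Iterable[str]) -> "Phylogeny":
        keep = [l for l in self._labels if l in set(labels)]
        if not keep:
            raise EmptyOverlap("no tree tips match the requested labels")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(keep)
        # retain_taxa leaves degree-2 nodes behind; collapse them so the
        # pruned tree sums their branch lengths.
        clone.suppress_unifurcations()
        return Phylogeny(clone)

    def scaled_to_depth(self, depth: float = 1.0) -> "Phylogeny":
        """Return a copy with all branch lengths rescaled to a target depth."""
        factor = depth / self.depth()
        clone = self._tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        return Phylogeny(clone)


class TraitTable:
    """Species-by-trait matrix with optional per-species measurement error.

    Backed by a pandas DataFrame indexed by species label.  Measurement
    error variances (within-species variance of a species mean) live in
    companion columns named ``<trait>_me_var``.
    """

    ME_SUFFIX = "_me_var"

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            raise ParseError("duplicate species labels in trait table")
        me_cols = [c for c in frame.columns if c.endswith(self.ME_SUFFIX)]
        for c in me_cols:
            vals = frame[c].to_numpy(dtype=float)
            if np.any(vals < 0):
                raise ValueError(f"negative measurement-error variance in {c}")
        self._frame = frame

    # -- constructors -------------------------------------------------
    @classmethod
    def from_csv(cls, path, species_col: str = "species") -> "TraitTable":
        frame = pd.read_csv(path, comment="#")
        if species_col not in frame.columns:
            raise ParseError(f"trait table must contain a {species_col!r} column")
        return cls(frame.set_index(species_col))

    def to_csv(self, path) -> None:
        self._frame.to_csv(path, index_label="species")

    # -- access --------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def species(self) -> list[str]:
        return list(self._frame.index)

    @property
    def trait_columns(self) -> list[str]:
        return [c for c in self._frame.columns if not c.endswith(self.ME_SUFFIX)]

    def values(self, columns: Sequence[str]) -> np.ndarray:
        sub = self._frame[list(columns)]
        if sub.isna().any().any():
            raise ValueError(f"missing values in analysed columns {list(columns)}")
        return sub.to_numpy(dtype=float)

    def me_variance(self, column: str) -> np.ndarray | None:
        me_col = column + self.ME_SUFFIX
        if me_col not in self._frame.columns:
            return None
        return self._frame[me_col].to_numpy(dtype=float)

    def reordered(self, species: Sequence[str]) -> "TraitTable":
        missing = [s for s in species if s not in self._frame.index]
        if missing:
            raise KeyError(f"species absent from trait table: {missing}")
        return TraitTable(self._frame.loc[list(species)])

    def with_column(self, name: str, values) -> "TraitTable":
        frame = self._frame.copy()
        frame[name] = np.asarray(values, dtype=float)
        return TraitTable(frame)

    def log_transformed(self, columns: Sequence[str]) -> "TraitTable":
        """Natural-log transform of the given columns (new table)."""
        frame = self._frame.copy()
        for c in columns:
            vals = frame[c].to_numpy(dtype=float)
            if np.any(vals <= 0):
                raise ValueError(f"column {c!r} must be strictly positive to log-transform")
            frame[c] = np.log(vals)
        return TraitTable(frame)

    def __len__(self) -> int:
        return len(self._frame)


def read_newick(path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths."""
    with open(path) as fh:
        return Phylogeny.from_newick(fh.read())


def prune_to_overlap(tree: Phylogeny, table: TraitTable) -> tuple[Phylogeny, TraitTable]:
    """Restrict tree and table to their shared species, in tip order."""
    shared = [l for l in tree.tip_labels if l in set(table.species)]
    if not shared:
        raise EmptyOverlap("tree and trait table share no species labels")
    pruned = tree if len(shared) == tree.n_tips else tree.pruned_to(shared)
    return pruned, table.reordered(pruned.tip_labels)


def phylo_vcv(tree: Phylogeny) -> np.ndarray:
    """Brownian-motion phylogenetic covariance matrix (see Phylogeny.vcv)."""
    return tree.vcv()


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda rescaling: off-diagonals times lambda, diagonal kept."""
    if not 0.0 <= lam <= 1.0:
        raise LambdaOutOfRange(f"lambda must lie in [0, 1], got {lam!r}")
    out = lam * np.asarray(C, dtype=float)
    np.fill_diagonal(out, np.diag(C))
    return out
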