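"""Phylogeny handling: newick I/O, cophenetic and covariance matrices, pruning.

A :class:`Phylogeny` wraps a rooted :class:`dendropy.Tree` and exposes the
tree algebra every downstream analysis consumes: the cophenetic distance
matrix (path-length sums between tips), the trait variance--covariance
matrix under Brownian motion (shared root-to-MRCA path lengths), an
ultrametricity check, and induced-subtree extraction.

Branch lengths are treated as opaque units (substitutions per site or
time); all derived quantities inherit them.  A length attached to the root
edge is dropped with a warning: it would add a constant to every entry of
the covariance matrix without any standard interpretation.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "DistanceMatrix",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
]


class NewickParseError(ValueError):
    """Raised when a newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


@dataclass
class DistanceMatrix:
    """A labelled symmetric matrix over species.

    Used both for cophenetic distances (zero diagonal) and for
    phylogenetic covariance matrices (positive diagonal = root-to-tip
    depth); ``kind`` records which.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "distance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix is not symmetric")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, labels) -> "DistanceMatrix":
        """Restriction to ``labels`` (order preserved as given)."""
        labels = list(labels)
        missing = [s for s in labels if s not in self._index]
        if missing:
            raise KeyError(f"labels not in matrix: {missing}")
        idx = [self._index[s] for s in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


class Phylogeny:
    """A rooted phylogeny with branch lengths and uniquely labelled tips."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            if "Duplicate taxon labels" in str(exc):
                raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
            raise NewickParseError(f"malformed newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        out = io.StringIO()
        self._tree.write(
            file=out,
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
        )
        return out.getvalue().strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        labels = [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        root = self._tree.seed_node
        if root.edge.length:
            warnings.warn(
                "root edge length ignored (adds an uninterpretable constant "
                "to the covariance matrix)",
                stacklevel=3,
            )
            root.edge.length = None
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            bl = node.edge.length
            if bl is None:
                node.edge.length = 0.0
            elif bl < 0:
                raise TreeValidationError(
                    f"negative branch length {bl} above {node}"
                )
        self._tip_labels = [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    # -- basic accessors ----------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def __len__(self) -> int:
        return self.n_tips

    # -- tree algebra -------------------------------------------------

    def _depths(self) -> dict:
        """Root-to-node path length for every node."""
        depths = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        return depths

    def vcv_matrix(self) -> DistanceMatrix:
        """Brownian-motion trait covariance: C[i,j] = depth of MRCA(i,j).

        The diagonal is the root-to-tip depth.  Computed in one postorder
        sweep: an internal node at depth h is the MRCA of every tip pair
        split across its children.
        """
        labels = self._tip_labels
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        C = np.zeros((n, n))
        depths = self._depths()
        tipsets: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                tipsets[node] = [idx[node.taxon.label]]
                C[tipsets[node][0], tipsets[node][0]] = depths[node]
            else:
                children = [tipsets.pop(c) for c in node.child_nodes()]
                h = depths[node]
                for a in range(len(children)):
                    for b in range(a + 1, len(children)):
                        for i in children[a]:
                            for j in children[b]:
                                C[i, j] = C[j, i] = h
                tipsets[node] = [i for ch in children for i in ch]
        return DistanceMatrix(labels, C, kind="covariance")

    def cophenetic_matrix(self) -> DistanceMatrix:
        """Pairwise path-length distances between tips.

        Derived from the covariance matrix through the identity
        d(i,j) = C[i,i] + C[j,j] - 2 C[i,j].
        """
        C = self.vcv_matrix()
        diag = np.diag(C.values)
        d = diag[:, None] + diag[None, :] - 2 * C.values
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(C.labels, d, kind="distance")

    def is_ultrametric(self, rel_tol: float = 1e-6) -> tuple[bool, float]:
        """Whether all tips are (numerically) equidistant from the root.

        Returns ``(flag, T)`` with ``T`` the mean root-to-tip depth.
        Sequence-derived trees are never exactly ultrametric, hence the
        relative tolerance.
        """
        depths = self._depths()
        tip_depths = np.array(
            [depths[leaf] for leaf in self._tree.leaf_node_iter()]
        )
        T = float(tip_depths.mean())
        if len(tip_depths) == 1:
            return True, T
        spread = tip_depths.max() - tip_depths.min()
        return bool(spread <= rel_tol * tip_depths.max()), T

    @property
    def height(self) -> float:
        return self.is_ultrametric()[1]

    def prune(self, keep) -> "Phylogeny":
        """Induced subtree on ``keep``; pairwise tip distances are preserved.

        Degree-2 internal nodes created by the restriction are suppressed
        with their edge lengths summed.
        """
        keep = list(dict.fromkeys(keep))
        unknown = [s for s in keep if s not in set(self._tip_labels)]
        if unknown:
            raise KeyError(f"species not in tree: {sorted(unknown)}")
        if len(keep) < 2:
            raise ValueError("prune requires at least 2 tips to keep")
        clone = dendropy.Tree(self._tree)
        taxa = [t for t in clone.taxon_namespace if t.label in set(keep)]
        clone.retain_taxa(taxa, suppress_unifurcations=True)
        # retain_taxa can leave a unifurcate root; fold it into the child edge
        root = clone.seed_node
        while len(root.child_nodes()) == 1 and not root.is_leaf():
            child = root.child_nodes()[0]
            child.edge.length = None  # becomes new root edge; dropped
            clone.seed_node = child
            child.parent_node = None
            root = child
        return Phylogeny(clone)


def parse_newick(text: str) -> Phylogeny:
    """Parse a newick string into a validated :class:`Phylogeny`."""
    return Phylogeny.from_newick(text)
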