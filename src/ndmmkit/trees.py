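"""Rooted phylogenies as flat arrays, plus tree utilities.

Trees are parsed with dendropy and converted to an index-based
representation (parent pointers, child lists, branch lengths, postorder)
that the likelihood, stochastic-mapping and signal statistics operate on.
Tips occupy indices ``0..n_tips-1`` in sorted-label order; internal nodes
follow in postorder, with the root last. This layout makes the recursive
passes simple array loops and keeps every computation deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny", "read_newick", "UltrametricityWarning"]


class UltrametricityWarning(UserWarning):
    """Input tree is not ultrametric within tolerance."""


@dataclass
class Phylogeny:
    """A rooted tree over named tips with branch lengths in time units.

    ``clades`` optionally names disjoint tip sets (e.g. the four major
    ingroup clades plus an outgroup).
    """

    tip_labels: tuple[str, ...]
    parent: np.ndarray  # int, -1 at root
    children: tuple[tuple[int, ...], ...]
    edge_length: np.ndarray  # float, 0.0 at root
    postorder: np.ndarray  # int, internal nodes only, root last
    clades: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.edge_length < 0).any():
            raise ValueError("negative branch length")
        seen: set[str] = set()
        for name, tips in self.clades.items():
            overlap = seen & set(tips)
            if overlap:
                raise ValueError(
                    f"clade {name!r} overlaps earlier clades: {overlap}"
                )
            seen |= set(tips)
            unknown = set(tips) - set(self.tip_labels)
            if unknown:
                raise ValueError(f"clade {name!r} has unknown tips {unknown}")

    # -- basic structure --------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def tip_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.tip_labels)}

    def is_binary(self) -> bool:
        return all(
            len(ch) == 2 for ch in self.children if len(ch) > 0
        )

    # -- depths and distances ---------------------------------------------
    def node_depths(self) -> np.ndarray:
        """Distance of every node from the root."""
        depth = np.zeros(self.n_nodes)
        for node in self.postorder[::-1]:  # preorder
            for c in self.children[node]:
                depth[c] = depth[node] + self.edge_length[c]
        return depth

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        """All tip depths equal within a relative spread tolerance."""
        d = self.node_depths()[: self.n_tips]
        dmax = d.max()
        if dmax == 0:
            return True
        return (d.max() - d.min()) / dmax < rel_tol

    def check_ultrametric(self, rel_tol: float = 1e-6) -> None:
        if not self.is_ultrametric(rel_tol):
            warnings.warn(
                "tree is not ultrametric; time-scaled analyses (Brownian "
                "nulls) assume equal tip depths",
                UltrametricityWarning,
                stacklevel=2,
            )

    def mrca(self, tips: Sequence[str]) -> int:
        """Index of the most recent common ancestor of the named tips."""
        idx = self.tip_index
        nodes = [idx[t] for t in tips]
        if not nodes:
            raise ValueError("empty tip set")
        # ancestor paths to root
        paths = []
        for node in nodes:
            path = []
            while node != -1:
                path.append(node)
                node = int(self.parent[node])
            paths.append(set(path))
        common = set.intersection(*paths)
        depths = self.node_depths()
        return max(common, key=lambda n: depths[n])

    def clade_mrcas(self) -> dict[str, int]:
        return {name: self.mrca(tips) for name, tips in self.clades.items()}

    def patristic_distances(self) -> np.ndarray:
        """Symmetric tip-to-tip path-length matrix (cophenetic distances).

        ``d(i, j) = depth(i) + depth(j) - 2 * depth(mrca(i, j))``, computed
        by accumulating, at every internal node, the tip pairs for which it
        is the MRCA.
        """
        n = self.n_tips
        depths = self.node_depths()
        dist = np.zeros((n, n))
        # tips under each node, accumulated in postorder
        under: dict[int, np.ndarray] = {
            i: np.array([i]) for i in range(n)
        }
        for node in self.postorder:
            groups = [under.pop(c) for c in self.children[node]]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ii = groups[a][:, None]
                    jj = groups[b][None, :]
                    d = depths[ii] + depths[jj] - 2 * depths[node]
                    dist[ii, jj] = d
                    dist[jj.T, ii.T] = d.T
            under[node] = np.concatenate(groups)
        return dist

    # -- parsimony ---------------------------------------------------------
    def fitch_score(self, states: np.ndarray) -> int:
        """Minimum number of binary-state changes (Fitch parsimony)."""
        sets = [None] * self.n_nodes
        for i in range(self.n_tips):
            sets[i] = {int(states[i])}
        score = 0
        for node in self.postorder:
            inter = set.intersection(*(sets[c] for c in self.children[node]))
            if inter:
                sets[node] = inter
            else:
                sets[node] = set.union(
                    *(sets[c] for c in self.children[node])
                )
                score += 1
        return score

    # -- construction and serialisation -------------------------------------
    @classmethod
    def from_dendropy(
        cls,
        tree: dendropy.Tree,
        clades: Optional[Mapping[str, Sequence[str]]] = None,
    ) -> "Phylogeny":
        tips = sorted(
            (leaf for leaf in tree.leaf_node_iter()),
            key=lambda leaf: leaf.taxon.label,
        )
        labels = tuple(leaf.taxon.label for leaf in tips)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        index: dict[int, int] = {id(leaf): i for i, leaf in enumerate(tips)}
        internal = [
            nd for nd in tree.postorder_node_iter() if not nd.is_leaf()
        ]
        for k, nd in enumerate(internal):
            index[id(nd)] = len(labels) + k
        n_nodes = len(labels) + len(internal)
        parent = np.full(n_nodes, -1, dtype=int)
        edge = np.zeros(n_nodes)
        children: list[tuple[int, ...]] = [() for _ in range(n_nodes)]
        for nd in tree.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    raise ValueError(
                        "missing branch length in input tree"
                    )
                parent[i] = index[id(nd.parent_node)]
                edge[i] = float(nd.edge.length)
            if not nd.is_leaf():
                children[i] = tuple(
                    index[id(c)] for c in nd.child_nodes()
                )
        post = np.array(
            [index[id(nd)] for nd in internal], dtype=int
        )
        return cls(
            tip_labels=labels,
            parent=parent,
            children=tuple(children),
            edge_length=edge,
            postorder=post,
            clades={
                k: tuple(v) for k, v in (clades or {}).items()
            },
        )

    @classmethod
    def from_newick(
        cls,
        newick: str,
        clades: Optional[Mapping[str, Sequence[str]]] = None,
    ) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except dendropy.utility.error.DataParseError as exc:
            raise ValueError(f"invalid Newick input: {exc}") from exc
        return cls.from_dendropy(tree, clades)

    def prune_to(self, labels: Sequence[str]) -> "Phylogeny":
        """Restrict the tree to the given tips, merging unifurcations.

        Branch lengths along collapsed paths are summed, so patristic
        distances among the retained tips are preserved.
        """
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValueError(f"cannot retain unknown tips {missing}")
        if len(keep) < 2:
            raise ValueError("need at least 2 tips after pruning")
        tree = dendropy.Tree.get(
            data=self.to_newick(), schema="newick",
            preserve_underscores=True,
        )
        tree.retain_taxa_with_labels(sorted(keep))
        clades = {
            name: tuple(t for t in tips if t in keep)
            for name, tips in self.clades.items()
        }
        clades = {k: v for k, v in clades.items() if v}
        return Phylogeny.from_dendropy(tree, clades)

    def to_newick(self) -> str:
        """Newick string with branch lengths (deterministic rendering)."""

        def render(node: int) -> str:
            if node < self.n_tips:
                body = self.tip_labels[node]
            else:
                body = (
                    "("
                    + ",".join(render(c) for c in self.children[node])
                    + ")"
                )
            if self.parent[node] == -1:
                return body
            return f"{body}:{self.edge_length[node]:.10g}"

        return render(self.root) + ";"


def read_newick(
    path: str | Path,
    clades: Optional[Mapping[str, Sequence[str]]] = None,
    warn_non_ultrametric: bool = True,
) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths from a file.

    Duplicate tip labels and missing branch lengths are errors; a
    non-ultrametric tree triggers :class:`UltrametricityWarning` (analyses
    still run, but Brownian nulls assume time-scaling).
    """
    with open(path, encoding="utf-8") as fh:
        phy = Phylogeny.from_newick(fh.read(), clades)
    if warn_non_ultrametric:
        phy.check_ultrametric()
    return phy
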