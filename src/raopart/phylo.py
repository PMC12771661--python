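"""Phylogeny handling: Newick I/O, cophenetic distances, unit scaling.

The phylogenetic facet of Rao's quadratic entropy needs a species-by-species
dissimilarity matrix. Here that matrix is the cophenetic distance — the sum
of branch lengths along the path between two tips — rescaled to [0, 1] so
that phylogenetic and taxonomic diversity share a common scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .matrices import DissimilarityMatrix

__all__ = [
    "Phylogeny",
    "read_newick",
    "write_newick",
    "cophenetic_distances",
    "scale_unit",
]

logger = logging.getLogger(__name__)


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths whose tips index a species pool.

    Wraps a :class:`dendropy.Tree`; construction validates the invariants
    the diversity pipeline relies on (unique non-empty tip labels, no
    missing or negative branch lengths). Polytomies are accepted.
    """

    tree: dendropy.Tree = field(repr=False)

    def __post_init__(self) -> None:
        tips = self.tips
        if any(not t for t in tips):
            raise ValueError("empty tip label in tree")
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ValueError(f"duplicate tip labels in tree: {dupes}")
        if self.tree.is_rooted is False:
            raise ValueError("tree is explicitly unrooted; a rooted tree is required")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue  # root edge may legitimately lack a length
            if edge.length is None:
                raise ValueError("missing branch length on an edge")
            if edge.length < 0:
                raise ValueError("negative branch length")

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def depth_of(self, tip: str) -> float:
        """Sum of branch lengths from the root to ``tip``."""
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon.label == tip:
                return float(leaf.distance_from_root())
        raise KeyError(f"tip not in tree: {tip}")

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def prune_to(self, tips: list[str]) -> "Phylogeny":
        """Return a copy restricted to ``tips`` (labels must exist)."""
        missing = sorted(set(tips) - set(self.tips))
        if missing:
            raise KeyError(f"tips absent from tree: {missing}")
        clone = self.tree.clone(depth=1)
        keep = [t for t in clone.taxon_namespace if t.label in set(tips)]
        clone.retain_taxa(keep)
        return Phylogeny(clone)


def read_newick(path: str | Path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths on every edge.

    A Newick string without an explicit ``[&U]`` rooting comment is taken
    as rooted. Missing branch lengths, duplicate tip labels, and malformed
    Newick all raise ``ValueError``.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            rooting="default-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    return Phylogeny(tree)


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (same validation as :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="default-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def write_newick(phy: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(phy.as_newick() + "\n")


def cophenetic_distances(phy: Phylogeny) -> DissimilarityMatrix:
    """Tip-to-tip path-length (cophenetic) distance matrix.

    Entry (i, j) is the sum of branch lengths along the unique path
    between tips i and j; the diagonal is zero. Requires >= 2 tips.
    """
    tips = phy.tips
    if len(tips) < 2:
        raise ValueError("cophenetic distances need at least 2 tips")
    pdm = phy.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in phy.tree.taxon_namespace if t.label in set(tips)}
    n = len(tips)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[tips[i]], taxa[tips[j]])
    return DissimilarityMatrix(tips, d)


def scale_unit(dm: DissimilarityMatrix) -> DissimilarityMatrix:
    """Divide every entry by the global maximum so the largest becomes 1.

    An all-zero matrix is returned unchanged with a warning: there is no
    scale to normalise.
    """
    mx = float(dm.values.max()) if dm.size else 0.0
    if mx == 0.0:
        warnings.warn("all-zero dissimilarity matrix; unit scaling is a no-op")
        logger.warning("scale_unit: all-zero matrix left unchanged")
        return DissimilarityMatrix(list(dm.labels), dm.values.copy())
    return DissimilarityMatrix(list(dm.labels), dm.values / mx)
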