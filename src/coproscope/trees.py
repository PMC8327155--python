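"""Time-calibrated phylogenetic trees.

A calibrated tree is a rooted, leaf-labelled, ultrametric tree whose node
ages (time before present) are derived from branch lengths: every leaf sits
at age 0 and the root age equals the (common) root-to-tip path length.  The
type underlies both the bacterial 16S tree that BDTT slices and the host
mitogenomic tree whose cophenetic distances serve as the phylogeny factor.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import skbio
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "CalibratedTree",
    "UltrametricityError",
    "read_calibrated_tree",
    "cophenetic_distances",
    "CalibrationSet",
    "DEFAULT_CALIBRATION_GROUPS",
]

#: Relative tolerance on the root-to-tip spread accepted as "ultrametric".
ULTRAMETRIC_RTOL = 1e-6


class UltrametricityError(ValueError):
    """Raised when tip-to-root path lengths disagree beyond tolerance."""


@dataclass
class CalibratedTree:
    """Rooted ultrametric tree with node ages.

    Parameters
    ----------
    tree : skbio.TreeNode
        Rooted tree with branch lengths; tip names must be unique.

    Attributes
    ----------
    depth : float
        Root age (maximum root-to-tip distance; all tips are within
        tolerance of it).
    ages : dict
        Maps every node (by identity) to its age before present.
    """

    tree: TreeNode
    depth: float = field(init=False)
    ages: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        tips = list(self.tree.tips())
        if not tips:
            # single-node "tree": treat the root itself as a leaf
            tips = [self.tree]
        names = [t.name for t in tips]
        if any(n is None for n in names):
            raise ValueError("all leaves must be labelled")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")

        # root-to-tip distances; ultrametricity check
        dists = {}
        for node in self.tree.preorder(include_self=True):
            length = node.length or 0.0 if node is not self.tree else 0.0
            dists[id(node)] = (dists[id(node.parent)] + length
                               if node.parent is not None else 0.0)
        tip_depths = np.array([dists[id(t)] for t in tips])
        depth = float(tip_depths.max())
        spread = float(tip_depths.max() - tip_depths.min())
        if depth > 0 and spread > ULTRAMETRIC_RTOL * depth:
            offending = [t.name for t, d in zip(tips, tip_depths)
                         if abs(d - depth) > ULTRAMETRIC_RTOL * depth]
            raise UltrametricityError(
                f"tree is not ultrametric: root-to-tip spread {spread:g} "
                f"exceeds tolerance; offending tips: {offending}")
        self.depth = depth
        self.ages = {id(n): depth - d for n, d in
                     ((n, dists[id(n)]) for n in
                      self.tree.preorder(include_self=True))}
        # snap float noise around zero so leaves sit exactly at age 0
        for k, v in self.ages.items():
            if abs(v) <= ULTRAMETRIC_RTOL * max(depth, 1.0):
                self.ages[k] = 0.0

    # -- basic queries -----------------------------------------------------

    @property
    def leaf_names(self) -> list[str]:
        tips = list(self.tree.tips())
        return [t.name for t in tips] if tips else [self.tree.name]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def age_of(self, node: TreeNode) -> float:
        return self.ages[id(node)]

    # -- serialisation -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "CalibratedTree":
        try:
            tree = TreeNode.read(_io.StringIO(newick), convert_underscores=False)
        except (skbio.io.FormatIdentificationError, Exception) as exc:
            if isinstance(exc, (ValueError, skbio.io.FileFormatError)):
                raise ValueError(f"malformed Newick: {exc}") from exc
            raise
        return cls(tree)

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- relabelling (leaf-shuffle null model) ------------------------------

    def with_shuffled_leaves(self, rng: np.random.Generator) -> "CalibratedTree":
        """Return a copy whose leaf labels are randomly permuted.

        Keeps the tree shape and branch lengths fixed; breaks the mapping
        between labels and phylogenetic position.
        """
        clone = self.tree.copy()
        tips = list(clone.tips())
        names = [t.name for t in tips]
        perm = rng.permutation(len(names))
        for tip, j in zip(tips, perm):
            tip.name = names[j]
        return CalibratedTree(clone)


def read_calibrated_tree(path) -> CalibratedTree:
    """Read a Newick file with branch lengths into a :class:`CalibratedTree`.

    Node ages are computed from root-to-tip sums; a tree whose tip depths
    spread beyond the relative tolerance is rejected with
    :class:`UltrametricityError` naming the offending tips.
    """
    with open(path) as fh:
        return CalibratedTree.from_newick(fh.read())


def cophenetic_distances(ctree: CalibratedTree) -> DistanceMatrix:
    """Patristic (cophenetic) distances between all leaf pairs.

    Entry (i, j) is the sum of branch lengths along the path between leaves
    i and j; on an ultrametric tree this is twice the age of their most
    recent common ancestor.
    """
    if ctree.n_leaves < 2:
        raise ValueError("cophenetic distances require at least 2 leaves")
    return ctree.tree.tip_tip_distances()


# ---------------------------------------------------------------------------
# External calibration sequence sets for divergence-time estimation
# ---------------------------------------------------------------------------

#: Group sizes of the external 16S rRNA sequences used to anchor divergence
#: times on the bacterial tree (removed again before any analysis).
DEFAULT_CALIBRATION_GROUPS = {
    "Cyanobacteria": 50,
    "Rickettsiales": 50,
    "Chlorobium": 15,
    "Chromatiales": 15,
}


@dataclass(frozen=True)
class CalibrationSet:
    """External calibration-sequence bookkeeping for tree dating.

    Records how many outgroup 16S sequences per taxonomic group are added to
    the alignment purely to carry fossil/biomarker age calibrations; they are
    stripped before downstream analyses, so only the counts matter here.
    """

    groups: dict = field(default_factory=lambda: dict(DEFAULT_CALIBRATION_GROUPS))

    def __post_init__(self):
        for name, n in self.groups.items():
            if not (isinstance(n, (int, np.integer)) and n >= 0):
                raise ValueError(f"calibration group {name!r}: count must be "
                                 f"a non-negative integer, got {n!r}")

    @property
    def total(self) -> int:
        """Total number of external calibration sequences."""
        return int(sum(self.groups.values()))
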