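"""Synthetic-data generators with the statistical structure the analyses assume.

Four generators, each a pure function of a frozen spec (seed included):

* random ultrametric bacterial/host trees,
* host-by-taxon presence/abundance tables carrying a *planted phylogenetic
  scale disparity* — taxa inside young clades co-occur according to host
  phylogenetic distance, while deep clades are occupied according to host
  ecological group (wolf / dog / ancient-intermediate), so that slicing the
  tree through time should recover a phylogeny signal at young ages and an
  ecology signal at old ages,
* ancient-DNA read records with exponentially decaying 5' C→T damage,
* Poisson read counts over a target gene region and control windows at a
  known true copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .authenticity import N_POSITIONS, ReadRecord
from .copynumber import RegionCounts
from .hosts import HostMeta
from .trees import CalibratedTree, cophenetic_distances

__all__ = [
    "CommunitySimSpec",
    "DamageSimSpec",
    "CoverageSimSpec",
    "simulate_calibrated_tree",
    "simulate_community",
    "simulate_scenario",
    "simulate_reads",
    "simulate_coverage",
]


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_calibrated_tree(n_taxa: int, depth: float, seed,
                             prefix: str = "t") -> CalibratedTree:
    """Random ultrametric tree with root age exactly ``depth``.

    Built by sequential random pair-merging (uniform random joins give the
    Yule labelled-history topology); the n-1 merge ages are sorted uniforms
    on (0, depth) with the final merge pinned at ``depth``.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    width = len(str(n_taxa))
    clusters = [(f"{prefix}{i + 1:0{width}d}", 0.0) for i in range(n_taxa)]
    if n_taxa == 2:
        ages = np.array([depth])
    else:
        ages = np.append(np.sort(rng.uniform(0, depth, size=n_taxa - 2)), depth)
    for t in ages:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (nwk_i, age_i), (nwk_j, age_j) = clusters[i], clusters[j]
        merged = (f"({nwk_i}:{t - age_i:.17g},{nwk_j}:{t - age_j:.17g})", t)
        clusters[i] = merged
        clusters.pop(j)
    return CalibratedTree.from_newick(clusters[0][0] + ";")


# ---------------------------------------------------------------------------
# Host-structured communities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunitySimSpec:
    """Scenario for a host-structured synthetic community.

    Group sizes default to the study design (4 wolves, 5 modern dogs, 1
    ancient sample).  ``phylo_cutoff`` marks the clade age below which taxon
    occurrence tracks host phylogenetic distance (strength
    ``phylo_strength``); deep clades older than ``eco_cutoff`` are occupied
    according to host group (strength ``eco_strength``); everything else
    occurs i.i.d. at ``baseline``.
    """

    n_wolves: int = 4
    n_dogs: int = 5
    n_ancient: int = 1
    n_taxa: int = 160
    tree_depth: float = 1000.0
    phylo_cutoff: float = 150.0
    phylo_strength: float = 0.8
    eco_cutoff: float = 500.0
    eco_strength: float = 0.8
    eco_taxa_fraction: float = 0.35
    baseline: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if min(self.n_wolves, self.n_dogs) < 1 or self.n_ancient < 0:
            raise ValueError("wolf and dog groups must be non-empty")
        for name in ("phylo_strength", "eco_strength", "baseline"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("phylo_cutoff", "eco_cutoff"):
            v = getattr(self, name)
            if not (0.0 < v < self.tree_depth):
                raise ValueError(f"{name} must lie within (0, tree depth)")

    @property
    def n_hosts(self) -> int:
        return self.n_wolves + self.n_dogs + self.n_ancient

    def host_meta(self) -> list[HostMeta]:
        meta = [HostMeta(f"wolf{i + 1}", "wolf") for i in range(self.n_wolves)]
        meta += [HostMeta(f"dog{i + 1}", "dog") for i in range(self.n_dogs)]
        meta += [HostMeta(f"ancient{i + 1}", "ancient")
                 for i in range(self.n_ancient)]
        return meta


def _clades_at(tree: CalibratedTree, age: float) -> list[list[str]]:
    """Leaf sets of the clades the tree's lineages occupy at ``age``."""
    out = []
    for node in tree.tree.preorder(include_self=True):
        parent_age = (tree.age_of(node.parent) if node.parent is not None
                      else np.inf)
        if tree.age_of(node) <= age < parent_age:
            tips = [t.name for t in node.tips()] or [node.name]
            out.append(tips)
    return out


def simulate_community(tree: CalibratedTree, host_tree: CalibratedTree,
                       spec: CommunitySimSpec,
                       ) -> tuple[pd.DataFrame, list[HostMeta]]:
    """Presence-structured abundance table over the given bacterial tree.

    ``host_tree`` tip labels must be exactly the spec's host ids
    (wolfK/dogK/ancientK).  Deep clades (older than ``eco_cutoff``, >= 2
    tips) are alternately assigned a
    wolf or dog preference; a preferred host carries the clade with high
    probability and then holds a random half of its member taxa.  Taxa
    outside deep ecology clades get, with probability ``phylo_strength``, an
    occurrence profile decaying with host phylogenetic distance from a
    random focal host, and otherwise occur i.i.d. at ``baseline``.
    Occupied cells receive log-series abundances.
    """
    rng = np.random.default_rng(spec.seed)
    meta = spec.host_meta()
    host_ids = [m.host_id for m in meta]
    if set(host_tree.leaf_names) != set(host_ids):
        raise ValueError("host tree tip labels must equal the spec's "
                         "host ids")
    dh = cophenetic_distances(host_tree).filter(host_ids).data
    dh = dh / dh.max() if dh.max() > 0 else dh
    groups = np.array([m.group for m in meta])

    taxa = list(tree.leaf_names)
    tax_idx = {t: k for k, t in enumerate(taxa)}
    presence = np.zeros((len(host_ids), len(taxa)), dtype=bool)

    # --- deep ecology clades -------------------------------------------
    # mid-sized deep clades are recruited until ~1/3 of all taxa sit in an
    # ecology clade (clades above 20% of the tree are passed over so the
    # group signal is spread across several deep units); the rest of the
    # tree carries the phylogeny signal
    cap = max(2, int(0.2 * len(tree.leaf_names)))
    deep = [] if spec.eco_strength == 0 else \
        sorted((c for c in _clades_at(tree, spec.eco_cutoff)
                if 2 <= len(c) <= cap), key=len, reverse=True)
    eco_taxa: set[str] = set()
    eco_clades = []
    for clade in deep:
        if len(eco_taxa) >= spec.eco_taxa_fraction * len(tree.leaf_names):
            break
        eco_clades.append(clade)
        eco_taxa.update(clade)
    prefs = ["wolf", "dog"]
    for k, clade in enumerate(eco_clades):
        pref = prefs[k % 2]
        p_pref = spec.eco_strength * 0.95 + (1 - spec.eco_strength) * 0.5
        p_off = spec.eco_strength * 0.05 + (1 - spec.eco_strength) * 0.5
        for h in range(len(host_ids)):
            if groups[h] == "ancient":
                p_present = 0.5 * (p_pref + p_off)
            elif groups[h] == pref:
                p_present = p_pref
            else:
                p_present = p_off
            if rng.random() < p_present:
                # a host carrying the clade holds a random subset of its
                # members: the group signal lives at the clade level and is
                # diluted by fill noise at the tip level
                member_idx = [tax_idx[t] for t in clade]
                fill = rng.random(len(member_idx)) < 0.35
                if not fill.any():
                    fill[rng.integers(len(member_idx))] = True
                presence[h, np.array(member_idx)[fill]] = True

    # --- tip-level phylogeny taxa and baseline noise --------------------
    # occurrence probability falls off linearly with host distance from a
    # random focal host (0.95 at the focal host down to 0.05 at the
    # farthest); strength 0 degrades continuously to i.i.d.
    # Bernoulli(baseline)
    s = spec.phylo_strength
    for t in taxa:
        if t in eco_taxa:
            continue
        focal = rng.integers(len(host_ids))
        affinity = 0.05 + 0.9 * (1.0 - dh[focal])
        p = (1 - s) * spec.baseline + s * affinity
        presence[:, tax_idx[t]] = rng.random(len(host_ids)) < p

    # --- abundances ------------------------------------------------------
    counts = np.zeros_like(presence, dtype=int)
    n_occupied = int(presence.sum())
    if n_occupied:
        counts[presence] = rng.logseries(0.9, size=n_occupied)
    table = pd.DataFrame(counts, index=host_ids, columns=taxa)
    return table, meta


def simulate_scenario(spec: CommunitySimSpec,
                      ) -> tuple[CalibratedTree, CalibratedTree,
                                 pd.DataFrame, list[HostMeta]]:
    """Generate bacterial tree, host tree, and community for one spec.

    Host-tree tips are relabelled to the host ids in a seed-determined
    random order, so group membership is unconfounded with host phylogeny
    by construction.
    """
    ss = np.random.SeedSequence(spec.seed)
    s_bact, s_host, s_assign, s_comm = (int(s.generate_state(1)[0] % 2**31)
                                        for s in ss.spawn(4))
    tree = simulate_calibrated_tree(spec.n_taxa, spec.tree_depth, s_bact)
    host_tree = simulate_calibrated_tree(spec.n_hosts, 1.0, s_host,
                                         prefix="h")
    host_ids = [m.host_id for m in spec.host_meta()]
    rng = np.random.default_rng(s_assign)
    order = rng.permutation(spec.n_hosts)
    relabelled = host_tree.tree.copy()
    for k, t in enumerate(relabelled.tips()):
        t.name = host_ids[order[k]]
    host_tree = CalibratedTree(relabelled)
    table, meta = simulate_community(
        tree, host_tree,
        CommunitySimSpec(**{**spec.__dict__, "seed": s_comm}))
    return tree, host_tree, table, meta


# ---------------------------------------------------------------------------
# Damaged reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DamageSimSpec:
    """Ancient-DNA read simulation: 5' C→T damage decaying into the read.

    Position-1 excess C→T probability ``p0`` decays as exp(-lam*(i-1));
    every base additionally mismatches at ``baseline``.  ``ancient_fraction``
    mixes in undamaged (modern) reads.
    """

    n_reads: int = 10000
    mean_length: float = 65.0
    sd_length: float = 15.0
    p0: float = 0.2
    lam: float = 0.4
    baseline: float = 0.01
    ancient_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("p0", "baseline", "ancient_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.lam <= 0:
            raise ValueError("decay rate lam must be positive")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


_BASES = np.array(list("ACGT"))


def simulate_reads(spec: DamageSimSpec) -> list[ReadRecord]:
    """Draw read records with per-position 5' mismatch codes."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_reads
    lengths = np.clip(rng.normal(spec.mean_length, spec.sd_length, n),
                      30, 150).astype(int)
    ancient = rng.random(n) < spec.ancient_fraction
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    pos = np.arange(N_POSITIONS)
    damage_p = spec.p0 * np.exp(-spec.lam * pos) + spec.baseline

    # reference bases at the first 10 positions (uniform over ACGT)
    refs = _BASES[rng.integers(0, 4, size=(n, N_POSITIONS))]
    u = rng.random((n, N_POSITIONS))
    is_c = refs == "C"
    p_mm = np.where(is_c & ancient[:, None], damage_p[None, :], spec.baseline)
    mism = u < p_mm

    reads = []
    for k in range(n):
        codes = []
        for i in range(N_POSITIONS):
            ref = refs[k, i]
            if mism[k, i]:
                if ref == "C":
                    alt = "T"   # deamination-dominated
                else:
                    alt = rng.choice([b for b in "ACGT" if b != ref])
                codes.append(ref + alt)
            else:
                codes.append(ref + ref)
        n5 = int(mism[k].sum())
        rest = int(rng.binomial(max(lengths[k] - N_POSITIONS, 0),
                                spec.baseline))
        reads.append(ReadRecord(length=int(lengths[k]),
                                strand=str(strands[k]),
                                five_prime=codes,
                                edit_distance=n5 + rest,
                                ancient=bool(ancient[k])))
    return reads


# ---------------------------------------------------------------------------
# Region coverage for copy-number estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageSimSpec:
    """Poisson read counts over a duplicated target region vs. diploid
    control windows, at known true copy numbers.

    Defaults mirror an amylase-style design: a ~7.5 kb target region and
    75 control windows of 1 kb; wolves carry the ancestral diploid copy
    number 2, modern dogs an expanded 8, the ancient sample 2.
    """

    copy_numbers: dict = field(default_factory=lambda: {
        **{f"wolf{i + 1}": ("wolf", 2) for i in range(4)},
        **{f"dog{i + 1}": ("dog", 8) for i in range(5)},
        "ancient1": ("ancient", 2),
    })
    per_copy_depth: float = 0.02      # reads per bp per gene copy
    target_length: int = 7525
    control_windows: int = 75
    window_length: int = 1000
    seed: int = 0

    def __post_init__(self):
        for host, (group, cn) in self.copy_numbers.items():
            if not (isinstance(cn, (int, np.integer)) and cn >= 1):
                raise ValueError(f"{host}: copy number must be an integer >= 1")
        if self.per_copy_depth <= 0:
            raise ValueError("per-copy depth must be positive")


def simulate_coverage(spec: CoverageSimSpec) -> list[RegionCounts]:
    rng = np.random.default_rng(spec.seed)
    control_len = spec.control_windows * spec.window_length
    out = []
    for host, (group, cn) in spec.copy_numbers.items():
        target = int(rng.poisson(cn * spec.per_copy_depth * spec.target_length))
        control = int(rng.poisson(2 * spec.per_copy_depth * control_len))
        out.append(RegionCounts(host_id=host, group=group,
                                target_reads=target, control_reads=control,
                                target_length=spec.target_length,
                                control_length=control_len))
    return out
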