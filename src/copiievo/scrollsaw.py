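"""Taxon-sampling reduction and ancient-paralog counting.

The workflow mirrors how deep paralogies in large gene families are resolved
when only short regions of homology align well: align everything once, trim,
break the alignment into supergroup-specific data sets (keeping the master
columns so every analysis sees the same sites), infer per-supergroup trees,
detect supported clades (>= 2 sequences from >= 2 organisms, support above
the per-method thresholds: posterior 0.8, bootstrap 50), retain the two
shortest branches of each clade as surrogates, and re-analyze the combined
pan-eukaryotic surrogate set.  Clades of the pan-eukaryotic tree that span
two or more supergroups are evidence for paralogs already present in the
LECA.

Unrooted trees are analyzed on bipartitions: both sides of every internal
edge are candidate clades, carrying that edge's support.  A clade counted as
a single ancient paralog may contain at most one sequence per organism
(``max_per_taxon=1``): a clade that conflates two ancient paralogs almost
surely repeats an organism, which is what the iterative pruning experiments
resolve by hand.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .formats import PhyloTree, SequenceRecord, TreeNode
from .phylo import Msa, bootstrap_tree, distance_matrix, neighbor_joining

__all__ = [
    "SupergroupMap",
    "CladeCall",
    "SelectionReport",
    "DEFAULT_THRESHOLDS",
    "split_by_supergroup",
    "find_supported_clades",
    "select_surrogates",
    "assemble_pan_dataset",
    "prune_and_reanalyze",
    "count_ancient_clades",
    "AncientCladeResult",
]

DEFAULT_THRESHOLDS: dict[str, float] = {"posterior": 0.8, "bootstrap": 50.0}


# ---------------------------------------------------------------------------
# supergroup bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class SupergroupMap:
    """taxon -> supergroup assignment for one analysis."""

    mapping: dict[str, str]
    supergroups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.supergroups:
            seen: list[str] = []
            for sg in self.mapping.values():
                if sg not in seen:
                    seen.append(sg)
            self.supergroups = seen

    def __getitem__(self, taxon: str) -> str:
        return self.mapping[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.mapping

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "SupergroupMap":
        mapping: dict[str, str] = {}
        for r in records:
            mapping.setdefault(r.taxon, r.supergroup)
        return cls(mapping)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SupergroupMap":
        mapping: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            taxon, sg = line.split("\t")[:2]
            mapping[taxon] = sg
        return cls(mapping)


def split_by_supergroup(msa: Msa, sgmap: SupergroupMap) -> dict[str, Msa]:
    """Partition a trimmed master alignment into supergroup-specific subsets.

    Each subset keeps the master column mask untouched, so the sequence
    regions used in every downstream analysis are identical.  An unmapped
    taxon is a hard error; a single-sequence subset is emitted with a warning.
    """
    for rec in msa.records:
        if rec.taxon not in sgmap:
            raise ValueError(f"taxon {rec.taxon!r} is not mapped to a supergroup")
    out: dict[str, Msa] = {}
    for sg in sgmap.supergroups:
        rows = [r for r in msa.records if sgmap[r.taxon] == sg]
        if not rows:
            continue
        if len(rows) == 1:
            warnings.warn(f"supergroup {sg}: single sequence, unanalyzable", stacklevel=2)
        out[sg] = Msa(rows, msa.mask.copy())
    return out


# ---------------------------------------------------------------------------
# supported clades
# ---------------------------------------------------------------------------

@dataclass
class CladeCall:
    """A supported clade of one tree."""

    leaf_ids: frozenset
    supports: dict[str, float]
    organisms: frozenset
    supergroups: frozenset
    surrogates: list[str] = field(default_factory=list)
    declared: bool = False  # True for pass-through subsets too small to analyze

    def __post_init__(self) -> None:
        if len(self.leaf_ids) < 2:
            raise ValueError("a clade needs at least 2 leaves")
        if not set(self.surrogates) <= set(self.leaf_ids):
            raise ValueError("surrogates must be clade members")

    @property
    def size(self) -> int:
        return len(self.leaf_ids)


def default_taxon_of(leaf_id: str) -> str:
    """Simulator convention: sequence ids are ``<taxon>_<paralog>``."""
    return leaf_id.rsplit("_", 1)[0]


def _candidate_sides(tree: PhyloTree) -> list[tuple[frozenset, dict[str, float]]]:
    all_leaves = frozenset(tree.leaf_names())
    out: list[tuple[frozenset, dict[str, float]]] = []
    for node in tree.root.preorder():
        if node is tree.root or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.append((side, dict(node.supports)))
        if not tree.rooted:
            out.append((other, dict(node.supports)))
    return out


def _passes_support(supports: Mapping[str, float], thresholds: Mapping[str, float]) -> bool:
    available = [m for m in supports if m in thresholds]
    if not available:
        return False
    return all(supports[m] >= thresholds[m] for m in available)


def find_supported_clades(
    tree: PhyloTree,
    *,
    thresholds: Mapping[str, float] | None = None,
    min_seqs: int = 2,
    min_organisms: int = 2,
    max_per_taxon: int | None = None,
    taxon_of: Callable[[str], str] = default_taxon_of,
    supergroup_of: Mapping[str, str] | None = None,
) -> list[CladeCall]:
    """Maximal supported clades of a tree.

    A clade passes iff every support method present on its branch (among the
    thresholded methods) meets its threshold, it has >= ``min_seqs`` leaves
    from >= ``min_organisms`` distinct organisms, and (if ``max_per_taxon``)
    no organism contributes more sequences than that.  Passing sides are
    reduced to a disjoint set preferring larger clades, so no reported clade
    nests inside another.
    """
    thresholds = dict(thresholds or DEFAULT_THRESHOLDS)
    if not any(node.supports for node in tree.iter_nodes()):
        raise ValueError("unsupported tree: no support values on any node")
    passing: list[tuple[frozenset, dict[str, float]]] = []
    for side, supports in _candidate_sides(tree):
        if not _passes_support(supports, thresholds):
            continue
        if len(side) < min_seqs:
            continue
        organisms = [taxon_of(l) for l in side]
        if len(set(organisms)) < min_organisms:
            continue
        if max_per_taxon is not None:
            counts: dict[str, int] = {}
            for org in organisms:
                counts[org] = counts.get(org, 0) + 1
            if max(counts.values()) > max_per_taxon:
                continue
        passing.append((side, supports))

    passing.sort(key=lambda t: (-len(t[0]), sorted(t[0])))
    chosen: list[tuple[frozenset, dict[str, float]]] = []
    taken: set = set()
    for side, supports in passing:
        if side & taken:
            continue
        chosen.append((side, supports))
        taken |= side

    calls = []
    for side, supports in chosen:
        organisms = frozenset(taxon_of(l) for l in side)
        sgs = (
            frozenset(supergroup_of[taxon_of(l)] for l in side)
            if supergroup_of is not None
            else frozenset()
        )
        calls.append(CladeCall(side, supports, organisms, sgs))
    return calls


# ---------------------------------------------------------------------------
# surrogate selection
# ---------------------------------------------------------------------------

def _adjacency(tree: PhyloTree) -> dict[TreeNode, list[tuple[TreeNode, float]]]:
    adj: dict[TreeNode, list[tuple[TreeNode, float]]] = {}
    for node in tree.iter_nodes():
        for child in node.children:
            adj.setdefault(node, []).append((child, child.length))
            adj.setdefault(child, []).append((node, child.length))
    return adj


def select_surrogates(
    tree: PhyloTree,
    clade: CladeCall | frozenset,
    k: int = 2,
    metric: str = "mrca_to_tip",
) -> list[str]:
    """The k slowest-evolving members of a clade.

    ``mrca_to_tip`` (default) ranks leaves by path length from the clade's
    attachment point (its MRCA when the tree is viewed rooted on the clade's
    edge); ``terminal`` ranks by the terminal branch alone.  Ties break
    lexicographically by id; clades smaller than k return every member.
    """
    side = clade.leaf_ids if isinstance(clade, CladeCall) else frozenset(clade)
    if metric not in ("mrca_to_tip", "terminal"):
        raise ValueError(f"unknown metric {metric!r}")
    leaves = {n.name: n for n in tree.leaves()}
    missing = side - set(leaves)
    if missing:
        raise KeyError(f"clade leaves not in tree: {sorted(missing)}")
    if metric == "terminal":
        scored = sorted((leaves[l].length, l) for l in side)
        return [l for _, l in scored[:k]]

    # locate the edge defining this side
    attach = forbidden = None
    all_leaves = frozenset(tree.leaf_names())
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        below = frozenset(node.leaf_names())
        if below == side:
            attach, forbidden = node, node.parent
            break
        if below == all_leaves - side:
            attach, forbidden = node.parent, node
            break
    if attach is None:
        raise ValueError("clade is not a bipartition side of this tree")

    adj = _adjacency(tree)
    dist: dict[str, float] = {}
    stack = [(attach, forbidden, 0.0)]
    while stack:
        node, came_from, d = stack.pop()
        if node.is_leaf and node.name in side:
            dist[node.name] = d
        for nbr, length in adj.get(node, []):
            if nbr is not came_from:
                stack.append((nbr, node, d + length))
    scored = sorted((dist[l], l) for l in side)
    return [l for _, l in scored[:k]]


# ---------------------------------------------------------------------------
# pan-eukaryotic reassembly
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Per-supergroup outcome of the taxon-reduction stage."""

    supergroup: str
    clades: list[CladeCall]
    unplaced: list[str]
    tree: PhyloTree | None = None

    def surrogate_ids(self) -> list[str]:
        out: list[str] = []
        for clade in self.clades:
            out.extend(clade.surrogates)
        return out


def assemble_pan_dataset(
    reports: Sequence[SelectionReport],
    master: Msa,
    outgroup_ids: Iterable[str] = (),
) -> Msa:
    """Rows = union of all surrogates plus declared outgroup; columns = master mask."""
    wanted: list[str] = []
    for report in reports:
        for rid in report.surrogate_ids():
            if rid not in wanted:
                wanted.append(rid)
    for rid in outgroup_ids:
        if rid not in wanted:
            wanted.append(rid)
    return master.subset(sorted(wanted))


def prune_and_reanalyze(
    pan: Msa,
    remove: Iterable[str],
    *,
    n_reps: int = 100,
    seed: int = 0,
    provenance: list | None = None,
) -> tuple[Msa, PhyloTree]:
    """Drop rows and re-infer the tree on the identical columns.

    Each removal round is appended to ``provenance`` (if supplied) so the
    chain of pruning experiments is auditable.
    """
    remove_set = set(remove)
    missing = remove_set - set(pan.ids())
    if missing:
        raise KeyError(f"cannot remove absent ids: {sorted(missing)}")
    keep = [rid for rid in pan.ids() if rid not in remove_set]
    if len(keep) < 4:
        raise ValueError("fewer than 4 rows would remain after removal")
    sub = pan.subset(keep)
    tree = bootstrap_tree(sub, n_reps=n_reps, seed=seed)
    if provenance is not None:
        provenance.append(
            {"removed": sorted(remove_set), "remaining": len(keep), "seed": seed, "n_reps": n_reps}
        )
    return sub, tree


# ---------------------------------------------------------------------------
# ancient paralog counting
# ---------------------------------------------------------------------------

@dataclass
class AncientCladeResult:
    count: int
    clades: list[CladeCall]
    unclassified: list[str]


def count_ancient_clades(
    pan_tree: PhyloTree,
    supergroup_of: Mapping[str, str],
    *,
    thresholds: Mapping[str, float] | None = None,
    min_supergroups: int = 2,
    min_seqs: int = 2,
    min_organisms: int = 2,
    max_per_taxon: int | None = 1,
    taxon_of: Callable[[str], str] = default_taxon_of,
) -> AncientCladeResult:
    """Count supported clades of the pan-eukaryotic tree that span >= 2 supergroups.

    Leaves are partitioned into maximal supported clades; clades spanning
    fewer than ``min_supergroups`` supergroups and leftover leaves are
    reported as unclassified rather than counted.
    """
    calls = find_supported_clades(
        pan_tree,
        thresholds=thresholds,
        min_seqs=min_seqs,
        min_organisms=min_organisms,
        max_per_taxon=max_per_taxon,
        taxon_of=taxon_of,
        supergroup_of=supergroup_of,
    )
    ancient = [c for c in calls if len(c.supergroups) >= min_supergroups]
    placed: set = set()
    for c in ancient:
        placed |= c.leaf_ids
    unclassified = sorted(set(pan_tree.leaf_names()) - placed)
    return AncientCladeResult(count=len(ancient), clades=ancient, unclassified=unclassified)
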