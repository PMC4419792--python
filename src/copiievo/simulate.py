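"""Gene-family evolution simulator with known duplication/loss histories.

A :class:`SpeciesScaffold` is a rooted, roughly ultrametric species tree over
eukaryotic supergroups whose root is the LECA (the last eukaryotic common
ancestor), with a stem edge above the root on which pre-LECA duplications can
be placed.  A :class:`Scenario` adds duplications (edge + time fraction),
lineage-specific losses (paralog x species subtree), and per-subtree rate
multipliers that create long-branch lineages.  Sequences evolve under an
equal-input amino-acid substitution process (flat exchangeabilities, empirical
stationary frequencies), no indels by default, so the true site
correspondence — and every paralog label — is known exactly.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.linalg import expm

from ._scoring import AA20, BACKGROUND_FREQS
from .formats import PhyloTree, SequenceRecord, TreeNode

__all__ = [
    "SubstitutionModel",
    "DEFAULT_MODEL",
    "ScaffoldConfig",
    "SpeciesScaffold",
    "build_scaffold",
    "Duplication",
    "Loss",
    "RateMultiplier",
    "Scenario",
    "load_scenario",
    "packaged_scenarios",
    "FamilyTruth",
    "evolve_sequence",
    "simulate_family",
]

SUPERGROUP_DEFAULTS = ("Opisthokonta", "Amoebozoa", "Archaeplastida", "SAR_CCTH", "Excavata")


# ---------------------------------------------------------------------------
# substitution model
# ---------------------------------------------------------------------------

class SubstitutionModel:
    """A 20-state continuous-time substitution model.

    Built from an exchangeability matrix and stationary frequencies,
    normalized to one expected substitution per site per unit branch length.
    The shipped default uses flat exchangeabilities with empirical amino-acid
    frequencies (an equal-input model).
    """

    def __init__(self, exchangeabilities: np.ndarray, freqs: np.ndarray):
        freqs = np.asarray(freqs, dtype=float)
        freqs = freqs / freqs.sum()
        ex = np.asarray(exchangeabilities, dtype=float)
        if ex.shape != (20, 20) or freqs.shape != (20,):
            raise ValueError("model requires a 20x20 exchangeability and 20 frequencies")
        Q = ex * freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -(freqs * np.diag(Q)).sum()
        self.Q = Q / rate
        self.freqs = freqs
        self._cache: dict[float, np.ndarray] = {}

    def transition(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t), cached on the (rounded) branch length."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        key = round(float(t), 12)
        P = self._cache.get(key)
        if P is None:
            P = expm(self.Q * key)
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=1, keepdims=True)
            self._cache[key] = P
        return P


def _default_model() -> SubstitutionModel:
    return SubstitutionModel(np.ones((20, 20)), BACKGROUND_FREQS)


DEFAULT_MODEL = _default_model()


def evolve_sequence(
    parent: str, t: float, model: SubstitutionModel | None = None, rng: np.random.Generator | None = None
) -> str:
    """Evolve a residue string for branch length ``t`` (expected subs/site).

    Length is preserved (no indels); t = 0 returns the parent unchanged; for
    large t the per-site distribution approaches the stationary frequencies.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    model = model or DEFAULT_MODEL
    rng = rng if rng is not None else np.random.default_rng()
    if t == 0:
        return parent
    idx = np.fromiter((AA20.index(c) for c in parent), dtype=np.int64, count=len(parent))
    P = model.transition(t)
    cum = np.cumsum(P, axis=1)
    u = rng.random(len(idx))
    new = (u[:, None] > cum[idx]).sum(axis=1)
    return "".join(AA20[i] for i in new)


def _sample_root(length: int, model: SubstitutionModel, rng: np.random.Generator) -> str:
    cum = np.cumsum(model.freqs)
    u = rng.random(length)
    idx = (u[:, None] > cum[None, :]).sum(axis=1)
    return "".join(AA20[i] for i in idx)


# ---------------------------------------------------------------------------
# species scaffold
# ---------------------------------------------------------------------------

@dataclass
class ScaffoldConfig:
    """Shape and depths of the species scaffold.

    Depths are in expected substitutions per site at rate 1: tips sit
    ``crown_start + crown_depth`` below the LECA; the stem above the LECA
    (where pre-LECA duplications live) has length ``stem_length``.
    """

    supergroups: Sequence[str] = SUPERGROUP_DEFAULTS
    taxa_per_supergroup: int | dict[str, int] = 4
    stem_length: float = 0.4
    crown_start: float = 0.25
    crown_depth: float = 0.25
    backbone_step: float = 0.05

    def n_taxa(self, sg: str) -> int:
        if isinstance(self.taxa_per_supergroup, dict):
            return int(self.taxa_per_supergroup[sg])
        return int(self.taxa_per_supergroup)


@dataclass
class SpeciesScaffold:
    """Rooted species tree (root = LECA) plus supergroup bookkeeping."""

    tree: PhyloTree
    stem_length: float
    supergroups: list[str]
    supergroup_of: dict[str, str]

    @property
    def taxa(self) -> list[str]:
        return self.tree.leaf_names()

    def clade_taxa(self, node_name: str) -> list[str]:
        return self.tree.find(node_name).leaf_names()

    def node_names(self) -> set[str]:
        return {n.name for n in self.tree.iter_nodes() if n.name}


def _taxon_prefix(sg: str, taken: set[str]) -> str:
    base = sg[:3]
    prefix = base
    k = 1
    while prefix in taken:
        k += 1
        prefix = f"{base}{k}_"
    taken.add(prefix)
    return prefix


def build_scaffold(config: ScaffoldConfig | None = None) -> SpeciesScaffold:
    """Deterministically build the species scaffold from a config.

    Every supergroup is monophyletic; within-supergroup topology is balanced
    and ultrametric; the backbone is a balanced arrangement of supergroups
    with short internal edges, so the root (LECA) is ancestral to all of them.
    """
    config = config or ScaffoldConfig()
    sgs = list(config.supergroups)
    if len(sgs) < 2:
        raise ValueError("scaffold needs at least 2 supergroups")
    for sg in sgs:
        if config.n_taxa(sg) < 1:
            raise ValueError(f"supergroup {sg!r} has no taxa")

    prefixes: set[str] = set()
    supergroup_of: dict[str, str] = {}
    counters: dict[str, int] = {}

    def crown(sg: str) -> TreeNode:
        prefix = _taxon_prefix(sg, prefixes)
        names = [f"{prefix}{i + 1}" for i in range(config.n_taxa(sg))]
        for name in names:
            supergroup_of[name] = sg
        counters[sg] = 0

        def rec(group: list[str], depth: float) -> TreeNode:
            node = TreeNode()
            levels = max(1, math.ceil(math.log2(len(group))))
            step = depth / levels
            mid = (len(group) + 1) // 2
            for half in (group[:mid], group[mid:]):
                if len(half) == 1:
                    node.add(TreeNode(half[0], depth))
                else:
                    sub = rec(half, depth - step)
                    sub.length = step
                    counters[sg] += 1
                    sub.name = f"{sg}_{counters[sg]}"
                    node.add(sub)
            return node

        if len(names) == 1:
            top = TreeNode(names[0])
        else:
            top = rec(names, config.crown_depth)
        top.name = sg if len(names) > 1 else names[0]
        return top

    bb_count = 0

    def backbone(groups: list[str], depth_used: float) -> TreeNode:
        nonlocal bb_count
        if len(groups) == 1:
            node = crown(groups[0])
            node.length = config.crown_start - depth_used
            if node.length <= 0:
                raise ValueError("backbone_step too large for crown_start")
            return node
        mid = (len(groups) + 1) // 2
        node = TreeNode()
        bb_count += 1
        node.name = f"node_{bb_count}"
        node.length = config.backbone_step
        for half in (groups[:mid], groups[mid:]):
            node.add(backbone(half, depth_used + config.backbone_step))
        return node

    root = TreeNode("LECA", 0.0)
    mid = (len(sgs) + 1) // 2
    for half in (sgs[:mid], sgs[mid:]):
        child = backbone(half, 0.0) if len(half) > 1 else crown(half[0])
        if len(half) == 1:
            child.length = config.crown_start
        root.add(child)
    tree = PhyloTree(root, rooted=True)
    return SpeciesScaffold(
        tree=tree,
        stem_length=config.stem_length,
        supergroups=sgs,
        supergroup_of=supergroup_of,
    )


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass
class Duplication:
    """A gene duplication at ``fraction`` along the edge above ``edge`` node.

    ``edge == "root"`` places it on the stem above the LECA (a pre-LECA
    duplication).  ``parent`` names the paralog that duplicates (default: the
    scenario's base paralog); ``name`` is the new paralog lineage.
    """

    edge: str
    fraction: float
    name: str
    parent: str | None = None


@dataclass
class Loss:
    paralog: str
    clade: str  # species-tree node name; the paralog is lost in that subtree


@dataclass
class RateMultiplier:
    clade: str
    factor: float
    stem_only: bool = False


@dataclass
class Scenario:
    """A duplication/loss/rate history for one gene family."""

    name: str
    component: str
    base_paralog: str
    duplications: list[Duplication] = field(default_factory=list)
    losses: list[Loss] = field(default_factory=list)
    rate_multipliers: list[RateMultiplier] = field(default_factory=list)
    root_length: int = 500
    subst_rate: float = 1.0
    indel_rate: float = 0.0
    indel_mean_length: float = 3.0

    def paralog_names(self) -> list[str]:
        return [self.base_paralog] + [d.name for d in self.duplications]

    def validate(self, scaffold: SpeciesScaffold) -> None:
        nodes = scaffold.node_names() | {"root"}
        known = {self.base_paralog}
        for dup in self.duplications:
            if dup.edge not in nodes:
                raise ValueError(f"duplication edge {dup.edge!r} not in scaffold")
            if not 0.0 <= dup.fraction < 1.0:
                raise ValueError(f"duplication fraction {dup.fraction} outside [0, 1)")
            parent = dup.parent or self.base_paralog
            if parent not in known:
                raise ValueError(f"duplication parent paralog {parent!r} unknown")
            if dup.name in known:
                raise ValueError(f"duplicate paralog name {dup.name!r}")
            known.add(dup.name)
        for loss in self.losses:
            if loss.clade not in nodes - {"root"}:
                raise ValueError(f"loss clade {loss.clade!r} not in scaffold")
            if loss.paralog not in known:
                raise ValueError(f"loss paralog {loss.paralog!r} unknown")
        for mult in self.rate_multipliers:
            if mult.clade not in nodes - {"root"}:
                raise ValueError(f"rate multiplier clade {mult.clade!r} not in scaffold")
            if mult.factor <= 0:
                raise ValueError("rate multipliers must be > 0")

    def scaled(self, divergence_multiplier: float) -> "Scenario":
        """Copy with the overall substitution rate multiplied (for stress grids)."""
        import copy

        out = copy.deepcopy(self)
        out.subst_rate *= divergence_multiplier
        return out


def load_scenario(source: str | Path) -> Scenario:
    """Load a scenario from a YAML file or a packaged scenario name.

    Packaged scenarios: ``sec24``, ``sec23``, ``sed4``, ``null``.
    """
    path = Path(source)
    if not path.suffix and not path.exists():
        ref = resources.files("copiievo").joinpath(f"scenarios/{source}.yaml")
        text = ref.read_text()
    else:
        text = path.read_text()
    raw = yaml.safe_load(text)
    return Scenario(
        name=raw["name"],
        component=raw.get("component", raw["name"]),
        base_paralog=raw["base_paralog"],
        duplications=[Duplication(**d) for d in raw.get("duplications", [])],
        losses=[Loss(**l) for l in raw.get("losses", [])],
        rate_multipliers=[RateMultiplier(**m) for m in raw.get("rate_multipliers", [])],
        root_length=int(raw.get("root_length", 500)),
        subst_rate=float(raw.get("subst_rate", 1.0)),
        indel_rate=float(raw.get("indel_rate", 0.0)),
        indel_mean_length=float(raw.get("indel_mean_length", 3.0)),
    )


def packaged_scenarios() -> list[str]:
    base = resources.files("copiievo").joinpath("scenarios")
    return sorted(p.name[: -len(".yaml")] for p in base.iterdir() if p.name.endswith(".yaml"))


# ---------------------------------------------------------------------------
# gene tree construction and sequence simulation
# ---------------------------------------------------------------------------

@dataclass
class FamilyTruth:
    """Ground truth emitted alongside a simulated family."""

    labels: dict[str, str]  # sequence id -> true paralog
    ancient_paralog_count: int
    paralogs: list[str]
    extinct_paralogs: list[str] = field(default_factory=list)


def _scaled_tree(scaffold: SpeciesScaffold, scenario: Scenario) -> tuple[PhyloTree, float]:
    tree = scaffold.tree.copy()
    stem = scaffold.stem_length
    for mult in scenario.rate_multipliers:
        node = tree.find(mult.clade)
        if mult.stem_only:
            node.length *= mult.factor
        else:
            for sub in node.preorder():
                sub.length *= mult.factor
    return tree, stem


def _build_gene_tree(scaffold: SpeciesScaffold, scenario: Scenario) -> tuple[TreeNode, dict]:
    """Graft duplication subtrees onto the base paralog's species-tree copy.

    Returns the gene-tree root and a map (species node name, paralog) -> gene
    node, used to place nested duplications.
    """
    scaled, stem = _scaled_tree(scaffold, scenario)
    root_name = scaled.root.name  # "LECA"

    gmap: dict[tuple[str, str], TreeNode] = {}
    spans: dict[tuple[str, str], list[tuple[TreeNode, float, float]]] = {}

    def copy_subtree(snode: TreeNode, paralog: str) -> TreeNode:
        gname = f"{snode.name}_{paralog}" if snode.is_leaf else None
        gnode = TreeNode(gname, snode.length)
        if snode.name:
            gmap[(snode.name, paralog)] = gnode
            spans[(snode.name, paralog)] = [(gnode, 0.0, 1.0)]
        for child in snode.children:
            gnode.add(copy_subtree(child, paralog))
        return gnode

    origin = TreeNode("origin", 0.0)
    base_top = copy_subtree(scaled.root, scenario.base_paralog)
    base_top.length = stem
    origin.add(base_top)
    # the stem is the edge above the root node; key it by the root's name
    edge_lengths = {n.name: n.length for n in scaled.iter_nodes() if n.name}
    edge_lengths[root_name] = stem

    for dup in scenario.duplications:
        parent_paralog = dup.parent or scenario.base_paralog
        edge_child = root_name if dup.edge == "root" else dup.edge
        key = (edge_child, parent_paralog)
        if key not in spans:
            raise ValueError(
                f"duplication on edge {dup.edge!r}: paralog {parent_paralog!r} "
                "does not pass through that edge"
            )
        segs = spans[key]
        seg = next(((g, s, e) for g, s, e in segs if s <= dup.fraction <= e), None)
        if seg is None:
            raise ValueError(
                f"duplication fraction {dup.fraction} collides with an earlier event"
            )
        gnode, s, e = seg
        total = edge_lengths[edge_child]
        parent = gnode.parent
        upper = TreeNode(None, (dup.fraction - s) * total)
        parent.children[parent.children.index(gnode)] = upper
        upper.parent = parent
        upper.add(gnode)
        gnode.length = (e - dup.fraction) * total
        segs.remove(seg)
        segs.extend([(upper, s, dup.fraction), (gnode, dup.fraction, e)])

        snode = scaled.root if dup.edge == "root" else scaled.find(dup.edge)
        new_top = copy_subtree(snode, dup.name)
        new_top.length = (1.0 - dup.fraction) * total
        spans[(edge_child, dup.name)] = [(new_top, dup.fraction, 1.0)]
        upper.add(new_top)

    return origin, gmap


def _lost_leaf_ids(scaffold: SpeciesScaffold, scenario: Scenario) -> set[str]:
    lost: set[str] = set()
    for loss in scenario.losses:
        for taxon in scaffold.clade_taxa(loss.clade):
            lost.add(f"{taxon}_{loss.paralog}")
    return lost


def expected_leaf_ids(scaffold: SpeciesScaffold, scenario: Scenario) -> set[str]:
    """Set-arithmetic view of which (taxon, paralog) sequences survive."""
    lost = _lost_leaf_ids(scaffold, scenario)
    out: set[str] = set()
    for paralog in scenario.paralog_names():
        for taxon in scaffold.taxa:
            rid = f"{taxon}_{paralog}"
            if rid not in lost:
                out.add(rid)
    return out


def _prune_gene_tree(node: TreeNode, drop: set[str]) -> TreeNode | None:
    if node.is_leaf:
        return None if node.name in drop else node
    kept = []
    for child in node.children:
        sub = _prune_gene_tree(child, drop)
        if sub is not None:
            kept.append(sub)
    if not kept:
        return None
    if len(kept) == 1:
        kept[0].length += node.length
        return kept[0]
    node.children = kept
    for c in kept:
        c.parent = node
    return node


def _apply_indels(
    seq: str, t: float, scenario: Scenario, model: SubstitutionModel, rng: np.random.Generator
) -> str:
    n_events = rng.poisson(scenario.indel_rate * t * max(len(seq), 1))
    for _ in range(n_events):
        length = 1 + rng.geometric(1.0 / scenario.indel_mean_length)
        if rng.random() < 0.5 and len(seq) > length:
            pos = int(rng.integers(0, len(seq) - length))
            seq = seq[:pos] + seq[pos + length :]
        else:
            pos = int(rng.integers(0, len(seq) + 1))
            seq = seq[:pos] + _sample_root(length, model, rng) + seq[pos:]
    return seq


def simulate_family(
    scaffold: SpeciesScaffold,
    scenario: Scenario,
    seed: int,
    model: SubstitutionModel | None = None,
) -> tuple[list[SequenceRecord], FamilyTruth]:
    """Simulate one gene family along the scaffold under a scenario.

    Emits one sequence per surviving (taxon, paralog); identical inputs give
    byte-identical output.  The truth records each sequence's paralog lineage
    and the number of pre-LECA paralogs that survive anywhere.
    """
    scenario.validate(scaffold)
    model = model or DEFAULT_MODEL
    rng = np.random.default_rng(seed)

    gene_root, _ = _build_gene_tree(scaffold, scenario)
    drop = _lost_leaf_ids(scaffold, scenario)
    pruned = _prune_gene_tree(gene_root, drop)
    if pruned is None:
        raise ValueError("every sequence was lost; scenario removes the whole family")

    surviving = {
        name.rsplit("_", 1)[1]
        for name in (leaf.name for leaf in pruned.leaves())
    }
    extinct = [p for p in scenario.paralog_names() if p not in surviving]
    if extinct:
        warnings.warn(f"paralog(s) lost everywhere: {extinct}", stacklevel=2)

    root_edges = {scaffold.tree.root.name, "root"}
    ancient = [scenario.base_paralog] + [
        d.name for d in scenario.duplications if d.edge in root_edges
    ]
    ancient_count = sum(1 for p in ancient if p in surviving)

    records: list[SequenceRecord] = []

    def walk(node: TreeNode, parent_seq: str) -> None:
        t = node.length * scenario.subst_rate
        seq = evolve_sequence(parent_seq, t, model, rng)
        if scenario.indel_rate > 0:
            seq = _apply_indels(seq, t, scenario, model, rng)
        if node.is_leaf:
            taxon, paralog = node.name.rsplit("_", 1)
            records.append(
                SequenceRecord(
                    id=node.name,
                    taxon=taxon,
                    supergroup=scaffold.supergroup_of[taxon],
                    component=scenario.component,
                    residues=seq,
                    true_paralog=paralog,
                )
            )
            return
        for child in node.children:
            walk(child, seq)

    root_seq = _sample_root(scenario.root_length, model, rng)
    walk(pruned, root_seq)
    records.sort(key=lambda r: r.id)

    truth = FamilyTruth(
        labels={r.id: r.true_paralog for r in records},
        ancient_paralog_count=ancient_count,
        paralogs=[p for p in scenario.paralog_names() if p in surviving],
        extinct_paralogs=extinct,
    )
    return records, truth
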