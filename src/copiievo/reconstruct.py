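"""Presence/absence assembly and Dollo-parsimony ancestral gene content.

Dollo parsimony allows a single gain per component and any number of losses:
the gain is placed at the MRCA of all tips carrying the component, and losses
are the minimal set of edges below the gain whose removal explains every
absence.  A component belongs to the reconstructed LECA complement iff its
gain node is the root of the species tree (the LECA).

The package ships a text-encoded reference presence/absence matrix for the
eight COPII-associated components (Sar1, Sec12, Sec16, Sec23, Sec24, Sec13,
Sec31, Sed4) over a representative eukaryote panel, together with the rooted
taxonomy it is read on; see ``copiievo/data/``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from .formats import (
    ABSENT,
    PRESENT,
    PRESENT_EXTRA,
    PhyloTree,
    PresenceMatrix,
    parse_newick,
    parse_presence_matrix,
)

__all__ = [
    "build_presence_matrix",
    "DolloResult",
    "dollo_reconstruct",
    "leca_complement",
    "LecaComplement",
    "load_reference_presence",
    "load_reference_taxonomy",
]


# ---------------------------------------------------------------------------
# presence matrix assembly
# ---------------------------------------------------------------------------

def build_presence_matrix(
    verdicts: Mapping[tuple[str, str], object],
    taxa: Iterable[str],
    components: Iterable[str],
) -> PresenceMatrix:
    """Assemble a matrix from per-(taxon, component) search outcomes.

    ``verdicts`` maps (taxon, component) to anything with ``is_present``/
    ``is_ortholog`` (or a plain bool) plus an optional ``evidence`` attribute
    ("rbh", "profile" or "declared").  Every declared (taxon, component) cell
    must have a verdict — absences are explicit, never missing.
    """
    taxa = list(taxa)
    components = list(components)
    cells: dict[tuple[str, str], str] = {}
    evidence: dict[tuple[str, str], str] = {}
    for taxon in taxa:
        for comp in components:
            if (taxon, comp) not in verdicts:
                raise ValueError(f"no verdict for ({taxon}, {comp}): absences must be explicit")
            v = verdicts[(taxon, comp)]
            if isinstance(v, bool):
                present, ev, extra = v, "declared", False
            else:
                present = bool(
                    getattr(v, "is_present", None)
                    if getattr(v, "is_present", None) is not None
                    else getattr(v, "is_ortholog")
                )
                ev = getattr(v, "evidence", "rbh")
                extra = bool(getattr(v, "unclassified_extra", False))
            cells[(taxon, comp)] = (PRESENT_EXTRA if extra else PRESENT) if present else ABSENT
            evidence[(taxon, comp)] = ev
    return PresenceMatrix(taxa, components, cells, evidence)


# ---------------------------------------------------------------------------
# Dollo parsimony
# ---------------------------------------------------------------------------

@dataclass
class DolloResult:
    """Single-gain / multiple-loss reconstruction of one component."""

    component: str
    gain_node: str | None  # None when the component is absent everywhere
    loss_edges: list[str]  # named by the child node below each lost edge
    loss_count: int
    states: dict[str, bool] = field(default_factory=dict)  # node name -> present


def dollo_reconstruct(
    tip_states: Mapping[str, bool], tree: PhyloTree, component: str = ""
) -> DolloResult:
    """Dollo reconstruction of one presence/absence column on a rooted tree.

    The gain sits at the MRCA of the present tips; every maximal subtree below
    it containing no present tip contributes one loss edge.  This is the
    minimum loss count under the single-gain constraint.
    """
    if not tree.rooted:
        raise ValueError("Dollo reconstruction needs a rooted species tree")
    leaf_names = tree.leaf_names()
    missing = set(leaf_names) - set(tip_states)
    if missing:
        raise ValueError(f"tips without a state: {sorted(missing)}")
    present_tips = [l for l in leaf_names if tip_states[l]]
    if not present_tips:
        return DolloResult(component, None, [], 0, {})

    gain = tree.mrca(present_tips)
    loss_edges: list[str] = []
    states: dict[str, bool] = {}

    def name_of(node) -> str:
        if node.name:
            return node.name
        return "mrca(" + ",".join(sorted(node.leaf_names())[:2]) + ",...)"

    # everything outside the gain subtree is absent
    gain_set = set(n for n in gain.preorder())
    for node in tree.iter_nodes():
        if node.name and node not in gain_set:
            states[node.name] = False

    def walk(node) -> None:
        tips = node.leaf_names()
        if not any(tip_states[t] for t in tips):
            loss_edges.append(name_of(node))
            for sub in node.preorder():
                if sub.name:
                    states[sub.name] = False
            return
        if node.name:
            states[node.name] = True
        for child in node.children:
            walk(child)

    walk(gain)
    return DolloResult(component, name_of(gain), sorted(loss_edges), len(loss_edges), states)


@dataclass
class LecaComplement:
    components: list[str]
    count: int
    per_component: dict[str, DolloResult]

    def losses(self, component: str) -> int:
        return self.per_component[component].loss_count


def leca_complement(matrix: PresenceMatrix, tree: PhyloTree) -> LecaComplement:
    """Components whose Dollo gain node is the root (the LECA).

    ``present_extra_unclassified`` cells count as presence: extra sequences of
    a family still witness the family in that organism.
    """
    root_name = tree.root.name or "root"
    if tree.root.name is None:
        tree = tree.copy()
        tree.root.name = root_name
    in_leca: list[str] = []
    per: dict[str, DolloResult] = {}
    for comp in matrix.components:
        column = matrix.column(comp)
        result = dollo_reconstruct(column, tree, comp)
        per[comp] = result
        if result.gain_node == root_name:
            in_leca.append(comp)
    return LecaComplement(in_leca, len(in_leca), per)


# ---------------------------------------------------------------------------
# shipped reference data
# ---------------------------------------------------------------------------

def load_reference_presence() -> PresenceMatrix:
    """The text-encoded COPII presence/absence matrix over 22 eukaryotes."""
    ref = resources.files("copiievo").joinpath("data/copii_presence.tsv")
    with resources.as_file(ref) as path:
        return parse_presence_matrix(path)


def load_reference_taxonomy() -> PhyloTree:
    """The rooted taxonomy (root = LECA) the reference matrix is read on."""
    ref = resources.files("copiievo").joinpath("data/eukaryote_taxonomy.nwk")
    return parse_newick(ref.read_text(), rooted=True)
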