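"""Readers/writers and the in-memory types every pipeline stage exchanges.

Sequences travel as :class:`SequenceRecord` lists (FASTA with a
``id|taxon|supergroup|component`` header convention, optional TSV sidecar),
similarity results as :class:`HitTable` (12-column BLAST tabular dialect),
trees as :class:`PhyloTree` (Newick; internal node labels carry support,
either a single value or the dual ``posterior/bootstrap`` dialect), and
presence/absence calls as :class:`PresenceMatrix` (TSV with 1/0/U cells).
"""
from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

SUPERGROUPS = ("Opisthokonta", "Amoebozoa", "Archaeplastida", "SAR_CCTH", "Excavata")

_FASTA_WRAP = 60


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A labelled protein sequence.

    ``true_paralog`` is only ever set by the simulator and carries the
    ground-truth paralog lineage the sequence descends from.
    """

    id: str
    taxon: str
    supergroup: str
    component: str
    residues: str
    true_paralog: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has empty residues")
        self.residues = self.residues.upper()

    def header(self) -> str:
        return f"{self.id}|{self.taxon}|{self.supergroup}|{self.component}"


def parse_fasta(path: str | Path, metadata: str | Path | None = None) -> list[SequenceRecord]:
    """Read FASTA into records.

    Headers follow ``id|taxon|supergroup|component``; a TSV sidecar
    (columns id, taxon, supergroup, component) overrides or supplies the
    metadata for bare headers.  Duplicate ids and empty sequences are hard
    errors.
    """
    side: dict[str, tuple[str, str, str]] = {}
    if metadata is not None:
        for line in Path(metadata).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"metadata sidecar rows need 4 columns, got {len(parts)}")
            side[parts[0]] = (parts[1], parts[2], parts[3])

    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    with open(path) as handle:
        for pos, (title, seq) in enumerate(SimpleFastaParser(handle)):
            fields = title.strip().split("|")
            rid = fields[0]
            if rid in seen:
                raise ValueError(
                    f"duplicate sequence id {rid!r} (entries {seen[rid] + 1} and {pos + 1})"
                )
            seen[rid] = pos
            if rid in side:
                taxon, sg, comp = side[rid]
            elif len(fields) == 4:
                taxon, sg, comp = fields[1], fields[2], fields[3]
            else:
                raise ValueError(
                    f"header {title!r}: expected id|taxon|supergroup|component "
                    "or a metadata sidecar entry"
                )
            if not seq:
                raise ValueError(f"sequence {rid!r} has empty residues")
            records.append(SequenceRecord(rid, taxon, sg, comp, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records in the canonical form (pipe header, 60-column wrap)."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.header()}\n")
            for i in range(0, len(rec.residues), _FASTA_WRAP):
                out.write(rec.residues[i : i + _FASTA_WRAP] + "\n")


# ---------------------------------------------------------------------------
# similarity hits
# ---------------------------------------------------------------------------

_SMALLEST_POSITIVE = math.ulp(0.0)  # 5e-324, the smallest positive float


@dataclass
class HitRecord:
    """One pairwise similarity result (BLAST tabular field order)."""

    query_id: str
    subject_id: str
    pident: float
    aln_len: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    raw_score: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not math.isfinite(self.raw_score):
            raise ValueError("raw_score must be finite")


@dataclass
class HitTable:
    """An ordered collection of hits plus parser warnings."""

    records: list[HitRecord] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[HitRecord]:
        return iter(self.records)

    def by_query(self, query_id: str) -> list[HitRecord]:
        return [h for h in self.records if h.query_id == query_id]

    def queries(self) -> list[str]:
        out: list[str] = []
        for h in self.records:
            if h.query_id not in out:
                out.append(h.query_id)
        return out


def parse_hit_table(path: str | Path) -> HitTable:
    """Read 12-column BLAST tabular TSV.

    E-values that print as positive but underflow to 0.0 are stored as the
    smallest positive representable float and flagged.
    """
    table = HitTable()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 12:
            raise ValueError(f"line {lineno}: expected 12 tab-separated columns, got {len(parts)}")
        evalue = float(parts[10])
        text = parts[10].strip().lower()
        if evalue == 0.0 and not text.startswith(("0", "-0", "+0", ".0", "0.")):
            evalue = _SMALLEST_POSITIVE
            table.flags.append(f"line {lineno}: evalue {parts[10]!r} underflowed; stored {evalue!r}")
        table.records.append(
            HitRecord(
                query_id=parts[0],
                subject_id=parts[1],
                pident=float(parts[2]),
                aln_len=int(parts[3]),
                mismatch=int(parts[4]),
                gapopen=int(parts[5]),
                qstart=int(parts[6]),
                qend=int(parts[7]),
                sstart=int(parts[8]),
                send=int(parts[9]),
                evalue=evalue,
                bitscore=float(parts[11]),
            )
        )
    return table


def write_hit_table(table: HitTable, path: str | Path) -> None:
    with open(path, "w") as out:
        for h in table:
            out.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pident:.2f}",
                        str(h.aln_len),
                        str(h.mismatch),
                        str(h.gapopen),
                        str(h.qstart),
                        str(h.qend),
                        str(h.sstart),
                        str(h.send),
                        _format_evalue(h.evalue),
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


def _format_evalue(e: float) -> str:
    if e == 0.0:
        return "0.0"
    if e < 1e-3 or e >= 1e4:
        return f"{e:.2e}"
    return f"{e:.3g}"


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

class NewickError(ValueError):
    """Raised for malformed Newick with the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


class TreeNode:
    """A node of a (possibly rooted) phylogenetic tree.

    ``length`` is the branch above the node; ``supports`` maps a method name
    ("bootstrap" on 0-100, "posterior" on 0-1) to the support of that branch's
    bipartition.
    """

    __slots__ = ("name", "length", "children", "supports", "parent")

    def __init__(
        self,
        name: str | None = None,
        length: float = 0.0,
        children: list["TreeNode"] | None = None,
        supports: dict[str, float] | None = None,
    ):
        self.name = name
        self.length = float(length)
        self.children: list[TreeNode] = children or []
        self.supports: dict[str, float] = supports or {}
        self.parent: TreeNode | None = None
        for c in self.children:
            c.parent = self

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]


class PhyloTree:
    """A tree with branch lengths and per-branch support values.

    ``rooted`` is declared (default: a binary root reads as rooted).  Unrooted
    trees are stored in rooted shape with an arbitrary basal multifurcation;
    analyses on them work with bipartitions.
    """

    def __init__(self, root: TreeNode, rooted: bool | None = None):
        self.root = root
        self.rooted = (len(root.children) == 2) if rooted is None else rooted
        self._validate()

    def _validate(self) -> None:
        names = self.leaf_names()
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf names: {dup}")
        for node in self.root.preorder():
            if node.length < 0:
                raise ValueError(f"negative branch length {node.length} at {node.name!r}")
            for method, value in node.supports.items():
                if method == "posterior" and not 0.0 <= value <= 1.0:
                    raise ValueError(f"posterior {value} outside [0, 1]")
                if method == "bootstrap" and not 0.0 <= value <= 100.0:
                    raise ValueError(f"bootstrap {value} outside [0, 100]")

    # -- basic accessors ----------------------------------------------------
    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def iter_nodes(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def find(self, name: str) -> TreeNode:
        for node in self.iter_nodes():
            if node.name == name:
                return node
        raise KeyError(f"no node named {name!r}")

    def mrca(self, leaf_names: Iterable[str]) -> TreeNode:
        wanted = set(leaf_names)
        missing = wanted - set(self.leaf_names())
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        for node in self.root.postorder():
            if wanted <= set(node.leaf_names()):
                return node
        return self.root

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            return TreeNode(
                node.name,
                node.length,
                [clone(c) for c in node.children],
                dict(node.supports),
            )

        return PhyloTree(clone(self.root), rooted=self.rooted)

    # -- bipartitions --------------------------------------------------------
    def bipartitions(self) -> dict[frozenset, dict[str, float]]:
        """Non-trivial bipartitions as {smaller-or-lexicographic side: supports}.

        Keyed canonically so trees over the same leaf set compare directly.
        """
        all_leaves = frozenset(self.leaf_names())
        out: dict[frozenset, dict[str, float]] = {}
        for node in self.root.preorder():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            out[canonical_side(side, all_leaves)] = dict(node.supports)
        return out

    # -- editing -------------------------------------------------------------
    def pruned_to(self, keep: Iterable[str]) -> "PhyloTree":
        """Return a copy restricted to ``keep`` leaves, collapsing unary nodes."""
        keep_set = set(keep)
        missing = keep_set - set(self.leaf_names())
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")

        def rec(node: TreeNode) -> TreeNode | None:
            if node.is_leaf:
                if node.name in keep_set:
                    return TreeNode(node.name, node.length, supports=dict(node.supports))
                return None
            kids = [k for k in (rec(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += node.length
                return kids[0]
            return TreeNode(node.name, node.length, kids, dict(node.supports))

        new_root = rec(self.root)
        if new_root is None:
            raise ValueError("pruning removed every leaf")
        new_root.length = 0.0
        return PhyloTree(new_root, rooted=self.rooted)

    # -- serialization -------------------------------------------------------
    def newick(self, *, supports: bool = True, lengths: bool = True) -> str:
        return write_newick(self, supports=supports, lengths=lengths)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({len(self.leaf_names())} leaves, rooted={self.rooted})"


def canonical_side(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Pick a canonical side of a bipartition (smaller set, ties by sorted names)."""
    other = all_leaves - side
    if len(side) != len(other):
        return side if len(side) < len(other) else other
    return side if sorted(side) <= sorted(other) else other


def _parse_support_label(label: str, scale: str | None) -> tuple[str | None, dict[str, float]]:
    """Interpret an internal node label as support value(s) or a plain name.

    The dual dialect is ``posterior/bootstrap`` (e.g. ``0.98/85``); single
    numeric values default to posterior when <= 1, bootstrap otherwise, unless
    ``scale`` pins the interpretation.
    """
    if "/" in label:
        a, _, b = label.partition("/")
        try:
            post, boot = float(a), float(b)
        except ValueError:
            return label, {}
        return None, {"posterior": post, "bootstrap": boot}
    try:
        value = float(label)
    except ValueError:
        return label, {}
    if scale == "posterior":
        return None, {"posterior": value}
    if scale == "bootstrap":
        return None, {"bootstrap": value}
    if value <= 1.0:
        return None, {"posterior": value}
    return None, {"bootstrap": value}


def parse_newick(
    text: str,
    *,
    support_scale: str | None = None,
    rooted: bool | None = None,
) -> PhyloTree:
    """Recursive-descent Newick parser.

    Internal node labels become support values (see
    :func:`_parse_support_label`); missing branch lengths default to 0.0;
    negative lengths and unbalanced parentheses are hard errors with the
    offending position.
    """
    text = text.strip()
    if not text:
        raise NewickError("empty Newick string", 0)
    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(msg, pos)

    def parse_clade() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(text) and text[pos] == "(":
            pos += 1
            while True:
                node.add(parse_clade())
                if pos >= len(text):
                    raise error("unbalanced parentheses: unexpected end of input")
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {text[pos]!r}")
        label = _read_token()
        if label:
            if node.is_leaf:
                node.name = label
            else:
                name, supports = _parse_support_label(label, support_scale)
                node.name = name
                node.supports = supports
        if pos < len(text) and text[pos] == ":":
            pos += 1
            token = _read_token()
            try:
                node.length = float(token)
            except ValueError:
                raise error(f"bad branch length {token!r}") from None
            if node.length < 0:
                raise error(f"negative branch length {node.length}")
        return node

    def _read_token() -> str:
        nonlocal pos
        start = pos
        while pos < len(text) and text[pos] not in "(),:;":
            pos += 1
        return text[start:pos].strip()

    root = parse_clade()
    if pos >= len(text) or text[pos] != ";":
        raise error("expected ';' at end of tree")
    pos += 1
    if text[pos:].strip():
        raise error("trailing characters after ';'")
    tree = PhyloTree(root, rooted=rooted)
    return tree


def write_newick(tree: PhyloTree, *, supports: bool = True, lengths: bool = True) -> str:
    def fmt_length(node: TreeNode) -> str:
        return f":{node.length:g}" if lengths else ""

    def fmt_label(node: TreeNode) -> str:
        if node.is_leaf:
            return node.name or ""
        if supports and node.supports:
            if set(node.supports) >= {"posterior", "bootstrap"}:
                return f"{node.supports['posterior']:g}/{node.supports['bootstrap']:g}"
            method, value = next(iter(node.supports.items()))
            return f"{value:g}"
        return node.name or ""

    def rec(node: TreeNode, is_root: bool = False) -> str:
        suffix = "" if is_root else fmt_length(node)
        if node.is_leaf:
            return f"{fmt_label(node)}{suffix}"
        inner = ",".join(rec(c) for c in node.children)
        return f"({inner}){fmt_label(node)}{suffix}"

    return rec(tree.root, is_root=True) + ";"


def reconcile_supports(primary: PhyloTree, secondary: PhyloTree) -> PhyloTree:
    """Paint a second tree's supports onto the primary topology.

    For every internal branch of ``primary`` whose bipartition also exists in
    ``secondary``, the secondary tree's support values are merged in (the
    primary's own values win on method collisions).  This is the two-tree
    alternative to the dual ``posterior/bootstrap`` label dialect.
    """
    if set(primary.leaf_names()) != set(secondary.leaf_names()):
        raise ValueError("trees must share the same leaf set")
    other = secondary.bipartitions()
    out = primary.copy()
    all_leaves = frozenset(out.leaf_names())
    for node in out.root.preorder():
        if node is out.root or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        match = other.get(canonical_side(side, all_leaves))
        if match:
            node.supports = {**match, **node.supports}
    return out


# ---------------------------------------------------------------------------
# presence/absence matrix
# ---------------------------------------------------------------------------

PRESENT = "present"
PRESENT_EXTRA = "present_extra_unclassified"
ABSENT = "absent"

_STATE_TO_CELL = {PRESENT: "1", PRESENT_EXTRA: "U", ABSENT: "0"}
_CELL_TO_STATE = {v: k for k, v in _STATE_TO_CELL.items()}


@dataclass
class PresenceMatrix:
    """Taxa x components grid of ortholog detection outcomes.

    Cells are one of present / present_extra_unclassified / absent; the
    parallel ``evidence`` grid records how the call was made (rbh, profile,
    declared).
    """

    taxa: list[str]
    components: list[str]
    cells: dict[tuple[str, str], str]
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon in self.taxa:
            for comp in self.components:
                state = self.cells.get((taxon, comp))
                if state is None:
                    raise ValueError(f"missing state for ({taxon}, {comp})")
                if state not in _STATE_TO_CELL:
                    raise ValueError(f"unknown state {state!r} for ({taxon}, {comp})")

    def state(self, taxon: str, component: str) -> str:
        return self.cells[(taxon, component)]

    def is_present(self, taxon: str, component: str) -> bool:
        return self.cells[(taxon, component)] in (PRESENT, PRESENT_EXTRA)

    def column(self, component: str) -> dict[str, bool]:
        if component not in self.components:
            raise KeyError(f"unknown component {component!r}")
        return {t: self.is_present(t, component) for t in self.taxa}


def parse_presence_matrix(path: str | Path) -> PresenceMatrix:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip() and not l.startswith("#")]
    header = lines[0].split("\t")
    components = header[1:]
    taxa: list[str] = []
    cells: dict[tuple[str, str], str] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(components) + 1:
            raise ValueError(f"line {lineno}: expected {len(components) + 1} columns")
        taxon = parts[0]
        taxa.append(taxon)
        for comp, cell in zip(components, parts[1:]):
            if cell not in _CELL_TO_STATE:
                raise ValueError(f"line {lineno}: unknown cell {cell!r}")
            cells[(taxon, comp)] = _CELL_TO_STATE[cell]
    return PresenceMatrix(taxa, components, cells)


def write_presence_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("taxon\t" + "\t".join(matrix.components) + "\n")
        for taxon in matrix.taxa:
            row = [_STATE_TO_CELL[matrix.cells[(taxon, c)]] for c in matrix.components]
            out.write(taxon + "\t" + "\t".join(row) + "\n")
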