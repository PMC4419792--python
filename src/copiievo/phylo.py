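"""Alignment, distance and tree inference.

This is the internal inference stack: a progressive profile-profile aligner
(k-mer UPGMA guide tree), automated gap-fraction column trimming,
Poisson-corrected distances with pairwise gap deletion, neighbor-joining, and
nonparametric bootstrap supports painted onto the full-data topology.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage

from ._dp import global_path
from ._scoring import AA_INDEX, GAP, ScoringScheme
from .formats import PhyloTree, SequenceRecord, TreeNode, canonical_side

__all__ = [
    "Msa",
    "DistanceMatrix",
    "SaturationError",
    "progressive_align",
    "trim_columns",
    "p_distance",
    "poisson_correct",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_tree",
]

_GAP_CODE = 255
DEFAULT_SATURATION_P = 0.95


class SaturationError(ValueError):
    """Raised when a pairwise distance is beyond correction (p >= 1 or no sites)."""


def _encode_aligned(residues: str) -> np.ndarray:
    out = np.empty(len(residues), dtype=np.uint8)
    for i, c in enumerate(residues):
        out[i] = _GAP_CODE if c == GAP else AA_INDEX[c]
    return out


# ---------------------------------------------------------------------------
# MSA container
# ---------------------------------------------------------------------------

@dataclass
class Msa:
    """Aligned records plus a boolean column mask (True = kept by trimming)."""

    records: list[SequenceRecord]
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) > 1:
            raise ValueError("MSA rows have unequal lengths")
        width = lengths.pop() if lengths else 0
        if self.mask is None:
            self.mask = np.ones(width, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != width:
            raise ValueError("mask length does not match alignment width")

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def width(self) -> int:
        return len(self.mask)

    @property
    def n_kept_columns(self) -> int:
        return int(self.mask.sum())

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def codes(self) -> np.ndarray:
        """Integer matrix (rows x width); gaps are 255."""
        return np.vstack([_encode_aligned(r.residues) for r in self.records])

    def masked_codes(self) -> np.ndarray:
        return self.codes()[:, self.mask]

    def subset(self, ids: Iterable[str]) -> "Msa":
        wanted = list(ids)
        by_id = {r.id: r for r in self.records}
        missing = [i for i in wanted if i not in by_id]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        return Msa([by_id[i] for i in wanted], self.mask.copy())

    def record(self, rid: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rid:
                return r
        raise KeyError(rid)


# ---------------------------------------------------------------------------
# progressive alignment
# ---------------------------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    def counts(s: str) -> dict[str, int]:
        d: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            d[w] = d.get(w, 0) + 1
        return d

    ca, cb = counts(a), counts(b)
    shared = sum(min(n, cb.get(w, 0)) for w, n in ca.items())
    denom = min(max(len(a) - k + 1, 1), max(len(b) - k + 1, 1))
    return 1.0 - shared / denom


def _profile(rows: list[np.ndarray]) -> np.ndarray:
    """Column frequency profile over the 21-letter alphabet (gaps weight 0)."""
    width = len(rows[0])
    prof = np.zeros((width, 21))
    for row in rows:
        valid = row != _GAP_CODE
        prof[np.arange(width)[valid], row[valid]] += 1.0
    return prof / len(rows)


def progressive_align(
    records: Sequence[SequenceRecord],
    scheme: ScoringScheme | None = None,
    *,
    guide_k: int = 3,
) -> Msa:
    """Progressive multiple alignment.

    Guide tree: UPGMA on k-mer distances (k=3 by default); merges are global
    profile-profile alignments with affine gaps.  Input rows are sorted
    lexicographically by id first, so the result is invariant under input
    permutation.
    """
    if len(records) < 2:
        raise ValueError("progressive_align needs at least 2 records")
    scheme = scheme or ScoringScheme()
    ordered = sorted(records, key=lambda r: r.id)
    seqs = [r.residues.replace(GAP, "") for r in ordered]

    n = len(ordered)
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            condensed.append(_kmer_distance(seqs[i], seqs[j], guide_k))
    Z = linkage(np.array(condensed), method="average")

    # each cluster: (member indices, list of aligned code rows)
    clusters: dict[int, tuple[list[int], list[np.ndarray]]] = {
        i: ([i], [_encode_aligned(seqs[i])]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        ma, rows_a = clusters.pop(ia)
        mb, rows_b = clusters.pop(ib)
        pa, pb = _profile(rows_a), _profile(rows_b)
        S = pa @ scheme.matrix @ pb.T
        _, pairs = global_path(S, scheme.gap_open, scheme.gap_extend)
        new_a = _merge_rows(rows_a, [p[0] for p in pairs])
        new_b = _merge_rows(rows_b, [p[1] for p in pairs])
        clusters[n + step] = (ma + mb, new_a + new_b)

    members, rows = next(iter(clusters.values()))
    aligned: list[SequenceRecord | None] = [None] * n
    for idx, row in zip(members, rows):
        src = ordered[idx]
        aligned[idx] = SequenceRecord(
            src.id,
            src.taxon,
            src.supergroup,
            src.component,
            _decode_aligned(row),
            true_paralog=src.true_paralog,
        )
    return Msa([r for r in aligned if r is not None])


def _decode_aligned(row: np.ndarray) -> str:
    from ._scoring import ALPHABET

    return "".join(GAP if c == _GAP_CODE else ALPHABET[c] for c in row)


def _merge_rows(rows: list[np.ndarray], path: list[int]) -> list[np.ndarray]:
    """Expand aligned rows with gap columns wherever the path skips them."""
    out = []
    for row in rows:
        new = np.full(len(path), _GAP_CODE, dtype=np.uint8)
        for pos, idx in enumerate(path):
            if idx >= 0:
                new[pos] = row[idx]
        out.append(new)
    return out


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def trim_columns(msa: Msa, max_gap_fraction: float = 0.5) -> Msa:
    """Mask columns whose gap fraction exceeds the threshold.

    All-gap columns are always masked; relative column order is preserved and
    the mask is recorded so sub-datasets reuse identical columns.
    """
    codes = msa.codes()
    gap_frac = (codes == _GAP_CODE).mean(axis=0)
    keep = msa.mask & (gap_frac <= max_gap_fraction) & (gap_frac < 1.0)
    if not keep.any():
        raise ValueError("no informative sites: every column masked")
    return Msa(list(msa.records), keep)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def p_distance(msa: Msa, i: int, j: int) -> float:
    """Observed proportion of differing sites (pairwise gap deletion)."""
    codes = msa.masked_codes()
    a, b = codes[i], codes[j]
    comparable = (a != _GAP_CODE) & (b != _GAP_CODE)
    n = int(comparable.sum())
    if n == 0:
        raise SaturationError(f"no comparable sites between rows {i} and {j}")
    return float((a[comparable] != b[comparable]).sum() / n)


def poisson_correct(p: float, *, saturation: float = 1.0) -> float:
    """Poisson multiple-hit correction d = -ln(1 - p)."""
    if p < 0:
        raise ValueError("p must be >= 0")
    if p >= saturation:
        raise SaturationError(f"p = {p} beyond correction")
    return -math.log1p(-p)


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be 0")
        if not np.isfinite(self.values).all():
            raise ValueError("distance matrix entries must be finite")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


def distance_matrix(
    msa: Msa,
    *,
    saturation_p: float = DEFAULT_SATURATION_P,
    codes: np.ndarray | None = None,
) -> DistanceMatrix:
    """Poisson-corrected distances over the masked columns.

    Saturated pairs (p >= ``saturation_p`` or no overlapping sites) are set to
    twice the largest finite corrected distance, with a warning.
    """
    M = msa.masked_codes() if codes is None else codes
    n = M.shape[0]
    d = np.zeros((n, n))
    saturated: list[tuple[int, int]] = []
    for i in range(n):
        ai = M[i]
        for j in range(i + 1, n):
            bj = M[j]
            comp = (ai != _GAP_CODE) & (bj != _GAP_CODE)
            nc = int(comp.sum())
            if nc == 0:
                saturated.append((i, j))
                continue
            p = float((ai[comp] != bj[comp]).sum() / nc)
            if p >= saturation_p:
                saturated.append((i, j))
                continue
            d[i, j] = d[j, i] = -math.log1p(-p)
    ids = msa.ids()
    sat_names: list[tuple[str, str]] = []
    if saturated:
        finite_max = d.max()
        if finite_max <= 0:
            raise SaturationError("every pairwise distance is saturated")
        fill = 2.0 * finite_max
        for i, j in saturated:
            d[i, j] = d[j, i] = fill
            sat_names.append((ids[i], ids[j]))
        warnings.warn(
            f"{len(saturated)} saturated pair(s) set to {fill:.3f} (2x max finite distance)",
            stacklevel=2,
        )
    return DistanceMatrix(ids, d, sat_names)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Standard NJ agglomeration; unrooted (basal trifurcation).

    Negative branch-length estimates are clamped to 0 with the deficit
    transferred to the sister edge; ties in the Q criterion break on the
    lexicographically smallest pair of cluster labels (a cluster is labelled
    by its smallest member id).
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name) for name in dm.ids]
    labels: list[str] = list(dm.ids)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        iu, ju = np.triu_indices(m, 1)
        vals = Q[iu, ju]
        qmin = vals.min()
        best: tuple[str, str] | None = None
        bi = bj = -1
        for t in np.nonzero(vals == qmin)[0]:
            i, j = int(iu[t]), int(ju[t])
            key = tuple(sorted((labels[i], labels[j])))
            if best is None or key < best:
                best = key
                bi, bj = i, j
        li = 0.5 * d[bi, bj] + (r[bi] - r[bj]) / (2 * (m - 2))
        lj = d[bi, bj] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[bi], nodes[bj]
        child_i.length = li
        child_j.length = lj
        new = TreeNode(None, 0.0, [child_i, child_j])
        du = 0.5 * (d[bi, :] + d[bj, :] - d[bi, bj])
        keep = [k for k in range(m) if k not in (bi, bj)]
        new_d = np.zeros((len(keep) + 1, len(keep) + 1))
        sub = d[np.ix_(keep, keep)]
        new_d[:-1, :-1] = sub
        new_d[-1, :-1] = du[keep]
        new_d[:-1, -1] = du[keep]
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [min(best)]
        d = np.maximum(new_d, 0.0)

    if len(nodes) == 3:
        dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
        la = max(0.5 * (dab + dac - dbc), 0.0)
        lb = max(0.5 * (dab + dbc - dac), 0.0)
        lc = max(0.5 * (dac + dbc - dab), 0.0)
        for node, length in zip(nodes, (la, lb, lc)):
            node.length = length
        root = TreeNode(None, 0.0, nodes)
    else:  # pragma: no cover - unreachable given n >= 3 guard
        raise AssertionError
    return PhyloTree(root, rooted=False)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_tree(
    msa: Msa,
    n_reps: int = 100,
    seed: int = 0,
    *,
    saturation_p: float = DEFAULT_SATURATION_P,
) -> PhyloTree:
    """NJ tree with bootstrap supports on the full-data topology.

    Masked columns are resampled with replacement ``n_reps`` times; each
    internal branch's support is the percentage of replicate trees containing
    its bipartition.  ``n_reps == 0`` returns the full-data tree with no
    supports.  Deterministic for a given seed.
    """
    if n_reps < 0:
        raise ValueError("n_reps must be >= 0")
    if msa.n_rows < 4:
        raise ValueError("bootstrap_tree needs at least 4 rows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = neighbor_joining(distance_matrix(msa, saturation_p=saturation_p))
    if n_reps == 0:
        return full
    codes = msa.masked_codes()
    n_cols = codes.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {side: 0 for side in full.bipartitions()}
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_codes = codes[:, cols]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dm = distance_matrix(msa, saturation_p=saturation_p, codes=rep_codes)
                rep_tree = neighbor_joining(dm)
        except SaturationError:
            continue
        rep_sides = set(rep_tree.bipartitions())
        for side in counts:
            if side in rep_sides:
                counts[side] += 1
    all_leaves = frozenset(full.leaf_names())
    for node in full.root.preorder():
        if node is full.root or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        key = canonical_side(side, all_leaves)
        node.supports["bootstrap"] = 100.0 * counts[key] / n_reps
    return full
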