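"""Similarity search and orthology classification.

The search engine is an exact Smith-Waterman with affine gaps (desk-scale
datasets make heuristic seeding unnecessary); significance uses the
Karlin-Altschul form E = K*m*n*exp(-lambda*S) with fixed per-scheme
constants.  Orthology follows the reciprocal-best-hit rule: a candidate is an
ortholog of a reference component iff its top reverse-search hit against the
reference proteome is one of the expected reference sequences AND the next
best hit's E-value is at least two orders of magnitude larger.  A PSSM
profile search provides the fallback for families that raw pairwise search
misses, and a cascade retries the search with progressively closer reference
species.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._dp import local_path
from ._scoring import AA20, AA_INDEX, BACKGROUND_FREQS, GAP, ScoringScheme, encode
from .formats import HitRecord, HitTable, SequenceRecord

__all__ = [
    "ScoringScheme",
    "LocalAlignment",
    "local_align",
    "evalue",
    "search_all",
    "RbhVerdict",
    "rbh_classify",
    "Pssm",
    "build_pssm",
    "pssm_search",
    "CascadeResult",
    "cascade_search",
]

DEFAULT_FORWARD_EVALUE_MAX = 1e-3
DEFAULT_RATIO_THRESHOLD = 1e2


# ---------------------------------------------------------------------------
# pairwise local alignment
# ---------------------------------------------------------------------------

@dataclass
class LocalAlignment:
    raw_score: int
    a_aligned: str
    b_aligned: str
    a_start: int
    a_end: int  # exclusive
    b_start: int
    b_end: int

    @property
    def length(self) -> int:
        return len(self.a_aligned)

    @property
    def identities(self) -> int:
        return sum(1 for x, y in zip(self.a_aligned, self.b_aligned) if x == y and x != GAP)

    @property
    def mismatches(self) -> int:
        return sum(
            1
            for x, y in zip(self.a_aligned, self.b_aligned)
            if x != GAP and y != GAP and x != y
        )

    @property
    def gap_opens(self) -> int:
        opens = 0
        in_gap = False
        for x, y in zip(self.a_aligned, self.b_aligned):
            if x == GAP or y == GAP:
                if not in_gap:
                    opens += 1
                in_gap = True
            else:
                in_gap = False
        return opens


def local_align(a: str, b: str, scheme: ScoringScheme | None = None) -> LocalAlignment:
    """Exact Smith-Waterman local alignment with affine gaps.

    The score is the maximum over all local alignments; a pair with no
    positive-scoring alignment returns score 0 and an empty alignment.
    """
    if not a or not b:
        raise ValueError("local_align requires non-empty sequences")
    scheme = scheme or ScoringScheme()
    ai, bi = encode(a.upper()), encode(b.upper())
    S = scheme.matrix[np.ix_(ai, bi)]
    score, pairs, (si, sj), (ei, ej) = local_path(S, scheme.gap_open, scheme.gap_extend)
    a_aln = "".join(a[i] if i >= 0 else GAP for i, _ in pairs)
    b_aln = "".join(b[j] if j >= 0 else GAP for _, j in pairs)
    return LocalAlignment(
        raw_score=int(round(score)),
        a_aligned=a_aln,
        b_aligned=b_aln,
        a_start=si,
        a_end=ei,
        b_start=sj,
        b_end=ej,
    )


def evalue(raw_score: float, m: int, n: int, scheme: ScoringScheme | None = None) -> float:
    """Karlin-Altschul expected number of chance hits at raw score >= S."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    scheme = scheme or ScoringScheme()
    return scheme.karlin_K * m * n * math.exp(-scheme.karlin_lambda * raw_score)


def bitscore(raw_score: float, scheme: ScoringScheme | None = None) -> float:
    scheme = scheme or ScoringScheme()
    return (scheme.karlin_lambda * raw_score - math.log(scheme.karlin_K)) / math.log(2.0)


def search_all(
    queries: Sequence[SequenceRecord],
    database: Sequence[SequenceRecord],
    scheme: ScoringScheme | None = None,
    *,
    evalue_max: float | None = None,
) -> HitTable:
    """All-against-all local search.

    Hits for each query are sorted by ascending E-value, then descending raw
    score, then subject id.  ``evalue_max`` (if given) drops weaker hits.
    """
    if not database:
        raise ValueError("empty database")
    scheme = scheme or ScoringScheme()
    table = HitTable()
    for query in queries:
        hits: list[HitRecord] = []
        for subject in database:
            aln = local_align(query.residues, subject.residues, scheme)
            if aln.raw_score <= 0:
                continue
            e = evalue(aln.raw_score, len(query.residues), len(subject.residues), scheme)
            if evalue_max is not None and e > evalue_max:
                continue
            ident = 100.0 * aln.identities / aln.length if aln.length else 0.0
            hits.append(
                HitRecord(
                    query_id=query.id,
                    subject_id=subject.id,
                    pident=ident,
                    aln_len=aln.length,
                    mismatch=aln.mismatches,
                    gapopen=aln.gap_opens,
                    qstart=aln.a_start + 1,
                    qend=aln.a_end,
                    sstart=aln.b_start + 1,
                    send=aln.b_end,
                    evalue=e,
                    bitscore=bitscore(aln.raw_score, scheme),
                    raw_score=aln.raw_score,
                )
            )
        hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.subject_id))
        table.records.extend(hits)
    return table


# ---------------------------------------------------------------------------
# reciprocal best hit
# ---------------------------------------------------------------------------

@dataclass
class RbhVerdict:
    candidate_id: str
    status: str  # "ortholog" | "unconfirmed"
    reason: str
    top_hit: str | None = None
    ratio: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def is_ortholog(self) -> bool:
        return self.status == "ortholog"


def rbh_classify(
    candidate_id: str,
    forward_hits: HitTable | None,
    reverse_hits: HitTable,
    expected_ids: Iterable[str],
    *,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> RbhVerdict:
    """Apply the reciprocal-best-hit orthology rule.

    ``reverse_hits`` are the candidate's hits against the reference proteome;
    ``expected_ids`` is the set of reference sequences for the component under
    test.  Ortholog iff the rank-1 reverse hit is expected and
    (next-best E) / (top E) >= ratio_threshold.  A singleton reverse hit list
    is ruled ortholog-if-expected and flagged "single-hit"; the forward table
    only nominates candidates and does not enter the rule.
    """
    expected = set(expected_ids)
    hits = sorted(
        (h for h in reverse_hits if h.query_id == candidate_id),
        key=lambda h: (h.evalue, -h.raw_score, h.subject_id),
    )
    if not hits:
        return RbhVerdict(candidate_id, "unconfirmed", "no-hit")
    top = hits[0]
    if top.subject_id not in expected:
        return RbhVerdict(
            candidate_id, "unconfirmed", "top-hit-not-expected", top_hit=top.subject_id
        )
    if len(hits) == 1:
        return RbhVerdict(
            candidate_id, "ortholog", "single-hit", top_hit=top.subject_id, flags=["single-hit"]
        )
    nxt = hits[1]
    if top.evalue == 0.0:
        ratio = math.inf
    else:
        ratio = nxt.evalue / top.evalue
    if ratio >= ratio_threshold:
        return RbhVerdict(candidate_id, "ortholog", "rbh", top_hit=top.subject_id, ratio=ratio)
    return RbhVerdict(
        candidate_id, "unconfirmed", "ambiguous-margin", top_hit=top.subject_id, ratio=ratio
    )


# ---------------------------------------------------------------------------
# PSSM profile search (stand-in for a profile-HMM search)
# ---------------------------------------------------------------------------

@dataclass
class Pssm:
    """Per-column log-odds scores (bits) over the 20 amino acids."""

    scores: np.ndarray  # (columns, 20)
    pseudocount: float
    source_id: str = ""

    @property
    def width(self) -> int:
        return self.scores.shape[0]


def build_pssm(
    records: Sequence[SequenceRecord],
    pseudocount: float = 1.0,
    *,
    max_gap_fraction: float = 0.5,
    source_id: str = "",
) -> Pssm:
    """Build a log-odds PSSM from aligned sequences.

    Columns with more than ``max_gap_fraction`` gaps are dropped before
    scoring; counts get ``pseudocount`` background-proportional smoothing.
    """
    if len(records) < 2:
        raise ValueError("a PSSM needs at least 2 aligned sequences")
    lengths = {len(r.residues) for r in records}
    if len(lengths) != 1:
        raise ValueError("records are not aligned (unequal lengths)")
    n = len(records)
    cols = []
    for j in range(lengths.pop()):
        column = [r.residues[j] for r in records]
        if column.count(GAP) / n > max_gap_fraction:
            continue
        cols.append(column)
    if not cols:
        raise ValueError("no informative columns after gap filtering")
    scores = np.zeros((len(cols), 20))
    for j, column in enumerate(cols):
        counts = np.zeros(20)
        for c in column:
            idx = AA_INDEX.get(c)
            if idx is not None and idx < 20:
                counts[idx] += 1
        total = counts.sum()
        probs = (counts + pseudocount * BACKGROUND_FREQS) / (total + pseudocount)
        with np.errstate(divide="ignore"):
            col = np.log2(probs / BACKGROUND_FREQS)
        # keep scores finite even at pseudocount 0 (absent residue floor)
        scores[j] = np.maximum(col, -30.0)
    return Pssm(scores=scores, pseudocount=pseudocount, source_id=source_id)


def pssm_score(pssm: Pssm, residues: str) -> float:
    """Best ungapped placement score of the PSSM along a sequence (bits)."""
    idx = encode(residues.upper())
    w = pssm.width
    n = len(idx)
    per_col = np.zeros((w, n))
    valid = idx < 20
    per_col[:, valid] = pssm.scores[:, idx[valid]]
    best = -math.inf
    # slide the profile over the sequence; when the sequence is shorter than
    # the profile, partial placements use the overlapping columns only
    for offset in range(-(w - 1), n):
        lo = max(0, -offset)
        hi = min(w, n - offset)
        if hi - lo < min(w, n):
            continue
        s = float(per_col[np.arange(lo, hi), np.arange(lo + offset, hi + offset)].sum())
        if s > best:
            best = s
    return best


def pssm_search(pssm: Pssm, database: Sequence[SequenceRecord]) -> HitTable:
    """Score every database sequence against the profile; rank by score.

    E-values use the ungapped bit-score convention E = m*n*2^-S.
    """
    if not database:
        raise ValueError("empty database")
    table = HitTable()
    scored = []
    for rec in database:
        s = pssm_score(pssm, rec.residues)
        e = pssm.width * len(rec.residues) * math.pow(2.0, -s) if math.isfinite(s) else math.inf
        scored.append((rec, s, min(e, 1e300)))
    scored.sort(key=lambda t: (-t[1], t[0].id))
    for rec, s, e in scored:
        table.records.append(
            HitRecord(
                query_id=pssm.source_id or "pssm",
                subject_id=rec.id,
                pident=0.0,
                aln_len=pssm.width,
                mismatch=0,
                gapopen=0,
                qstart=1,
                qend=pssm.width,
                sstart=1,
                send=len(rec.residues),
                evalue=e,
                bitscore=s,
                raw_score=int(round(s)),
            )
        )
    return table


# ---------------------------------------------------------------------------
# cascading query strategy
# ---------------------------------------------------------------------------

@dataclass
class CascadeResult:
    status: str  # "present" | "absent"
    component: str
    candidate_ids: list[str] = field(default_factory=list)
    winning_reference: str | None = None
    winning_rank: int | None = None
    attempts: list[dict] = field(default_factory=list)

    @property
    def is_present(self) -> bool:
        return self.status == "present"


def cascade_search(
    target_proteome: Sequence[SequenceRecord],
    component: str,
    references: Sequence[tuple[SequenceRecord, Sequence[SequenceRecord]]],
    scheme: ScoringScheme | None = None,
    *,
    forward_evalue_max: float = DEFAULT_FORWARD_EVALUE_MAX,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> CascadeResult:
    """Search a taxon for a component with neighbor-ordered references.

    ``references`` is an ordered list (closest species first) of
    ``(reference sequence, reference proteome)`` pairs.  The first reference
    whose forward search plus reciprocal confirmation yields an ortholog wins;
    provenance records every attempt.  All references exhausted -> absent.
    """
    scheme = scheme or ScoringScheme()
    result = CascadeResult(status="absent", component=component)
    for rank, (ref_seq, ref_proteome) in enumerate(references, start=1):
        forward = search_all([ref_seq], target_proteome, scheme, evalue_max=forward_evalue_max)
        attempt = {
            "reference": ref_seq.id,
            "rank": rank,
            "forward_hits": [h.subject_id for h in forward],
        }
        expected = [r.id for r in ref_proteome if r.component == component]
        confirmed: list[str] = []
        for hit in forward:
            candidate = next(t for t in target_proteome if t.id == hit.subject_id)
            reverse = search_all([candidate], ref_proteome, scheme)
            verdict = rbh_classify(
                candidate.id, forward, reverse, expected, ratio_threshold=ratio_threshold
            )
            if verdict.is_ortholog:
                confirmed.append(candidate.id)
        attempt["confirmed"] = confirmed
        result.attempts.append(attempt)
        if confirmed:
            result.status = "present"
            result.candidate_ids = confirmed
            result.winning_reference = ref_seq.id
            result.winning_rank = rank
            return result
    return result
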