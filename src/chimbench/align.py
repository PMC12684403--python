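"""Pairwise alignment layer: global identity, semi-global identity/coverage,
and iterative multi-HSP local alignment.

Scoring mirrors the short-word BLASTN costs commonly used for ITS work:
match +1, mismatch -1, gap of length L costs 1 + 2L (open 1, extend 2).
``N`` is treated as mismatching every base, including ``N`` itself, so masked
intervals can never re-align. Identity denominators include gap columns
(BLAST convention). All dynamic programming is delegated to
:class:`Bio.Align.PairwiseAligner`; this module owns the contracts (identity,
coverage, HSP iteration with query masking, best-hit selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import AmpliconRecord, revcomp

__all__ = [
    "ScoringParams",
    "GlobalAlignment",
    "Hsp",
    "AlignmentHit",
    "align_global",
    "align_semiglobal",
    "find_hsps",
    "best_hit",
    "hits_to_tsv",
]


@dataclass(frozen=True)
class ScoringParams:
    """Match/mismatch/affine-gap scoring. Gap of length L costs open + extend*L."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -1
    gap_extend: int = -2


def _matrix(params: ScoringParams):
    m = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGTN":
        for y in "ACGTN":
            m[x, y] = params.match if (x == y and x != "N") else params.mismatch
    return m


def _make_aligner(params: ScoringParams, mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = _matrix(params)
    a.mode = mode
    # Biopython charges `open` on the first gap column and `extend` on the
    # rest; BLAST-style open+extend*L therefore maps to open+extend, extend.
    a.open_gap_score = params.gap_open + params.gap_extend
    a.extend_gap_score = params.gap_extend
    return a


def _column_stats(row_a: str, row_b: str) -> tuple[int, int]:
    """(matches, columns); N never matches."""
    matches = sum(
        1 for x, y in zip(row_a, row_b) if x == y and x not in ("-", "N")
    )
    return matches, len(row_a)


@dataclass
class GlobalAlignment:
    """One optimal global alignment with a per-column view."""

    identity_pct: float
    n_columns: int
    score: int
    a_gapped: str
    b_gapped: str

    @property
    def column_map(self) -> list[tuple[Optional[str], Optional[str]]]:
        return [
            (None if x == "-" else x, None if y == "-" else y)
            for x, y in zip(self.a_gapped, self.b_gapped)
        ]

    def match_vector_b(self) -> np.ndarray:
        """Boolean per-position vector over sequence *b*: position matched in *a*."""
        out = np.zeros(sum(1 for c in self.b_gapped if c != "-"), dtype=bool)
        j = 0
        for x, y in zip(self.a_gapped, self.b_gapped):
            if y != "-":
                out[j] = x == y and x not in ("-", "N")
                j += 1
        return out


def align_global(a: str, b: str, params: ScoringParams = ScoringParams()) -> GlobalAlignment:
    """Optimal global alignment of two sequences."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(params, "global")
    aln = aligner.align(a.upper(), b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches, columns = _column_stats(row_a, row_b)
    return GlobalAlignment(
        identity_pct=100.0 * matches / columns,
        n_columns=columns,
        score=int(aln.score),
        a_gapped=row_a,
        b_gapped=row_b,
    )


@dataclass(frozen=True)
class Hsp:
    """One high-scoring segment pair (half-open query/target coordinates)."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    score: int
    identity_pct: float
    strand: str = "+"

    def __post_init__(self):
        if not (self.q_start < self.q_end and self.t_start < self.t_end):
            raise ValueError("HSP intervals must be nonempty")

    def query_coverage_pct(self, query_length: int) -> float:
        return 100.0 * (self.q_end - self.q_start) / query_length


@dataclass
class AlignmentHit:
    """Alignment of one query against one target, possibly in several HSPs."""

    query_id: str
    target_id: str
    query_length: int
    hsps: list[Hsp] = field(default_factory=list)

    @property
    def total_score(self) -> int:
        return sum(h.score for h in self.hsps)

    @property
    def best_identity_pct(self) -> float:
        return max((h.identity_pct for h in self.hsps), default=0.0)

    @property
    def query_coverage_pct(self) -> float:
        # HSP query intervals are pairwise disjoint (masking), so sum is exact.
        covered = sum(h.q_end - h.q_start for h in self.hsps)
        return 100.0 * covered / self.query_length

    @property
    def first_hsp(self) -> Optional[Hsp]:
        """Highest-scoring HSP ("first HSP" in BLAST report order)."""
        return self.hsps[0] if self.hsps else None


def align_semiglobal(
    query: str,
    target: str,
    params: ScoringParams = ScoringParams(),
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentHit:
    """Align the query end-to-end; target overhangs are free.

    Query coverage is 100 by construction; identity (computed over the columns
    spanned by the query, gaps included) carries the signal.
    """
    if not query or not target:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(params, "global")
    # Gaps in the query row (= unaligned target overhang) are free at the ends.
    aligner.open_left_deletion_score = 0
    aligner.extend_left_deletion_score = 0
    aligner.open_right_deletion_score = 0
    aligner.extend_right_deletion_score = 0
    aln = aligner.align(target.upper(), query.upper())[0]
    row_t, row_q = str(aln[0]), str(aln[1])
    # Trim to the columns actually spanned by the query.
    first = next(i for i, c in enumerate(row_q) if c != "-")
    last = len(row_q) - next(i for i, c in enumerate(reversed(row_q)) if c != "-")
    sub_t, sub_q = row_t[first:last], row_q[first:last]
    matches, columns = _column_stats(sub_t, sub_q)
    t_start = sum(1 for c in row_t[:first] if c != "-")
    t_aligned = sum(1 for c in sub_t if c != "-")
    hsp = Hsp(
        q_start=0,
        q_end=len(query),
        t_start=t_start,
        t_end=max(t_start + t_aligned, t_start + 1),
        score=int(aln.score),
        identity_pct=100.0 * matches / columns,
        strand="+",
    )
    return AlignmentHit(query_id=query_id, target_id=target_id, query_length=len(query), hsps=[hsp])


def _best_local(query: str, target: str, aligner) -> Optional[tuple]:
    """Best local alignment, or None when no positive-scoring alignment exists."""
    alns = aligner.align(query, target)
    if alns.score <= 0:
        return None
    aln = alns[0]
    if len(aln.aligned[0]) == 0:
        return None
    row_q, row_t = str(aln[0]), str(aln[1])
    q_start, q_end = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][-1])
    t_start, t_end = int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][-1])
    matches, columns = _column_stats(row_q, row_t)
    identity = 100.0 * matches / columns if columns else 0.0
    return int(aln.score), q_start, q_end, t_start, t_end, identity


def find_hsps(
    query: str,
    target: str,
    params: ScoringParams = ScoringParams(),
    max_hsps: int = 4,
    min_hsp_score: int = 30,
    both_strands: bool = True,
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentHit:
    """Iterative best-local-alignment HSP discovery with query masking.

    Each round takes the best local alignment on either strand, records it,
    masks its query interval with N (so rounds never overlap on the query) and
    repeats until ``max_hsps`` HSPs are found or the best score drops below
    ``min_hsp_score``. HSPs are returned sorted by score descending.
    """
    if max_hsps < 1:
        raise ValueError("max_hsps must be >= 1")
    if not query or not target:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(params, "local")
    q = query.upper()
    t = target.upper()
    L = len(q)
    masked = list(q)
    hsps: list[Hsp] = []
    for _ in range(max_hsps):
        cur = "".join(masked)
        best = None
        fwd = _best_local(cur, t, aligner)
        if fwd is not None and fwd[0] >= min_hsp_score:
            best = (*fwd, "+")
        if both_strands:
            rev = _best_local(revcomp(cur), t, aligner)
            if rev is not None and rev[0] >= min_hsp_score:
                if best is None or rev[0] > best[0]:
                    score, qs, qe, ts, te, ident = rev
                    best = (score, L - qe, L - qs, ts, te, ident, "-")
        if best is None:
            break
        score, qs, qe, ts, te, ident, strand = best
        hsps.append(
            Hsp(q_start=qs, q_end=qe, t_start=ts, t_end=te, score=score, identity_pct=ident, strand=strand)
        )
        for i in range(qs, qe):
            masked[i] = "N"
    hsps.sort(key=lambda h: (-h.score, h.q_start))
    return AlignmentHit(query_id=query_id, target_id=target_id, query_length=L, hsps=hsps)


def best_hit(
    query: AmpliconRecord,
    db: Sequence[AmpliconRecord],
    params: ScoringParams = ScoringParams(),
    exclude_self: bool = True,
    max_hsps: int = 4,
    min_hsp_score: int = 30,
    prescreen: Optional[int] = None,
) -> Optional[AlignmentHit]:
    """Highest-total-score hit over a database (ties: identity, then target id).

    Self-hits are excluded by record id. Returns None when nothing aligns.
    With ``prescreen`` set, only the top-``prescreen`` targets by shared 8-mer
    count are aligned (a seeding heuristic for large databases; alignment
    score tracks shared words closely, so the best hit is retained in
    practice); by default the scan is exhaustive.
    """
    if not db:
        raise ValueError("database is empty")
    targets = [t for t in db if not (exclude_self and t.id == query.id)]
    if prescreen is not None and len(targets) > prescreen:
        k = 8
        qk = frozenset(query.seq[i : i + k] for i in range(len(query.seq) - k + 1))

        def shared(t: AmpliconRecord) -> int:
            return sum(1 for i in range(len(t.seq) - k + 1) if t.seq[i : i + k] in qk)

        targets = sorted(targets, key=lambda t: (-shared(t), t.id))[:prescreen]
    best: Optional[AlignmentHit] = None
    for target in targets:
        hit = find_hsps(
            query.seq,
            target.seq,
            params=params,
            max_hsps=max_hsps,
            min_hsp_score=min_hsp_score,
            query_id=query.id,
            target_id=target.id,
        )
        if not hit.hsps:
            continue
        if best is None or (
            (-hit.total_score, -hit.best_identity_pct, hit.target_id)
            < (-best.total_score, -best.best_identity_pct, best.target_id)
        ):
            best = hit
    return best


def hits_to_tsv(hits: Sequence[AlignmentHit], path) -> None:
    """Write hits in BLAST outfmt-6-like columns (one row per HSP)."""
    import pandas as pd

    rows = []
    for hit in hits:
        for h in hit.hsps:
            rows.append(
                {
                    "qseqid": hit.query_id,
                    "sseqid": hit.target_id,
                    "pident": round(h.identity_pct, 3),
                    "length": h.q_end - h.q_start,
                    "qstart": h.q_start + 1,
                    "qend": h.q_end,
                    "sstart": h.t_start + 1,
                    "send": h.t_end,
                    "score": h.score,
                    "qcovhsp": round(h.query_coverage_pct(hit.query_length), 3),
                }
            )
    pd.DataFrame(
        rows,
        columns=["qseqid", "sseqid", "pident", "length", "qstart", "qend", "sstart", "send", "score", "qcovhsp"],
    ).to_csv(path, sep="\t", index=False)
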