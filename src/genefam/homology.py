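"""Family-membership search by exact local protein alignment.

A BLASTP-like search implemented as full Smith–Waterman dynamic
programming with affine gap penalties (a gap of length L costs
open + extend·L), Karlin–Altschul E-values with fixed gapped constants,
an inclusive E-value gate, and exact-duplicate removal. Default scoring
mirrors BLASTP defaults: BLOSUM62, gap open 11, gap extend 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord

log = logging.getLogger(__name__)

# BLAST's precomputed Karlin-Altschul constants for gapped BLOSUM62 (11,1).
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

_BLOSUM62 = None


def blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both positive).

    ``matrix`` maps a residue pair to a score; a Biopython substitution
    matrix or a plain dict of tuples works. A gap of length L costs
    ``gap_open + gap_extend * L``.
    """

    matrix: object = field(default_factory=blosum62)
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    def sub(self, a: str, b: str) -> float:
        return float(self.matrix[a, b])


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    score: float
    bitscore: float
    evalue: float
    query_span: tuple[int, int]    # 1-based inclusive
    subject_span: tuple[int, int]  # 1-based inclusive
    identity_fraction: float
    alignment_length: int = 0

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("local alignment score must be >= 0")
        if not 0.0 <= self.identity_fraction <= 1.0:
            raise ValueError("identity_fraction must lie in [0, 1]")


def smith_waterman(query, subject, scoring: ScoringScheme | None = None) -> AlignmentHit:
    """Optimal local alignment by affine-gap (Gotoh) dynamic programming.

    Returns the single best local alignment; among equal-scoring cells
    the one with lexicographically smallest (query_end, subject_end) is
    chosen. Spans are 1-based inclusive; a score of 0 (no positive-scoring
    local alignment) yields empty spans (0, 0).
    """
    scoring = scoring or ScoringScheme()
    q = query.residues if isinstance(query, SequenceRecord) else str(query)
    s = subject.residues if isinstance(subject, SequenceRecord) else str(subject)
    if not q or not s:
        raise ValueError("smith_waterman requires non-empty sequences")
    m, n = len(q), len(s)
    NEG = -1e18
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)  # gap in query (consumes subject)
    F = np.full((m + 1, n + 1), NEG)  # gap in subject (consumes query)
    # pointers: H: 0 local-start, 1 diag, 2 from E, 3 from F
    ptr_h = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptr_e = np.zeros((m + 1, n + 1), dtype=np.int8)  # 1: opened from H, 0: extended
    ptr_f = np.zeros((m + 1, n + 1), dtype=np.int8)
    go, ge = scoring.gap_open + scoring.gap_extend, scoring.gap_extend
    best, best_ij = 0.0, (0, 0)
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - go
            e_ext = E[i, j - 1] - ge
            if e_open >= e_ext:
                E[i, j], ptr_e[i, j] = e_open, 1
            else:
                E[i, j], ptr_e[i, j] = e_ext, 0
            f_open = H[i - 1, j] - go
            f_ext = F[i - 1, j] - ge
            if f_open >= f_ext:
                F[i, j], ptr_f[i, j] = f_open, 1
            else:
                F[i, j], ptr_f[i, j] = f_ext, 0
            diag = H[i - 1, j - 1] + scoring.sub(qi, s[j - 1])
            h, p = 0.0, 0
            if diag > h:
                h, p = diag, 1
            if E[i, j] > h:
                h, p = E[i, j], 2
            if F[i, j] > h:
                h, p = F[i, j], 3
            H[i, j], ptr_h[i, j] = h, p
            if h > best:  # strict: keeps smallest (i, j) on ties
                best, best_ij = h, (i, j)

    if best == 0.0:
        return AlignmentHit(
            _rid(query), _rid(subject), 0.0, 0.0, math.inf, (0, 0), (0, 0), 0.0, 0
        )
    # traceback
    i, j = best_ij
    qe, se = i, j
    identities = 0
    length = 0
    state = "H"
    while not (state == "H" and ptr_h[i, j] == 0):
        if state == "H":
            p = ptr_h[i, j]
            if p == 1:
                identities += q[i - 1] == s[j - 1]
                length += 1
                i, j = i - 1, j - 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            length += 1
            opened = ptr_e[i, j]
            j -= 1
            if opened:
                state = "H"
        else:  # F
            length += 1
            opened = ptr_f[i, j]
            i -= 1
            if opened:
                state = "H"
    qs, ss = i + 1, j + 1
    return AlignmentHit(
        query_id=_rid(query), subject_id=_rid(subject), score=best,
        bitscore=bitscore(best), evalue=math.nan,
        query_span=(qs, qe), subject_span=(ss, se),
        identity_fraction=identities / length if length else 0.0,
        alignment_length=length,
    )


def _rid(x) -> str:
    return x.id if isinstance(x, SequenceRecord) else "seq"


def bitscore(score: float, lam: float = DEFAULT_LAMBDA, K: float = DEFAULT_K) -> float:
    return (lam * score - math.log(K)) / math.log(2)


def evalue(score: float, m: int, n: int,
           lam: float = DEFAULT_LAMBDA, K: float = DEFAULT_K) -> float:
    """Karlin–Altschul expected number of chance hits: K·m·n·exp(−λ·score)."""
    if m < 1 or n < 1:
        raise ValueError("sequence and database lengths must be >= 1")
    if lam <= 0 or K <= 0:
        raise ValueError("Karlin-Altschul parameters must be positive")
    return K * m * n * math.exp(-lam * score)


def deduplicate(database: list[SequenceRecord]) -> list[SequenceRecord]:
    """Collapse exact-duplicate sequences, keeping the smallest id."""
    by_seq: dict[str, SequenceRecord] = {}
    for rec in database:
        prev = by_seq.get(rec.residues)
        if prev is None or rec.id < prev.id:
            if prev is not None:
                log.info("redundancy: %s collapsed into %s", prev.id, rec.id)
            by_seq[rec.residues] = rec
        else:
            log.info("redundancy: %s collapsed into %s", rec.id, prev.id)
    kept = set(r.id for r in by_seq.values())
    return [r for r in database if r.id in kept]


def search_family(
    queries: list[SequenceRecord],
    database: list[SequenceRecord],
    threshold: float = 1e-5,
    scoring: ScoringScheme | None = None,
    lam: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
) -> tuple[list[AlignmentHit], set[str]]:
    """Search every query against the database and gate on E-value.

    The gate is inclusive: a subject is accepted iff some query attains
    E <= threshold. Exact-duplicate subjects are collapsed beforehand;
    the database size n used in the E-value is the total residue count
    after deduplication. Hits are returned sorted by ascending E-value.
    """
    if threshold <= 0:
        raise ValueError("E-value threshold must be positive")
    if not database:
        return [], set()
    db = deduplicate(database)
    n = sum(len(r) for r in db)
    hits: list[AlignmentHit] = []
    accepted: set[str] = set()
    for query in queries:
        for subject in db:
            hit = smith_waterman(query, subject, scoring)
            hit.evalue = evalue(hit.score, len(query), n, lam, K)
            hits.append(hit)
            if hit.evalue <= threshold:
                accepted.add(subject.id)
    hits.sort(key=lambda h: (h.evalue, h.query_id, h.subject_id))
    return hits, accepted
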