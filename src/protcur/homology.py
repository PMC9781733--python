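"""Pairwise protein alignment and homolog search over an in-memory pool.

The aligner is an affine-gap Gotoh dynamic program (global Needleman-Wunsch
and local Smith-Waterman modes) scored with BLOSUM62 and BLAST's protein gap
defaults (open 11, extend 1; a gap of length L costs ``open + L * extend``).
Traceback ties are broken deterministically: a match/mismatch step is
preferred over a gap in sequence ``a``, which is preferred over a gap in
sequence ``b``.

Percent identity follows BLAST's ``pident`` convention: identical columns
divided by all columns of the aligned region, gap columns included.

The pool search is an exhaustive all-vs-all scan — adequate at the scale of
a curated seed list plus its homolog candidates; externally produced BLAST
tabular hits can be ingested instead for large pools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .io_formats import BlastHitRow, ProteinRecord

__all__ = [
    "PairwiseAlignment",
    "SearchHit",
    "pairwise_align",
    "is_exact_subsequence",
    "search_pool",
    "hits_from_blast",
    "DEFAULT_MIN_IDENTITY",
    "DEFAULT_MAX_HITS",
]

DEFAULT_MIN_IDENTITY = 80.0
DEFAULT_MAX_HITS = 1000
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

_NEG = -1e30

# BLOSUM62 as shipped with Biopython; letters absent from its alphabet
# (U, O, J) are scored as X but still count as ordinary letters when
# identical columns are tallied.
_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)
_SUB = np.asarray(_BLOSUM62, dtype=np.float64)
_X_INDEX = _ALPHABET.index("X")

_CHAR_TO_INDEX = np.full(128, _X_INDEX, dtype=np.int64)
for _i, _c in enumerate(_ALPHABET):
    _CHAR_TO_INDEX[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int64)
    return _CHAR_TO_INDEX[arr]


@dataclass(frozen=True)
class PairwiseAlignment:
    """An optimal gapped alignment of two sequences.

    ``mismatches`` counts columns holding two different residues;
    ``gap_columns`` counts columns with a gap in either row. For local mode
    ``a_span``/``b_span`` are the 1-based inclusive ranges of the aligned
    region in each input.
    """

    aligned_a: str
    aligned_b: str
    score: float
    mode: str
    a_span: Optional[tuple[int, int]] = None
    b_span: Optional[tuple[int, int]] = None

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    @property
    def matches(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-"
        )

    @property
    def mismatches(self) -> int:
        return sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x != y and x != "-" and y != "-"
        )

    @property
    def gap_columns(self) -> int:
        return sum(1 for x, y in zip(self.aligned_a, self.aligned_b) if x == "-" or y == "-")

    @property
    def identity_pct(self) -> float:
        if self.length == 0:
            return 0.0
        return 100.0 * self.matches / self.length

    def mismatch_positions_in_b(self) -> list[int]:
        """1-based positions in input ``b`` of mismatch columns."""
        out = []
        pos = self.b_span[0] - 1 if self.b_span else 0
        for x, y in zip(self.aligned_a, self.aligned_b):
            if y != "-":
                pos += 1
                if x != y and x != "-":
                    out.append(pos)
        return out


@dataclass(frozen=True)
class SearchHit:
    """One homolog-search hit of a query against a pool member."""

    query_acc: str
    subject_acc: str
    identity_pct: float
    score: float
    aln_length: int
    source: str = "builtin"

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError(f"identity_pct {self.identity_pct} outside [0, 100]")


# States: 0 = M (match/mismatch), 1 = Y (gap in a, consumes b),
# 2 = X (gap in b, consumes a), 3 = local-alignment start.
_M, _Y, _X, _START = 0, 1, 2, 3


@njit(cache=False)
def _gotoh_global(a, b, sub, gap_open, gap_extend):
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + gap_extend * i)
        ptrX[i, 0] = _X if i > 1 else _M
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + gap_extend * j)
        ptrY[0, j] = _Y if j > 1 else _M
    open_cost = gap_open + gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            # M: diagonal step; tie preference M > Y > X.
            best = M[i - 1, j - 1]
            arg = _M
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                arg = _Y
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                arg = _X
            M[i, j] = best + sub[ai, b[j - 1]]
            ptrM[i, j] = arg
            # Y: gap in a (consume b[j-1]).
            best = M[i, j - 1] - open_cost
            arg = _M
            if Y[i, j - 1] - gap_extend > best:
                best = Y[i, j - 1] - gap_extend
                arg = _Y
            if X[i, j - 1] - open_cost > best:
                best = X[i, j - 1] - open_cost
                arg = _X
            Y[i, j] = best
            ptrY[i, j] = arg
            # X: gap in b (consume a[i-1]).
            best = M[i - 1, j] - open_cost
            arg = _M
            if Y[i - 1, j] - open_cost > best:
                best = Y[i - 1, j] - open_cost
                arg = _Y
            if X[i - 1, j] - gap_extend > best:
                best = X[i - 1, j] - gap_extend
                arg = _X
            X[i, j] = best
            ptrX[i, j] = arg
    # Final state, preference M > Y > X.
    end_state = _M
    best = M[n, m]
    if Y[n, m] > best:
        best = Y[n, m]
        end_state = _Y
    if X[n, m] > best:
        best = X[n, m]
        end_state = _X
    return best, end_state, ptrM, ptrX, ptrY


@njit(cache=False)
def _gotoh_local(a, b, sub, gap_open, gap_extend):
    n, m = a.shape[0], b.shape[0]
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    ptrM = np.full((n + 1, m + 1), _START, dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    open_cost = gap_open + gap_extend
    best_score = 0.0
    best_i = 0
    best_j = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            # A cell with M == 0 and a START pointer is empty (no alignment
            # ends there); a START pointer with M > 0 marks an opening column.
            best = 0.0
            arg = _START
            pm = M[i - 1, j - 1]
            if pm > best and not (ptrM[i - 1, j - 1] == _START and pm == 0.0):
                best = pm
                arg = _M
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                arg = _Y
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                arg = _X
            val = best + sub[ai, b[j - 1]]
            if val <= 0.0:
                M[i, j] = 0.0
                ptrM[i, j] = _START
            elif arg == _START:
                M[i, j] = val
                ptrM[i, j] = _START
            else:
                M[i, j] = val
                ptrM[i, j] = arg
            best = M[i, j - 1] - open_cost
            arg = _M
            if Y[i, j - 1] - gap_extend > best:
                best = Y[i, j - 1] - gap_extend
                arg = _Y
            if X[i, j - 1] - open_cost > best:
                best = X[i, j - 1] - open_cost
                arg = _X
            Y[i, j] = best
            ptrY[i, j] = arg
            best = M[i - 1, j] - open_cost
            arg = _M
            if Y[i - 1, j] - open_cost > best:
                best = Y[i - 1, j] - open_cost
                arg = _Y
            if X[i - 1, j] - gap_extend > best:
                best = X[i - 1, j] - gap_extend
                arg = _X
            X[i, j] = best
            ptrX[i, j] = arg
            if M[i, j] > best_score:
                best_score = M[i, j]
                best_i = i
                best_j = j
    return best_score, best_i, best_j, ptrM, ptrX, ptrY


def _traceback(a, b, i, j, state, ptrM, ptrX, ptrY, local):
    """Walk pointer matrices back to (0,0) (global) or a local start cell."""
    out_a: list[str] = []
    out_b: list[str] = []
    while not (i == 0 and j == 0):
        if state == _M:
            prev = ptrM[i, j]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
            if local and prev == _START:
                break  # this M cell opened the local alignment
            state = prev
        elif state == _Y:
            prev = ptrY[i, j]
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
            state = prev
        else:  # _X
            prev = ptrX[i, j]
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            state = prev
    return "".join(reversed(out_a)), "".join(reversed(out_b)), i, j


def pairwise_align(
    a: str,
    b: str,
    mode: str = "global",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal affine-gap alignment of two protein sequences under BLOSUM62.

    ``mode`` is ``"global"`` (end-to-end) or ``"local"`` (best-scoring
    segment pair; empty alignment with score 0 if nothing scores positive).
    """
    if not a or not b:
        raise ValueError("pairwise_align requires two non-empty sequences")
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    a = a.upper()
    b = b.upper()
    ea, eb = _encode(a), _encode(b)
    if mode == "global":
        score, end_state, ptrM, ptrX, ptrY = _gotoh_global(
            ea, eb, _SUB, float(gap_open), float(gap_extend)
        )
        al_a, al_b, _, _ = _traceback(
            a, b, len(a), len(b), end_state, ptrM, ptrX, ptrY, local=False
        )
        return PairwiseAlignment(al_a, al_b, float(score), "global")
    score, bi, bj, ptrM, ptrX, ptrY = _gotoh_local(
        ea, eb, _SUB, float(gap_open), float(gap_extend)
    )
    if score <= 0.0:
        return PairwiseAlignment("", "", 0.0, "local", a_span=None, b_span=None)
    al_a, al_b, si, sj = _traceback(a, b, bi, bj, _M, ptrM, ptrX, ptrY, local=True)
    return PairwiseAlignment(
        al_a,
        al_b,
        float(score),
        "local",
        a_span=(si + 1, bi),
        b_span=(sj + 1, bj),
    )


def is_exact_subsequence(short: str, long: str) -> tuple[bool, Optional[int]]:
    """True iff ``short`` occurs contiguously in ``long``; leftmost 1-based hit."""
    if not short or not long:
        raise ValueError("both sequences must be non-empty")
    pos = long.upper().find(short.upper())
    if pos < 0:
        return False, None
    return True, pos + 1


def _sorted_hits(hits: list[SearchHit], max_hits: int) -> list[SearchHit]:
    hits.sort(key=lambda h: (-h.identity_pct, -h.score, h.subject_acc))
    return hits[:max_hits]


def search_pool(
    query: ProteinRecord,
    pool: Sequence[ProteinRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_hits: int = DEFAULT_MAX_HITS,
    organism_filter: Optional[str] = None,
    coverage_min: Optional[float] = None,
) -> list[SearchHit]:
    """Exhaustive local-alignment search of ``query`` against ``pool``.

    Keeps subjects whose local percent identity is >= ``min_identity``
    (and, when given, whose organism contains ``organism_filter`` and whose
    query coverage is >= ``coverage_min`` as a fraction of query length).
    Hits are sorted by identity desc, score desc, accession asc and truncated
    at ``max_hits``. The query is never its own hit.
    """
    hits: list[SearchHit] = []
    for rec in pool:
        if rec.accession == query.accession:
            continue
        if organism_filter is not None and organism_filter.lower() not in rec.organism.lower():
            continue
        aln = pairwise_align(query.sequence, rec.sequence, mode="local")
        if aln.length == 0 or aln.identity_pct < min_identity:
            continue
        if coverage_min is not None:
            covered = (aln.a_span[1] - aln.a_span[0] + 1) / len(query.sequence)
            if covered < coverage_min:
                continue
        hits.append(
            SearchHit(
                query_acc=query.accession,
                subject_acc=rec.accession,
                identity_pct=aln.identity_pct,
                score=aln.score,
                aln_length=aln.length,
                source="builtin",
            )
        )
    return _sorted_hits(hits, max_hits)


def hits_from_blast(
    rows: Sequence[BlastHitRow],
    pool: Sequence[ProteinRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_hits: int = DEFAULT_MAX_HITS,
    evalue_max: float = 10.0,
    organism_filter: Optional[str] = None,
) -> list[SearchHit]:
    """Convert ingested BLAST tabular rows into search hits.

    Applies the same identity threshold and sort contract as
    :func:`search_pool`; identities are taken from the file, not recomputed.
    Subjects must exist in ``pool``; missing accessions are an error.
    """
    by_acc = {rec.accession: rec for rec in pool}
    missing = sorted({r.subject_acc for r in rows} - set(by_acc))
    if missing:
        raise ValueError(f"BLAST subjects absent from the pool FASTA: {missing}")
    hits: list[SearchHit] = []
    for row in rows:
        if row.subject_acc == row.query_acc:
            continue
        if row.evalue > evalue_max:
            continue
        if row.percent_identity < min_identity:
            continue
        if organism_filter is not None:
            org = by_acc[row.subject_acc].organism
            if organism_filter.lower() not in org.lower():
                continue
        hits.append(
            SearchHit(
                query_acc=row.query_acc,
                subject_acc=row.subject_acc,
                identity_pct=row.percent_identity,
                score=row.bitscore,
                aln_length=row.aln_length,
                source="blast_tabular",
            )
        )
    return _sorted_hits(hits, max_hits)
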