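"""Built-in protein similarity search: affine-gap Smith–Waterman with
Karlin–Altschul e-value statistics.

The enzyme-classification stages consume 12-column tabular hits; those may
come from an external search tool or from this engine, interchangeably. The
engine makes no heuristic shortcuts beyond a provably safe score upper bound
used to skip hopeless pairs, so its hit set is exactly the set of pairs whose
optimal local alignment reaches the e-value cutoff.

Gap model: a gap of length k costs ``gap_open + k * gap_extend`` (both
penalties are negative; opening a gap therefore costs ``gap_open +
gap_extend`` for its first residue). Defaults are the classic BLOSUM62/11/1
scheme with the published gapped Karlin–Altschul constants λ=0.267, K=0.041.

E = K·m·n·exp(−λ·S);  bitscore = (λ·S − ln K) / ln 2.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

from Bio.Align import substitution_matrices

from .errors import UsageError
from .records import ProteinRecord, SimilarityHit


@lru_cache(maxsize=None)
def _load_matrix(name: str):
    mat = substitution_matrices.load(name)
    lookup = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            lookup[(a, b)] = float(mat[a, b])
    return lookup, min(lookup.values()), max(float(mat[a, a]) for a in mat.alphabet if a != "*")


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties and e-value constants."""

    matrix_name: str = "BLOSUM62"
    match: float | None = None      # used instead of a matrix when set
    mismatch: float | None = None
    gap_open: float = -11.0
    gap_extend: float = -1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise UsageError("gap penalties must be <= 0")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise UsageError("Karlin-Altschul lambda and K must be positive")

    def score(self, a: str, b: str) -> float:
        if self.match is not None:
            return self.match if a == b else (self.mismatch or 0.0)
        lookup, floor, _ = _load_matrix(self.matrix_name)
        # ambiguity letters absent from the matrix score as the matrix minimum
        return lookup.get((a, b), floor)

    @property
    def max_pair_score(self) -> float:
        if self.match is not None:
            return self.match
        return _load_matrix(self.matrix_name)[2]


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    raw_score: float
    bitscore: float
    evalue: float
    q_span: tuple  # (start, end) 1-based inclusive; (0, 0) for empty alignment
    s_span: tuple
    aligned_query: str = field(default="", compare=False)
    aligned_subject: str = field(default="", compare=False)


def local_align(a: str, b: str, scheme: ScoringScheme | None = None) -> AlignmentResult:
    """Optimal affine-gap Smith–Waterman alignment of *a* (query) vs *b*.

    Deterministic traceback: ties prefer the diagonal move, then the gap in the
    subject (consuming a query residue), then the gap in the query. An empty
    input yields score 0 with empty spans.
    """
    scheme = scheme or ScoringScheme()
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return AlignmentResult("", "", 0.0, _bitscore(0.0, scheme), math.inf, (0, 0), (0, 0))
    go, ge = scheme.gap_open, scheme.gap_extend
    NEG = -math.inf
    # H: best local score ending at (i, j); E: ending with a gap in b (up);
    # F: ending with a gap in a (left). Full matrices kept for traceback.
    H = [[0.0] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, la + 1):
        ai = a[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Ei1 = E[i], E[i - 1]
        Fi = F[i]
        for j in range(1, lb + 1):
            e = max(Hi1[j] + go + ge, Ei1[j] + ge)
            f = max(Hi[j - 1] + go + ge, Fi[j - 1] + ge)
            d = Hi1[j - 1] + scheme.score(ai, b[j - 1])
            h = max(0.0, d, e, f)
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0.0:
        return AlignmentResult("", "", 0.0, _bitscore(0.0, scheme),
                               estimate_evalue(0.0, la, lb, scheme), (0, 0), (0, 0))
    # traceback from (bi, bj), tie order: diagonal, up (E), left (F)
    aln_a: list[str] = []
    aln_b: list[str] = []
    i, j, state = bi, bj, "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i][j]
            if h == 0.0:
                break
            d = H[i - 1][j - 1] + scheme.score(a[i - 1], b[j - 1])
            if h == d:
                aln_a.append(a[i - 1])
                aln_b.append(b[j - 1])
                i, j = i - 1, j - 1
            elif h == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            aln_a.append(a[i - 1])
            aln_b.append("-")
            opened = H[i - 1][j] + go + ge
            state = "H" if E[i][j] == opened else "E"
            i -= 1
        else:  # F
            aln_a.append("-")
            aln_b.append(b[j - 1])
            opened = H[i][j - 1] + go + ge
            state = "H" if F[i][j] == opened else "F"
            j -= 1
    q_span = (i + 1, bi)
    s_span = (j + 1, bj)
    return AlignmentResult(
        "", "", best, _bitscore(best, scheme), estimate_evalue(best, la, lb, scheme),
        q_span, s_span, "".join(reversed(aln_a)), "".join(reversed(aln_b)),
    )


def _bitscore(score: float, scheme: ScoringScheme) -> float:
    return (scheme.karlin_lambda * score - math.log(scheme.karlin_k)) / math.log(2.0)


def estimate_evalue(score: float, m: int, n: int, scheme: ScoringScheme | None = None) -> float:
    """Karlin–Altschul expected hit count for *score* in an m×n search space."""
    scheme = scheme or ScoringScheme()
    if m <= 0 or n <= 0:
        raise UsageError("search-space dimensions m and n must be positive")
    if score < 0:
        raise UsageError("local-alignment scores are non-negative")
    return scheme.karlin_k * m * n * math.exp(-scheme.karlin_lambda * score)


def bitscore(score: float, scheme: ScoringScheme | None = None) -> float:
    return _bitscore(score, scheme or ScoringScheme())


def _hit_from_alignment(q: ProteinRecord, s: ProteinRecord, res: AlignmentResult,
                        evalue: float) -> SimilarityHit:
    pairs = list(zip(res.aligned_query, res.aligned_subject))
    aln_len = len(pairs)
    matches = sum(1 for x, y in pairs if x == y)
    mismatches = sum(1 for x, y in pairs if x != y and x != "-" and y != "-")
    gap_opens = 0
    for k, (x, y) in enumerate(pairs):
        if (x == "-" and (k == 0 or pairs[k - 1][0] != "-")) or (
            y == "-" and (k == 0 or pairs[k - 1][1] != "-")
        ):
            gap_opens += 1
    pident = 100.0 * matches / aln_len if aln_len else 0.0
    return SimilarityHit(
        query_id=q.protein_id, subject_id=s.protein_id,
        percent_identity=round(pident, 1), alignment_length=aln_len,
        mismatches=mismatches, gap_opens=gap_opens,
        qstart=res.q_span[0], qend=res.q_span[1],
        sstart=res.s_span[0], send=res.s_span[1],
        evalue=evalue, bitscore=round(res.bitscore, 1),
    )


def search(queries: Sequence[ProteinRecord], db: Sequence[ProteinRecord],
           evalue_cutoff: float, scheme: ScoringScheme | None = None,
           prefilter: bool = True) -> list[SimilarityHit]:
    """All query–subject pairs whose optimal local alignment reaches the cutoff.

    The e-value search space is (query length) × (total residues in *db*).
    The optional prefilter skips a pair only when even a perfect-match
    alignment of the shorter sequence could not reach the cutoff, so the hit
    set is identical with and without it. Hits are sorted by (query id,
    e-value, subject id).
    """
    scheme = scheme or ScoringScheme()
    if not db:
        raise UsageError("similarity search requires a non-empty database")
    n_total = sum(r.length for r in db)
    hits: list[SimilarityHit] = []
    for q in queries:
        for s in db:
            if prefilter and evalue_cutoff != math.inf:
                ub = min(q.length, s.length) * scheme.max_pair_score
                if estimate_evalue(ub, q.length, n_total, scheme) > evalue_cutoff:
                    continue
            res = local_align(q.sequence, s.sequence, scheme)
            ev = estimate_evalue(res.raw_score, q.length, n_total, scheme)
            if ev <= evalue_cutoff:
                hits.append(_hit_from_alignment(q, s, res, ev))
    hits.sort(key=lambda h: (h.query_id, h.evalue, h.subject_id))
    return hits
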