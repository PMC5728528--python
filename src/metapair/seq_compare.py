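"""Sequence identity, candidate prescreening, and reverse complement.

This module is the single authority on what "percent identity" means for
every downstream stage (clustering threshold, classifier hits, chimera
models, recovery matching).  The definition:

* semi-global dynamic-programming alignment — terminal gaps on either
  sequence are free, so a fragment aligning inside a longer sequence pays
  nothing for the overhangs;
* scoring +1 for a (IUPAC-compatible) match, -1 for a mismatch, -2 per gap
  position, linear gap cost;
* identity = 100 x matches / aligned_columns, computed over the aligned
  region only (terminal gaps excluded); internal gap columns count as
  mismatch columns;
* among equal-score alignments the canonical one maximizes matches, then
  minimizes columns (a lexicographic DP objective), which makes identity
  deterministic and symmetric in the two sequences;
* IUPAC ambiguity codes match any compatible base (intersecting base sets).

All coordinates are 0-based half-open on the plus strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "AlignmentResult",
    "KmerIndex",
    "align_identity",
    "query_match_profile",
    "revcomp",
    "encode",
]

# 4-bit base masks: A=1 C=2 G=4 T=8; ambiguity codes are unions.
_IUPAC_MASKS = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}

_ENCODE_LUT = np.zeros(256, dtype=np.uint8)
for _ch, _m in _IUPAC_MASKS.items():
    _ENCODE_LUT[ord(_ch)] = _m
    _ENCODE_LUT[ord(_ch.lower())] = _m

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}
_COMPLEMENT.update({k.lower(): v.lower() for k, v in _COMPLEMENT.items()})
_REVCOMP_TABLE = str.maketrans(_COMPLEMENT)

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -2


def encode(sequence: str) -> np.ndarray:
    """Encode an IUPAC DNA string as an array of 4-bit base masks."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if codes.size and (codes == 0).any():
        bad = int(np.argmax(codes == 0))
        raise ValueError(f"non-IUPAC character {sequence[bad]!r} at position {bad}")
    return codes


def revcomp(sequence: str) -> str:
    """Reverse complement with correct ambiguity-code complements."""
    for ch in sequence:
        if ch not in _COMPLEMENT:
            raise ValueError(f"non-IUPAC character {ch!r}")
    return sequence.translate(_REVCOMP_TABLE)[::-1]


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one semi-global alignment (query vs target)."""

    identity_pct: float
    aligned_cols: int
    matches: int
    score: int
    match_vector: np.ndarray  # bool per aligned column
    query_span: tuple[int, int]  # half-open, 0-based
    target_span: tuple[int, int]
    # per aligned column: query/target index consumed, -1 for a gap
    query_cols: np.ndarray
    target_cols: np.ndarray


@njit(cache=False, inline="always")
def _lex_gt(s1, m1, c1, s2, m2, c2):  # pragma: no cover
    # (score, matches, -cols) lexicographic comparison
    if s1 != s2:
        return s1 > s2
    if m1 != m2:
        return m1 > m2
    return c1 < c2


@njit(cache=False)
def _fill_matrix(a, b):  # pragma: no cover - exercised via align_identity
    la, lb = a.shape[0], b.shape[0]
    # canonical optimum: lexicographic max of (score, matches, -cols);
    # every term is additive along a path, so Bellman optimality holds and
    # the choice is symmetric under transposition
    S = np.zeros((la + 1, lb + 1), dtype=np.int32)
    M = np.zeros((la + 1, lb + 1), dtype=np.int32)
    C = np.zeros((la + 1, lb + 1), dtype=np.int32)
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            compat = (ai & b[j - 1]) != 0
            sub = MATCH_SCORE if compat else MISMATCH_SCORE
            s = S[i - 1, j - 1] + sub
            m = M[i - 1, j - 1] + (1 if compat else 0)
            c = C[i - 1, j - 1] + 1
            s2 = S[i - 1, j] + GAP_SCORE
            if _lex_gt(s2, M[i - 1, j], C[i - 1, j] + 1, s, m, c):
                s, m, c = s2, M[i - 1, j], C[i - 1, j] + 1
            s3 = S[i, j - 1] + GAP_SCORE
            if _lex_gt(s3, M[i, j - 1], C[i, j - 1] + 1, s, m, c):
                s, m, c = s3, M[i, j - 1], C[i, j - 1] + 1
            S[i, j], M[i, j], C[i, j] = s, m, c
    return S, M, C


@njit(cache=False)
def _traceback(S, M, C, a, b):  # pragma: no cover - exercised via align_identity
    la, lb = a.shape[0], b.shape[0]
    # best end on the last row or last column under the lex objective
    bi, bj = la, lb
    for j in range(lb + 1):
        if _lex_gt(S[la, j], M[la, j], C[la, j],
                   S[bi, bj], M[bi, bj], C[bi, bj]):
            bi, bj = la, j
    for i in range(la + 1):
        if _lex_gt(S[i, lb], M[i, lb], C[i, lb],
                   S[bi, bj], M[bi, bj], C[bi, bj]):
            bi, bj = i, lb
    best = S[bi, bj]
    maxlen = la + lb
    q_cols = np.empty(maxlen, dtype=np.int32)
    t_cols = np.empty(maxlen, dtype=np.int32)
    mvec = np.empty(maxlen, dtype=np.bool_)
    n = 0
    i, j = bi, bj
    while i > 0 and j > 0:
        compat = (a[i - 1] & b[j - 1]) != 0
        sub = MATCH_SCORE if compat else MISMATCH_SCORE
        dm = 1 if compat else 0
        if (S[i, j] == S[i - 1, j - 1] + sub
                and M[i, j] == M[i - 1, j - 1] + dm
                and C[i, j] == C[i - 1, j - 1] + 1):
            q_cols[n] = i - 1
            t_cols[n] = j - 1
            mvec[n] = compat
            i -= 1
            j -= 1
        elif (S[i, j] == S[i - 1, j] + GAP_SCORE
                and M[i, j] == M[i - 1, j]
                and C[i, j] == C[i - 1, j] + 1):
            q_cols[n] = i - 1
            t_cols[n] = -1
            mvec[n] = False
            i -= 1
        else:
            q_cols[n] = -1
            t_cols[n] = j - 1
            mvec[n] = False
            j -= 1
        n += 1
    return best, bi, bj, i, j, q_cols[:n][::-1], t_cols[:n][::-1], mvec[:n][::-1]


def align_identity(query: str, target: str) -> AlignmentResult:
    """Align two sequences and report identity over the aligned region.

    Raises ``ValueError`` on empty input or non-IUPAC characters.
    """
    if not query or not target:
        raise ValueError("align_identity requires non-empty sequences")
    a = encode(query)
    b = encode(target)
    S, M, C = _fill_matrix(a, b)
    score, ei, ej, si, sj, q_cols, t_cols, mvec = _traceback(S, M, C, a, b)
    cols = len(mvec)
    matches = int(mvec.sum())
    identity = 100.0 * matches / cols if cols else 0.0
    return AlignmentResult(
        identity_pct=identity,
        aligned_cols=cols,
        matches=matches,
        score=int(score),
        match_vector=mvec,
        query_span=(int(si), int(ei)),
        target_span=(int(sj), int(ej)),
        query_cols=q_cols,
        target_cols=t_cols,
    )


def query_match_profile(query: str, target: str) -> np.ndarray:
    """Boolean array over query positions: True where the position aligns
    to a compatible target base.  Positions outside the aligned region (or
    aligned to a gap/mismatch) are False.  Used by the chimera model.
    """
    res = align_identity(query, target)
    profile = np.zeros(len(query), dtype=bool)
    idx = res.query_cols[(res.query_cols >= 0) & res.match_vector]
    profile[idx] = True
    return profile


class KmerIndex:
    """Exact k-mer postings used to prescreen alignment candidates.

    Candidates are ranked by the number of *distinct* query words they
    share with the reference, descending; ties break on record id.
    References sharing zero words are never returned.
    """

    def __init__(self, k: int = 8):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self._postings: dict[str, list[str]] = {}
        self._ids: set[str] = set()

    def add(self, record_id: str, sequence: str) -> None:
        if record_id in self._ids:
            raise ValueError(f"duplicate record id {record_id!r}")
        self._ids.add(record_id)
        k = self.k
        seq = sequence.upper()
        for word in {seq[i: i + k] for i in range(len(seq) - k + 1)}:
            self._postings.setdefault(word, []).append(record_id)

    @classmethod
    def build(cls, records: dict[str, str], k: int = 8) -> "KmerIndex":
        index = cls(k=k)
        for rid, seq in records.items():
            index.add(rid, seq)
        return index

    def __len__(self) -> int:
        return len(self._ids)

    def search_candidates(self, query: str, top_n: int | None = None) -> list[str]:
        k = self.k
        seq = query.upper()
        counts: dict[str, int] = {}
        for word in {seq[i: i + k] for i in range(len(seq) - k + 1)}:
            for rid in self._postings.get(word, ()):
                counts[rid] = counts.get(rid, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ids = [rid for rid, _ in ranked]
        return ids if top_n is None else ids[:top_n]


def search_candidates(query: str, index: KmerIndex, top_n: int | None = None) -> list[str]:
    """Module-level convenience wrapper around :meth:`KmerIndex.search_candidates`."""
    return index.search_candidates(query, top_n=top_n)
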