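"""Affine-gap fit alignment of a whole read against a candidate region.

Given a region T (length m) and a read R (length n), find the sub-region
T' of T maximising the alignment score of R against T' with the read
consumed end to end (no soft clipping).  Three tables are defined:

* M(i,j) — best score of R[1..j] against any suffix of T[1..i];
* I(i,j) — same, conditioned on R[j] aligned to a gap (insertion);
* D(i,j) — same, conditioned on T[i] aligned to a gap (deletion);

with recurrences

    M(i,j) = max(M(i-1,j-1) + s(T_i, R_j), I(i,j), D(i,j))
    I(i,j) = max(M(i,j-1) - S_GO - S_GE, I(i,j-1) - S_GE)
    D(i,j) = max(M(i-1,j) - S_GO - S_GE, D(i-1,j) - S_GE)

where s(x,y) = +S_MA on a match and -S_MI on a mismatch, and a gap of
length L costs S_GO + S_GE * L.  Base cases: M(i,0) = 0 (the fit may start
anywhere in T), M(0,j) = -(S_GO + S_GE*j) (leading read bases as one
insertion run), I(i,0) = D(0,j) = -inf.  The result is max_i M(i, n).

Two implementations are provided with identical results:

* ``dp_full`` — the straightforward form storing all three tables; its
  inner loop performs 7 stored-table reads and 3 writes.
* ``dp_reduced`` — I is never stored: the running I value and the
  diagonal/vertical M values (M^u = M(i-1,j-1), M^d = M(i-1,j)) live in
  per-iteration scalars, leaving 2 stored-table reads (M(i-1,j), D(i-1,j))
  and 2 writes (M(i,j), D(i,j)) per inner iteration.

``instrument=True`` selects a pure-Python twin of either recurrence that
counts every stored-table access; the default path runs a compiled kernel.
Traceback needs only the M table, so both variants share it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from ._util import encode

NEG = -(10 ** 9)


@dataclass(frozen=True)
class ScoringScheme:
    """Match reward and penalty magnitudes (all penalties subtracted)."""

    match: int = 1          # S_MA
    mismatch: int = 2       # S_MI
    gap_open: int = 2       # S_GO, charged once per gap
    gap_extend: int = 1     # S_GE, charged per gap base
    cutoff_fraction: float = 0.3

    def __post_init__(self):
        if self.match <= 0 or min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("match must be > 0 and penalties >= 0")

    def cutoff(self, read_length: int) -> int:
        """Minimum acceptable fit-alignment score for a read of this length."""
        return math.ceil(self.cutoff_fraction * read_length)

    def gap_cost(self, length: int) -> int:
        return self.gap_open + self.gap_extend * length

    def max_gap(self, read_length: int) -> int:
        """Longest single deletion an otherwise perfect read can carry and
        still meet the cutoff; also used as the candidate-window pad."""
        budget = self.match * read_length - self.cutoff(read_length) - self.gap_open
        return max(0, budget // self.gap_extend)

    def read_score(self, read_length: int, mismatches: int) -> int:
        """Score of an ungapped placement with the given mismatch count."""
        return (read_length - mismatches) * self.match - mismatches * self.mismatch


@dataclass
class DPResult:
    score: int
    start_in_T: int          # 0-based start of the aligned sub-region T'
    end_in_T: int            # exclusive end of T' (the i* of max_i M(i,n))
    cigar: str               # M/I/D ops; consumes exactly len(R) read bases
    table_reads: Optional[int] = None    # stored-table accesses, total
    table_writes: Optional[int] = None
    iterations: Optional[int] = None     # inner-loop count (m*n)

    @property
    def reads_per_iteration(self) -> float:
        return self.table_reads / self.iterations

    @property
    def writes_per_iteration(self) -> float:
        return self.table_writes / self.iterations


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return encode(seq)
    return np.asarray(seq, dtype=np.uint8)


# ---------------------------------------------------------------------------
# compiled kernels


@njit(cache=False)
def _full_kernel(t, r, ma, mi, go, ge):
    m, n = t.shape[0], r.shape[0]
    M = np.empty((m + 1, n + 1), dtype=np.int64)
    I = np.empty((m + 1, n + 1), dtype=np.int64)
    D = np.empty((m + 1, n + 1), dtype=np.int64)
    for i in range(m + 1):
        M[i, 0] = 0
        I[i, 0] = NEG
        D[i, 0] = NEG
    for j in range(1, n + 1):
        M[0, j] = -(go + ge * j)
        I[0, j] = NEG
        D[0, j] = NEG
    for i in range(1, m + 1):
        ti = t[i - 1]
        for j in range(1, n + 1):
            iv = max(M[i, j - 1] - go - ge, I[i, j - 1] - ge)
            dv = max(M[i - 1, j] - go - ge, D[i - 1, j] - ge)
            s = ma if ti == r[j - 1] else -mi
            mv = M[i - 1, j - 1] + s
            if iv > mv:
                mv = iv
            if dv > mv:
                mv = dv
            I[i, j] = iv
            D[i, j] = dv
            M[i, j] = mv
    return M


@njit(cache=False)
def _reduced_kernel(t, r, ma, mi, go, ge):
    m, n = t.shape[0], r.shape[0]
    M = np.empty((m + 1, n + 1), dtype=np.int64)
    D = np.empty((m + 1, n + 1), dtype=np.int64)
    for i in range(m + 1):
        M[i, 0] = 0
        D[i, 0] = NEG
    for j in range(1, n + 1):
        M[0, j] = -(go + ge * j)
        D[0, j] = NEG
    for i in range(1, m + 1):
        ti = t[i - 1]
        m_u = M[i - 1, 0]   # M(i-1, j-1), register
        m_left = 0          # M(i, j-1), register
        i_left = NEG        # I(i, j-1), register
        for j in range(1, n + 1):
            m_d = M[i - 1, j]            # stored-table read 1
            d_up = D[i - 1, j]           # stored-table read 2
            iv = max(m_left - go - ge, i_left - ge)
            dv = max(m_d - go - ge, d_up - ge)
            s = ma if ti == r[j - 1] else -mi
            mv = m_u + s
            if iv > mv:
                mv = iv
            if dv > mv:
                mv = dv
            M[i, j] = mv                 # stored-table write 1
            D[i, j] = dv                 # stored-table write 2
            m_u = m_d
            m_left = mv
            i_left = iv
    return M


# ---------------------------------------------------------------------------
# instrumented pure-Python twins


class _Counted:
    """2-D int table counting every read/write access."""

    __slots__ = ("data", "reads", "writes", "ncols")

    def __init__(self, nrows, ncols):
        self.data = [[0] * ncols for _ in range(nrows)]
        self.ncols = ncols
        self.reads = 0
        self.writes = 0

    def get(self, i, j):
        self.reads += 1
        return self.data[i][j]

    def set(self, i, j, v):
        self.writes += 1
        self.data[i][j] = v

    def init(self, i, j, v):  # base-case initialisation, not inner-loop traffic
        self.data[i][j] = v


def _full_python(t, r, ma, mi, go, ge):
    m, n = len(t), len(r)
    M = _Counted(m + 1, n + 1)
    I = _Counted(m + 1, n + 1)
    D = _Counted(m + 1, n + 1)
    for i in range(m + 1):
        M.init(i, 0, 0)
        I.init(i, 0, NEG)
        D.init(i, 0, NEG)
    for j in range(1, n + 1):
        M.init(0, j, -(go + ge * j))
        I.init(0, j, NEG)
        D.init(0, j, NEG)
    for i in range(1, m + 1):
        ti = t[i - 1]
        for j in range(1, n + 1):
            iv = max(M.get(i, j - 1) - go - ge, I.get(i, j - 1) - ge)
            I.set(i, j, iv)
            dv = max(M.get(i - 1, j) - go - ge, D.get(i - 1, j) - ge)
            D.set(i, j, dv)
            s = ma if ti == r[j - 1] else -mi
            mv = max(M.get(i - 1, j - 1) + s, I.get(i, j), D.get(i, j))
            M.set(i, j, mv)
    reads = M.reads + I.reads + D.reads
    writes = M.writes + I.writes + D.writes
    return np.array(M.data, dtype=np.int64), reads, writes, m * n


def _reduced_python(t, r, ma, mi, go, ge):
    m, n = len(t), len(r)
    M = _Counted(m + 1, n + 1)
    D = _Counted(m + 1, n + 1)
    for i in range(m + 1):
        M.init(i, 0, 0)
        D.init(i, 0, NEG)
    for j in range(1, n + 1):
        M.init(0, j, -(go + ge * j))
        D.init(0, j, NEG)
    for i in range(1, m + 1):
        ti = t[i - 1]
        m_u = M.data[i - 1][0]
        m_left = 0
        i_left = NEG
        for j in range(1, n + 1):
            m_d = M.get(i - 1, j)
            d_up = D.get(i - 1, j)
            iv = max(m_left - go - ge, i_left - ge)
            dv = max(m_d - go - ge, d_up - ge)
            s = ma if ti == r[j - 1] else -mi
            mv = max(m_u + s, iv, dv)
            M.set(i, j, mv)
            D.set(i, j, dv)
            m_u = m_d
            m_left = mv
            i_left = iv
    reads = M.reads + D.reads
    writes = M.writes + D.writes
    return np.array(M.data, dtype=np.int64), reads, writes, m * n


# ---------------------------------------------------------------------------
# traceback (M table only — the reason table I can be dropped)


def _traceback(M, t, r, scheme, i_star):
    ma, mi = scheme.match, scheme.mismatch
    go, ge = scheme.gap_open, scheme.gap_extend
    n = len(r)
    i, j = i_star, n
    ops: list[tuple[int, str]] = []

    def push(op, count=1):
        if ops and ops[-1][1] == op:
            ops[-1] = (ops[-1][0] + count, op)
        else:
            ops.append((count, op))

    while j > 0:
        if i > 0:
            s = ma if t[i - 1] == r[j - 1] else -mi
            if M[i, j] == M[i - 1, j - 1] + s:
                push("M")
                i -= 1
                j -= 1
                continue
        # deletion run: M(i,j) closed from M(i-l,j) - (go + ge*l)
        done = False
        for l in range(1, i + 1):
            if M[i, j] == M[i - l, j] - go - ge * l:
                push("D", l)
                i -= l
                done = True
                break
        if done:
            continue
        # insertion run: M(i,j) closed from M(i,j-l) - (go + ge*l)
        for l in range(1, j + 1):
            if M[i, j] == M[i, j - l] - go - ge * l:
                push("I", l)
                j -= l
                done = True
                break
        if not done:  # pragma: no cover - recurrence violation
            raise RuntimeError("traceback failed: inconsistent DP table")
    start = i
    return start, "".join(f"{c}{op}" for c, op in reversed(ops))


def _finish(M, t, r, scheme, reads=None, writes=None, iters=None) -> DPResult:
    n = len(r)
    col = M[:, n]
    i_star = int(np.argmax(col))  # first (smallest) argmax
    score = int(col[i_star])
    start, cigar = _traceback(M, t, r, scheme, i_star)
    return DPResult(score=score, start_in_T=start, end_in_T=i_star, cigar=cigar,
                    table_reads=reads, table_writes=writes, iterations=iters)


def dp_full(T, R, scheme: ScoringScheme = ScoringScheme(), instrument: bool = False) -> DPResult:
    """Three-table fit alignment (straightforward implementation)."""
    t, r = _as_codes(T), _as_codes(R)
    if t.shape[0] == 0 or r.shape[0] == 0:
        raise ValueError("empty sequence")
    if instrument:
        M, reads, writes, iters = _full_python(
            list(t), list(r), scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend)
        return _finish(M, t, r, scheme, reads, writes, iters)
    M = _full_kernel(t, r, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend)
    return _finish(M, t, r, scheme)


def dp_reduced(T, R, scheme: ScoringScheme = ScoringScheme(), instrument: bool = False) -> DPResult:
    """Two-table fit alignment; identical results to :func:`dp_full`."""
    t, r = _as_codes(T), _as_codes(R)
    if t.shape[0] == 0 or r.shape[0] == 0:
        raise ValueError("empty sequence")
    if instrument:
        M, reads, writes, iters = _reduced_python(
            list(t), list(r), scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend)
        return _finish(M, t, r, scheme, reads, writes, iters)
    M = _reduced_kernel(t, r, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend)
    return _finish(M, t, r, scheme)


def accepts(result: DPResult, scheme: ScoringScheme, read_length: int) -> bool:
    """Acceptance rule: the fit score must reach the length-scaled cutoff."""
    return result.score >= scheme.cutoff(read_length)


def rescore_cigar(cigar: str, T, R, start_in_T: int, scheme: ScoringScheme) -> int:
    """Recompute the score of an alignment path; must equal DPResult.score."""
    t, r = _as_codes(T), _as_codes(R)
    i, j = start_in_T, 0
    score = 0
    count = 0
    for ch in cigar:
        if ch.isdigit():
            count = count * 10 + int(ch)
            continue
        if ch == "M":
            for _ in range(count):
                score += scheme.match if t[i] == r[j] else -scheme.mismatch
                i += 1
                j += 1
        elif ch == "D":
            score -= scheme.gap_cost(count)
            i += count
        elif ch == "I":
            score -= scheme.gap_cost(count)
            j += count
        else:
            raise ValueError(f"bad cigar op {ch!r}")
        count = 0
    if j != r.shape[0]:
        raise ValueError("cigar does not consume the read")
    return score
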