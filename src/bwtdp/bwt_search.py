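"""Step-1 ungapped alignment: all-best k-mismatch search on the FM-index.

Two complete search strategies share one output contract (the exact set of
both-strand hits achieving the minimal mismatch count m* <= k_max):

* ``pigeonhole`` — the read is cut into k_max+1 contiguous segments; any
  placement with <= k_max mismatches leaves at least one segment exact, so
  exact backward search of every segment followed by whole-read
  verification against the packed reference enumerates all hits.  This is
  the default (fast) route.
* ``branch`` — breadth-first backward extension over SA ranges with case
  splitting on mismatch positions.  It additionally records, after every
  extended base, the number of live SA ranges — the complexity parameter
  used to stratify reads into three effort tiers.

Stratified scheduling (:func:`stratified_search`) suspends a read at the
first extension whose live-range count exceeds the current tier's
threshold and re-runs it in the next tier; tiers change scheduling only,
never the reported hit set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._util import encode, revcomp_codes
from .gapped_dp import ScoringScheme
from .index_core import FMIndex, SARange, backward_search, extend_left, locate_concat

DEFAULT_LEVEL_THRESHOLDS = (4, 32)


@dataclass(frozen=True)
class MismatchHit:
    reference: str
    position: int          # 0-based leftmost, local coordinates
    strand: str            # '+' or '-'
    mismatch_count: int
    score: int
    concat_pos: int        # leftmost in concatenated coordinates

    @property
    def sort_key(self):
        return (self.concat_pos, self.strand != "+")


@dataclass(frozen=True)
class ComplexityLevel:
    level: int                     # 1, 2 or 3
    live_range_count_at_stop: int  # count that decided the level


def _masked_concat(index: FMIndex) -> list[tuple[int, int]]:
    out = []
    for name, ivs in index.masked_intervals.items():
        i = index.reference_names.index(name)
        off = int(index.reference_offsets[i])
        out.extend((off + a, off + b) for a, b in ivs)
    return out


def _in_masked(index: FMIndex, start: int, end: int) -> bool:
    for a, b in _masked_concat(index):
        if start < b and a < end:
            return True
    return False


def _segment_bounds(n: int, parts: int) -> list[tuple[int, int]]:
    cuts = np.linspace(0, n, parts + 1).astype(int)
    return [(int(cuts[i]), int(cuts[i + 1])) for i in range(parts)]


def _verify_anchor(index: FMIndex, codes: np.ndarray, anchor: int, k_max: int) -> Optional[int]:
    n = codes.shape[0]
    if anchor < 0 or anchor + n > index.text_length:
        return None
    lo, hi = index.sequence_bounds(anchor)
    if anchor < lo or anchor + n > hi:
        return None
    mm = int(np.count_nonzero(index.text[anchor:anchor + n] != codes))
    return mm if mm <= k_max else None


def _pigeonhole_anchors(index: FMIndex, codes: np.ndarray, k_max: int) -> dict[int, int]:
    """anchor concat position -> mismatch count, for one read orientation."""
    n = codes.shape[0]
    found: dict[int, int] = {}
    for off, end in _segment_bounds(n, k_max + 1):
        seg = codes[off:end]
        if np.any(seg > 3):  # a segment with N can never be the exact one
            continue
        rng = backward_search(index, seg)
        if rng.empty:
            continue
        for pos in locate_concat(index, rng):
            anchor = int(pos) - off
            if anchor in found:
                continue
            mm = _verify_anchor(index, codes, anchor, k_max)
            if mm is not None:
                found[anchor] = mm
    return found


def _branch_anchors(
    index: FMIndex,
    codes: np.ndarray,
    k_max: int,
    suspend_threshold: Optional[int] = None,
) -> tuple[Optional[dict[int, int]], list[int]]:
    """Branch-and-bound backward search of one orientation.

    Returns (anchors, trace) where trace[i] is the live SA-range count
    after extending the i-th base (from the read's 3' end).  If the count
    exceeds ``suspend_threshold`` the search is suspended and anchors is
    None (the trace covers the steps actually executed).
    """
    n = codes.shape[0]
    states: dict[tuple[int, int], int] = {(0, index.text_length): 0}
    trace: list[int] = []
    for p in range(n - 1, -1, -1):
        rc = codes[p]
        nxt: dict[tuple[int, int], int] = {}
        for (lo, hi), mm in states.items():
            rng = SARange(lo, hi)
            for c in range(4):
                mm2 = mm + (1 if c != rc else 0)
                if mm2 > k_max:
                    continue
                ext = extend_left(index, rng, c)
                if ext.empty:
                    continue
                key = (ext.low, ext.high)
                if key not in nxt or nxt[key] > mm2:
                    nxt[key] = mm2
        states = nxt
        trace.append(len(states))
        if not states:
            break
        if suspend_threshold is not None and len(states) > suspend_threshold:
            return None, trace
    anchors: dict[int, int] = {}
    for (lo, hi), mm in states.items():
        for pos in locate_concat(index, SARange(lo, hi)):
            pos = int(pos)
            if pos not in anchors or anchors[pos] > mm:
                anchors[pos] = mm
    return anchors, trace


def _hits_from_anchors(
    index: FMIndex,
    per_strand: dict[str, dict[int, int]],
    read_length: int,
    scheme: ScoringScheme,
) -> list[MismatchHit]:
    best = min((mm for d in per_strand.values() for mm in d.values()), default=None)
    if best is None:
        return []
    hits = []
    for strand, anchors in per_strand.items():
        for anchor, mm in anchors.items():
            if mm != best:
                continue
            if _in_masked(index, anchor, anchor + read_length):
                continue
            name, local = index.to_local(anchor)
            hits.append(MismatchHit(
                reference=name, position=local, strand=strand,
                mismatch_count=mm, score=scheme.read_score(read_length, mm),
                concat_pos=anchor,
            ))
    hits.sort(key=lambda h: h.sort_key)
    return hits


def all_best_mismatch_search(
    index: FMIndex,
    read: str,
    k_max: int = 2,
    scheme: ScoringScheme = ScoringScheme(),
    method: str = "pigeonhole",
) -> list[MismatchHit]:
    """All hits (both strands) at the minimal achievable mismatch count.

    Empty list when the read has no placement with <= k_max mismatches.
    Output is sorted by (concatenated position, forward strand first).
    """
    if not 0 <= k_max <= 4:
        raise ValueError("k_max must be in 0..4")
    if len(read) < k_max + 1:
        raise ValueError("read shorter than k_max + 1")
    fwd = encode(read)
    rev = revcomp_codes(fwd)
    per_strand = {}
    for strand, codes in (("+", fwd), ("-", rev)):
        if method == "pigeonhole":
            per_strand[strand] = _pigeonhole_anchors(index, codes, k_max)
        elif method == "branch":
            per_strand[strand], _ = _branch_anchors(index, codes, k_max)
        else:
            raise ValueError(f"unknown method {method!r}")
    return _hits_from_anchors(index, per_strand, len(read), scheme)


def _case_trace(index: FMIndex, codes: np.ndarray, k_max: int) -> tuple[dict[int, int], list[int]]:
    """Case-split search of one orientation with a live-range trace.

    One case per pigeonhole segment: the case's segment is matched exactly
    by backward extension (one live SA range while non-empty), after which
    the located placements are extended over the remaining read positions
    with the mismatch budget, each surviving placement counting as one
    live range.  trace[s] is the number of live ranges across all cases
    after every case has extended its (s+1)-th base.
    """
    n = codes.shape[0]
    live: list[set[int]] = [set() for _ in range(n)]  # distinct anchors per step
    anchors: dict[int, int] = {}
    text = index.text
    tlen = index.text_length
    for a, b in _segment_bounds(n, k_max + 1):
        seg = codes[a:b]
        seg_len = b - a
        if np.any(seg > 3):
            continue
        # exact phase: deterministic extension of one range — no divergence,
        # so it does not contribute to the live branching-range count
        rng = SARange(0, tlen)
        for s in range(seg_len):
            rng = extend_left(index, rng, int(seg[seg_len - 1 - s]))
            if rng.empty:
                break
        if rng.empty:
            continue
        # verification phase: remaining positions, leftward then rightward
        order = list(range(a - 1, -1, -1)) + list(range(b, n))
        cands = []
        for pos in locate_concat(index, rng):
            anchor = int(pos) - a
            if anchor < 0 or anchor + n > tlen:
                continue
            lo, hi = index.sequence_bounds(anchor)
            if anchor < lo or anchor + n > hi:
                continue
            cands.append((anchor, 0))
        for s, p in enumerate(order, start=seg_len):
            nxt = []
            for anchor, mm in cands:
                if text[anchor + p] != codes[p]:
                    mm += 1
                    if mm > k_max:
                        continue
                nxt.append((anchor, mm))
            cands = nxt
            live[s].update(anchor for anchor, _ in cands)
            if not cands:
                break
        for anchor, mm in cands:
            if anchor not in anchors or anchors[anchor] > mm:
                anchors[anchor] = mm
    return anchors, [len(s) for s in live]


def search_trace(index: FMIndex, read: str, k_max: int = 2) -> list[int]:
    """Combined live-SA-range counts per extended base over both strands."""
    fwd = encode(read)
    rev = revcomp_codes(fwd)
    _, tf = _case_trace(index, fwd, k_max)
    _, tr = _case_trace(index, rev, k_max)
    return [a + b for a, b in zip(tf, tr)]


def classify_read(
    trace: list[int],
    thresholds: tuple[int, int] = DEFAULT_LEVEL_THRESHOLDS,
) -> ComplexityLevel:
    """Map a live-range trace to an effort tier.

    Strict "exceeds" semantics: a trace that touches but never exceeds a
    threshold stays in the lower tier.
    """
    t1, t2 = thresholds
    if not t1 < t2:
        raise ValueError("thresholds must satisfy t1 < t2")
    peak = max(trace, default=0)
    for count in trace:
        if count > t2:
            return ComplexityLevel(3, count)
    for count in trace:
        if count > t1:
            return ComplexityLevel(2, count)
    return ComplexityLevel(1, peak)


def stratified_search(
    index: FMIndex,
    read: str,
    k_max: int = 2,
    scheme: ScoringScheme = ScoringScheme(),
    thresholds: tuple[int, int] = DEFAULT_LEVEL_THRESHOLDS,
) -> tuple[list[MismatchHit], ComplexityLevel]:
    """Suspend/resume search over the three effort tiers.

    A read whose live-range count exceeds the active tier's threshold at
    some extension is stopped there and re-run in the next tier (the last
    tier is uncapped), so the hit set always equals the unstratified one.
    """
    t1, t2 = thresholds
    if not t1 < t2:
        raise ValueError("thresholds must satisfy t1 < t2")
    fwd = encode(read)
    rev = revcomp_codes(fwd)
    trigger = 0  # the count that forced promotion out of the previous tier
    final_level = 3
    per_strand: dict[str, dict[int, int]] = {}
    for cap, lvl in ((t1, 1), (t2, 2), (None, 3)):
        per_strand = {}
        combined: Optional[list[int]] = None
        for strand, codes in (("+", fwd), ("-", rev)):
            anchors, trace = _case_trace(index, codes, k_max)
            per_strand[strand] = anchors
            combined = trace if combined is None else [x + y for x, y in zip(combined, trace)]
        violation = next((c for c in (combined or []) if cap is not None and c > cap), None)
        if violation is None:
            final_level = lvl
            if lvl == 1:
                trigger = max(combined or [0])
            break
        # suspended at the first violating extension; re-run in the next tier
        trigger = violation
    level = ComplexityLevel(final_level, trigger)
    return _hits_from_anchors(index, per_strand, len(read), scheme), level
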