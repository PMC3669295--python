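"""Three-step alignment workflow for paired-end (and single-end) reads.

Step 1 — all-best k-mismatch BWT search of both ends; a combination of
hits that satisfies the insert-size/orientation expectations resolves the
pair immediately (category ``gout``).

Step 2 — pairs with exactly one end aligned: the unaligned mate is
rescued by fit alignment inside the reference window where a properly
paired placement could start (category ``dpout``).

Step 3 — remaining pairs: seeds nominate candidate regions genome-wide
for each unresolved end, the DP kernel aligns the read into the best
regions (subject to the effort ceiling), and pairing is re-evaluated.
Pairs that still cannot be properly paired fall back to individual
per-end reporting (category ``unpair``); single-end mode runs steps 1
and 3 only.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from ._util import encode, revcomp_codes
from .bwt_search import MismatchHit, all_best_mismatch_search
from .gapped_dp import DPResult, ScoringScheme, accepts, dp_reduced
from .index_core import FMIndex
from .mapq_output import Alignment, alignment_end, cigar_ops, compute_mapq
from .seed_candidates import (
    DEFAULT_CEILING,
    DEFAULT_SEED_HIT_LIMIT,
    DEFAULT_SEED_LENGTH,
    DEFAULT_SEED_STRIDE,
    enumerate_candidates,
    extract_seeds,
    map_seeds,
)

_COMBO_CAP = 64  # hit pairs examined when searching for a proper combination


@dataclass(frozen=True)
class PairConfig:
    """Insert-size expectations (-v/-u analogues) and mate orientation."""

    min_insert: int
    max_insert: int
    orientation: str = "FR"

    def __post_init__(self):
        if not 0 < self.min_insert <= self.max_insert:
            raise ValueError("need 0 < min_insert <= max_insert")
        if self.orientation not in ("FR", "FF"):
            raise ValueError("orientation must be FR or FF")


@dataclass(frozen=True)
class AlignParams:
    """Configuration-file knobs for the three steps."""

    max_mismatch: int = 2
    level_thresholds: tuple[int, int] = (4, 32)
    output_mode: str = "all-best"
    seed_length: int = DEFAULT_SEED_LENGTH
    seed_stride: int = DEFAULT_SEED_STRIDE
    candidate_ceiling: int = DEFAULT_CEILING
    seed_hit_limit: int = DEFAULT_SEED_HIT_LIMIT
    enough_alignments: int = 2


@dataclass
class PairResult:
    name: str
    seq1: str
    qual1: str
    aln1: Optional[Alignment]
    status: str        # properly_paired | both_aligned_unpaired | one_aligned | unaligned | aligned
    category: str      # gout | dpout | unpair
    step: int          # 1, 2 or 3
    seq2: str = ""
    qual2: str = ""
    aln2: Optional[Alignment] = None
    paired: bool = True


# ---------------------------------------------------------------------------
# pairing geometry


def is_properly_paired(a1: Alignment, a2: Alignment, cfg: PairConfig) -> bool:
    """Orientation matches and the outermost span lies in [min, max]
    (inclusive).  Different reference sequences are never proper."""
    if a1.reference != a2.reference:
        return False
    span = max(alignment_end(a1), alignment_end(a2)) - min(a1.pos, a2.pos)
    if not cfg.min_insert <= span <= cfg.max_insert:
        return False
    if cfg.orientation == "FF":
        return a1.strand == a2.strand
    if a1.pos == a2.pos:
        return {a1.strand, a2.strand} == {"+", "-"}
    up, down = (a1, a2) if a1.pos < a2.pos else (a2, a1)
    return up.strand == "+" and down.strand == "-"


def _hit_alignment(hit: MismatchHit, read_length: int, mapq: int = 0,
                   n_best: int = 1, others: list | None = None) -> Alignment:
    return Alignment(
        reference=hit.reference, pos=hit.position, strand=hit.strand,
        cigar=f"{read_length}M", score=hit.score, nm=hit.mismatch_count,
        mapq=mapq, n_best=n_best, from_dp=False,
        co_optimal=others or [],
    )


def _nm_from_cigar(window: np.ndarray, start: int, read_codes: np.ndarray, cigar: str) -> int:
    nm = 0
    i, j = start, 0
    for count, op in cigar_ops(cigar):
        if op == "M":
            nm += int(np.count_nonzero(window[i:i + count] != read_codes[j:j + count]))
            i += count
            j += count
        elif op == "D":
            nm += count
            i += count
        elif op == "I":
            nm += count
            j += count
    return nm


def _dp_alignment(index: FMIndex, window_start: int, window: np.ndarray,
                  codes: np.ndarray, strand: str, scheme: ScoringScheme) -> Optional[Alignment]:
    if window.shape[0] < 1 or np.any(window > 3):
        return None
    res: DPResult = dp_reduced(window, codes, scheme)
    if not accepts(res, scheme, codes.shape[0]):
        return None
    concat_pos = window_start + res.start_in_T
    name, local = index.to_local(concat_pos)
    nm = _nm_from_cigar(window, res.start_in_T, codes, res.cigar)
    return Alignment(reference=name, pos=local, strand=strand, cigar=res.cigar,
                     score=res.score, nm=nm, from_dp=True)


# ---------------------------------------------------------------------------
# step 2: mate rescue


def mate_rescue(
    anchor: Alignment,
    mate_read: str,
    index: FMIndex,
    cfg: PairConfig,
    scheme: ScoringScheme = ScoringScheme(),
) -> Optional[Alignment]:
    """Fit-align an unaligned mate inside the window where a properly
    paired placement could start; None when no placement reaches the
    score cutoff (or the window is fully clipped)."""
    mlen = len(mate_read)
    pad = scheme.max_gap(mlen)
    ref_i = index.reference_names.index(anchor.reference)
    seq_off = int(index.reference_offsets[ref_i])
    seq_end = seq_off + int(index.reference_lengths[ref_i])
    a_start = seq_off + anchor.pos
    a_end = seq_off + alignment_end(anchor)

    if cfg.orientation == "FR":
        if anchor.strand == "+":
            lo = a_start + cfg.min_insert - mlen - pad
            hi = a_start + cfg.max_insert + pad
            mate_strand = "-"
        else:
            lo = a_end - cfg.max_insert - pad
            hi = a_end - cfg.min_insert + mlen + pad
            mate_strand = "+"
    else:  # FF: the mate may sit on either side of the anchor
        lo = a_start - cfg.max_insert - pad
        hi = a_end + cfg.max_insert + pad
        mate_strand = anchor.strand

    lo, hi = max(lo, seq_off), min(hi, seq_end)
    if hi - lo < 1:
        return None
    fwd = encode(mate_read)
    codes = fwd if mate_strand == "+" else revcomp_codes(fwd)
    return _dp_alignment(index, lo, index.text[lo:hi], codes, mate_strand, scheme)


# ---------------------------------------------------------------------------
# step 3: seed -> candidate regions -> DP


def _dp_candidates(
    index: FMIndex,
    read: str,
    scheme: ScoringScheme,
    params: AlignParams,
) -> list[Alignment]:
    """Accepted DP alignments over the best candidate regions, sorted by
    (score desc, position asc), deduplicated by placement."""
    n = len(read)
    pad = scheme.max_gap(n)
    seeds = extract_seeds(read, params.seed_length, params.seed_stride)
    hits = map_seeds(index, read, seeds, params.seed_hit_limit)
    regions = enumerate_candidates(
        hits, n, ceiling=params.candidate_ceiling,
        merge_window=max(pad, 1), pad=pad, index=index,
    )
    fwd = encode(read)
    rev = revcomp_codes(fwd)
    out: dict[tuple, Alignment] = {}
    for region in regions:
        codes = fwd if region.strand == "+" else rev
        aln = _dp_alignment(index, region.start,
                            index.text[region.start:region.end],
                            codes, region.strand, scheme)
        if aln is None:
            continue
        key = (aln.reference, aln.pos, aln.strand)
        if key not in out or out[key].score < aln.score:
            out[key] = aln
    alns = sorted(out.values(), key=lambda a: (-a.score, a.reference, a.pos, a.strand != "+"))
    return alns


def _score_rank(alns: list[Alignment]) -> None:
    """Fill mapq/n_best/second_score of the head alignment in place."""
    if not alns:
        return
    best = alns[0]
    n_best = sum(1 for a in alns if a.score == best.score)
    second = next((a.score for a in alns if a.score < best.score), None)
    best.n_best = n_best
    best.second_score = second
    read_len = sum(c for c, op in cigar_ops(best.cigar) if op in "MI")
    best.mapq = compute_mapq(best.score, second, n_best, read_len)
    best.co_optimal = [
        (a.reference, a.pos, a.strand, a.cigar, a.nm)
        for a in alns[1:] if a.score == best.score
    ]


# ---------------------------------------------------------------------------
# the pair workflow


def _best_proper_combo(
    alns1: list[Alignment], alns2: list[Alignment], cfg: PairConfig
) -> Optional[tuple[Alignment, Alignment, int, int]]:
    """Highest combined-score properly paired combination; ties broken by
    leftmost coordinate, then forward-first.  Returns (a1, a2, combined
    score, number of co-optimal combos)."""
    combos = []
    for a1, a2 in itertools.islice(
            itertools.product(alns1, alns2), _COMBO_CAP * _COMBO_CAP):
        if is_properly_paired(a1, a2, cfg):
            combos.append((a1, a2))
    if not combos:
        return None
    def key(c):
        a1, a2 = c
        return (-(a1.score + a2.score), min(a1.pos, a2.pos),
                a1.strand != "+", a1.pos, a2.pos)
    combos.sort(key=key)
    a1, a2 = combos[0]
    best_score = a1.score + a2.score
    n_best = sum(1 for c1, c2 in combos if c1.score + c2.score == best_score)
    return a1, a2, best_score, n_best


def _finalize_pair_mapqs(a1: Alignment, a2: Alignment, combos_n: int,
                         len1: int, len2: int, scheme: ScoringScheme) -> None:
    for aln, rl in ((a1, len1), (a2, len2)):
        n_best = max(aln.n_best, combos_n)
        aln.mapq = compute_mapq(aln.score, aln.second_score, n_best, rl, scheme)


def align_pair(
    name: str,
    r1: str,
    r2: str,
    index: FMIndex,
    cfg: PairConfig,
    scheme: ScoringScheme = ScoringScheme(),
    params: AlignParams = AlignParams(),
    qual1: str = "",
    qual2: str = "",
) -> PairResult:
    qual1 = qual1 or "I" * len(r1)
    qual2 = qual2 or "I" * len(r2)

    def result(a1, a2, status, category, step):
        return PairResult(name=name, seq1=r1, qual1=qual1, seq2=r2, qual2=qual2,
                          aln1=a1, aln2=a2, status=status, category=category, step=step)

    k1 = min(params.max_mismatch, len(r1) - 1)
    k2 = min(params.max_mismatch, len(r2) - 1)
    hits1 = all_best_mismatch_search(index, r1, k1, scheme)
    hits2 = all_best_mismatch_search(index, r2, k2, scheme)
    alns1 = [_hit_alignment(h, len(r1)) for h in hits1[:_COMBO_CAP]]
    alns2 = [_hit_alignment(h, len(r2)) for h in hits2[:_COMBO_CAP]]

    # ---- step 1: both ends by BWT search
    if alns1 and alns2:
        combo = _best_proper_combo(alns1, alns2, cfg)
        if combo is not None:
            a1, a2, _, n_combos = combo
            _finalize_pair_mapqs(a1, a2, n_combos, len(r1), len(r2), scheme)
            return result(a1, a2, "properly_paired", "gout", 1)
        # both ends align but never as a proper pair: report individually
        for alns, rl in ((alns1, len(r1)), (alns2, len(r2))):
            alns[0].n_best = len(alns)
            alns[0].mapq = compute_mapq(alns[0].score, None, len(alns), rl, scheme)
            alns[0].co_optimal = [
                (a.reference, a.pos, a.strand, a.cigar, a.nm) for a in alns[1:]
            ]
        return result(alns1[0], alns2[0], "both_aligned_unpaired", "unpair", 1)

    # ---- step 2: one end anchored, rescue the mate by DP
    if bool(alns1) != bool(alns2):
        anchors, mate_read = (alns1, r2) if alns1 else (alns2, r1)
        rescued = []
        for anchor in anchors[:max(params.enough_alignments, 1)]:
            maln = mate_rescue(anchor, mate_read, index, cfg, scheme)
            if maln is not None and is_properly_paired(anchor, maln, cfg):
                rescued.append((anchor, maln))
        if rescued:
            rescued.sort(key=lambda p: (-(p[0].score + p[1].score), p[0].pos))
            anchor, maln = rescued[0]
            n_combos = sum(1 for a, m in rescued
                           if a.score + m.score == anchor.score + maln.score)
            anchor.n_best = len(anchors)
            a1, a2 = (anchor, maln) if alns1 else (maln, anchor)
            _finalize_pair_mapqs(a1, a2, n_combos, len(r1), len(r2), scheme)
            return result(a1, a2, "properly_paired", "dpout", 2)

    # ---- step 3: seed + DP per unresolved end, then re-pair
    cand1 = alns1 if alns1 else _dp_candidates(index, r1, scheme, params)
    cand2 = alns2 if alns2 else _dp_candidates(index, r2, scheme, params)
    if cand1 and cand2:
        combo = _best_proper_combo(cand1, cand2, cfg)
        if combo is not None:
            a1, a2, _, n_combos = combo
            _finalize_pair_mapqs(a1, a2, n_combos, len(r1), len(r2), scheme)
            return result(a1, a2, "properly_paired", "dpout", 3)

    # ---- fallback: individual ends
    _score_rank(cand1)
    _score_rank(cand2)
    a1 = cand1[0] if cand1 else None
    a2 = cand2[0] if cand2 else None
    if a1 is not None and a2 is not None:
        status = "both_aligned_unpaired"
    elif a1 is not None or a2 is not None:
        status = "one_aligned"
    else:
        status = "unaligned"
    return result(a1, a2, status, "unpair", 3)


def align_single(
    name: str,
    read: str,
    index: FMIndex,
    scheme: ScoringScheme = ScoringScheme(),
    params: AlignParams = AlignParams(),
    qual: str = "",
) -> PairResult:
    """Single-end mode: step 1 (BWT) then step 3 (seed + DP)."""
    qual = qual or "I" * len(read)
    k = min(params.max_mismatch, len(read) - 1)
    hits = all_best_mismatch_search(index, read, k, scheme)
    if hits:
        alns = [_hit_alignment(h, len(read)) for h in hits[:_COMBO_CAP]]
        _score_rank(alns)
        return PairResult(name=name, seq1=read, qual1=qual, aln1=alns[0],
                          status="aligned", category="gout", step=1, paired=False)
    cands = _dp_candidates(index, read, scheme, params)
    if cands:
        _score_rank(cands)
        return PairResult(name=name, seq1=read, qual1=qual, aln1=cands[0],
                          status="aligned", category="dpout", step=3, paired=False)
    return PairResult(name=name, seq1=read, qual1=qual, aln1=None,
                      status="unaligned", category="unpair", step=3, paired=False)


# ---------------------------------------------------------------------------
# FASTQ streaming


def _open_maybe_gzip(path: str):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str) -> Iterator[tuple[str, str, str]]:
    from Bio import SeqIO

    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield rec.id, str(rec.seq).upper(), qual


def align_paired_files(
    index: FMIndex,
    fastq1: str,
    fastq2: str,
    cfg: PairConfig,
    scheme: ScoringScheme = ScoringScheme(),
    params: AlignParams = AlignParams(),
) -> Iterator[PairResult]:
    """Mate-synchronised streaming over two FASTQ files."""
    it1, it2 = read_fastq(fastq1), read_fastq(fastq2)
    for rec1, rec2 in itertools.zip_longest(it1, it2):
        if rec1 is None or rec2 is None:
            raise ValueError("mate files differ in read count")
        name = rec1[0].removesuffix("/1")
        yield align_pair(name, rec1[1], rec2[1], index, cfg, scheme, params,
                         qual1=rec1[2], qual2=rec2[2])


def align_single_file(
    index: FMIndex,
    fastq: str,
    scheme: ScoringScheme = ScoringScheme(),
    params: AlignParams = AlignParams(),
) -> Iterator[PairResult]:
    for name, seq, qual in read_fastq(fastq):
        yield align_single(name, seq, index, scheme, params, qual=qual)
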