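"""Mapping quality and SAM emission, split into three category files.

Output files follow the three-way split used by the aligner: gapped /
extensively-mismatched DP alignments (``.dpout``), few-mismatch BWT
alignments (``.gout``), and improperly paired or unaligned reads
(``.unpair``).  Every file carries a full header, so the three are
independently valid SAM and can be concatenated after header
deduplication.

MAPQ sits on the BWA-compatible 0–60 scale and keeps the two hard
conventions downstream callers rely on: 0 whenever two or more co-optimal
placements exist, 60 for a unique hit with no runner-up.  Between those
extremes the score gap to the runner-up is scaled into (0, 60]:

    mapq = min(60, floor(60 * (best - second) / (S_MA*n - cutoff(n))))

floored at 1 (an accepted unique-best placement never reports 0).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO

from ._util import revcomp
from .gapped_dp import ScoringScheme

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80

XA_CAP = 10
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

CATEGORIES = ("gout", "dpout", "unpair")


@dataclass
class Alignment:
    """One placement of a read, 0-based internally (1-based only in SAM)."""

    reference: str
    pos: int
    strand: str
    cigar: str
    score: int
    nm: int
    mapq: int = 0
    n_best: int = 1
    second_score: Optional[int] = None
    from_dp: bool = False
    co_optimal: list = field(default_factory=list)  # (ref, pos, strand, cigar, nm)


def cigar_ops(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def cigar_read_span(cigar: str) -> int:
    return sum(n for n, op in cigar_ops(cigar) if op in "MIS=X")


def cigar_ref_span(cigar: str) -> int:
    return sum(n for n, op in cigar_ops(cigar) if op in "MDN=X")


def alignment_end(aln: Alignment) -> int:
    """Exclusive reference end of the alignment."""
    return aln.pos + cigar_ref_span(aln.cigar)


def compute_mapq(
    best_score: int,
    second_score: Optional[int],
    n_best: int,
    read_length: int,
    scheme: ScoringScheme = ScoringScheme(),
) -> int:
    """Map score separation to the 0-60 confidence scale."""
    if n_best < 1:
        raise ValueError("n_best must be >= 1")
    if second_score is not None and second_score > best_score:
        raise ValueError("second_score exceeds best_score")
    if n_best >= 2:
        return 0
    if second_score is None:
        return 60
    denom = scheme.match * read_length - scheme.cutoff(read_length)
    if denom <= 0:
        return 60
    return max(1, min(60, 60 * (best_score - second_score) // denom))


def to_sam_record(
    name: str,
    seq: str,
    qual: str,
    aln: Optional[Alignment],
    *,
    paired: bool = False,
    first: bool = True,
    proper: bool = False,
    mate: Optional[Alignment] = None,
    tlen: int = 0,
) -> str:
    """One conformant SAM line.

    A None alignment emits an unmapped record; if the mate is mapped its
    coordinates are borrowed for RNAME/POS (sort-friendly convention).
    """
    flag = 0
    if paired:
        flag |= FLAG_PAIRED | (FLAG_FIRST if first else FLAG_SECOND)
        if proper:
            flag |= FLAG_PROPER
        if mate is None:
            flag |= FLAG_MATE_UNMAPPED
        elif mate.strand == "-":
            flag |= FLAG_MATE_REVERSE
    if aln is None:
        flag |= FLAG_UNMAPPED
        rname = mate.reference if mate is not None else "*"
        pos = mate.pos + 1 if mate is not None else 0
        out_seq, out_qual = seq, qual
        fields = [name, str(flag), rname, str(pos), "0", "*",
                  "=" if mate is not None else "*",
                  str(mate.pos + 1) if mate is not None else "0",
                  "0", out_seq, out_qual]
        return "\t".join(fields)
    if cigar_read_span(aln.cigar) != len(seq):
        raise ValueError(
            f"CIGAR {aln.cigar} consumes {cigar_read_span(aln.cigar)} bases "
            f"but SEQ has {len(seq)}")
    if aln.strand == "-":
        flag |= FLAG_REVERSE
        out_seq, out_qual = revcomp(seq), qual[::-1]
    else:
        out_seq, out_qual = seq, qual
    if mate is not None:
        rnext = "=" if mate.reference == aln.reference else mate.reference
        pnext = mate.pos + 1
    else:
        rnext, pnext = "*", 0
    fields = [
        name, str(flag), aln.reference, str(aln.pos + 1), str(aln.mapq),
        aln.cigar, rnext, str(pnext), str(tlen), out_seq, out_qual,
        f"AS:i:{aln.score}", f"NM:i:{aln.nm}",
    ]
    if aln.co_optimal:
        alts = ";".join(
            f"{r},{'+' if s == '+' else '-'}{p + 1},{c},{n}"
            for r, p, s, c, n in aln.co_optimal[:XA_CAP]
        )
        fields.append(f"XA:Z:{alts};")
    return "\t".join(fields)


def _signed_tlen(a: Alignment, b: Alignment) -> tuple[int, int]:
    """Outer-span TLEN for two mapped mates on one reference."""
    if a.reference != b.reference:
        return 0, 0
    left = min(a.pos, b.pos)
    right = max(alignment_end(a), alignment_end(b))
    span = right - left
    # leftmost segment positive; ties resolved in favour of the first read
    if a.pos <= b.pos:
        return span, -span
    return -span, span


def pair_records(result) -> list[str]:
    """Both SAM lines for one PairResult-shaped object."""
    a1, a2 = result.aln1, result.aln2
    proper = result.status == "properly_paired"
    t1 = t2 = 0
    if a1 is not None and a2 is not None and a1.reference == a2.reference:
        t1, t2 = _signed_tlen(a1, a2)
    rec1 = to_sam_record(result.name, result.seq1, result.qual1, a1,
                         paired=True, first=True, proper=proper, mate=a2, tlen=t1)
    rec2 = to_sam_record(result.name, result.seq2, result.qual2, a2,
                         paired=True, first=False, proper=proper, mate=a1, tlen=t2)
    return [rec1, rec2]


def sam_header(reference_info: list[tuple[str, int]], command_line: str = "") -> list[str]:
    from . import __version__

    lines = ["@HD\tVN:1.6\tSO:unknown"]
    lines += [f"@SQ\tSN:{name}\tLN:{length}" for name, length in reference_info]
    cl = f"\tCL:{command_line}" if command_line else ""
    lines.append(f"@PG\tID:bwtdp\tPN:bwtdp\tVN:{__version__}{cl}")
    return lines


def write_outputs(
    results: Iterable,
    out_prefix: str,
    reference_info: list[tuple[str, int]],
    merged: bool = False,
    command_line: str = "",
) -> dict[str, int]:
    """Write SAM records into the three category files (or one merged
    file); returns the record count per category."""
    header = "\n".join(sam_header(reference_info, command_line)) + "\n"
    counts = dict.fromkeys(CATEGORIES, 0)
    handles: dict[str, TextIO] = {}
    try:
        if merged:
            fh = open(out_prefix + ".sam", "w")
            handles = {cat: fh for cat in CATEGORIES}
            fh.write(header)
        else:
            for cat in CATEGORIES:
                handles[cat] = open(f"{out_prefix}.{cat}", "w")
                handles[cat].write(header)
        for result in results:
            lines = pair_records(result) if result.paired else [
                to_sam_record(result.name, result.seq1, result.qual1, result.aln1)
            ]
            for line in lines:
                handles[result.category].write(line + "\n")
            counts[result.category] += len(lines)
    finally:
        for fh in {id(h): h for h in handles.values()}.values():
            fh.close()
    return counts
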