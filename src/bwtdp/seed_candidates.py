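"""Step-3 seeding: nominate candidate regions for gapped alignment.

Seeds (substrings of the read) are taken at regular offsets along the
read and its reverse complement, mapped exactly with the FM-index, and
their hits clustered by the read placement they imply.  Clusters become
candidate regions scored by the number of distinct supporting seeds; only
the best ``ceiling`` regions (default 30) are handed to the DP stage, and
seeds hitting more than ``seed_hit_limit`` loci are dropped outright —
a homopolymer seed can hit tens of thousands of places and would other-
wise swamp the locate step long before the region ceiling applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import encode, revcomp_codes
from .index_core import FMIndex, backward_search, locate_concat

DEFAULT_SEED_LENGTH = 25
DEFAULT_SEED_STRIDE = 25
DEFAULT_CEILING = 30
DEFAULT_SEED_HIT_LIMIT = 1024


@dataclass(frozen=True)
class Seed:
    read_offset: int   # 0-based start within its orientation's sequence
    length: int
    strand: str        # orientation of the read the seed came from


@dataclass(frozen=True)
class CandidateRegion:
    start: int         # concatenated coords, half-open, padded
    end: int
    strand: str
    support: int       # distinct supporting seeds
    anchor: int        # implied leftmost read placement (concat coords)


def extract_seeds(
    read: str,
    seed_length: int = DEFAULT_SEED_LENGTH,
    stride: int = DEFAULT_SEED_STRIDE,
) -> list[Seed]:
    """Seeds at offsets 0, stride, 2*stride, ... on both orientations,
    plus an end-anchored seed when the last regular one stops short.
    Reads shorter than seed_length yield one full-length seed each way."""
    if seed_length < 1 or stride < 1:
        raise ValueError("seed_length and stride must be >= 1")
    n = len(read)
    if n < seed_length:
        offsets = [0]
        seed_length = n
    else:
        offsets = list(range(0, n - seed_length + 1, stride))
        last = n - seed_length
        if offsets[-1] != last:
            offsets.append(last)
    return [Seed(off, seed_length, strand) for strand in "+-" for off in offsets]


def map_seeds(
    index: FMIndex,
    read: str,
    seeds: list[Seed],
    hit_limit: int = DEFAULT_SEED_HIT_LIMIT,
) -> list[tuple[Seed, int]]:
    """Exact-match each seed; returns (seed, concat position) pairs.
    Seeds with more than hit_limit loci or containing N are discarded."""
    fwd = encode(read)
    rev = revcomp_codes(fwd)
    out = []
    for seed in seeds:
        codes = fwd if seed.strand == "+" else rev
        pat = codes[seed.read_offset:seed.read_offset + seed.length]
        if np.any(pat > 3):
            continue
        rng = backward_search(index, pat)
        if rng.empty or rng.width > hit_limit:
            continue
        out.extend((seed, int(p)) for p in locate_concat(index, rng))
    return out


def enumerate_candidates(
    seed_hits: list[tuple[Seed, int]],
    read_length: int,
    ceiling: int = DEFAULT_CEILING,
    merge_window: int = 32,
    pad: int = 32,
    index: FMIndex | None = None,
) -> list[CandidateRegion]:
    """Cluster seed hits into ranked candidate regions.

    Hits whose implied anchors (hit position minus read offset) fall
    within ``merge_window`` of each other on the same strand merge into
    one region; regions are sorted by (support desc, start asc) and cut
    to the top ``ceiling``.  Intervals are padded by the DP band
    half-width and clipped to the containing sequence when an index is
    supplied.
    """
    if ceiling < 1:
        raise ValueError("ceiling must be >= 1")
    by_strand: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
    for seed, pos in seed_hits:
        anchor = pos - seed.read_offset
        if anchor < 0:
            continue
        by_strand[seed.strand].append((anchor, seed.read_offset))
    regions = []
    for strand, items in by_strand.items():
        items.sort()
        cluster: list[tuple[int, int]] = []
        for anchor, off in items + [(None, None)]:
            if cluster and (anchor is None or anchor - cluster[-1][0] > merge_window):
                anchors = [a for a, _ in cluster]
                support = len({o for _, o in cluster})
                lead = min(anchors)
                start = lead - pad
                end = max(anchors) + read_length + pad
                if index is not None:
                    lo, hi = index.sequence_bounds(min(max(lead, 0), index.text_length - 1))
                    start, end = max(start, lo), min(end, hi)
                if end - start >= read_length:
                    regions.append(CandidateRegion(start, end, strand, support, lead))
                cluster = []
            if anchor is not None:
                cluster.append((anchor, off))
    regions.sort(key=lambda r: (-r.support, r.start, r.strand))
    return regions[:ceiling]
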