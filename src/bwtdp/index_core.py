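"""BWT/FM-index over a (multi-)FASTA reference.

The reference sequences are concatenated with one sentinel per sequence;
sentinels sort before A < C < G < T and are pairwise distinguished by
sequence order during suffix sorting, so the suffix array is well defined
for any number of sequences.  The index stores

* the BWT of the concatenated text,
* cumulative character counts,
* an occurrence table sampled every ``occ_stride`` BWT positions
  (one sampling level; default 128),
* suffix-array values at every ``sa_stride``-th rank (1, 2 or 4).

Query results are independent of the suffix-array stride; a sparser SA
only trades memory for extra LF-mapping steps during ``locate``.

Ambiguity handling: isolated N bases are replaced by a pseudo-random base
drawn from a fixed seed (the alphabet must stay 4-letter); runs of >= 10
consecutive Ns are additionally recorded as masked intervals so that
alignments falling inside them can be suppressed downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from numba import njit

from ._util import decode, encode

INDEX_FORMAT_VERSION = 1
DEFAULT_OCC_STRIDE = 128
_N_FILL_SEED = 0x4E
_LONG_N_RUN = 10


@dataclass(frozen=True)
class SARange:
    """Half-open interval [low, high) of suffix-array ranks."""

    low: int
    high: int

    @property
    def width(self) -> int:
        return self.high - self.low

    def __post_init__(self):
        if self.low < 0 or self.high < self.low:
            raise ValueError(f"invalid SA range [{self.low}, {self.high})")

    @property
    def empty(self) -> bool:
        return self.high <= self.low


@dataclass
class FMIndex:
    bwt: np.ndarray                # uint8 codes, 4 = sentinel
    counts: np.ndarray             # int64[5]; counts[c] = rank where char c starts
    occ: np.ndarray                # int64[(nblocks+1), 4] checkpoint table
    occ_stride: int
    sa_samples: np.ndarray         # int64, SA value at every sa_stride-th rank
    sa_stride: int
    text: np.ndarray               # concatenated codes incl. sentinels
    text_length: int               # bases including sentinels
    reference_names: list[str]
    reference_offsets: np.ndarray  # int64, start of each sequence in concat coords
    reference_lengths: np.ndarray  # int64
    sentinel_rows: np.ndarray      # ranks r with bwt[r] == sentinel, sorted
    sentinel_row_sa: np.ndarray    # SA[r] for those ranks
    masked_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    # -- coordinate helpers -------------------------------------------------

    def to_local(self, concat_pos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.reference_offsets, concat_pos, side="right")) - 1
        return self.reference_names[i], int(concat_pos - self.reference_offsets[i])

    def sequence_bounds(self, concat_pos: int) -> tuple[int, int]:
        """Concatenated [start, end) of the sequence containing concat_pos."""
        i = int(np.searchsorted(self.reference_offsets, concat_pos, side="right")) - 1
        start = int(self.reference_offsets[i])
        return start, start + int(self.reference_lengths[i])

    def fetch_codes(self, concat_start: int, concat_end: int) -> np.ndarray:
        return self.text[concat_start:concat_end]

    @property
    def n_sequences(self) -> int:
        return len(self.reference_names)

    @property
    def bwt_string(self) -> str:
        return decode(self.bwt)

    # -- persistence --------------------------------------------------------

    def save(self, prefix: str) -> None:
        meta = {
            "version": INDEX_FORMAT_VERSION,
            "occ_stride": self.occ_stride,
            "sa_stride": self.sa_stride,
            "text_length": self.text_length,
            "reference_names": self.reference_names,
            "masked_intervals": {k: list(map(list, v)) for k, v in self.masked_intervals.items()},
        }
        np.savez(
            prefix + ".fmi.npz",
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            bwt=self.bwt,
            counts=self.counts,
            occ=self.occ,
            sa_samples=self.sa_samples,
            text=self.text,
            reference_offsets=self.reference_offsets,
            reference_lengths=self.reference_lengths,
            sentinel_rows=self.sentinel_rows,
            sentinel_row_sa=self.sentinel_row_sa,
        )

    @classmethod
    def load(cls, prefix: str) -> "FMIndex":
        with np.load(prefix + ".fmi.npz") as z:
            meta = json.loads(z["meta"].tobytes().decode())
            if meta["version"] != INDEX_FORMAT_VERSION:
                raise ValueError(f"unsupported index version {meta['version']}")
            return cls(
                bwt=z["bwt"],
                counts=z["counts"],
                occ=z["occ"],
                occ_stride=meta["occ_stride"],
                sa_samples=z["sa_samples"],
                sa_stride=meta["sa_stride"],
                text=z["text"],
                text_length=meta["text_length"],
                reference_names=list(meta["reference_names"]),
                reference_offsets=z["reference_offsets"],
                reference_lengths=z["reference_lengths"],
                sentinel_rows=z["sentinel_rows"],
                sentinel_row_sa=z["sentinel_row_sa"],
                masked_intervals={k: [tuple(iv) for iv in v] for k, v in meta["masked_intervals"].items()},
            )


# ---------------------------------------------------------------------------
# suffix array (prefix doubling)


def _suffix_array(keys: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence whose suffixes are pairwise
    distinct (guaranteed here by distinct sentinel keys).  Manber–Myers
    prefix doubling, O(n log^2 n) via numpy lexsort."""
    n = keys.shape[0]
    sa = np.argsort(keys, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    sorted_keys = keys[sa]
    r = np.zeros(n, dtype=np.int64)
    if n > 1:
        r[1:] = np.cumsum(sorted_keys[1:] != sorted_keys[:-1])
    rank[sa] = r
    k = 1
    while rank[sa[-1]] != n - 1:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        sa = np.lexsort((second, rank))
        pair_first = rank[sa]
        pair_second = second[sa]
        new = np.zeros(n, dtype=np.int64)
        new[1:] = np.cumsum(
            (pair_first[1:] != pair_first[:-1]) | (pair_second[1:] != pair_second[:-1])
        )
        rank[sa] = new
        k *= 2
    return sa


# ---------------------------------------------------------------------------
# numba kernels: occurrence lookup, backward extension, locate


@njit(cache=False)
def _occ_kernel(bwt, ckpt, stride, c, p):
    b = p // stride
    cnt = ckpt[b, c]
    for i in range(b * stride, p):
        if bwt[i] == c:
            cnt += 1
    return cnt


@njit(cache=False)
def _backward_search_kernel(bwt, ckpt, stride, counts, pat):
    lo = 0
    hi = bwt.shape[0]
    for idx in range(pat.shape[0] - 1, -1, -1):
        c = pat[idx]
        if c > 3:
            return 0, 0
        lo = counts[c] + _occ_kernel(bwt, ckpt, stride, c, lo)
        hi = counts[c] + _occ_kernel(bwt, ckpt, stride, c, hi)
        if lo >= hi:
            return 0, 0
    return lo, hi


@njit(cache=False)
def _locate_kernel(bwt, ckpt, stride, counts, sa_stride, sa_samples,
                   sent_rows, sent_sa, lo, hi, out):
    for k in range(hi - lo):
        r = lo + k
        steps = 0
        while r % sa_stride != 0:
            c = bwt[r]
            if c == 4:
                j = np.searchsorted(sent_rows, r)
                r = -1
                out[k] = sent_sa[j] + steps
                break
            r = counts[c] + _occ_kernel(bwt, ckpt, stride, c, r)
            steps += 1
        if r >= 0:
            out[k] = sa_samples[r // sa_stride] + steps
    return out


# ---------------------------------------------------------------------------
# public operations


def _fill_ns(codes: np.ndarray, name: str, masked: dict) -> None:
    """Replace N codes in place; record runs of >= _LONG_N_RUN as masked."""
    npos = np.nonzero(codes == 4)[0]
    if npos.size == 0:
        return
    rng = np.random.default_rng(_N_FILL_SEED)
    codes[npos] = rng.integers(0, 4, size=npos.size, dtype=np.uint8)
    runs = []
    start = prev = int(npos[0])
    for p in npos[1:]:
        p = int(p)
        if p != prev + 1:
            if prev - start + 1 >= _LONG_N_RUN:
                runs.append((start, prev + 1))
            start = p
        prev = p
    if prev - start + 1 >= _LONG_N_RUN:
        runs.append((start, prev + 1))
    if runs:
        masked[name] = runs


def build_index(
    reference: dict[str, str] | Iterable[tuple[str, str]],
    sa_stride: int = 1,
    occ_stride: int = DEFAULT_OCC_STRIDE,
) -> FMIndex:
    """Build the FM-index of a set of named DNA sequences.

    sa_stride selects full (1), 1/2 or 1/4 suffix-array sampling; all
    query results are identical across strides.
    """
    if sa_stride not in (1, 2, 4):
        raise ValueError("sa_stride must be 1, 2 or 4")
    items = list(reference.items()) if isinstance(reference, dict) else list(reference)
    if not items:
        raise ValueError("empty reference")
    names, offsets, lengths, chunks = [], [], [], []
    masked: dict[str, list[tuple[int, int]]] = {}
    pos = 0
    for name, seq in items:
        if len(seq) == 0:
            raise ValueError(f"empty sequence {name!r}")
        codes = encode(seq)
        _fill_ns(codes, name, masked)
        names.append(name)
        offsets.append(pos)
        lengths.append(len(codes))
        chunks.append(codes)
        chunks.append(np.array([4], dtype=np.uint8))
        pos += len(codes) + 1
    text = np.concatenate(chunks)
    n = text.shape[0]
    nseq = len(names)

    # distinct sort keys: sentinel of the t-th sequence gets key t; bases get nseq+code
    keys = text.astype(np.int64) + nseq
    sent_pos = np.nonzero(text == 4)[0]
    keys[sent_pos] = np.arange(nseq)
    sa = _suffix_array(keys)

    bwt = text[(sa - 1) % n]
    counts = np.zeros(5, dtype=np.int64)
    base_counts = np.bincount(text, minlength=5)
    counts[0] = nseq
    for c in range(1, 4):
        counts[c] = counts[c - 1] + base_counts[c - 1]
    counts[4] = n  # guard

    nblocks = n // occ_stride + 1
    occ = np.zeros((nblocks + 1, 4), dtype=np.int64)
    onehot = np.zeros((n, 4), dtype=np.int64)
    valid = bwt < 4
    onehot[np.nonzero(valid)[0], bwt[valid]] = 1
    csum = np.cumsum(onehot, axis=0)
    for b in range(1, nblocks + 1):
        end = min(b * occ_stride, n)
        occ[b] = csum[end - 1]

    sa_samples = sa[::sa_stride].astype(np.int64)
    sent_rows = np.nonzero(bwt == 4)[0].astype(np.int64)
    sent_sa = sa[sent_rows].astype(np.int64)

    return FMIndex(
        bwt=bwt,
        counts=counts,
        occ=occ,
        occ_stride=occ_stride,
        sa_samples=sa_samples,
        sa_stride=sa_stride,
        text=text,
        text_length=n,
        reference_names=names,
        reference_offsets=np.array(offsets, dtype=np.int64),
        reference_lengths=np.array(lengths, dtype=np.int64),
        sentinel_rows=sent_rows,
        sentinel_row_sa=sent_sa,
        masked_intervals=masked,
    )


def occ(index: FMIndex, c: int, p: int) -> int:
    """Occurrences of code c in bwt[0:p) via the sampled table."""
    return int(_occ_kernel(index.bwt, index.occ, index.occ_stride, c, p))


def backward_search(index: FMIndex, pattern: str | np.ndarray) -> SARange:
    """Exact backward search; returns the SA range of the pattern.

    The empty pattern matches everywhere (full rank range); an absent
    pattern yields an empty range.
    """
    pat = encode(pattern) if isinstance(pattern, str) else np.asarray(pattern, dtype=np.uint8)
    if pat.shape[0] == 0:
        return SARange(0, index.text_length)
    lo, hi = _backward_search_kernel(index.bwt, index.occ, index.occ_stride, index.counts, pat)
    return SARange(int(lo), int(hi))


def extend_left(index: FMIndex, rng: SARange, c: int) -> SARange:
    """One backward-extension step: prepend code c to the matched pattern."""
    lo = index.counts[c] + _occ_kernel(index.bwt, index.occ, index.occ_stride, c, rng.low)
    hi = index.counts[c] + _occ_kernel(index.bwt, index.occ, index.occ_stride, c, rng.high)
    if lo >= hi:
        return SARange(0, 0)
    return SARange(int(lo), int(hi))


def locate_concat(index: FMIndex, rng: SARange) -> np.ndarray:
    """Concatenated-coordinate positions of a range, sorted ascending."""
    if rng.high > index.text_length:
        raise ValueError("SA range out of bounds")
    if rng.empty:
        return np.empty(0, dtype=np.int64)
    out = np.empty(rng.width, dtype=np.int64)
    _locate_kernel(
        index.bwt, index.occ, index.occ_stride, index.counts,
        index.sa_stride, index.sa_samples,
        index.sentinel_rows, index.sentinel_row_sa,
        rng.low, rng.high, out,
    )
    out.sort()
    return out


def locate(index: FMIndex, rng: SARange) -> list[tuple[str, int]]:
    """Resolve a range to (reference name, 0-based local position) pairs."""
    return [index.to_local(p) for p in locate_concat(index, rng)]


def reconstruct_sequences(index: FMIndex) -> list[str]:
    """Rebuild every reference sequence by repeated LF-mapping from its
    sentinel rank.  Used to check index integrity."""
    seqs = []
    for t in range(index.n_sequences):
        r = t
        chars: list[int] = []
        while True:
            c = int(index.bwt[r])
            if c == 4:
                break
            chars.append(c)
            r = int(index.counts[c]) + occ(index, c, r)
        seqs.append(decode(np.array(chars[::-1], dtype=np.uint8)))
    return seqs


def read_fasta(path: str) -> list[tuple[str, str]]:
    """Multi-FASTA reader (wrapped lines, case-insensitive)."""
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records
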