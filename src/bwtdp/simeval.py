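"""Illumina-style paired-end read simulation and alignment scoring.

The simulator emulates the classic haplotype-resampling protocol: a
random (or supplied) reference, two haplotypes mutated at a SNP rate of
1e-3 and an indel rate of 1e-4 per base, fragments drawn with normally
distributed insert length (mean 500, sd 25), mates sequenced from
opposite fragment ends (FR), and uniform per-base substitution
sequencing error.  Every read carries a truth record mapping it back to
its pre-mutation reference coordinate.

The evaluator applies the standard correctness rule for simulated data:
an alignment is correct when its leftmost position lands within 50 bp of
the simulator-assigned origin on the same strand and reference (the
tolerance absorbs soft-clipping and indel-placement ambiguity).
Sensitivity is correct/all-simulated; FDR is incorrect/all-aligned; a
cumulative ROC table stratifies both counts from high to low MAPQ.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from ._util import BASES, decode, revcomp

_INDEL_MEAN = 2     # geometric length model
_INDEL_CAP = 50
DEFAULT_TOLERANCE = 50


@dataclass(frozen=True)
class SimulationParams:
    genome_length: int = 100_000
    snp_rate: float = 0.001
    indel_rate: float = 0.0001
    read_length: int = 100
    n_pairs: int = 20_000
    insert_mean: float = 500.0
    insert_sd: float = 25.0
    error_rate: float = 0.005
    n_haplotypes: int = 2
    seed: int = 0
    repeat_copies: int = 0      # optional tandem-repeat planting
    repeat_length: int = 0

    def __post_init__(self):
        for r in (self.snp_rate, self.indel_rate, self.error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome length")


@dataclass
class SimulatedReads:
    reference: dict[str, str]
    haplotypes: list[str]
    pairs: list[tuple[str, str, str, str, str]]  # (name, seq1, qual1, seq2, qual2)
    truth: pd.DataFrame  # read_id, end, reference, position, strand

    def write(self, prefix: str) -> None:
        with open(prefix + ".fa", "w") as fa:
            for name, seq in self.reference.items():
                fa.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fa.write(seq[i:i + 70] + "\n")
        with open(prefix + "_1.fq", "w") as f1, open(prefix + "_2.fq", "w") as f2:
            for name, s1, q1, s2, q2 in self.pairs:
                f1.write(f"@{name}/1\n{s1}\n+\n{q1}\n")
                f2.write(f"@{name}/2\n{s2}\n+\n{q2}\n")
        self.truth.to_csv(prefix + ".truth.tsv", sep="\t", index=False)


def _random_reference(params: SimulationParams, rng: np.random.Generator) -> str:
    codes = rng.integers(0, 4, size=params.genome_length, dtype=np.uint8)
    if params.repeat_copies and params.repeat_length:
        unit = codes[: params.repeat_length].copy()
        pos = params.repeat_length
        for _ in range(params.repeat_copies):
            end = min(pos + params.repeat_length, params.genome_length)
            codes[pos:end] = unit[: end - pos]
            pos = end
    return decode(codes)


def _mutate(ref: str, params: SimulationParams, rng: np.random.Generator) -> tuple[str, np.ndarray]:
    """One haplotype plus a map from haplotype to reference coordinates."""
    out: list[str] = []
    coord: list[int] = []
    i = 0
    n = len(ref)
    while i < n:
        if rng.random() < params.indel_rate:
            length = min(int(rng.geometric(1.0 / _INDEL_MEAN)), _INDEL_CAP)
            if rng.random() < 0.5:  # deletion: skip reference bases
                i += length
                continue
            for _ in range(length):  # insertion: novel bases at this point
                out.append(BASES[rng.integers(0, 4)])
                coord.append(i)
        base = ref[i]
        if rng.random() < params.snp_rate:
            base = BASES[(CODEMAP[base] + int(rng.integers(1, 4))) % 4]
        out.append(base)
        coord.append(i)
        i += 1
    return "".join(out), np.array(coord, dtype=np.int64)


CODEMAP = {c: i for i, c in enumerate(BASES)}


def _sequencing_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for p in hits:
        arr[p] = BASES[(CODEMAP[arr[p]] + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


def simulate(params: SimulationParams) -> SimulatedReads:
    """Deterministic for a fixed seed; returns reads plus truth table."""
    rng = np.random.default_rng(params.seed)
    ref = _random_reference(params, rng)
    ref_name = "chrS"
    haplotypes, coords = [], []
    for _ in range(params.n_haplotypes):
        hap, coord = _mutate(ref, params, rng)
        haplotypes.append(hap)
        coords.append(coord)

    qual = chr(33 + 30) * params.read_length
    pairs = []
    truth_rows = []
    rl = params.read_length
    for i in range(params.n_pairs):
        h = int(rng.integers(0, params.n_haplotypes))
        hap, coord = haplotypes[h], coords[h]
        insert = int(round(rng.normal(params.insert_mean, params.insert_sd)))
        insert = max(rl, min(insert, len(hap)))
        start = int(rng.integers(0, len(hap) - insert + 1))
        frag = hap[start:start + insert]
        left = frag[:rl]
        right = revcomp(frag[-rl:])
        left_pos = int(coord[start])
        right_pos = int(coord[start + insert - rl])
        name = f"sim{i}"
        if rng.random() < 0.5:
            s1, p1, st1 = left, left_pos, "+"
            s2, p2, st2 = right, right_pos, "-"
        else:
            s1, p1, st1 = right, right_pos, "-"
            s2, p2, st2 = left, left_pos, "+"
        s1 = _sequencing_errors(s1, params.error_rate, rng)
        s2 = _sequencing_errors(s2, params.error_rate, rng)
        pairs.append((name, s1, qual, s2, qual))
        truth_rows.append((name, 1, ref_name, p1, st1))
        truth_rows.append((name, 2, ref_name, p2, st2))

    truth = pd.DataFrame(truth_rows, columns=["read_id", "end", "reference", "position", "strand"])
    return SimulatedReads(
        reference={ref_name: ref}, haplotypes=haplotypes, pairs=pairs, truth=truth)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationResult:
    n_simulated: int
    n_aligned: int
    n_correct: int
    sensitivity: float
    fdr: float
    roc: pd.DataFrame  # mapq, correct, incorrect, cum_correct, cum_incorrect

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "metric": ["simulated", "aligned", "correct", "sensitivity", "fdr"],
            "value": [self.n_simulated, self.n_aligned, self.n_correct,
                      self.sensitivity, self.fdr],
        })


def _load_truth(truth) -> pd.DataFrame:
    if isinstance(truth, pd.DataFrame):
        return truth
    return pd.read_csv(truth, sep="\t")


def evaluate(
    sam_path: str,
    truth,
    tolerance: int = DEFAULT_TOLERANCE,
    min_mapq: int = 0,
) -> EvaluationResult:
    """Score a SAM stream against the simulator's truth table.

    Correct = mapped primary record on the truth reference and strand
    whose leftmost position is within ``tolerance`` (inclusive) of the
    assigned origin.  Unknown read ids raise with the offenders listed.
    """
    import pysam

    tdf = _load_truth(truth)
    lookup = {
        (str(r.read_id), int(r.end)): (r.reference, int(r.position), r.strand)
        for r in tdf.itertuples()
    }
    n_simulated = len(lookup)
    n_aligned = n_correct = 0
    per_mapq: dict[int, list[int]] = {}
    unknown = []
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            end = 2 if (rec.is_paired and rec.is_read2) else 1
            key = (rec.query_name, end)
            if key not in lookup:
                unknown.append(f"{rec.query_name}/{end}")
                continue
            if rec.is_unmapped or rec.mapping_quality < min_mapq:
                continue
            n_aligned += 1
            ref, pos, strand = lookup[key]
            rec_strand = "-" if rec.is_reverse else "+"
            ok = (rec.reference_name == ref and rec_strand == strand
                  and abs(rec.reference_start - pos) <= tolerance)
            n_correct += ok
            bucket = per_mapq.setdefault(rec.mapping_quality, [0, 0])
            bucket[0 if ok else 1] += 1
    if unknown:
        raise ValueError("read ids absent from truth: " + ", ".join(sorted(set(unknown))[:20]))

    sensitivity = n_correct / n_simulated if n_simulated else 0.0
    n_incorrect = n_aligned - n_correct
    fdr = n_incorrect / n_aligned if n_aligned else 0.0

    rows = []
    cum_c = cum_i = 0
    for mapq in sorted(per_mapq, reverse=True):
        c, i = per_mapq[mapq]
        cum_c += c
        cum_i += i
        rows.append((mapq, c, i, cum_c, cum_i))
    roc = pd.DataFrame(rows, columns=["mapq", "correct", "incorrect",
                                      "cum_correct", "cum_incorrect"])
    return EvaluationResult(
        n_simulated=n_simulated, n_aligned=n_aligned, n_correct=n_correct,
        sensitivity=sensitivity, fdr=fdr, roc=roc)
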