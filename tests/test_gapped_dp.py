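"""Fit-alignment DP: ground truth by exhaustive enumeration, two-table vs
three-table equivalence, access-count instrumentation, acceptance rule."""

import numpy as np
import pytest

from bwtdp.gapped_dp import (
    ScoringScheme,
    accepts,
    dp_full,
    dp_reduced,
    rescore_cigar,
)
from tests.conftest import random_dna

DEFAULT = ScoringScheme()


def enumeration_best_score(T: str, R: str, sc: ScoringScheme) -> int:
    """Independent oracle: enumerate every alignment of all of R against
    every start position of T (ops M/I/D, affine run costs), return the
    best score.  Exponential; only for tiny instances."""
    n, m = len(R), len(T)
    best = -10 ** 9

    def rec(ti, rj, score, last):
        nonlocal best
        if rj == n:
            best = max(best, score)
            return
        # match/mismatch
        if ti < m:
            s = sc.match if T[ti] == R[rj] else -sc.mismatch
            rec(ti + 1, rj + 1, score + s, "M")
        # insertion: read base against a gap
        cost = sc.gap_extend + (0 if last == "I" else sc.gap_open)
        rec(ti, rj + 1, score - cost, "I")
        # deletion: reference base skipped
        if ti < m:
            cost = sc.gap_extend + (0 if last == "D" else sc.gap_open)
            rec(ti + 1, rj, score - cost, "D")

    for start in range(m):
        rec(start, 0, 0, "")
    return best


class TestExamples:
    def test_identity(self):
        res = dp_full("ACGTACGT", "ACGTACGT")
        assert (res.score, res.cigar) == (8, "8M")

    def test_single_deletion(self):
        res = dp_full("ACGTTACGT", "ACGTACGT")
        assert res.score == 8 - (2 + 1)
        # deletion placement inside the TT run is ambiguous
        assert res.cigar in ("3M1D5M", "4M1D4M")
        assert rescore_cigar(res.cigar, "ACGTTACGT", "ACGTACGT", res.start_in_T, DEFAULT) == res.score

    def test_single_mismatch(self):
        res = dp_full("ACGTACGT", "ACGAACGT")
        assert (res.score, res.cigar) == (7 - 2, "8M")

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            dp_full("", "ACGT")
        with pytest.raises(ValueError):
            dp_reduced("ACGT", "")

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(match=0)


class TestEnumerationOracle:
    def test_small_instances_match_enumeration(self, rng):
        for _ in range(40):
            m = int(rng.integers(1, 13))
            n = int(rng.integers(1, min(m + 3, 9)))
            T, R = random_dna(rng, m), random_dna(rng, n)
            sc = ScoringScheme(
                match=int(rng.integers(1, 4)), mismatch=int(rng.integers(1, 6)),
                gap_open=int(rng.integers(1, 6)), gap_extend=int(rng.integers(1, 4)))
            expected = enumeration_best_score(T, R, sc)
            got = dp_full(T, R, sc)
            assert got.score == expected
            assert rescore_cigar(got.cigar, T, R, got.start_in_T, sc) == expected


class TestReducedEquivalence:
    def test_random_instances(self, rng):
        for _ in range(300):
            m = int(rng.integers(1, 120))
            n = int(rng.integers(1, 80))
            T, R = random_dna(rng, m), random_dna(rng, n)
            sc = ScoringScheme(
                match=int(rng.integers(1, 5)), mismatch=int(rng.integers(1, 11)),
                gap_open=int(rng.integers(1, 11)), gap_extend=int(rng.integers(1, 11)))
            a, b = dp_full(T, R, sc), dp_reduced(T, R, sc)
            assert (a.score, a.end_in_T, a.cigar) == (b.score, b.end_in_T, b.cigar)
            assert rescore_cigar(a.cigar, T, R, a.start_in_T, sc) == a.score

    def test_instrumented_matches_compiled(self, rng):
        for _ in range(20):
            T = random_dna(rng, int(rng.integers(5, 40)))
            R = random_dna(rng, int(rng.integers(3, 25)))
            for fn in (dp_full, dp_reduced):
                fast, slow = fn(T, R), fn(T, R, instrument=True)
                assert (fast.score, fast.cigar, fast.start_in_T) == \
                    (slow.score, slow.cigar, slow.start_in_T)


class TestInstrumentation:
    @pytest.mark.parametrize("fn,reads,writes", [(dp_reduced, 2, 2), (dp_full, 7, 3)])
    def test_access_counts_per_iteration(self, rng, fn, reads, writes):
        T, R = random_dna(rng, 10), random_dna(rng, 10)
        res = fn(T, R, instrument=True)
        assert res.iterations == 100
        assert res.reads_per_iteration == reads
        assert res.writes_per_iteration == writes

    def test_counts_independent_of_content(self, rng):
        """Access traffic is a function of table shape only."""
        for _ in range(5):
            m, n = int(rng.integers(2, 30)), int(rng.integers(2, 20))
            res = dp_reduced(random_dna(rng, m), random_dna(rng, n), instrument=True)
            assert (res.table_reads, res.table_writes) == (2 * m * n, 2 * m * n)


class TestAcceptanceRule:
    def test_cutoff_default(self):
        assert DEFAULT.cutoff(100) == 30
        assert DEFAULT.cutoff(50) == 15

    def test_cutoff_monotone(self):
        cuts = [DEFAULT.cutoff(n) for n in range(10, 300)]
        assert all(b >= a for a, b in zip(cuts, cuts[1:]))

    def test_long_deletion_boundary(self, rng):
        """100 bp read: a single deletion up to 68 bp passes, 69 fails.

        The read avoids A and the deleted reference run is poly-A, so no
        alternative alignment can beat the planted single-gap path."""
        for gap, ok in ((68, True), (69, False)):
            read = "".join(np.array(list("CGT"))[rng.integers(0, 3, 100)])
            ref = read[:50] + "A" * gap + read[50:]
            res = dp_reduced(ref, read)
            assert res.score == 100 - (2 + gap)
            assert accepts(res, DEFAULT, 100) is ok

    def test_many_single_base_deletions_boundary(self, rng):
        """100 bp read: up to 23 isolated 1-bp deletions pass, 24 fail."""
        for gaps, ok in ((23, True), (24, False)):
            read = "".join(np.array(list("CGT"))[rng.integers(0, 3, 100)])
            parts, prev = [], 0
            for g in range(gaps):
                cut = 4 * (g + 1)
                parts.extend([read[prev:cut], "A"])
                prev = cut
            parts.append(read[prev:])
            ref = "".join(parts)
            res = dp_reduced(ref, read)
            assert res.score == 100 - 3 * gaps
            assert accepts(res, DEFAULT, 100) is ok

    def test_perfect_read_always_accepted(self, rng):
        for n in (20, 75, 250):
            read = random_dna(rng, n)
            assert accepts(dp_reduced(read, read), DEFAULT, n)
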