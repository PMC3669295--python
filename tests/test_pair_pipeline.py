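"""Proper-pair geometry, mate rescue and the three-step pair workflow."""

import collections

import numpy as np
import pytest

from bwtdp._util import revcomp
from bwtdp.index_core import build_index
from bwtdp.mapq_output import Alignment
from bwtdp.pair_pipeline import (
    PairConfig,
    align_pair,
    align_single,
    is_properly_paired,
    mate_rescue,
)
from tests.conftest import random_dna


def aln(pos, strand, cigar="100M", ref="chr1"):
    return Alignment(reference=ref, pos=pos, strand=strand, cigar=cigar,
                     score=100, nm=0)


CFG = PairConfig(300, 700)


class TestProperPair:
    def test_fr_span_500(self):
        # mate A at 1000 (+), mate B ends at 1500: outer span 500
        assert is_properly_paired(aln(1000, "+"), aln(1400, "-"), CFG)

    def test_same_strand_not_proper_under_fr(self):
        assert not is_properly_paired(aln(1000, "+"), aln(1400, "+"), CFG)

    def test_inclusive_max_boundary(self):
        assert is_properly_paired(aln(1000, "+"), aln(1600, "-"), CFG)      # span 700
        assert not is_properly_paired(aln(1000, "+"), aln(1601, "-"), CFG)  # span 701

    def test_inclusive_min_boundary(self):
        assert is_properly_paired(aln(1000, "+"), aln(1200, "-"), CFG)      # span 300
        assert not is_properly_paired(aln(1000, "+"), aln(1199, "-"), CFG)  # span 299

    def test_wrong_order_under_fr(self):
        assert not is_properly_paired(aln(1400, "+"), aln(1000, "-"), CFG)

    def test_different_references(self):
        assert not is_properly_paired(aln(1000, "+"), aln(1400, "-", ref="chr2"), CFG)

    def test_ff_orientation(self):
        ff = PairConfig(300, 700, orientation="FF")
        assert is_properly_paired(aln(1000, "+"), aln(1400, "+"), ff)
        assert not is_properly_paired(aln(1000, "+"), aln(1400, "-"), ff)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            PairConfig(700, 300)
        with pytest.raises(ValueError):
            PairConfig(300, 700, orientation="RF")


@pytest.fixture(scope="module")
def pe_genome():
    genome = random_dna(np.random.default_rng(77), 30_000)
    return genome, build_index({"chr1": genome})


class TestMateRescue:
    def test_deleted_mate_rescued(self, pe_genome):
        genome, idx = pe_genome
        anchor_read = genome[2000:2100]
        anchor = align_single("a", anchor_read, idx).aln1
        # mate with a 5 bp deletion, reverse strand, outer span 500
        mate_region = genome[2400:2505]
        mate = revcomp(mate_region[:50] + mate_region[55:])
        rescued = mate_rescue(anchor, mate, idx, CFG)
        assert rescued is not None
        assert "5D" in rescued.cigar
        assert rescued.strand == "-"
        assert is_properly_paired(anchor, rescued, CFG)

    def test_random_mate_not_rescued(self, pe_genome):
        _, idx = pe_genome
        anchor = aln(2000, "+")
        rng = np.random.default_rng(5)
        assert mate_rescue(anchor, random_dna(rng, 100), idx, CFG) is None

    def test_anchor_near_reference_end_clips(self, pe_genome):
        genome, idx = pe_genome
        anchor = aln(29_950, "+", cigar="50M")
        rng = np.random.default_rng(6)
        assert mate_rescue(anchor, random_dna(rng, 100), idx, CFG) is None


class TestAlignPair:
    def test_exact_pair_step1_gout(self, pe_genome):
        genome, idx = pe_genome
        r1 = genome[5000:5100]
        r2 = revcomp(genome[5400:5500])
        res = align_pair("p", r1, r2, idx, CFG)
        assert (res.status, res.category, res.step) == ("properly_paired", "gout", 1)
        assert res.aln1.pos == 5000 and res.aln2.pos == 5400
        assert res.aln1.mapq == 60

    def test_deleted_mate_step2_dpout(self, pe_genome):
        genome, idx = pe_genome
        r1 = genome[8000:8100]
        region = genome[8400:8510]
        r2 = revcomp(region[:40] + region[50:110])  # 10 bp deletion
        res = align_pair("p", r1, r2, idx, CFG)
        assert (res.status, res.category, res.step) == ("properly_paired", "dpout", 2)
        assert "10D" in res.aln2.cigar

    def test_both_ends_indel_step3_dpout(self, pe_genome):
        genome, idx = pe_genome
        reg1 = genome[12_000:12_105]
        r1 = reg1[:50] + reg1[55:105]            # 5 bp deletion
        reg2 = genome[12_400:12_504]
        r2 = revcomp(reg2[:60] + reg2[64:104])   # 4 bp deletion
        res = align_pair("p", r1, r2, idx, CFG)
        assert (res.status, res.category, res.step) == ("properly_paired", "dpout", 3)
        assert res.aln1.from_dp and res.aln2.from_dp

    def test_unalignable_pair_unpair(self, pe_genome):
        _, idx = pe_genome
        rng = np.random.default_rng(9)
        res = align_pair("p", random_dna(rng, 100), random_dna(rng, 100), idx, CFG)
        assert (res.status, res.category) == ("unaligned", "unpair")
        assert res.aln1 is None and res.aln2 is None

    def test_category_partition_conserves_records(self, pe_genome):
        """Every pair lands in exactly one category; records sum to 2N."""
        genome, idx = pe_genome
        rng = np.random.default_rng(10)
        pairs = []
        for i in range(30):
            s = int(rng.integers(0, 29_000))
            ins = int(rng.integers(300, 600))
            r1 = genome[s:s + 100]
            r2 = revcomp(genome[s + ins - 100:s + ins])
            pairs.append((f"p{i}", r1, r2))
        pairs.append(("junk", random_dna(rng, 100), random_dna(rng, 100)))
        results = [align_pair(n, a, b, idx, CFG) for n, a, b in pairs]
        by_cat = collections.Counter(r.category for r in results)
        assert sum(by_cat.values()) == len(pairs)
        n_records = sum(2 for r in results)
        assert n_records == 2 * len(pairs)

    def test_step_monotonicity(self, pe_genome):
        """A pair resolvable at step 1 resolves at step 1."""
        genome, idx = pe_genome
        r1 = genome[20_000:20_100]
        r2 = revcomp(genome[20_350:20_450])
        assert align_pair("p", r1, r2, idx, CFG).step == 1


class TestAlignSingle:
    def test_exact_read(self, pe_genome):
        genome, idx = pe_genome
        res = align_single("s", genome[100:200], idx)
        assert (res.category, res.step) == ("gout", 1)
        assert not res.paired

    def test_gapped_read_uses_step3(self, pe_genome):
        genome, idx = pe_genome
        region = genome[15_000:15_110]
        read = region[:50] + region[58:108]  # 8 bp deletion
        res = align_single("s", read, idx)
        assert (res.category, res.step) == ("dpout", 3)
        assert "8D" in res.aln1.cigar
        assert res.aln1.pos == 15_000

    def test_unalignable(self, pe_genome):
        _, idx = pe_genome
        rng = np.random.default_rng(11)
        res = align_single("s", random_dna(rng, 100), idx)
        assert (res.category, res.status) == ("unpair", "unaligned")
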