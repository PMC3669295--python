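"""Read simulator statistics and the 50 bp correctness evaluator."""

import pytest
from scipy import stats

from bwtdp.mapq_output import Alignment, sam_header, to_sam_record
from bwtdp.simeval import SimulationParams, evaluate, simulate


class TestSimulate:
    def test_deterministic_for_seed(self):
        a = simulate(SimulationParams(genome_length=5000, n_pairs=50, seed=42))
        b = simulate(SimulationParams(genome_length=5000, n_pairs=50, seed=42))
        assert a.reference == b.reference
        assert a.pairs == b.pairs
        assert a.truth.equals(b.truth)

    def test_snp_count_within_binomial_interval(self):
        # indel_rate 0 keeps coordinates aligned so SNPs can be counted
        # positionally against the central 99.9% interval of Bin(L, rate)
        params = SimulationParams(genome_length=100_000, n_pairs=1, seed=1,
                                  indel_rate=0.0)
        sim = simulate(params)
        ref = sim.reference["chrS"]
        lo, hi = stats.binom.interval(0.999, 100_000, params.snp_rate)
        for hap in sim.haplotypes:
            snps = sum(a != b for a, b in zip(ref, hap))
            assert lo <= snps <= hi

    def test_null_rates_give_exact_substrings(self):
        params = SimulationParams(genome_length=20_000, n_pairs=100, seed=7,
                                  snp_rate=0.0, indel_rate=0.0, error_rate=0.0)
        sim = simulate(params)
        ref = sim.reference["chrS"]
        truth = sim.truth.set_index(["read_id", "end"])
        from bwtdp._util import revcomp
        for name, s1, _, s2, _ in sim.pairs:
            for end, seq in ((1, s1), (2, s2)):
                row = truth.loc[(name, end)]
                expected = ref[row.position:row.position + 100]
                assert seq == (expected if row.strand == "+" else revcomp(expected))

    def test_insert_size_distribution(self):
        sim = simulate(SimulationParams(genome_length=50_000, n_pairs=500, seed=3,
                                        snp_rate=0.0, indel_rate=0.0, error_rate=0.0))
        t = sim.truth.pivot(index="read_id", columns="end", values="position")
        spans = (t[2] - t[1]).abs() + 100
        assert 490 < spans.mean() < 510
        assert 15 < spans.std() < 35

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(genome_length=50, read_length=100)


def _write_sam(path, truth, records):
    """records: (read_id, end, pos or None, strand, mapq)."""
    lines = sam_header([("chrS", 100_000)])
    for read_id, end, pos, strand, mapq in records:
        flag_pair = 0x1 | (0x40 if end == 1 else 0x80)
        if pos is None:
            lines.append(f"{read_id}\t{flag_pair | 0x4 | 0x8}\t*\t0\t0\t*\t*\t0\t0\t"
                         + "A" * 100 + "\t" + "I" * 100)
        else:
            aln = Alignment(reference="chrS", pos=pos, strand=strand,
                            cigar="100M", score=100, nm=0, mapq=mapq)
            rec = to_sam_record(read_id, "A" * 100, "I" * 100, aln,
                                paired=True, first=(end == 1))
            lines.append(rec)
    path.write_text("\n".join(lines) + "\n")


class TestEvaluate:
    def _truth(self):
        import pandas as pd
        rows = [(f"r{i}", e, "chrS", 1000 * i + e, "+") for i in range(6) for e in (1, 2)]
        return pd.DataFrame(rows, columns=["read_id", "end", "reference",
                                           "position", "strand"])

    def test_sensitivity_and_fdr_arithmetic(self, tmp_path):
        """12 simulated, 10 aligned, 9 correct -> 0.75 and 0.10."""
        truth = self._truth()
        recs = []
        for i in range(6):
            for e in (1, 2):
                if i == 5:
                    recs.append((f"r{i}", e, None, "+", 0))  # unaligned pair
                elif (i, e) == (4, 2):
                    recs.append((f"r{i}", e, 90_000, "+", 30))  # wrong locus
                else:
                    recs.append((f"r{i}", e, 1000 * i + e, "+", 60))
        sam = tmp_path / "a.sam"
        _write_sam(sam, truth, recs)
        res = evaluate(str(sam), truth)
        assert (res.n_simulated, res.n_aligned, res.n_correct) == (12, 10, 9)
        assert res.sensitivity == pytest.approx(9 / 12)
        assert res.fdr == pytest.approx(1 / 10)

    def test_tolerance_is_inclusive_at_50(self, tmp_path):
        truth = self._truth()
        recs = [("r0", 1, 1 + 50, "+", 60), ("r0", 2, 2 + 51, "+", 60)]
        sam = tmp_path / "b.sam"
        _write_sam(sam, truth.head(2), recs)
        res = evaluate(str(sam), truth.head(2))
        assert res.n_correct == 1 and res.n_aligned == 2

    def test_wrong_strand_incorrect(self, tmp_path):
        truth = self._truth().head(2)
        recs = [("r0", 1, 1, "-", 60), ("r0", 2, 2, "+", 60)]
        sam = tmp_path / "c.sam"
        _write_sam(sam, truth, recs)
        assert evaluate(str(sam), truth).n_correct == 1

    def test_all_unaligned_degenerate(self, tmp_path):
        truth = self._truth().head(2)
        recs = [("r0", 1, None, "+", 0), ("r0", 2, None, "+", 0)]
        sam = tmp_path / "d.sam"
        _write_sam(sam, truth, recs)
        res = evaluate(str(sam), truth)
        assert (res.sensitivity, res.fdr) == (0.0, 0.0)

    def test_unknown_read_id_raises(self, tmp_path):
        truth = self._truth().head(2)
        recs = [("ghost", 1, 1, "+", 60)]
        sam = tmp_path / "e.sam"
        _write_sam(sam, truth, recs)
        with pytest.raises(ValueError, match="ghost"):
            evaluate(str(sam), truth)

    def test_roc_cumulative_monotone(self, tmp_path):
        truth = self._truth()
        recs = [(f"r{i}", e, 1000 * i + e, "+", mapq)
                for i, e, mapq in [(0, 1, 60), (0, 2, 40), (1, 1, 40), (1, 2, 3),
                                   (2, 1, 0), (2, 2, 60)]]
        sam = tmp_path / "f.sam"
        _write_sam(sam, truth, recs)
        roc = evaluate(str(sam), truth).roc
        assert list(roc.mapq) == sorted(roc.mapq, reverse=True)
        assert roc.cum_correct.is_monotonic_increasing
        assert roc.cum_incorrect.is_monotonic_increasing
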