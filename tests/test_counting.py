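"""Allele counting from alignments and the heteroplasmy estimator."""

import numpy as np
import pysam
import pytest

from mitotrace.counting import (
    AlleleCountTensor,
    PileupFilters,
    compute_heteroplasmy,
    pileup_allele_counts,
)
from mitotrace.reference import MitoGenome, SnpRecord, SnpTable
from mitotrace.simulate import (
    SimConfig,
    simulate_allele_counts,
    simulate_embryo_reads,
    simulate_hybrid_genomes,
)

REF = "ACGTACGTACGTACGTACGTACGTACGTACGT"  # 32 bp toy reference


def toy_table():
    # maternal A at position 5, C at position 10 (1-based)
    return SnpTable(
        records=[
            SnpRecord(position=5, maternal_allele="A", paternal_allele="G"),
            SnpRecord(position=10, maternal_allele="C", paternal_allele="T"),
        ],
        maternal_name="chrM",
    )


def write_sam(path, reads, ref_name="chrM", ref_len=32):
    """reads: list of dicts(name, seq, pos0, mapq, cigar, flag, quals)."""
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": ref_name, "LN": ref_len}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for spec in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = spec["name"]
            a.query_sequence = spec["seq"]
            a.flag = spec.get("flag", 0)
            a.reference_id = 0
            a.reference_start = spec["pos0"]
            a.mapping_quality = spec.get("mapq", 60)
            a.cigarstring = spec.get("cigar", f"{len(spec['seq'])}M")
            quals = spec.get("quals", [40] * len(spec["seq"]))
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            )
            out.write(a)


class TestPileup:
    def test_clean_maternal_reads_count_fully(self, tmp_path):
        sam = tmp_path / "e.sam"
        write_sam(sam, [dict(name=f"r{i}", seq=REF[2:12], pos0=2) for i in range(10)])
        tensor = pileup_allele_counts({"e": sam}, toy_table(), PileupFilters())
        # position 5 is ref A (index 0), position 10 ref C (index 1)
        assert tensor.counts[0, 0].tolist() == [10, 0, 0, 0]
        assert tensor.counts[0, 1].tolist() == [0, 10, 0, 0]

    def test_low_mapping_quality_read_excluded_everywhere(self, tmp_path):
        sam = tmp_path / "e.sam"
        write_sam(sam, [dict(name="good", seq=REF[2:12], pos0=2),
                        dict(name="bad", seq=REF[2:12], pos0=2, mapq=10)])
        tensor = pileup_allele_counts({"e": sam}, toy_table(), PileupFilters())
        assert tensor.depth[0].tolist() == [1, 1]

    def test_low_base_quality_site_excluded(self, tmp_path):
        sam = tmp_path / "e.sam"
        quals = [40] * 10
        quals[2] = 5  # query offset of reference position 5 for pos0=2
        write_sam(sam, [dict(name="r", seq=REF[2:12], pos0=2, quals=quals)])
        tensor = pileup_allele_counts({"e": sam}, toy_table(), PileupFilters())
        assert tensor.depth[0].tolist() == [0, 1]

    def test_deletion_at_site_contributes_nothing(self, tmp_path):
        sam = tmp_path / "e.sam"
        # read spans 2..12 but deletes reference position 5 (0-based 4)
        seq = REF[2:4] + REF[5:12]
        write_sam(sam, [dict(name="r", seq=seq, pos0=2, cigar="2M1D7M")])
        tensor = pileup_allele_counts({"e": sam}, toy_table(), PileupFilters())
        assert tensor.depth[0].tolist() == [0, 1]

    def test_duplicates_skipped_unless_requested(self, tmp_path):
        sam = tmp_path / "e.sam"
        write_sam(sam, [dict(name="r1", seq=REF[2:12], pos0=2),
                        dict(name="r2", seq=REF[2:12], pos0=2, flag=0x400)])
        assert pileup_allele_counts({"e": sam}, toy_table(), PileupFilters()).depth[0, 0] == 1
        keep = PileupFilters(count_duplicates=True)
        assert pileup_allele_counts({"e": sam}, toy_table(), keep).depth[0, 0] == 2

    def test_overlapping_mates_count_once(self, tmp_path):
        sam = tmp_path / "e.sam"
        write_sam(sam, [dict(name="frag", seq=REF[2:12], pos0=2, flag=0x43),
                        dict(name="frag", seq=REF[2:12], pos0=2, flag=0x83)])
        tensor = pileup_allele_counts({"e": sam}, toy_table(), PileupFilters())
        assert tensor.depth[0].tolist() == [1, 1]

    def test_reference_mismatch_is_hard_error(self, tmp_path):
        sam = tmp_path / "e.sam"
        write_sam(sam, [dict(name="r", seq=REF[2:12], pos0=2)])
        wrong = MitoGenome("chrM", REF + "AAAA", circular=False)
        with pytest.raises(ValueError, match="length"):
            pileup_allele_counts({"e": sam}, toy_table(), PileupFilters(), genome=wrong)
        other = MitoGenome("chr1", REF, circular=False)
        with pytest.raises(ValueError, match="references"):
            pileup_allele_counts({"e": sam}, toy_table(), PileupFilters(), genome=other)

    def test_simulated_counts_match_truth_at_zero_error(self, tmp_path):
        cfg = SimConfig(seed=3, genome_length=4000, n_snps=30, mean_depth=40,
                        error_rate=0.0, embryo_cv=0.0, read_length=60)
        maternal, paternal, truth, ann = simulate_hybrid_genomes(cfg)
        paths, sim_truth = simulate_embryo_reads(
            cfg, maternal, paternal, ann, tmp_path, groups={"LFD": 1}
        )
        filters = PileupFilters(min_site_coverage=1)
        tensor = pileup_allele_counts(paths, truth, filters, genome=maternal)
        # every base observed at a SNP is one of the two parental alleles
        mat_idx = np.array(["ACGT".index(a) for a in truth.maternal_alleles])
        pat_idx = np.array(["ACGT".index(a) for a in truth.paternal_alleles])
        parental = (
            tensor.counts[0, np.arange(len(truth)), mat_idx]
            + tensor.counts[0, np.arange(len(truth)), pat_idx]
        )
        assert (parental == tensor.depth[0]).all()
        # pooled paternal read fraction near the simulated embryo fraction
        frac = sim_truth.feature_paternal_fraction[tensor.embryo_ids[0]]
        pat_total = tensor.counts[0, np.arange(len(truth)), pat_idx].sum()
        depth_total = tensor.depth[0].sum()
        p_bar = np.mean(list(frac.values()))
        se = np.sqrt(p_bar * (1 - p_bar) / depth_total)
        assert abs(pat_total / depth_total - p_bar) < 4 * se + 0.01


class TestHeteroplasmy:
    def _tensor(self, a=0, c=0, g=0, t=0):
        counts = np.zeros((1, 2, 4), dtype=np.int64)
        counts[0, 0] = [a, c, g, t]
        counts[0, 1] = [a, c, g, t]
        return AlleleCountTensor(["e"], np.array([5, 10]), counts)

    def test_pure_maternal_gives_zero(self):
        het = compute_heteroplasmy(self._tensor(a=100), toy_table())
        assert het.values[0, 0] == 0.0

    def test_eighty_twenty_gives_point_two(self):
        counts = np.zeros((1, 2, 4), dtype=np.int64)
        counts[0, 0] = [80, 0, 20, 0]  # maternal A=80, paternal G=20
        counts[0, 1] = [0, 80, 0, 20]
        het = compute_heteroplasmy(AlleleCountTensor(["e"], np.array([5, 10]), counts),
                                   toy_table())
        assert het.values[0, 0] == pytest.approx(0.2)
        assert het.values[0, 1] == pytest.approx(0.2)

    def test_third_allele_counts_in_denominator(self):
        counts = np.zeros((1, 2, 4), dtype=np.int64)
        counts[0, 0] = [90, 10, 0, 0]  # C is neither parental allele at snp 1
        counts[0, 1] = [0, 100, 0, 0]
        het = compute_heteroplasmy(AlleleCountTensor(["e"], np.array([5, 10]), counts),
                                   toy_table())
        assert het.values[0, 0] == pytest.approx(0.1)

    def test_low_depth_masked(self):
        het = compute_heteroplasmy(self._tensor(a=5), toy_table(),
                                   PileupFilters(min_site_coverage=20))
        assert het.mask[0, 0]
        het2 = compute_heteroplasmy(self._tensor(a=20), toy_table(),
                                    PileupFilters(min_site_coverage=20))
        assert not het2.mask[0, 0]

    def test_position_mismatch_rejected(self):
        tensor = AlleleCountTensor(["e"], np.array([5, 11]),
                                   np.zeros((1, 2, 4), dtype=np.int64))
        with pytest.raises(ValueError):
            compute_heteroplasmy(tensor, toy_table())

    def test_unmasked_values_bounded(self):
        cfg = SimConfig(seed=9, n_snps=50, genome_length=4000, mean_depth=100)
        _, _, truth, _ = simulate_hybrid_genomes(cfg)
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, size=(5, 50))
        tensor = simulate_allele_counts(cfg, truth, p, rng)
        het = compute_heteroplasmy(tensor, truth)
        vals = het.values[~het.mask]
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_error_only_inflation_bounded_by_rate(self):
        """With true paternal fraction 0, expected heteroplasmy equals the
        substitution error rate; the empirical mean stays within 3 SE."""
        e = 0.005
        cfg = SimConfig(seed=21, n_snps=100, genome_length=4000,
                        mean_depth=200, error_rate=e)
        _, _, truth, _ = simulate_hybrid_genomes(cfg)
        rng = np.random.default_rng(1)
        tensor = simulate_allele_counts(cfg, truth, np.zeros((10, 100)), rng)
        het = compute_heteroplasmy(tensor, truth)
        total_depth = het.coverage.sum()
        se = np.sqrt(e * (1 - e) / total_depth)
        mean = np.average(het.values[~het.mask], weights=het.coverage[~het.mask])
        assert abs(mean - e) < 3 * se

    @pytest.mark.parametrize("p", [0.01, 0.05, 0.2])
    def test_parameter_recovery(self, p):
        cfg = SimConfig(seed=int(p * 1000), n_snps=100, genome_length=4000,
                        mean_depth=500, error_rate=0.0)
        _, _, truth, _ = simulate_hybrid_genomes(cfg)
        rng = np.random.default_rng(int(p * 1000))
        tensor = simulate_allele_counts(cfg, truth, np.full((1, 100), p), rng)
        het = compute_heteroplasmy(tensor, truth)
        mean = np.average(het.values[0], weights=het.coverage[0])
        se = np.sqrt(p * (1 - p) / het.coverage.sum())
        assert abs(mean - p) < 3 * se
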