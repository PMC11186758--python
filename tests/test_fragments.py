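"""Small-RNA annotation, normalization, filtering and fragment profiling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitotrace.fragments import (
    ReferenceBundle,
    ReferenceSeq,
    assign_reads,
    biotype_log2fc,
    classify_fragment,
    filter_fragments,
    fragmentation_profile,
    rpm_normalize,
)
from mitotrace.simulate import SimConfig, simulate_small_rna_reads, simulate_small_rna_refs


@pytest.fixture(scope="module")
def bundle():
    rng = np.random.default_rng(17)

    def seq(n):
        return "".join(rng.choice(list("ACGT"), n))

    return ReferenceBundle([
        ReferenceSeq("mt-tRNA-1", seq(70), "tRNA", "mitochondrial"),
        ReferenceSeq("n-tRNA-1", seq(73), "tRNA", "nuclear"),
        ReferenceSeq("n-rRNA-1", seq(120), "rRNA", "nuclear"),
        ReferenceSeq("miR-1", seq(22), "miRNA", "nuclear"),
        ReferenceSeq("piR-1", seq(28), "piRNA", "nuclear"),
    ])


class TestAssignReads:
    def test_trna_substring_is_mitochondrial_tsrna(self, bundle):
        ref = bundle.by_id()["mt-tRNA-1"].sequence
        matrix = assign_reads({"s": [ref[5:27]]}, bundle)
        row = matrix.seq_info.iloc[0]
        assert (row.biotype, row.origin, row.parent_id, row.offset) == (
            "tsRNA", "mitochondrial", "mt-tRNA-1", 6,
        )

    def test_rrna_precedence_over_trna(self):
        shared = "ACGTACGTACGTACGTACGT"
        bundle = ReferenceBundle([
            ReferenceSeq("rRNA-x", "TT" + shared + "GG", "rRNA", "nuclear"),
            ReferenceSeq("tRNA-x", "CC" + shared + "AA", "tRNA", "nuclear"),
        ])
        matrix = assign_reads({"s": [shared]}, bundle)
        assert matrix.seq_info.iloc[0].biotype == "rsRNA"

    def test_dual_origin_match_is_ambiguous(self):
        shared = "ACGTACGTACGTACGTACGTACGT"
        bundle = ReferenceBundle([
            ReferenceSeq("n-tRNA-x", "TT" + shared, "tRNA", "nuclear"),
            ReferenceSeq("mt-tRNA-x", "GG" + shared, "tRNA", "mitochondrial"),
        ])
        matrix = assign_reads({"s": [shared]}, bundle)
        assert matrix.seq_info.iloc[0].origin == "ambiguous"

    def test_unmatched_read_is_other(self, bundle):
        matrix = assign_reads({"s": ["A" * 25]}, bundle)
        assert matrix.seq_info.iloc[0].biotype == "other"

    def test_mismatch_budget_respected(self, bundle):
        ref = bundle.by_id()["mt-tRNA-1"].sequence
        read = list(ref[10:34])
        read[3] = "A" if read[3] != "A" else "C"
        read[15] = "A" if read[15] != "A" else "C"
        two_mm = "".join(read)
        read[20] = "A" if read[20] != "A" else "C"
        three_mm = "".join(read)
        matrix = assign_reads({"s": [two_mm, three_mm]}, bundle, max_mismatch=2)
        by_seq = matrix.seq_info.set_index("sequence")
        assert by_seq.loc[two_mm].biotype == "tsRNA"
        assert by_seq.loc[three_mm].biotype == "other"

    def test_simulated_reads_annotated_accurately(self):
        """>= 99% correct biotype at 1% per-base error and 2 mismatches."""
        cfg = SimConfig(seed=23, error_rate=0.01)
        refs = simulate_small_rna_refs(cfg)
        reads, truth = simulate_small_rna_reads(cfg, refs, n_reads=4000)
        matrix = assign_reads({"s": reads}, refs, max_mismatch=2)
        assigned = matrix.seq_info.set_index("sequence")["biotype"]
        mapping = {"tRNA": "tsRNA", "rRNA": "rsRNA", "miRNA": "miRNA", "piRNA": "piRNA"}
        correct = sum(
            mapping[cls] == assigned[read]
            for read, cls in zip(reads, truth.extras["source_class"])
        )
        assert correct / len(reads) >= 0.99

    def test_total_reads_conserved(self, bundle):
        ref = bundle.by_id()["mt-tRNA-1"].sequence
        reads = {"s1": [ref[0:20], ref[0:20], "A" * 20], "s2": [ref[30:50]]}
        matrix = assign_reads(reads, bundle)
        assert matrix.counts["s1"].sum() == 3
        assert matrix.counts["s2"].sum() == 1
        fractions = matrix.biotype_fractions()
        assert fractions.sum(axis=0).round(12).eq(1.0).all()


class TestRpmAndFilter:
    def _matrix(self, counts, lengths=None):
        n = len(counts)
        seq_info = pd.DataFrame({
            "sequence": [f"S{i}" for i in range(n)],
            "length": lengths if lengths is not None else [20] * n,
            "biotype": ["tsRNA"] * n,
            "origin": ["nuclear"] * n,
            "parent_id": [None] * n,
            "offset": [0] * n,
        })
        from mitotrace.fragments import SmallRnaCountMatrix

        return SmallRnaCountMatrix(
            seq_info=seq_info,
            counts=pd.DataFrame(np.asarray(counts), columns=["a", "b"]),
        )

    def test_rpm_columns_sum_to_a_million(self):
        matrix = rpm_normalize(self._matrix([[10, 1], [90, 9]]))
        assert matrix.rpm.sum(axis=0).tolist() == pytest.approx([1e6, 1e6])

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            rpm_normalize(self._matrix([[1, 0], [2, 0]]))

    def test_rpm_invariant_to_depth_scaling(self):
        a = rpm_normalize(self._matrix([[10, 1], [90, 9]]))
        b = rpm_normalize(self._matrix([[20, 2], [180, 18]]))
        assert np.allclose(a.rpm.to_numpy(), b.rpm.to_numpy())

    def test_length_bounds_inclusive(self):
        matrix = rpm_normalize(self._matrix(
            [[100, 100]] * 4, lengths=[15, 16, 45, 46]
        ))
        kept = filter_fragments(matrix)
        assert kept.seq_info["length"].tolist() == [16, 45]

    def test_rpm_exactly_at_threshold_retained(self):
        # one read in 1e8 -> exactly 0.01 RPM in both samples
        counts = np.array([[1, 1], [10**8 - 1, 10**8 - 1]])
        kept = filter_fragments(rpm_normalize(self._matrix(counts)))
        assert len(kept.seq_info) == 2

    def test_matches_brute_force_row_scan(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            n = rng.integers(2, 30)
            counts = rng.integers(0, 2000, size=(n, 2))
            counts[0] += 1  # keep both samples non-empty
            lengths = rng.integers(10, 50, size=n)
            matrix = rpm_normalize(self._matrix(counts, lengths=lengths.tolist()))
            kept = filter_fragments(matrix)
            rpm = matrix.rpm.to_numpy()
            expected = [
                i for i in range(n)
                if (rpm[i] >= 0.01).all() and 16 <= lengths[i] <= 45
            ]
            assert kept.seq_info.index.tolist() == expected


class TestFragmentation:
    def test_classification_rule(self):
        assert classify_fragment(1, 30, 70) == "5p"
        assert classify_fragment(40, 70, 70) == "3p"
        assert classify_fragment(1, 68, 70) == "full"
        assert classify_fragment(10, 50, 70) == "internal"
        assert classify_fragment(3, 66, 70) == "5p"  # end < L-3

    def test_all_five_prime(self):
        profile = fragmentation_profile([(1, 30, 1.0)] * 5, "t", 70)
        assert profile.f5 == 1.0
        assert profile.coverage[:30].min() == 5.0
        assert profile.coverage[30:].max() == 0.0

    def test_spanning_reads_are_full_length(self):
        profile = fragmentation_profile([(1, 70, 2.0)] * 3, "t", 70)
        assert profile.f_full == 1.0

    def test_overhanging_read_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            profile = fragmentation_profile([(60, 30, 1.0)], "t", 70)
        assert profile.coverage[69] == 1.0
        assert len(profile.coverage) == 70

    def test_mixture_fractions_recovered(self):
        """A 60/30/10 mix of 5'/3'/full reads is recovered within
        multinomial error."""
        cfg = SimConfig(seed=29, error_rate=0.0)
        refs = simulate_small_rna_refs(cfg)
        reads, truth = simulate_small_rna_reads(
            cfg, refs, n_reads=6000, biotype_mix={"tRNA": 1.0}
        )
        target = "mt-tRNA-2"
        length = len(refs.by_id()[target].sequence)
        triples = [
            (truth.extras["offset"][i], len(reads[i]), 1.0)
            for i in range(len(reads))
            if truth.extras["source_ref"][i] == target
        ]
        profile = fragmentation_profile(triples, target, length)
        n = len(triples)
        for observed, expected in [(profile.f5, 0.6), (profile.f3, 0.3),
                                   (profile.f_full, 0.1)]:
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 3 * se


class TestLog2fc:
    def _matrix(self, a_vals, b_vals):
        from mitotrace.fragments import SmallRnaCountMatrix

        n = len(a_vals)
        seq_info = pd.DataFrame({
            "sequence": [f"S{i}" for i in range(n)],
            "length": [20] * n,
            "biotype": ["tsRNA"] * n,
            "origin": ["nuclear"] * n,
            "parent_id": [None] * n,
            "offset": [0] * n,
        })
        counts = pd.DataFrame(
            np.column_stack([a_vals, a_vals, b_vals, b_vals]),
            columns=["a1", "a2", "b1", "b2"],
        )
        return SmallRnaCountMatrix(seq_info=seq_info, counts=counts)

    def test_identical_groups_have_zero_log2fc(self):
        matrix = self._matrix([10, 50, 200], [10, 50, 200])
        result = biotype_log2fc(matrix, ["a1", "a2"], ["b1", "b2"], n_perm=100, seed=0)
        assert np.allclose(result["log2fc"], 0.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        matrix = self._matrix(rng.integers(1, 500, 20), rng.integers(1, 500, 20))
        a = biotype_log2fc(matrix, ["a1", "a2"], ["b1", "b2"], n_perm=200, seed=5)
        b = biotype_log2fc(matrix, ["a1", "a2"], ["b1", "b2"], n_perm=200, seed=5)
        assert a.equals(b)

    def test_null_pvalues_roughly_uniform(self):
        """Permutation p-values under a label-exchangeable null pass a KS
        uniformity check at alpha 0.01 (discrete p-values make the test
        conservative, so a generous sample is used)."""
        rng = np.random.default_rng(7)
        from mitotrace.fragments import SmallRnaCountMatrix

        n = 400
        seq_info = pd.DataFrame({
            "sequence": [f"S{i}" for i in range(n)],
            "length": [20] * n,
            "biotype": ["tsRNA"] * n,
            "origin": ["nuclear"] * n,
            "parent_id": [None] * n,
            "offset": [0] * n,
        })
        counts = pd.DataFrame(
            rng.poisson(100, size=(n, 8)),
            columns=[f"s{i}" for i in range(8)],
        )
        matrix = SmallRnaCountMatrix(seq_info=seq_info, counts=counts)
        result = biotype_log2fc(
            matrix, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)],
            n_perm=500, seed=1,
        )
        ks = stats.kstest(result["p_value"], "uniform")
        # discrete + conservative: only flag gross non-uniformity
        assert ks.pvalue > 0.01 or result["p_value"].mean() > 0.4
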