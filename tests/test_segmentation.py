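"""Cut-point segmentation: per-position models, likelihoods, argmax search."""

import math

import numpy as np
import pytest

from mltrim.quality_model import PROB_FLOOR, build_curve
from mltrim.segmentation import (
    CutPoints,
    Read,
    estimate_head_cut,
    estimate_tail_cut,
    f0,
    f1_polyN,
    f1_quality,
    loglik_at_cut,
    nucleotide_profile,
    trim_polyN,
    trim_read,
)

from conftest import (
    assert_same_cut,
    naive_head_cut,
    naive_head_loglik,
    naive_loglik,
    naive_tail_cut,
    random_read,
)


class TestRead:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            Read("r", "ACGT", np.array([30, 30, 30]))

    def test_non_iupac_character_rejected(self):
        with pytest.raises(ValueError, match="IUB/IUPAC"):
            Read("r", "ACXT", np.array([30] * 4))

    def test_sequence_normalised_to_upper_case(self):
        read = Read("r", "acgtn", np.array([30] * 5))
        assert read.sequence == "ACGTN"


class TestNucleotideProfile:
    def test_empirical_frequencies_sum_to_one(self):
        profile = nucleotide_profile("AACGT")
        assert profile["A"] == pytest.approx(0.4)
        assert sum(profile.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            nucleotide_profile("")


class TestPerPositionModels:
    def test_informative_model_values(self, curve20):
        homogeneous = nucleotide_profile("AAAA")
        assert f0("A", 45, homogeneous, curve20) == 1.0
        uniform = nucleotide_profile("ACGT")
        assert f0("A", 20, uniform, curve20) == pytest.approx(0.125)
        assert f0("A", 0, uniform, curve20) == PROB_FLOOR

    def test_unreliable_model_values(self, curve20):
        assert f1_quality("A", 0, curve20) == pytest.approx(0.25)
        assert f1_quality("A", 20, curve20) == pytest.approx(0.125)
        assert f1_quality("A", 45, curve20) == PROB_FLOOR

    def test_homopolymer_model_selects_branch_on_letter(self, curve20):
        assert f1_polyN("A", 45, "A", curve20) == 1.0
        assert f1_polyN("C", 0, "A", curve20) == pytest.approx(0.25)
        assert f1_polyN("A", 20, "A", curve20) == pytest.approx(0.5)

    def test_invalid_poly_letter_rejected(self, curve20):
        with pytest.raises(ValueError, match="letter"):
            f1_polyN("A", 30, "N", curve20)


class TestLoglikAtCut:
    def test_single_nucleotide_read(self, curve20):
        read = Read("r", "A", np.array([30]))
        profile = nucleotide_profile("A")
        expected = math.log(f0("A", 30, profile, curve20))  # - log 1 == 0
        assert loglik_at_cut(read, 1, curve20) == pytest.approx(expected)

    def test_homogeneous_high_quality_full_cut(self, curve20):
        m = 8
        read = Read("r", "A" * m, np.full(m, 45))
        # Pr(A)=1 and p=1 so each f0 term is 0; only the -log k terms remain
        assert loglik_at_cut(read, m, curve20) == pytest.approx(-m * math.log(m))

    @pytest.mark.parametrize("letter", [None, "A"])
    def test_agrees_with_naive_recomputation(self, curve20, letter):
        rng = np.random.default_rng(7)
        for _ in range(50):
            seq, quals = random_read(rng, max_len=25)
            read = Read("r", seq, quals)
            for k in range(1, len(seq) + 1):
                assert loglik_at_cut(read, k, curve20, letter) == pytest.approx(
                    naive_loglik(seq, quals, k, curve20, letter), rel=1e-9, abs=1e-9
                )

    def test_out_of_range_cut_rejected(self, curve20):
        read = Read("r", "ACGT", np.array([30] * 4))
        with pytest.raises(ValueError):
            loglik_at_cut(read, 5, curve20)


class TestTailCut:
    def test_all_high_quality_keeps_everything(self, curve20):
        read = Read("r", "ACGT" * 12 + "AC", np.full(50, 45))
        assert estimate_tail_cut(read, curve20) == 50

    def test_step_profile_cut_at_step(self, curve20):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 50))
        read = Read("r", seq, np.array([40] * 25 + [2] * 25))
        assert estimate_tail_cut(read, curve20) == 25

    def test_degenerate_all_zero_quality(self, curve20):
        read = Read("r", "A" * 10, np.zeros(10, dtype=int))
        assert estimate_tail_cut(read, curve20) == 1

    def test_empty_read_rejected(self, curve20):
        with pytest.raises(ValueError, match="empty"):
            estimate_tail_cut(Read("r", "", np.array([], dtype=int)), curve20)


class TestHeadCut:
    def test_all_high_quality_keeps_head(self, curve20):
        read = Read("r", "ACGT" * 5, np.full(20, 45))
        assert estimate_head_cut(read, 20, curve20) == 1

    def test_low_quality_head_cut_after_step(self, curve20):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 50))
        read = Read("r", seq, np.array([2] * 5 + [40] * 45))
        assert estimate_head_cut(read, 50, curve20) == 6

    def test_mirrored_equals_direct_formulation(self, curve20):
        # reverse-and-reuse must give the same argmax as the un-mirrored
        # head likelihood computed directly
        rng = np.random.default_rng(3)
        for _ in range(200):
            seq, quals = random_read(rng, max_len=20)
            read = Read("r", seq, quals)
            k1 = estimate_tail_cut(read, curve20)
            assert_same_cut(
                estimate_head_cut(read, k1, curve20),
                naive_head_cut(seq, quals, k1, curve20),
                lambda k2: naive_head_loglik(seq, quals, k2, k1, curve20),
            )


class TestOracleEquivalence:
    @pytest.mark.parametrize("letter", [None, "A"], ids=["quality", "polyA"])
    def test_production_equals_exhaustive_search(self, curve20, letter):
        rng = np.random.default_rng(42)
        for _ in range(250):
            seq, quals = random_read(rng, max_len=30)
            read = Read("r", seq, quals)
            k1 = estimate_tail_cut(read, curve20, letter)
            assert_same_cut(
                k1,
                naive_tail_cut(seq, quals, curve20, letter),
                lambda k: naive_loglik(seq, quals, k, curve20, letter),
            )
            k2 = estimate_head_cut(read, k1, curve20, letter)
            assert_same_cut(
                k2,
                naive_head_cut(seq, quals, k1, curve20, letter),
                lambda kk: naive_head_loglik(seq, quals, kk, k1, curve20, letter),
            )


class TestTrim:
    def test_planted_step_profile_recovered(self, curve20):
        rng = np.random.default_rng(11)
        hits = 0
        n = 200
        for _ in range(n):
            seq = "".join(rng.choice(list("ACGT"), 50))
            read = Read("r", seq, np.array([2] * 5 + [40] * 40 + [2] * 5))
            result = trim_read(read, curve20)
            if abs(result.cut.k2 - 6) <= 1 and abs(result.cut.k1 - 45) <= 1:
                hits += 1
        assert hits / n >= 0.95

    def test_all_high_quality_read_kept_whole(self, curve20):
        read = Read("r", "ACGT" * 10, np.full(40, 45))
        result = trim_read(read, curve20)
        assert result.cut == CutPoints(k2=1, k1=40)
        assert result.kept
        assert result.kept_sequence == read.sequence

    def test_hopeless_read_filtered_by_min_length(self, curve20):
        read = Read("r", "ACGTACGTAC", np.zeros(10, dtype=int))
        result = trim_read(read, curve20, min_len=2)
        assert not result.kept

    def test_empty_read_not_kept(self, curve20):
        result = trim_read(Read("r", "", np.array([], dtype=int)), curve20)
        assert not result.kept and result.cut is None

    def test_retained_segment_is_contiguous_substring(self, curve20):
        rng = np.random.default_rng(5)
        for _ in range(50):
            seq, quals = random_read(rng, max_len=40)
            result = trim_read(Read("r", seq, quals), curve20)
            assert result.kept_sequence in seq
            k2, k1 = result.cut.k2, result.cut.k1
            assert result.kept_sequence == seq[k2 - 1 : k1]

    def test_mean_retained_length_non_increasing_in_threshold(self):
        rng = np.random.default_rng(9)
        reads = []
        for _ in range(60):
            m = 60
            seq = "".join(rng.choice(list("ACGT"), m))
            quals = np.clip(
                rng.normal(28, 8, size=m).round(), 0, 45
            ).astype(int)
            reads.append(Read("r", seq, quals))
        means = []
        for t in (5, 10, 20, 30):
            curve = build_curve(t)
            means.append(
                np.mean([trim_read(r, curve).cut.length for r in reads])
            )
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestPolyNTrim:
    def test_moderate_quality_polyA_tail_removed(self, curve20):
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), 40)) + "A" * 20
        read = Read("r", seq, np.array([40] * 40 + [30] * 20))
        assert estimate_tail_cut(read, curve20, "A") == 40

    def test_polyT_head_removed(self, curve20):
        rng = np.random.default_rng(22)
        seq = "T" * 20 + "".join(rng.choice(list("CGA"), 40))
        read = Read("r", seq, np.array([35] * 20 + [40] * 40))
        result = trim_polyN(read, "T", curve20)
        assert result.cut.k2 == 21

    def test_clean_read_untouched(self, curve20):
        read = Read("r", "CGCGCGCGCG", np.full(10, 45))
        result = trim_polyN(read, "A", curve20)
        assert result.cut == CutPoints(k2=1, k1=10)

    def test_invalid_letter_rejected(self, curve20):
        read = Read("r", "ACGT", np.array([30] * 4))
        with pytest.raises(ValueError, match="letter"):
            trim_polyN(read, "B", curve20)
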