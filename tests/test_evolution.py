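import math

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from promkit.evolution import (
    SENSE_CODONS,
    CodonPair,
    SaturationError,
    align_global,
    codon_site_counts,
    jukes_cantor,
    nei_gojobori,
    pairwise_codon_differences,
    promoter_distance,
    rate_correlation,
    selection_z_test,
)
from promkit.simulate import simulate_divergent_pair


class TestCodonSiteCounts:
    @pytest.mark.parametrize(
        "codon,syn,nonsyn",
        [("TTT", 1 / 3, 8 / 3), ("GGG", 1.0, 2.0), ("TGG", 0.0, 3.0)],
    )
    def test_worked_codons(self, codon, syn, nonsyn):
        s, n = codon_site_counts(codon)
        assert s == pytest.approx(syn)
        assert n == pytest.approx(nonsyn)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_site_counts("TAA")

    @pytest.mark.parametrize("policy", ["nonsynonymous", "excluded"])
    def test_sites_sum_to_three_for_all_sense_codons(self, policy):
        """Independent route: classify each single-nucleotide change by
        Biopython translation and compare the per-codon site counts."""
        for codon in SENSE_CODONS:
            syn = 0.0
            for pos in range(3):
                s_pos = 0
                considered = 0
                for b in "ACGT":
                    if b == codon[pos]:
                        continue
                    mutant = codon[:pos] + b + codon[pos + 1 :]
                    aa = str(Seq(mutant).translate())
                    if aa == "*":
                        if policy == "excluded":
                            continue
                        considered += 1
                        continue
                    considered += 1
                    if aa == str(Seq(codon).translate()):
                        s_pos += 1
                syn += s_pos / considered if considered else 0.0
            got_s, got_n = codon_site_counts(codon, policy)
            assert got_s == pytest.approx(syn)
            assert got_s + got_n == pytest.approx(3.0)


class TestPairwiseDifferences:
    def test_identical_pair_has_no_differences(self):
        pair = CodonPair("TTTGGG", "TTTGGG")
        sd, nd, s, n = pairwise_codon_differences(pair)
        assert (sd, nd) == (0.0, 0.0)

    def test_ten_codon_synonymous_example(self):
        a = "TTT" * 10
        b = "TTT" * 9 + "TTC"
        sd, nd, s, n = pairwise_codon_differences(CodonPair(a, b))
        assert (sd, nd) == (1.0, 0.0)
        assert s == pytest.approx(10 / 3)
        assert n == pytest.approx(80 / 3)

    def test_two_difference_pathway_average(self):
        # TTT->CTT(nonsyn)->CTC(syn) and TTT->TTC(syn)->CTC(nonsyn)
        sd, nd, _, _ = pairwise_codon_differences(CodonPair("TTT", "CTC"))
        assert sd == pytest.approx(1.0)
        assert nd == pytest.approx(1.0)

    def test_gapped_codons_are_skipped(self):
        pair = CodonPair("TTT---", "TTTGGG")
        sd, nd, s, n = pairwise_codon_differences(pair)
        assert s == pytest.approx(1 / 3)

    def test_symmetry_in_sequence_order(self, rng):
        (a, b), _ = simulate_divergent_pair(n_codons=100, omega=0.5, seed=9)
        fwd = pairwise_codon_differences(CodonPair(a, b))
        rev = pairwise_codon_differences(CodonPair(b, a))
        assert fwd == pytest.approx(rev)


class TestJukesCantor:
    def test_zero_distance(self):
        assert jukes_cantor(0.0) == 0.0

    def test_known_value(self):
        assert jukes_cantor(0.3) == pytest.approx(0.3831, abs=1e-4)

    def test_saturation_rejected(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.75)

    def test_monotone_and_above_argument(self):
        grid = np.linspace(0.0, 0.74, 500)
        d = np.array([jukes_cantor(p) for p in grid])
        assert (np.diff(d) > 0).all()
        assert (d >= grid).all()


class TestNeiGojobori:
    def test_identical_pair_rates_are_zero(self):
        rates = nei_gojobori(CodonPair("TTTGGG", "TTTGGG"))
        assert rates.dN == 0.0 and rates.dS == 0.0
        assert math.isnan(rates.omega)

    def test_composition_of_worked_example(self):
        a = "TTT" * 10
        b = "TTT" * 9 + "TTC"
        rates = nei_gojobori(CodonPair(a, b))
        assert rates.dS == pytest.approx(jukes_cantor(0.3))
        assert rates.dN == 0.0
        assert rates.omega == 0.0

    def test_purifying_selection_recovered_from_simulation(self):
        (a, b), truth = simulate_divergent_pair(
            n_codons=2000, omega=0.2, t_expected_subs_per_codon=0.2, seed=17
        )
        rates = nei_gojobori(CodonPair(a, b))
        assert 0.1 < rates.omega < 0.35

    def test_omega_error_shrinks_with_length(self):
        errors = []
        for n_codons in (200, 2000):
            errs = []
            for seed in range(8):
                (a, b), _ = simulate_divergent_pair(
                    n_codons=n_codons, omega=1.0, t_expected_subs_per_codon=0.3,
                    seed=seed,
                )
                errs.append(abs(nei_gojobori(CodonPair(a, b)).omega - 1.0))
            errors.append(np.median(errs))
        assert errors[1] < errors[0]


class TestSelectionZTest:
    def test_identical_pair_gives_p_one(self):
        z, p = selection_z_test(CodonPair("TTTGGGCCCAAA" * 10, "TTTGGGCCCAAA" * 10), seed=0)
        assert p == 1.0

    def test_strong_purifying_selection_detected(self):
        detected = 0
        for seed in range(5):
            (a, b), _ = simulate_divergent_pair(
                n_codons=500, omega=0.1, t_expected_subs_per_codon=0.4, seed=seed
            )
            _, p = selection_z_test(CodonPair(a, b), reps=500, seed=seed)
            detected += p < 0.05
        assert detected >= 3

    def test_too_few_codons_rejected(self):
        with pytest.raises(ValueError):
            selection_z_test(CodonPair("TTTGGG", "TTTGGG"), seed=0)


class TestPromoterDistance:
    def test_identical_pair(self):
        assert promoter_distance("A" * 100, "A" * 100) == 0.0

    def test_single_mismatch(self):
        a = "A" * 100
        b = "A" * 99 + "C"
        assert promoter_distance(a, b) == pytest.approx(0.01)

    def test_pairwise_deletion_of_gap_columns(self):
        a = "A" * 98 + "--"
        b = "C" * 2 + "A" * 96 + "AA"
        assert promoter_distance(a, b) == pytest.approx(2 / 98)

    def test_recovers_simulated_site_rate(self):
        (a, b), truth = simulate_divergent_pair(
            mode="promoter", p_site=0.1, n_sites=10_000, seed=4
        )
        se = math.sqrt(0.1 * 0.9 / 10_000)
        assert abs(promoter_distance(a, b) - 0.1) < 3 * se

    def test_all_gap_columns_rejected(self):
        with pytest.raises(ValueError):
            promoter_distance("--", "AA")


class TestAlignGlobal:
    def test_identical_sequences(self):
        a, b, score = align_global("ACGT", "ACGT")
        assert (a, b, score) == ("ACGT", "ACGT", 4)

    def test_single_gap(self):
        a, b, score = align_global("ACGT", "ACT")
        assert score == 1
        assert a == "ACGT"
        assert b.count("-") == 1

    def test_single_mismatch_beats_double_gap(self):
        a, b, score = align_global("A", "G")
        assert (a, b, score) == ("A", "G", -1)

    def test_matches_biopython_optimal_score(self, rng):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        for _ in range(20):
            x = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 30)))
            y = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 30)))
            _, _, score = align_global(x, y)
            assert score == aligner.score(x, y)


class TestRateCorrelation:
    def test_perfect_linearity(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        r, _ = rate_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_anti_linearity(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        r, _ = rate_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_three_point_example(self):
        r, _ = rate_correlation([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)

    def test_nan_pairs_dropped(self):
        x = [0.1, 0.2, 0.3, 0.4, float("nan")]
        y = [1.0, 2.0, 3.1, 3.9, 100.0]
        r, _ = rate_correlation(x, y)
        assert r > 0.99

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            rate_correlation([1, 1, 1], [1, 2, 3])
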