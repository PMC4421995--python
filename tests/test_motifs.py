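import math

import numpy as np
import pytest

import decaydet as d
from decaydet.motifs import (ALL_WORDS, M1Null, count_word, eligible_records,
                             motif_halflife_shift, motif_position_profile,
                             quartile_size, quartile_split,
                             score_exceptionality)

from oracles import count_word_in_chains, simulate_m1

_IDX = {b: i for i, b in enumerate("ACGT")}


class TestCountWord:
    def test_overlapping_occurrences(self):
        assert count_word("AAAAA", ["AAAAAAA"]) == 3
        assert count_word("AGGAG", ["AGGAGGAG"]) == 2

    def test_rna_words_normalized(self):
        assert count_word("CUGGC", ["ACTGGCA"]) == 1

    def test_search_limited_to_last_100_nt(self):
        seq = "C" * 5 + "AGGAG" + "C" * 140          # motif >100 nt upstream
        assert count_word("AGGAG", [seq]) == 0
        seq = "C" * 140 + "AGGAG" + "C" * 5          # motif within the window
        assert count_word("AGGAG", [seq]) == 1

    def test_no_counting_across_boundaries(self):
        assert count_word("AAAAA", ["AAA", "AA"]) == 0


class TestExceptionality:
    def test_uniform_m1_expected_count_closed_form(self):
        null = M1Null(np.full((4, 4), 0.25), [1028])
        for w in ("AAAAA", "AGGAG", "CTGGC"):
            assert null.expected(w) == pytest.approx((1028 - 4) / 4 ** 5)

    def test_homopolymer_set_scores_zero(self):
        # p(A|A) = 1, so the count is deterministic: E = L - 4 = observed
        # (L = 100 after truncation to the search window)
        out = score_exceptionality(["A" * 500])
        s = out["AAAAA"]
        assert s.observed == 100 - 4
        assert s.expected == pytest.approx(100 - 4)
        assert s.score == pytest.approx(0.0)

    def test_word_with_unseen_dinucleotide_flagged_unscorable(self):
        out = score_exceptionality(["ACACACAC" * 200])
        assert not out["GGGGG"].scorable

    def test_expectation_conservation_over_all_words(self, small_dataset):
        records, truth, feats, ref = small_dataset
        seqs = [u for _, u in eligible_records(records, "0.10")]
        null = M1Null.from_sequences(seqs)
        total = sum(null.expected(w) for w in ALL_WORDS)
        expected = sum(len(s) - 4 for s in seqs if len(s) >= 5)
        assert total == pytest.approx(expected, rel=1e-9)

    def test_score_sign_matches_deviation(self, small_dataset):
        records, truth, feats, ref = small_dataset
        seqs = [u for _, u in eligible_records(records, "0.10")]
        out = score_exceptionality(seqs)
        for s in out.values():
            if s.scorable and abs(s.observed - s.expected) > 1e-9:
                assert math.copysign(1, s.score) == \
                    math.copysign(1, s.observed - s.expected), s.word

    def test_moments_match_monte_carlo_oracle(self):
        """Analytic E and Var(N - E_hat) vs simulation from a fixed M1."""
        rng = np.random.default_rng(5)
        P = np.array([[.3, .2, .3, .2], [.25, .25, .25, .25],
                      [.2, .3, .2, .3], [.35, .15, .3, .2]])
        L, K = 500, 2500
        null = M1Null(P, [L])
        states = simulate_m1(P, null.mu, L, K, rng)
        dinuc = {a + b: count_word_in_chains(states, [_IDX[a], _IDX[b]])
                 for a in "ACGT" for b in "ACGT"}
        letters = {a: sum(dinuc[a + b] for b in "ACGT") for a in "ACGT"}
        zs = []
        for w in ("AAAAA", "AGGAG", "ATATA", "CTGGC"):
            N = count_word_in_chains(states, [_IDX[c] for c in w])
            e_hat = np.ones(K)
            for i in range(4):
                e_hat = e_hat * dinuc[w[i:i + 2]]
            for a in w[1:-1]:
                e_hat = e_hat / letters[a]
            T = N - e_hat
            E_an, V_an = null.expected(w), null.variance(w)
            assert N.mean() == pytest.approx(
                E_an, abs=4 * N.std(ddof=1) / math.sqrt(K)), w
            # variance SE ~ Var * sqrt(2/K); allow 4 SE plus O(1/L) boundary
            tol = 4 * T.var(ddof=1) * math.sqrt(2 / K) + 0.05 * V_an
            assert V_an == pytest.approx(T.var(ddof=1), abs=tol), w
            zs.append(T / math.sqrt(V_an))
        z = np.concatenate(zs)
        assert abs(z.mean()) < 0.1
        assert abs(z.std() - 1.0) < 0.1

    def test_empirical_null_agrees_with_gaussian_for_abundant_word(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(150)]
        gauss = score_exceptionality(seqs)
        emp = score_exceptionality(seqs, empirical_null=120, rng=rng)
        for w in ("AGGAG", "AAAAA", "CTGGC"):
            assert emp[w].score == pytest.approx(gauss[w].score, abs=1.0), w


class TestQuartiles:
    def test_quartile_size_arithmetic(self):
        assert quartile_size(1937) == 485
        assert quartile_size(100) == 25
        assert quartile_size(101) == 26

    def test_split_sets_are_disjoint_extremes(self, small_dataset):
        records, truth, feats, ref = small_dataset
        split = quartile_split(records, "0.10")
        assert not set(split.stable_ids) & set(split.unstable_ids)
        by_id = {r.gene_id: r.half_life["0.10"] for r in records}
        assert min(by_id[g] for g in split.stable_ids) >= \
            max(by_id[g] for g in split.unstable_ids)

    def test_identical_quartile_contents_give_no_differential_words(self):
        # both quartiles carry the same 5'UTR multiset -> equal scores
        utrs = ["".join(np.random.default_rng(i).choice(list("ACGT"), size=50))
                for i in range(20)]
        records = []
        for i in range(80):
            records.append(d.GeneRecord(
                f"g{i:03d}", orf_seq="ATGAAATAA", utr5_seq=utrs[i % 20],
                half_life={"0.10": float(100 - i)}))
        res = d.compare_quartiles(records, "0.10")
        for w in res["stable"]:
            s, u = res["stable"][w], res["unstable"][w]
            if s.scorable and u.scorable:
                assert s.score == pytest.approx(u.score, abs=1e-9)
        assert res["differential"] == []

    def test_too_few_eligible_genes_refused(self):
        records = [d.GeneRecord(f"g{i}", orf_seq="ATGTAA", utr5_seq="ACGTACGT",
                                half_life={"0.10": 2.0}) for i in range(10)]
        with pytest.raises(ValueError, match="eligible"):
            d.compare_quartiles(records, "0.10")

    def test_planted_motif_reported_as_differential(self):
        for seed in (0, 1, 2):
            truth = d.SyntheticTruth(
                seed=seed, motif_plant={"word": "AGGAG",
                                        "target_quartile": "stable",
                                        "plant_fraction": 0.5})
            recs, truth, feats, ref = d.generate_dataset(
                d.GenomeConfig(n_genes=1000), truth=truth, seed=seed)
            res = d.compare_quartiles(recs, "0.10")
            assert "AGGAG" in res["differential"], seed


class TestPositionProfile:
    def test_distance_conventions(self):
        recs = [d.GeneRecord("g1", orf_seq="ATGAAA", utr5_seq="CCAGGAG"),
                d.GeneRecord("g2", orf_seq="ATGAAA", utr5_seq="AGGAGNN".replace("N", "C"))]
        prof = motif_position_profile("AGGAG", recs)
        assert sorted(prof.distances) == [0, 2]

    def test_fraction_in_window(self):
        recs = [
            d.GeneRecord("g1", orf_seq="ATG", utr5_seq="AGGAG" + "C" * 2),
            d.GeneRecord("g2", orf_seq="ATG", utr5_seq="AGGAG" + "C" * 5),
            d.GeneRecord("g3", orf_seq="ATG", utr5_seq="AGGAG" + "C" * 9),
        ]
        prof = motif_position_profile("AGGAG", recs)
        assert sorted(prof.distances) == [2, 5, 9]
        assert prof.fraction_in_window(2, 8) == pytest.approx(2 / 3)

    def test_repeated_occurrences_all_counted(self):
        recs = [d.GeneRecord("g1", orf_seq="ATG", utr5_seq="AGGAGGAG")]
        prof = motif_position_profile("AGGAG", recs)
        assert sorted(prof.distances) == [0, 3]


class TestHalflifeShift:
    def test_whole_population_subpopulation_identical(self):
        records = [d.GeneRecord(f"g{i}", orf_seq="ATGTAA",
                                utr5_seq="CCCAGGAGCCC",
                                half_life={"0.10": float(i + 1)})
                   for i in range(50)]
        res = motif_halflife_shift(records, "AGGAG", "0.10")
        assert res["all"] == res["with_motif"]
        assert res["nonoverlap"] is False

    def test_absent_motif_is_an_error(self):
        records = [d.GeneRecord("g1", orf_seq="ATGTAA", utr5_seq="CCCCC",
                                half_life={"0.10": 2.0})]
        with pytest.raises(ValueError, match="absent"):
            motif_halflife_shift(records, "AGGAG", "0.10")

    def test_planted_stability_shift_separates_notches(self, rng):
        """+0.5 ln units for motif carriers at n = 1500 -> disjoint notches."""
        records = []
        for i in range(1500):
            has = i % 5 == 0
            utr = "CCAGGAGCC" if has else "CCCCTTCCC"
            ln_t = rng.normal(1.8, 0.8) + (0.5 if has else 0.0)
            records.append(d.GeneRecord(
                f"g{i:04d}", orf_seq="ATGTAA", utr5_seq=utr,
                half_life={"0.10": float(np.exp(ln_t))}))
        res = motif_halflife_shift(records, "AGGAG", "0.10")
        assert res["nonoverlap"] is True
        assert res["with_motif"].median > res["all"].median
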