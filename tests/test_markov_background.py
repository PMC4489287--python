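"""Markov background estimation and the binomial over-representation tail."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paccmit.markov_background import (
    MarkovModel,
    fit_markov,
    motif_probability,
    site_count_pvalue,
)

UNIFORM0 = fit_markov(["ACGT" * 50], order=0, pseudocount=0.0)


def uniform_model(order: int) -> MarkovModel:
    return fit_markov(["ACGT" * 200, "GTAC" * 200, "CATG" * 200, "TGCA" * 200],
                      order=order, pseudocount=1e9)  # huge pseudocount -> uniform


class TestFitMarkov:
    def test_add_one_transition_estimate(self):
        model = fit_markov(["AAAA"], order=1, pseudocount=1.0)
        # 3 A->A transitions observed
        assert model.transition_probs["A"][0] == pytest.approx(4 / 7)
        assert model.transition_probs["A"][1] == pytest.approx(1 / 7)

    def test_uniform_composition_order0(self):
        model = fit_markov(["ACGT" * 10], order=0, pseudocount=0.0)
        assert np.allclose(model.transition_probs[""], 0.25)

    def test_transition_rows_normalized(self, random_dna):
        model = fit_markov([random_dna(500) for _ in range(3)], order=2, pseudocount=1.0)
        for ctx, probs in model.transition_probs.items():
            assert np.sum(probs) == pytest.approx(1.0, abs=1e-9)
        assert sum(model.initial_probs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit_markov([], order=0)

    def test_unseen_context_with_zero_pseudocount_uniform_fallback(self):
        model = fit_markov(["AAAA"], order=1, pseudocount=0.0)
        assert np.allclose(model.transition_probs["C"], 0.25)

    def test_serialization_round_trip(self, tmp_path, random_dna):
        model = fit_markov([random_dna(300)], order=1, pseudocount=1.0)
        path = tmp_path / "model.txt"
        model.save(path)
        loaded = MarkovModel.load(path)
        assert loaded.order == model.order
        assert loaded.pseudocount == model.pseudocount
        for ctx in model.transition_probs:
            assert np.allclose(loaded.transition_probs[ctx], model.transition_probs[ctx])
        assert loaded.initial_probs == pytest.approx(model.initial_probs)


class TestMotifProbability:
    def test_uniform_seven_mer(self):
        assert motif_probability(UNIFORM0, "TTCCTGA") == pytest.approx(4.0**-7)

    def test_uniform_order1_matches_order0(self):
        m1 = uniform_model(1)
        for motif in ["TTCCTGA", "ACGTACG"]:
            assert motif_probability(m1, motif) == pytest.approx(4.0**-7, rel=1e-5)

    def test_probabilities_sum_to_one_over_all_3mers(self, random_dna):
        model = fit_markov([random_dna(400)], order=1, pseudocount=1.0)
        total = sum(
            motif_probability(model, "".join(m))
            for m in itertools.product("ACGT", repeat=3)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_strand_symmetric_model_gives_equal_rc_probability(self):
        # order-0 model with A/T and C/G balanced
        model = fit_markov(["AATTCG" * 50], order=0, pseudocount=0.0)
        rc = str.maketrans("ACGT", "TGCA")
        for motif in ["ACGTA", "TTCCTGA"]:
            assert motif_probability(model, motif) == pytest.approx(
                motif_probability(model, motif.translate(rc)[::-1])
            )

    def test_motif_shorter_than_order_rejected(self):
        model = fit_markov(["ACGTACGT"], order=2, pseudocount=1.0)
        with pytest.raises(ValueError):
            motif_probability(model, "AC")


class TestSiteCountPvalue:
    def test_zero_count_gives_one(self):
        assert site_count_pvalue(UNIFORM0, 1000, "TTCCTGA", 0).p_value == 1.0

    def test_closed_form_single_site(self):
        # P(X >= 1) = 1 - (1 - 4^-7)^994 for a 7-mer in 1000 nt
        res = site_count_pvalue(UNIFORM0, 1000, "TTCCTGA", 1)
        expected = 1.0 - (1.0 - 4.0**-7) ** 994
        assert res.positions_available == 994
        assert res.p_value == pytest.approx(expected, rel=1e-12)
        assert res.p_value == pytest.approx(0.0589, abs=5e-4)

    @given(st.integers(min_value=0, max_value=20))
    def test_monotone_nonincreasing_in_count(self, n):
        p1 = site_count_pvalue(UNIFORM0, 1000, "TTCCTGA", n).p_value
        p2 = site_count_pvalue(UNIFORM0, 1000, "TTCCTGA", n + 1).p_value
        assert p2 <= p1 <= 1.0

    def test_poisson_flag_close_to_binomial(self):
        b = site_count_pvalue(UNIFORM0, 1000, "TTCCTGA", 2).p_value
        p = site_count_pvalue(UNIFORM0, 1000, "TTCCTGA", 2, poisson=True).p_value
        assert p == pytest.approx(b, rel=0.01)

    def test_transcript_shorter_than_motif_rejected(self):
        with pytest.raises(ValueError):
            site_count_pvalue(UNIFORM0, 5, "TTCCTGA", 0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            site_count_pvalue(UNIFORM0, 1000, "TTCCTGA", -1)


def enumerate_count_distribution(letter_probs, length, motif):
    """Exact distribution of the motif-occurrence count over all 4^length
    sequences weighted by an order-0 model (the independent oracle)."""
    probs = np.asarray(letter_probs)
    bases = "ACGT"
    counts = {}
    for digits in itertools.product(range(4), repeat=length):
        seq = "".join(bases[d] for d in digits)
        w = float(np.prod(probs[list(digits)]))
        c = sum(1 for i in range(length - len(motif) + 1) if seq[i : i + len(motif)] == motif)
        counts[c] = counts.get(c, 0.0) + w
    return counts


class TestBinomialAgainstEnumeration:
    def test_tail_matches_enumeration_for_nonoverlapping_motif(self):
        probs = [0.4, 0.3, 0.2, 0.1]
        model = MarkovModel(
            order=0,
            pseudocount=0.0,
            initial_probs={"": 1.0},
            transition_probs={"": np.array(probs)},
        )
        counts = enumerate_count_distribution(probs, 8, "ACG")
        max_n = max(counts)
        for n in range(1, max_n + 1):
            true_tail = sum(w for c, w in counts.items() if c >= n)
            binom_tail = site_count_pvalue(model, 8, "ACG", n).p_value
            assert abs(binom_tail - true_tail) <= 0.02
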