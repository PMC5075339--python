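"""The ipHMM: estimation arithmetic, decoding against a brute-force
path-enumeration oracle, site calls and Fisher scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmiphmm.alphabet import AMINO_ACIDS
from cmiphmm.iphmm import (IpHMM, build_iphmm, fisher_scores,
                           forward_backward, predict_sites)
from cmiphmm.msa_io import LabeledAlignment, SiteLabel

from oracles import enumerate_path_likelihood, random_model


def single_column_alignment(residues, labels):
    rows = [(f"s{i}", ch) for i, ch in enumerate(residues)]
    site_labels = {(f"s{i}", 0): lab for i, lab in enumerate(labels)}
    return LabeledAlignment("fam", "A", rows, [0], site_labels)


def uniform_toy_model(p_interacting=0.5):
    """L=1 model: Begin splits between the two match flavors, both with
    uniform emissions, both going straight to End."""
    uni = np.full((1, 20), 1 / 20)
    trans = {"B": {"Mi1": p_interacting, "Mni1": 1 - p_interacting},
             "Mi1": {"End": 1.0}, "Mni1": {"End": 1.0}}
    return IpHMM.from_tables(uni, uni, np.full((2, 20), 1 / 20), trans)


class TestBuild:
    def test_add_one_emission_arithmetic(self):
        # interacting column residues {A, A, C, C}: add-one gives
        # e(A) = 3/24 and an unseen residue e(K) = 1/24
        aln = single_column_alignment("AACC",
                                      [SiteLabel.INTERACTING] * 4)
        model = build_iphmm(aln, pseudocount=1.0)
        e = model.emission("Mi1")
        assert e[AMINO_ACIDS.index("A")] == pytest.approx(3 / 24)
        assert e[AMINO_ACIDS.index("C")] == pytest.approx(3 / 24)
        assert e[AMINO_ACIDS.index("K")] == pytest.approx(1 / 24)

    def test_unseen_residue_has_positive_probability(self):
        aln = single_column_alignment("AAAA", [SiteLabel.INTERACTING] * 4)
        model = build_iphmm(aln)
        assert (model.emission("Mi1") > 0).all()
        assert (model.emission("Mni1") > 0).all()

    def test_ml_limit_recovers_empirical_frequencies(self):
        aln = single_column_alignment("AACC",
                                      [SiteLabel.NON_INTERACTING] * 4)
        model = build_iphmm(aln, pseudocount=1e-9)
        e = model.emission("Mni1")
        assert e[AMINO_ACIDS.index("A")] == pytest.approx(0.5, abs=1e-7)
        assert e[AMINO_ACIDS.index("C")] == pytest.approx(0.5, abs=1e-7)

    def test_distributions_normalized_and_positive(self, small_family):
        model = build_iphmm(small_family.aln_A)
        emit = model.space.emitting
        np.testing.assert_allclose(model.E[emit].sum(axis=1), 1.0,
                                   atol=1e-9)
        rows = model.T.sum(axis=1)
        active = rows > 0
        np.testing.assert_allclose(rows[active], 1.0, atol=1e-9)
        assert (model.E[emit] > 0).all()

    def test_invalid_inputs_rejected(self, toy_alignment):
        with pytest.raises(ValueError, match="pseudocount"):
            build_iphmm(toy_alignment, pseudocount=0.0)
        no_match = LabeledAlignment("f", "A", [("s1", "AC")], [], {})
        with pytest.raises(ValueError, match="match"):
            build_iphmm(no_match)


class TestDecoding:
    def test_two_path_likelihood(self):
        model = uniform_toy_model()
        dec = forward_backward(model, "A", "s")
        assert np.exp(dec.log_likelihood) == pytest.approx(0.05)

    def test_posterior_normalizes_over_match_flavors(self):
        dec = forward_backward(uniform_toy_model(), "A")
        assert dec.gamma.sum() == pytest.approx(1.0, abs=1e-9)
        assert dec.site_probability()[0] == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_likelihood_matches_path_enumeration(self, seed):
        """Forward total equals the exhaustive sum over all state paths
        on small random models."""
        rng = np.random.default_rng(seed)
        L = int(rng.integers(1, 5))
        model = random_model(L, rng)
        n = int(rng.integers(1, 7))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
        brute = enumerate_path_likelihood(model, seq)
        dec = forward_backward(model, seq)
        assert dec.log_likelihood == pytest.approx(np.log(brute),
                                                   rel=1e-8)
        # per-residue posterior normalization
        np.testing.assert_allclose(dec.gamma.sum(axis=1), 1.0, atol=1e-6)

    def test_invalid_letter_reported_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            forward_backward(uniform_toy_model(), "AXA")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            forward_backward(uniform_toy_model(), "")

    def test_serialization_round_trip(self, small_family, tmp_path):
        model = build_iphmm(small_family.aln_A)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = IpHMM.from_json(path)
        np.testing.assert_allclose(back.T, model.T)
        np.testing.assert_allclose(back.E, model.E)
        seq = small_family.aln_A.degapped(small_family.pairs[0][1])
        assert (forward_backward(back, seq).log_likelihood
                == pytest.approx(forward_backward(model, seq).log_likelihood))


class TestSiteCalls:
    def test_threshold_rule(self):
        dec = forward_backward(uniform_toy_model(p_interacting=0.9), "A")
        calls = predict_sites(dec)
        assert calls.p_int[0] == pytest.approx(0.9)
        assert calls.calls[0]

    def test_exact_tie_is_non_interacting(self):
        dec = forward_backward(uniform_toy_model(p_interacting=0.5), "A")
        calls = predict_sites(dec)
        assert calls.p_int[0] == pytest.approx(0.5)
        assert not calls.calls[0]

    def test_deleted_column_called_non_interacting_with_zero_p(self):
        # two-column model built from rows that delete one column each;
        # a 1-residue sequence must leave one column unoccupied
        aln = LabeledAlignment(
            "f", "A", [("s1", "A-"), ("s2", "-C"), ("s3", "AC")], [0, 1],
            {("s1", 0): SiteLabel.INTERACTING, ("s1", 1): SiteLabel.GAP,
             ("s2", 0): SiteLabel.GAP, ("s2", 1): SiteLabel.NON_INTERACTING,
             ("s3", 0): SiteLabel.INTERACTING,
             ("s3", 1): SiteLabel.NON_INTERACTING})
        model = build_iphmm(aln)
        calls = predict_sites(forward_backward(model, "A"))
        assert calls.occupied.sum() == 1
        j = int(np.flatnonzero(~calls.occupied)[0])
        assert not calls.calls[j]
        assert calls.p_int[j] == 0.0

    def test_site_signal_recovered_on_synthetic_family(self, small_family):
        """Interface posteriors separate truly interacting residues from
        non-interacting ones when interface emissions are distinct."""
        model = build_iphmm(small_family.aln_A)
        aln = small_family.aln_A
        p_pos, p_neg = [], []
        for seq_id, _ in aln.rows:
            dec = forward_backward(model, aln.degapped(seq_id), seq_id)
            p = dec.site_probability()
            for j, c in enumerate(aln.match_columns):
                lab = aln.site_labels[(seq_id, c)]
                if lab is SiteLabel.INTERACTING:
                    p_pos.append(p[j])
                elif lab is SiteLabel.NON_INTERACTING:
                    p_neg.append(p[j])
        assert np.mean(p_pos) > np.mean(p_neg)


class TestFisherScores:
    def test_gradient_formula_single_state(self):
        # whole posterior on Mi(1) with e(A) = 0.5: F(A) = 0.5,
        # F(C) = -e(C)
        e = np.full(20, 0.5 / 19)
        e[AMINO_ACIDS.index("A")] = 0.5
        model = IpHMM.from_tables(
            e[None, :], e[None, :], np.full((2, 20), 1 / 20),
            {"B": {"Mi1": 1.0}, "Mi1": {"End": 1.0}})
        dec = forward_backward(model, "A")
        F = fisher_scores(model, dec).scores[0]
        assert F[AMINO_ACIDS.index("A")] == pytest.approx(0.5)
        assert F[AMINO_ACIDS.index("C")] == pytest.approx(-0.5 / 19)

    def test_uniform_emission_plug_in(self):
        uni = np.full((1, 20), 1 / 20)
        model = IpHMM.from_tables(uni, uni, np.full((2, 20), 1 / 20),
                                  {"B": {"Mi1": 1.0}, "Mi1": {"End": 1.0}})
        F = fisher_scores(model, forward_backward(model, "A")).scores[0]
        assert F[AMINO_ACIDS.index("A")] == pytest.approx(19 / 20)
        others = np.delete(F, AMINO_ACIDS.index("A"))
        np.testing.assert_allclose(others, -1 / 20)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_vectors_sum_to_zero(self, seed):
        """Constrained-gradient identity: every residue's Fisher vector
        sums to zero."""
        rng = np.random.default_rng(seed)
        model = random_model(int(rng.integers(1, 5)), rng)
        seq = "".join(rng.choice(list(AMINO_ACIDS),
                                 size=int(rng.integers(1, 7))))
        fp = fisher_scores(model, forward_backward(model, seq))
        np.testing.assert_allclose(fp.scores.sum(axis=1), 0.0, atol=1e-6)

    def test_pure_insert_residue_flagged_zero(self):
        # a model whose match states are unreachable: every residue is
        # emitted by the insert state and carries zero match mass
        uni = np.full((1, 20), 1 / 20)
        model = IpHMM.from_tables(
            uni, uni, np.full((2, 20), 1 / 20),
            {"B": {"I0": 1.0}, "I0": {"I0": 0.5, "D1": 0.5},
             "D1": {"End": 1.0}})
        dec = forward_backward(model, "AG")
        fp = fisher_scores(model, dec)
        assert fp.insert_flags.all()
        np.testing.assert_allclose(fp.scores, 0.0)
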