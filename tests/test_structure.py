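import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rbpstruct as rb
from rbpstruct.structure import (
    CONTEXT_INDEX,
    StructureError,
    _BasicFold,
    classify_structure,
    enumerate_energy_distribution,
)

from conftest import random_rna

RT = 0.6163


class TestPairingProbabilities:
    def test_sequences_without_partners_are_all_zero(self):
        np.testing.assert_array_equal(rb.pairing_probabilities("AAAAA"), 0.0)
        # length 4 cannot satisfy the minimum hairpin of 3 unpaired bases
        np.testing.assert_array_equal(rb.pairing_probabilities("ACGU"), 0.0)

    def test_invalid_inputs_raise(self):
        with pytest.raises(StructureError):
            rb.pairing_probabilities("")
        with pytest.raises(StructureError):
            rb.pairing_probabilities("ACGX")

    def test_two_structure_ensemble_closed_form(self):
        # GAAAC folds into the open chain or the single pair (0, 4)
        w = math.exp(3.0 / RT)
        p = rb.pairing_probabilities("GAAAC")
        np.testing.assert_allclose(p[0], w / (1 + w), atol=1e-12)
        np.testing.assert_allclose(p[4], w / (1 + w), atol=1e-12)
        np.testing.assert_array_equal(p[1:4], 0.0)

    def test_matches_enumeration_on_hairpin(self):
        p_rec = rb.pairing_probabilities("GGGAAACCC")
        p_enum, _, _ = rb.exhaustive_boltzmann("GGGAAACCC")
        np.testing.assert_allclose(p_rec, p_enum, atol=1e-6)

    def test_max_span_silences_distant_pairs(self):
        # only possible pair is G(0)..C(10), span 10 > L = 5
        fp = rb.FoldParams(window=80, max_span=5)
        p = rb.pairing_probabilities("GAAAAAAAAAC", fp=fp)
        np.testing.assert_array_equal(p, 0.0)

    def test_pair_matrix_respects_span_constraint(self):
        seq = "GGGAAAACCCAAAGGGAAACCC"
        fold = _BasicFold(seq, rb.EnergyModel(), max_span=6)
        P = fold.pair_probabilities()
        i, j = np.nonzero(P)
        assert np.all(j - i <= 6)


class TestExhaustiveBoltzmann:
    def test_open_chain_only(self):
        p, prof, Z = rb.exhaustive_boltzmann("AAAA")
        assert Z == 1.0
        np.testing.assert_array_equal(prof[:, CONTEXT_INDEX["E"]], 1.0)

    def test_two_structure_partition_function(self):
        _, _, Z = rb.exhaustive_boltzmann("GAAAC")
        np.testing.assert_allclose(Z, 1 + math.exp(3.0 / RT), rtol=1e-12)

    def test_refuses_long_sequences(self):
        with pytest.raises(StructureError, match="enumeration"):
            rb.exhaustive_boltzmann("A" * 23)


class TestContextProfile:
    def test_unpairable_sequence_is_all_external(self):
        prof = rb.context_profile("AAAAAAA")
        np.testing.assert_array_equal(prof[:, CONTEXT_INDEX["E"]], 1.0)

    def test_two_structure_closed_form(self):
        # paired fraction sits in S for the ends, H for the loop positions
        w = math.exp(3.0 / RT)
        q = w / (1 + w)
        prof = rb.context_profile("GAAAC")
        np.testing.assert_allclose(prof[0], [q, 0, 0, 0, 1 - q], atol=1e-12)
        np.testing.assert_allclose(prof[2], [0, q, 0, 0, 1 - q], atol=1e-12)

    def test_recursion_matches_enumeration_on_random_sequences(self, basic_em):
        rng = np.random.default_rng(42)
        for _ in range(30):
            seq = random_rna(rng, rng.integers(8, 15))
            prof = rb.context_profile(seq, basic_em)
            p_enum, prof_enum, _ = rb.exhaustive_boltzmann(seq, basic_em)
            np.testing.assert_allclose(prof, prof_enum, atol=1e-6)
            np.testing.assert_allclose(
                prof[:, CONTEXT_INDEX["S"]], p_enum, atol=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=1, max_size=40))
    def test_rows_are_distributions(self, seq):
        prof = rb.context_profile(seq)
        assert np.all(prof >= -1e-12)
        np.testing.assert_allclose(prof.sum(axis=1), 1.0, atol=1e-9)

    def test_s_column_equals_pairing_probabilities(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            seq = random_rna(rng, 30)
            prof = rb.context_profile(seq)
            np.testing.assert_allclose(
                prof[:, CONTEXT_INDEX["S"]], rb.pairing_probabilities(seq), atol=1e-9)

    def test_turner_backend_profile_consistency(self, turner_em):
        rng = np.random.default_rng(4)
        seq = random_rna(rng, 35)
        prof = rb.context_profile(seq, turner_em)
        np.testing.assert_allclose(prof.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            prof[:, CONTEXT_INDEX["S"]],
            rb.pairing_probabilities(seq, turner_em),
            atol=1e-4,
        )


class TestStructureClassification:
    def test_loop_types_on_nested_structure(self):
        # ((...))  : stem of 2, hairpin loop of 3
        ctx = classify_structure(7, [(0, 6), (1, 5)])
        assert "".join("SHIME"[c] for c in ctx) == "SSHHHSS"

    def test_internal_and_multibranch_loops(self):
        # ( . ((...)) . ((...)) . ) -> multiloop spacers M; two branches
        pairs = [(0, 12), (2, 6), (8, 11)]
        ctx = classify_structure(13, pairs)
        assert ctx[1] == CONTEXT_INDEX["M"] and ctx[7] == CONTEXT_INDEX["M"]
        # single branch -> internal loop
        ctx2 = classify_structure(11, [(0, 10), (2, 8)])
        assert ctx2[1] == CONTEXT_INDEX["I"] and ctx2[9] == CONTEXT_INDEX["I"]


class TestUnstructuredProbability:
    def test_unfoldable_sequence_is_fully_unstructured(self):
        assert rb.unstructured_probability("AAAAAAA") == 1.0

    def test_minus_infinity_threshold_gives_one(self):
        fp = rb.FoldParams(shape_energy_threshold=-1e9)
        assert rb.unstructured_probability("GGGGAAAACCCC", fp=fp) == 1.0

    def test_matches_enumeration_oracle(self):
        seq = "GGGGAAAACCCC"
        dist = enumerate_energy_distribution(seq)
        Z = sum(w for _, w in dist)
        structured = sum(w for e, w in dist if e < -2.5)
        np.testing.assert_allclose(
            rb.unstructured_probability(seq), 1 - structured / Z, rtol=1e-9)

    def test_non_increasing_in_threshold(self):
        seq = "GGCGAAAGCGCC"
        thresholds = [-10.0, -5.0, -2.5, -1.0, -0.1]
        vals = [
            rb.unstructured_probability(seq, fp=rb.FoldParams(shape_energy_threshold=t))
            for t in thresholds
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_turner_backend_sampling(self, turner_em):
        fp = rb.FoldParams(n_samples=200)
        v = rb.unstructured_probability("GGGGCAAAAGCCCC", turner_em, fp, seed=1)
        assert 0.0 <= v <= 1.0
        with pytest.raises(StructureError, match="n_samples"):
            rb.unstructured_probability(
                "GGGGCAAAAGCCCC", turner_em, rb.FoldParams(n_samples=50), seed=1)


class TestRandomizeProfile:
    def test_rows_are_seeded_distributions(self):
        prof = rb.randomize_profile(25, seed=7)
        assert prof.shape == (25, 5)
        assert np.all(prof >= 0)
        np.testing.assert_allclose(prof.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(prof, rb.randomize_profile(25, seed=7))
        assert not np.array_equal(prof, rb.randomize_profile(25, seed=8))


def test_windowed_folding_of_long_sequences(basic_em):
    rng = np.random.default_rng(9)
    seq = random_rna(rng, 100)
    fp = rb.FoldParams(window=60, max_span=30)
    p = rb.pairing_probabilities(seq, basic_em, fp)
    assert len(p) == 100 and np.all((p >= 0) & (p <= 1))
    prof = rb.context_profile(seq, basic_em, fp)
    np.testing.assert_allclose(prof.sum(axis=1), 1.0, atol=1e-9)
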