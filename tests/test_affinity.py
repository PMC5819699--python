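import numpy as np
import pytest
from scipy import stats

import rbpstruct as rb
from rbpstruct.affinity import AffinityError, build_protein_features

from conftest import random_rna


class TestRnaFeatures:
    def test_all_external_profile_puts_counts_in_e_block(self):
        rng = np.random.default_rng(0)
        seqs = [random_rna(rng, 20) for _ in range(5)]
        profs = []
        for s in seqs:
            p = np.zeros((len(s), 5))
            p[:, 4] = 1.0
            profs.append(p)
        feats = rb.build_rna_features(seqs, profs, k=3)
        counts = feats.block("counts").toarray()
        assert np.array_equal(feats.block("E").toarray(), counts)
        for c in "SHIM":
            assert feats.block(c).nnz == 0

    def test_single_occurrence_mean_rule(self):
        seq = "ACGUACG"  # one occurrence of each 7-mer window (k=7 -> itself)
        prof = np.zeros((7, 5))
        prof[:, 4] = 0.5
        prof[:, 0] = 0.5
        feats = rb.build_rna_features([seq], [prof], k=7)
        assert feats.block("E").sum() == pytest.approx(0.5)
        assert feats.block("S").sum() == pytest.approx(0.5)

    def test_context_blocks_sum_to_counts(self, small_probe_set):
        seqs, profiles = small_probe_set
        feats = rb.build_rna_features(seqs, profiles, k=5)
        counts = feats.block("counts").toarray()
        total = sum(feats.block(c).toarray() for c in "SHIME")
        np.testing.assert_allclose(total, counts, atol=1e-9)

    def test_misaligned_profile_raises(self):
        with pytest.raises(AffinityError):
            rb.build_rna_features(["ACGUACGU"], [np.zeros((5, 5))], k=3)


class TestProteinFeatures:
    def test_counts_over_observed_vocabulary(self):
        mat, vocab = build_protein_features(["ACDEACDE", "CDEF"], k_aa=4)
        assert mat.shape == (2, len(vocab))
        row0 = dict(zip(vocab, mat.toarray()[0]))
        assert row0["ACDE"] == 2
        assert mat.toarray().min() >= 0

    def test_invalid_residue_raises(self):
        with pytest.raises(AffinityError, match="invalid residues"):
            build_protein_features(["ACDB"], k_aa=2)


class TestHalfSplit:
    def test_split_properties(self):
        tr, te = rb.half_split(101, seed=3)
        assert abs(len(tr) - len(te)) <= 1
        assert len(np.intersect1d(tr, te)) == 0
        assert len(np.union1d(tr, te)) == 101
        tr2, te2 = rb.half_split(101, seed=3)
        np.testing.assert_array_equal(tr, tr2)


class TestBilinearInteraction:
    def _tiny_panel(self, seed=0, noise=0.0):
        return rb.simulate_protein_panel(n_proteins=10, seed=seed, n_probes=120,
                                         rna_k=3, noise_sd_frac=noise,
                                         structure_loading=False)

    def test_noise_free_planted_interaction_is_recovered_held_out(self):
        panel = self._tiny_panel()
        tr, te = rb.half_split(len(panel.probes), seed=0)
        F = panel.rna_features.counts_only()
        res = rb.fit_interaction(panel.protein_features, F[tr], panel.Y[:, tr],
                                 rank=2, ridge=0.1, seed=0)
        pred = res.predict(panel.protein_features, F[te])
        rs = [stats.pearsonr(pred[p], panel.Y[p, te])[0]
              for p in range(panel.Y.shape[0])]
        assert np.mean(rs) > 0.9
        assert "rank" in res.summary()

    def test_infinite_ridge_shrinks_predictions_to_zero(self):
        panel = self._tiny_panel()
        F = panel.rna_features.counts_only()
        res = rb.fit_interaction(panel.protein_features, F, panel.Y,
                                 rank=2, ridge=1e12, seed=0)
        assert np.abs(res.predict(panel.protein_features, F)).max() < 1e-3

    def test_permuting_protein_labels_destroys_transfer(self):
        """Training on shuffled protein-to-intensity assignments and then
        predicting each protein from its true features should leave no
        systematic held-out correlation (individual wrong-pair r values can
        be large in magnitude because preferences share a low-rank space, so
        the signed mean is the meaningful null statistic)."""
        panel = self._tiny_panel()
        tr, te = rb.half_split(len(panel.probes), seed=1)
        F = panel.rna_features.counts_only()
        P = panel.Y.shape[0]
        rs = []
        for i in range(10):
            perm = np.random.default_rng(i).permutation(P)
            res = rb.fit_interaction(panel.protein_features[perm], F[tr],
                                     panel.Y[:, tr], rank=2, ridge=0.1, seed=i)
            pred = res.predict(panel.protein_features, F[te])
            rs.append(np.mean([stats.pearsonr(pred[p], panel.Y[p, te])[0]
                               for p in range(P)]))
        assert abs(np.mean(rs)) < 0.2
        # unpermuted fit transfers strongly by contrast
        res = rb.fit_interaction(panel.protein_features, F[tr], panel.Y[:, tr],
                                 rank=2, ridge=0.1, seed=0)
        pred = res.predict(panel.protein_features, F[te])
        assert np.mean([stats.pearsonr(pred[p], panel.Y[p, te])[0]
                        for p in range(P)]) > 0.9

    def test_predictions_are_linear_in_protein_features(self):
        panel = self._tiny_panel()
        F = panel.rna_features.counts_only()
        res = rb.fit_interaction(panel.protein_features, F, panel.Y,
                                 rank=2, ridge=1.0, seed=0)
        d = panel.protein_features[0].toarray().ravel()
        one = res.predict_for_protein(d, F)
        np.testing.assert_allclose(res.predict_for_protein(2 * d, F), 2 * one,
                                   rtol=1e-9)

    def test_hand_computed_two_by_two_prediction(self):
        res = rb.BilinearInteractionResults.__new__(rb.BilinearInteractionResults)
        res.A = np.array([[1.0], [0.0]])   # dp=2, r=1
        res.B = np.array([[0.0], [2.0]])   # df=2, r=1
        pred = res.predict(np.array([[1.0, 5.0]]), np.array([[3.0, 4.0]]))
        # d^T W f with W = A B^T = [[0,2],[0,0]] -> 1*2*4 = 8
        assert pred[0, 0] == pytest.approx(8.0)

    def test_rank_and_size_validation(self):
        with pytest.raises(AffinityError, match="rank"):
            rb.BilinearInteraction(np.zeros((6, 8)), np.ones((6, 3)),
                                   np.ones((8, 3)), rank=7)
        with pytest.raises(AffinityError, match="5 proteins"):
            rb.BilinearInteraction(np.zeros((3, 8)), np.ones((3, 3)),
                                   np.ones((8, 3)), rank=1)


class TestAupr:
    def test_perfect_ranking_gives_one(self):
        y = np.linspace(0, 1, 300)
        assert rb.aupr_top_vs_bottom(y, y, 1, 50) == 1.0
        assert rb.aupr_top_vs_bottom(y, y, 1, 99) == 1.0

    def test_harder_prevalence_is_no_easier(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=400)
        pred = y + rng.normal(size=400)
        a50 = rb.aupr_top_vs_bottom(pred, y, 1, 50)
        a99 = rb.aupr_top_vs_bottom(pred, y, 1, 99)
        assert a99 <= a50

    def test_random_predictions_approach_prevalence(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=500)
        vals = [rb.aupr_top_vs_bottom(rng.normal(size=500), y, 1, 50)
                for _ in range(50)]
        prevalence = 5 / (5 + 250)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - prevalence) < 3 * se + 0.01

    def test_empty_top_class_raises(self):
        with pytest.raises(AffinityError):
            rb.aupr_top_vs_bottom(np.ones(50), np.ones(50), 1, 50)


def test_identical_profiles_make_structure_columns_uninformative():
    """With every probe sharing one profile, context columns are exact
    multiples of the count columns and cannot change ridge predictions."""
    rng = np.random.default_rng(2)
    seqs = [random_rna(rng, 25) for _ in range(80)]
    row = rb.randomize_profile(1, seed=9)[0]
    shared = np.tile(row, (25, 1))  # position-constant: weights = const * count
    profs = [shared] * 80
    feats = rb.build_rna_features(seqs, profs, k=3)
    # verify exact collinearity occurrence-wise is preserved feature-wise
    counts = feats.block("counts").toarray()
    total = sum(feats.block(c).toarray() for c in "SHIME")
    np.testing.assert_allclose(total, counts, atol=1e-9)
    y = rng.normal(size=(6, 80))
    D = np.abs(rng.normal(size=(6, 4)))
    res_aug = rb.fit_interaction(D, feats.matrix, y, rank=2, ridge=1.0, seed=0)
    res_cnt = rb.fit_interaction(D, feats.counts_only(), y, rank=2, ridge=1.0, seed=0)
    r_aug = res_aug.predict(D, feats.matrix)
    r_cnt = res_cnt.predict(D, feats.counts_only())
    # same kernel up to scale -> same ranking of probes per protein
    for p in range(6):
        assert stats.spearmanr(r_aug[p], r_cnt[p]).statistic > 0.99
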