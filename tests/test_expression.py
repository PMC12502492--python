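"""VST, NMF, LCD projection, embedding and rank-selection behavior."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from recaplab import expression as ex
from recaplab import synthgen


def _df(arr, prefix="g"):
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                        columns=[f"s{j}" for j in range(arr.shape[1])])


class TestVst:
    def test_zero_count_maps_to_zero_with_equal_libraries(self):
        # symmetric libraries -> unit size factors; a zero count transforms to 0
        counts = _df(np.array([[0, 4], [4, 0], [10, 10], [20, 20]], float))
        out = ex.vst_transform(counts)
        assert out.loc["g0", "s0"] == 0.0
        assert out.loc["g1", "s1"] == 0.0

    def test_all_zero_gene_rows_dropped(self):
        counts = _df(np.array([[0, 0], [10, 10], [20, 20]], float))
        out = ex.vst_transform(counts)
        assert "g0" not in out.index and len(out) == 2

    def test_size_factor_tracks_relative_library_size(self, rng):
        """Proportional samples: size factors are exactly proportional to
        depth, doubling one library doubles its factor relative to the
        rest, and normalization equalizes all samples."""
        base = rng.uniform(5, 100, 200)
        libs = np.array([1.0, 1.5, 2.0, 0.8])
        counts = _df(np.outer(base, libs))
        sf = ex.median_of_ratios_size_factors(counts)
        np.testing.assert_allclose(sf / sf.iloc[0], libs / libs[0])
        doubled = counts.copy()
        doubled["s0"] *= 2
        sf2 = ex.median_of_ratios_size_factors(doubled)
        assert sf2["s0"] / sf2["s1"] == pytest.approx(2 * sf["s0"] / sf["s1"])
        out = ex.vst_transform(doubled)
        # depth removed: every sample carries the same transformed profile
        for col in out.columns[1:]:
            np.testing.assert_allclose(out[col], out["s0"], rtol=1e-12)

    def test_variance_mean_slope_flattened(self):
        spec = synthgen.PairedExpressionSpec(n_genes=1500, n_pairs=6, seed=3)
        counts, _, _ = synthgen.gen_paired_expression(spec)

        def slope(mat):
            mu = mat.mean(axis=1)
            var = mat.var(axis=1)
            keep = (mu > 0) & (var > 0)
            return np.polyfit(np.log10(mu[keep]), np.log10(var[keep]), 1)[0]

        assert abs(slope(ex.vst_transform(counts))) < abs(slope(counts))

    def test_zero_total_sample_rejected(self):
        counts = _df(np.array([[1, 0], [2, 0]], float))
        with pytest.raises(ValueError, match="zero total"):
            ex.vst_transform(counts)


class TestNmf:
    def test_exact_rank_one_matrix_recovered(self, rng):
        w = rng.uniform(0.5, 2.0, 60)
        h = rng.uniform(0.5, 2.0, 8)
        X = _df(np.outer(w, h))
        fm = ex.fit_nmf(X, 1, seed=0)
        assert fm.error / np.linalg.norm(X) < 1e-6

    def test_determinism(self, paired_counts):
        counts, pairing, _ = paired_counts
        mat = ex.vst_transform(counts)[list(pairing.values())]
        a = ex.fit_nmf(mat, 3, seed=7)
        b = ex.fit_nmf(mat, 3, seed=7)
        pd.testing.assert_frame_equal(a.W, b.W)
        pd.testing.assert_frame_equal(a.H, b.H)

    def test_objective_monotone_nonincreasing(self, paired_counts):
        counts, pairing, _ = paired_counts
        mat = ex.vst_transform(counts)[list(pairing.values())]
        fm = ex.fit_nmf(mat, 4, seed=0)
        assert fm.monotone

    def test_error_decreases_at_true_rank(self, paired_counts):
        counts, pairing, _ = paired_counts
        mat = ex.vst_transform(counts)[list(pairing.values())]
        errs = {k: ex.fit_nmf(mat, k, seed=0).error for k in (1, 4)}
        assert errs[4] < 0.9 * errs[1]

    def test_matches_sklearn_mu_solver_error(self, paired_counts):
        """Independent cross-check: our multiplicative updates reach the
        same objective neighborhood as sklearn's 'mu' solver."""
        from sklearn.decomposition import NMF
        counts, pairing, _ = paired_counts
        mat = ex.vst_transform(counts)[list(pairing.values())]
        ours = min(ex.fit_nmf(mat, 3, seed=s).error for s in range(3))
        theirs = min(
            NMF(3, solver="mu", init="random", random_state=s,
                max_iter=2000, tol=1e-5).fit(mat.T).reconstruction_err_
            for s in range(3))
        assert abs(ours - theirs) / theirs < 0.05

    def test_invalid_rank_and_negative_input_rejected(self):
        X = _df(np.ones((5, 4)))
        with pytest.raises(ValueError, match="rank"):
            ex.fit_nmf(X, 4, seed=0)
        X.iloc[0, 0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            ex.fit_nmf(X, 2, seed=0)


class TestProjection:
    def test_training_samples_reproject_onto_their_exposures(self, rng):
        W_true = rng.uniform(0, 1, (80, 3))
        H_true = rng.uniform(0, 2, (3, 10))
        X = _df(W_true @ H_true)
        fm = ex.fit_nmf(X, 3, seed=1)
        expo = ex.project_lcd(fm.W, X)
        rel = np.linalg.norm(expo.to_numpy().T - fm.H.to_numpy()) / \
            np.linalg.norm(fm.H.to_numpy())
        assert rel < 0.05

    def test_projection_error_bounded_by_training_error(self, paired_counts):
        counts, pairing, _ = paired_counts
        mat = ex.vst_transform(counts)[list(pairing.values())]
        fm = ex.fit_nmf(mat, 3, seed=0)
        expo = ex.project_lcd(fm.W, mat)
        proj_err = np.linalg.norm(mat.to_numpy() -
                                  fm.W.to_numpy() @ expo.to_numpy().T)
        assert proj_err <= fm.error * (1 + 1e-9)

    def test_zero_sample_gets_zero_exposures(self, rng):
        W = _df(rng.uniform(0, 1, (30, 2)))
        W.columns = ["F1", "F2"]
        X = _df(np.zeros((30, 3)))
        expo = ex.project_lcd(W, X)
        assert (expo.to_numpy() == 0).all()

    def test_exposures_nonnegative_for_random_input(self, rng):
        W = _df(rng.uniform(0, 1, (40, 3)))
        X = _df(rng.normal(2, 1, (40, 6)).clip(0))
        assert (ex.project_lcd(W, X).to_numpy() >= -1e-12).all()

    def test_gene_mismatch_reported(self, rng):
        W = _df(rng.uniform(0, 1, (10, 2)))
        X = _df(rng.uniform(0, 1, (8, 2)))
        with pytest.raises(ValueError, match="missing"):
            ex.project_lcd(W, X)


class TestEmbedding:
    def test_pca_duplicated_samples_coincide(self, rng):
        expo = pd.DataFrame(rng.uniform(0, 1, (5, 3)))
        expo.loc[5] = expo.loc[0]
        emb = ex.embed_exposures(expo, method="pca")
        np.testing.assert_allclose(emb.loc[5], emb.loc[0], atol=1e-12)

    def test_pca_separates_two_latent_clusters(self, rng):
        a = rng.normal(0, 0.05, (10, 4)) + [1, 0, 0, 0]
        b = rng.normal(0, 0.05, (10, 4)) + [0, 0, 1, 0]
        expo = pd.DataFrame(np.vstack([a, b]))
        emb = ex.embed_exposures(expo, method="pca")
        labels = [0] * 10 + [1] * 10
        assert silhouette_score(emb, labels) > 0.5

    def test_umap_deterministic_under_fixed_seed(self, rng):
        expo = pd.DataFrame(rng.uniform(0, 1, (20, 4)))
        a = ex.embed_exposures(expo, method="umap", seed=3)
        b = ex.embed_exposures(expo, method="umap", seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestRankSelection:
    def test_column_order_invariance(self, paired_counts):
        counts, pairing, _ = paired_counts
        shuffled = counts[list(counts.columns[::-1])]
        a = ex.select_rank(counts, pairing, ks=(2, 3), seed=0,
                           embed_method="pca")
        b = ex.select_rank(shuffled, pairing, ks=(2, 3), seed=0,
                           embed_method="pca")
        assert a.chosen_k == b.chosen_k
        for k in (2, 3):
            assert a.distances[k] == pytest.approx(b.distances[k], rel=1e-9)

    def test_paired_distance_beats_random_repairing(self, paired_counts, rng):
        counts, pairing, _ = paired_counts
        sel = ex.select_rank(counts, pairing, ks=range(2, 7), seed=0)
        emb = sel.embeddings[sel.chosen_k]
        observed = ex.paired_distances(emb, pairing)
        tumors, organoids = list(pairing), list(pairing.values())
        null = []
        for _ in range(100):
            null.append(ex.paired_distances(
                emb, dict(zip(tumors, rng.permutation(organoids)))))
        assert observed < np.mean(null)

    def test_pair_matching_recovery_in_exposure_space(self):
        """With one program per pair (the identifiable regime), nearest-
        exposure matching recovers every pairing despite the stromal offset."""
        for seed in (1, 2, 3):
            spec = synthgen.PairedExpressionSpec(n_genes=1000, n_pairs=6,
                                                 k_true=6, seed=seed)
            counts, pairing, _ = synthgen.gen_paired_expression(spec)
            mat = ex.vst_transform(counts).clip(lower=0)
            fm = ex.fit_nmf(mat[list(pairing.values())], 5, seed=0)
            expo = ex.project_lcd(fm.W, mat)
            expo = expo.div(expo.sum(axis=1), axis=0)
            assert ex.min_distance_pair_matching(expo, pairing) >= 0.9

    def test_unpaired_sample_rejected(self, paired_counts):
        counts, pairing, _ = paired_counts
        bad = dict(pairing)
        bad["T99"] = "P99"
        with pytest.raises(ValueError, match="missing"):
            ex.select_rank(counts, bad, ks=(2,), seed=0)


class TestSignatures:
    def test_top_five_percent_of_hundred_genes(self, rng):
        W = _df(rng.uniform(0, 1, (100, 3)))
        W.columns = ["F1", "F2", "F3"]
        sigs = ex.signature_top_genes(W, pct=5)
        assert all(len(v) == 5 for v in sigs.values())

    def test_planted_markers_recovered(self, rng):
        W = _df(rng.uniform(0, 1, (200, 2)))
        W.columns = ["F1", "F2"]
        planted = [f"g{i}" for i in range(5)]
        W.loc[planted, "F1"] = 10.0
        assert set(planted) <= set(ex.signature_top_genes(W, pct=5)["F1"])

    def test_pct_100_returns_weight_order(self, rng):
        W = _df(rng.uniform(0, 1, (20, 1)))
        W.columns = ["F1"]
        genes = ex.signature_top_genes(W, pct=100)["F1"]
        weights = W.loc[genes, "F1"].to_numpy()
        assert (np.diff(weights) <= 0).all()
        assert len(genes) == 20


class TestPairedCorrelation:
    def test_identical_columns_give_unit_r2(self, rng):
        x = rng.uniform(0, 10, 500)
        r, r2 = ex.paired_gene_correlation(x, x)
        assert (r, r2) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_independent_columns_near_zero(self, rng):
        r, _ = ex.paired_gene_correlation(rng.normal(size=10000),
                                          rng.normal(size=10000))
        assert abs(r) < 0.05

    def test_mean_pair_r2_decreases_with_stroma(self):
        def mean_r2(weight):
            spec = synthgen.PairedExpressionSpec(n_genes=600, n_pairs=5,
                                                 stroma_weight=weight, seed=4)
            counts, pairing, _ = synthgen.gen_paired_expression(spec)
            vst = ex.vst_transform(counts)
            return np.mean([ex.paired_gene_correlation(vst[t], vst[p])[1]
                            for t, p in pairing.items()])

        r2s = [mean_r2(w) for w in (0.0, 1.0, 2.0)]
        assert r2s[0] > r2s[1] > r2s[2]
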