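import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from herbfp.chemometrics import (hca, oplsda, pca, permutation_test,
                                 preprocess, vip, vip_markers)
from herbfp.errors import ValidationError


def uv(matrix):
    return preprocess(matrix, "uv")


class TestPreprocess:
    def test_closed_form_uv(self):
        out = preprocess(pd.DataFrame({"a": [1.0, 2.0, 3.0]}), "uv")
        assert np.allclose(out.values["a"], [-1.0, 0.0, 1.0])

    def test_none_is_identity(self):
        df = pd.DataFrame(np.random.default_rng(0).random((4, 3)))
        out = preprocess(df, "none")
        assert np.allclose(out.values, df)

    def test_standardized_matrix_unchanged(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(50, 4)))
        df = (df - df.mean()) / df.std(ddof=1)
        out = preprocess(df, "uv")
        assert np.allclose(out.values, df, atol=1e-10)

    def test_uv_columns_have_unit_moments(self):
        rng = np.random.default_rng(2)
        out = preprocess(pd.DataFrame(rng.random((20, 5))), "uv")
        assert np.allclose(out.values.mean(), 0.0, atol=1e-10)
        assert np.allclose(out.values.std(ddof=1), 1.0, atol=1e-10)

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValidationError, match="flat"):
            preprocess(df, "uv")

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.random((10, 4)) * 7 + 3)
        for scaling in ("center", "uv", "pareto", "none"):
            out = preprocess(df, scaling)
            assert np.allclose(out.inverse(), df, atol=1e-10)

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError):
            preprocess(pd.DataFrame({"a": [1.0]}), "uv")


class TestPca:
    def test_exact_rank_two(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(2, 6))
        X = pd.DataFrame(rng.normal(size=(12, 2)) @ base)
        res = pca(preprocess(X, "center"), k=2)
        assert res.cumulative[1] == pytest.approx(1.0, abs=1e-10)

    def test_k_too_large_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).random((5, 3)))
        with pytest.raises(ValidationError):
            pca(uv(X), k=4)

    def test_explained_fractions_non_increasing(self):
        X = pd.DataFrame(np.random.default_rng(1).random((15, 6)))
        res = pca(uv(X), k=4)
        assert np.all(np.diff(res.explained) <= 1e-12)
        assert np.all((res.explained >= 0) & (res.explained <= 1))

    def test_loadings_orthonormal(self):
        X = pd.DataFrame(np.random.default_rng(2).random((15, 6)))
        res = pca(uv(X), k=3)
        gram = res.loadings.to_numpy().T @ res.loadings.to_numpy()
        assert np.allclose(gram, np.eye(3), atol=1e-10)

    def test_isotropic_noise_equal_fractions(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(400, 5)))
        res = pca(preprocess(X, "center"), k=4)
        assert np.allclose(res.explained, 0.2, atol=0.06)

    def test_duplicate_rows_invariance(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.random((8, 5)))
        s1 = preprocess(X, "center")
        s2 = preprocess(pd.concat([X, X], ignore_index=True), "center")
        r1, r2 = pca(s1, k=2), pca(s2, k=2)
        assert np.allclose(np.abs(r2.loadings), np.abs(r1.loadings),
                           atol=1e-8)
        assert np.allclose(r2.scores.iloc[:8].abs(),
                           r2.scores.iloc[8:].abs(), atol=1e-8)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.random((10, 6)))
        scaled = uv(X)
        k = min(X.shape[0] - 1, X.shape[1])
        res = pca(scaled, k=k)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, scaled.values, atol=1e-8)

    def test_panel_origin_on_dominant_component(self, default_panel):
        panel = default_panel
        res = pca(uv(panel.realized_areas), k=2)
        pc1 = res.scores["PC1"]
        south = [b for b in panel.batches
                 if panel.group_of(b) == "southern"]
        north = [b for b in panel.batches if b not in south]
        assert (pc1[south].min() > pc1[north].max()
                or pc1[south].max() < pc1[north].min())
        # within the northern batches, processing separates on PC2
        pc2 = res.scores["PC2"]
        freeze = [b for b in north
                  if panel.group_of(b) == "northern_freeze_dried"]
        heat = [b for b in north if b not in freeze]
        assert (pc2[freeze].min() > pc2[heat].max()
                or pc2[freeze].max() < pc2[heat].min())


class TestHca:
    def test_two_far_clouds_perfect_split(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(np.vstack([rng.normal(0, 1, (6, 4)),
                                    rng.normal(50, 1, (6, 4))]))
        res = hca(preprocess(X, "center"), k=2)
        labels = res.labels.to_numpy()
        assert len(set(labels[:6])) == 1
        assert len(set(labels[6:])) == 1
        assert labels[0] != labels[-1]

    def test_duplicated_batch_zero_height_tree(self):
        X = pd.DataFrame(np.tile([1.0, 2.0, 3.0], (6, 1)))
        res = hca(preprocess(X, "none"))
        assert float(res.linkage[:, 2].max()) == 0.0
        assert res.k == 1

    def test_k_greater_than_n_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).random((4, 3)))
        with pytest.raises(ValidationError):
            hca(uv(X), k=5)

    def test_panel_silhouette_selects_three_groups(self, default_panel):
        panel = default_panel
        res = hca(uv(panel.realized_areas))
        assert res.k == 3
        truth = [panel.group_of(b) for b in res.labels.index]
        assert adjusted_rand_score(truth, res.labels.to_numpy()) == 1.0

    def test_newick_export_parses(self, default_panel):
        res = hca(uv(default_panel.realized_areas), k=3)
        assert res.newick.endswith(";")
        assert res.newick.count("(") == res.newick.count(")")
        for b in default_panel.batches:
            assert b in res.newick

    def test_heatmap_row_order_matches_leaves(self, default_panel):
        res = hca(uv(default_panel.realized_areas), k=3)
        assert list(res.heatmap.index) == res.leaf_order


def separable_toy(n=24, p=8, seed=0):
    """Classes perfectly separated along variable 0; the rest is faint noise
    (center scaling keeps the noise variables faint)."""
    rng = np.random.default_rng(seed)
    X = 0.05 * rng.normal(size=(n, p))
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X[:, 0] += 6.0 * y
    return preprocess(pd.DataFrame(X), "center"), y


class TestOplsda:
    def test_separable_classes(self):
        scaled, y = separable_toy()
        model = oplsda(scaled, y)
        assert model.r2y > 0.99
        assert model.q2 > 0.9

    def test_null_median_q2_nonpositive(self):
        q2s = []
        for seed in range(11):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(18, 30)))
            y = np.array([0] * 9 + [1] * 9)
            rng.shuffle(y)
            q2s.append(oplsda(uv(X), y).q2)
        assert np.median(q2s) <= 0.0

    def test_zero_orthogonal_equals_pls(self):
        scaled, y = separable_toy(seed=5)
        model = oplsda(scaled, y, n_orthogonal=0)
        # independent 1-component PLS oracle
        X = scaled.values.to_numpy()
        yc = np.where(y == 0, -1.0, 1.0)
        yc = yc - yc.mean()
        w = X.T @ yc
        w /= np.linalg.norm(w)
        assert np.allclose(model.t, X @ w, atol=1e-8)

    def test_orthogonal_filter_invariance(self):
        scaled, y = separable_toy(seed=2)
        model = oplsda(scaled, y, n_orthogonal=1)
        X = scaled.values.to_numpy()
        augmented = X + model.t_ortho @ model.p_ortho.T
        assert np.allclose(model.transform(augmented), model.t, atol=1e-8)
        assert np.allclose(model.transform(X), model.t, atol=1e-10)

    def test_r2_bounds_and_ordering(self):
        scaled, y = separable_toy(seed=3)
        model = oplsda(scaled, y)
        assert 0.0 <= model.r2y <= 1.0
        assert model.q2 <= model.r2y

    def test_constant_y_rejected(self):
        scaled, _ = separable_toy()
        with pytest.raises(ValidationError, match="constant"):
            oplsda(scaled, np.zeros(24))

    def test_fold_without_both_classes_rejected(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(7, 4)))
        y = np.array([1, 0, 0, 0, 0, 0, 0])   # class 1 only in fold 0
        with pytest.raises(ValidationError, match="fold"):
            oplsda(uv(X), y, cv_folds=7)


class TestVip:
    def test_mean_square_identity(self):
        scaled, y = separable_toy(seed=9)
        v = vip(oplsda(scaled, y))
        assert float((v ** 2).mean()) == pytest.approx(1.0, abs=1e-8)

    def test_informative_variable_attains_max(self):
        scaled, y = separable_toy(seed=4)
        v = vip(oplsda(scaled, y))
        assert v.idxmax() == v.index[0]
        assert v.iloc[0] > 1.0

    def test_identical_variables_all_unit_vip(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 6 + [1] * 6)
        col = np.where(y == 0, -1.0, 1.0) + rng.normal(0, 0.1, 12)
        X = pd.DataFrame(np.tile(col[:, None], (1, 5)))
        v = vip(oplsda(preprocess(X, "center"), y))
        assert np.allclose(v, 1.0, atol=1e-10)

    def test_marker_flagging(self):
        scaled, y = separable_toy(seed=6)
        flagged = vip_markers(oplsda(scaled, y))
        assert (flagged["VIP"] > 1.0).all()
        assert list(flagged["rank"]) == sorted(flagged["rank"])


class TestPermutationTest:
    def test_null_intercept_nonpositive_most_seeds(self):
        good = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(rng.normal(size=(18, 10)))
            y = np.array([0] * 9 + [1] * 9)
            rng.shuffle(y)
            res = permutation_test(uv(X), y, n_perm=25, seed=seed)
            good += (res.q2_intercept <= 0)
        assert good >= 9

    def test_original_point_recorded_at_corr_one(self):
        scaled, y = separable_toy(seed=1)
        res = permutation_test(scaled, y, n_perm=20, seed=0)
        first = res.record.iloc[0]
        assert first["perm_id"] == 0
        assert first["corr"] == pytest.approx(1.0)
        assert first["q2"] == pytest.approx(res.original_q2)

    def test_informative_contrast_valid(self):
        scaled, y = separable_toy(seed=8)
        res = permutation_test(scaled, y, n_perm=40, seed=3)
        assert res.verdict
        assert res.q2_intercept < 0

    def test_n_perm_minimum(self):
        scaled, y = separable_toy()
        with pytest.raises(ValidationError):
            permutation_test(scaled, y, n_perm=10)

    def test_record_shape(self):
        scaled, y = separable_toy(seed=2)
        res = permutation_test(scaled, y, n_perm=20, seed=1)
        assert list(res.record.columns) == ["perm_id", "corr", "r2y", "q2"]
        assert len(res.record) == res.n_permutations + 1
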