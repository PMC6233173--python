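"""PLS fitting, prediction, metrics, cross-validation and index screening."""

import numpy as np
import pytest

import spectralsar as ss
from spectralsar.pls import PredictionSet


def ols_min_norm_predict(X_train, y_train, X_test):
    """Minimum-norm least-squares oracle on centred data (pseudo-inverse)."""
    x_mean = X_train.mean(axis=0)
    y_mean = y_train.mean()
    beta = np.linalg.pinv(X_train - x_mean) @ (y_train - y_mean)
    return y_mean + (X_test - x_mean) @ beta


class TestFitPredict:
    def test_perfect_linear_relation_one_component(self):
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([1.0, 2.0, 3.0])
        model = ss.fit_pls(X, y, n_components=1)
        np.testing.assert_allclose(model.fitted_values, y, atol=1e-12)

    def test_duplicated_columns_handled_by_one_component(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        y = 2.0 * X[:, 0] + 1.0
        model = ss.fit_pls(X, y, n_components=1)
        assert ss.r_squared(y=y, y_hat=model.fitted_values) == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_full_components_match_ols_oracle(self, rng, trial):
        n, p = 6, 4
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        model = ss.fit_pls(X, y, n_components=min(n - 1, p))
        X_new = rng.normal(size=(3, p))
        np.testing.assert_allclose(
            ss.predict(model, X_new), ols_min_norm_predict(X, y, X_new), atol=1e-6
        )

    def test_training_predictions_reproduce_fitted_values(self, rng):
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        model = ss.fit_pls(X, y, n_components=3)
        np.testing.assert_allclose(
            ss.predict(model, X), model.fitted_values, atol=1e-9
        )

    def test_row_at_feature_mean_predicts_response_mean(self, rng):
        X = rng.normal(size=(7, 4))
        y = rng.normal(size=7)
        model = ss.fit_pls(X, y, n_components=2)
        assert ss.predict(model, X.mean(axis=0))[0] == pytest.approx(y.mean())

    def test_agrees_with_sklearn_nipals(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        for a in (1, 2, 4):
            mine = ss.fit_pls(X, y, n_components=a)
            ref = sklearn.PLSRegression(n_components=a, scale=False).fit(X, y)
            np.testing.assert_allclose(
                mine.fitted_values, ref.predict(X).ravel(), atol=1e-8
            )

    def test_zero_variance_response_rejected(self):
        X = np.arange(6.0).reshape(3, 2)
        with pytest.raises(ValueError, match="zero-variance"):
            ss.fit_pls(X, np.ones(3), n_components=1)

    @pytest.mark.parametrize("bad", [0, 3, 10])
    def test_out_of_bounds_components_rejected(self, bad):
        X = np.arange(8.0).reshape(4, 2)
        y = np.array([1.0, 2.0, 3.0, 5.0])
        with pytest.raises(ValueError, match="n_components"):
            ss.fit_pls(X, y, n_components=bad)

    def test_feature_count_mismatch_rejected(self, rng):
        model = ss.fit_pls(rng.normal(size=(5, 3)), rng.normal(size=5), 2)
        with pytest.raises(ValueError, match="feature count"):
            ss.predict(model, rng.normal(size=(2, 4)))


class TestMetrics:
    def test_identity_prediction_scores_one(self):
        y = np.array([1.0, 2.0, 3.0])
        assert ss.r_squared(y=y, y_hat=y) == pytest.approx(1.0)
        assert ss.rmse(y=y, y_hat=y) == 0.0

    def test_squared_pearson_is_affine_invariant(self):
        y = np.array([1.0, 2.0, 3.0])
        assert ss.r_squared(y=y, y_hat=2 * y) == pytest.approx(1.0)
        assert ss.r_squared(y=y, y_hat=3 * y - 5) == pytest.approx(1.0)

    def test_squared_pearson_rewards_anticorrelation(self):
        # documented caveat of the squared-correlation formula
        y = np.array([1.0, 2.0, 3.0])
        assert ss.r_squared(y=y, y_hat=y[::-1].copy()) == pytest.approx(1.0)
        assert ss.r2_residual(y=y, y_hat=y[::-1].copy()) < 1.0

    def test_rmse_hand_example(self):
        assert ss.rmse(y=np.zeros(2), y_hat=np.array([3.0, 4.0])) == pytest.approx(
            np.sqrt(12.5)
        )

    def test_rmse_scales_homogeneously_but_r2_does_not_change(self, rng):
        y = rng.normal(size=10)
        y_hat = y + rng.normal(size=10)
        base = ss.rmse(y=y, y_hat=y_hat)
        scaled = ss.rmse(y=y, y_hat=y + 3 * (y_hat - y))
        assert scaled == pytest.approx(3 * base)

    def test_zero_variance_prediction_flagged_nan(self):
        y = np.array([1.0, 2.0, 3.0])
        with pytest.warns(RuntimeWarning):
            assert np.isnan(ss.r_squared(y=y, y_hat=np.ones(3)))


class TestCrossValidation:
    def test_loocv_on_collinear_points_recovers_line(self):
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([1.0, 2.0, 3.0])
        report = ss.cross_validate(X, y, n_components=1, scheme="loocv")
        np.testing.assert_allclose(report.pooled.y_hat, y, atol=1e-9)
        assert report.r2 == pytest.approx(1.0)

    def test_loocv_pools_one_prediction_per_sample(self, rng):
        X = rng.normal(size=(9, 4))
        y = rng.normal(size=9)
        report = ss.cross_validate(X, y, n_components=2)
        assert report.pooled.n == 9

    def test_loocv_invariant_to_sample_ordering(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        base = ss.cross_validate(X, y, n_components=2)
        perm = rng.permutation(8)
        shuffled = ss.cross_validate(X[perm], y[perm], n_components=2)
        np.testing.assert_allclose(
            shuffled.pooled.y_hat[np.argsort(perm)], base.pooled.y_hat, atol=1e-10
        )

    def test_kfold_with_fixed_seed_is_reproducible(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        a = ss.cross_validate(X, y, n_components=2, scheme="kfold", k=5, seed=3)
        b = ss.cross_validate(X, y, n_components=2, scheme="kfold", k=5, seed=3)
        np.testing.assert_array_equal(a.pooled.y_hat, b.pooled.y_hat)
        assert a.scheme == "kfold(5)"

    def test_infeasible_components_for_smallest_fold_rejected(self, rng):
        X = rng.normal(size=(4, 10))
        y = rng.normal(size=4)
        with pytest.raises(ValueError, match="infeasible"):
            ss.cross_validate(X, y, n_components=3, scheme="loocv")


class TestComponentSelection:
    def test_one_latent_direction_selects_one_component(self, rng):
        n, p = 20, 6
        t = rng.normal(size=n)
        X = np.outer(t, rng.normal(size=p)) + 0.01 * rng.normal(size=(n, p))
        y = 2.0 * t + 0.01 * rng.normal(size=n)
        assert ss.select_components(X, y, max_components=5) == 1

    def test_max_one_returns_one(self, rng):
        X = rng.normal(size=(8, 4))
        y = rng.normal(size=8)
        assert ss.select_components(X, y, max_components=1) == 1

    def test_selection_never_exceeds_cap(self, rng):
        X = rng.normal(size=(8, 4))
        y = rng.normal(size=8)
        assert ss.select_components(X, y, max_components=10) <= 4


class TestScreening:
    def test_generating_index_ranks_first(self):
        """Activity built from one index's spectra singles that index out."""
        generating = ss.make_fixture_index(seed=1)
        decoys = [ss.make_fixture_index(seed=s) for s in (2, 3, 4, 5)]
        cfg = ss.LandscapeConfig(n_mutations=4, wt_length=30, sigma=0.0, seed=9)
        land = ss.simulate_landscape(cfg)
        seqs = [
            ss.apply_genotype(land.wt_sequence, g) for g in land.genotypes
        ]
        fm = ss.encode_dataset(seqs, land.variants["id"], generating, mode="fft")
        weights = np.linspace(0.5, 1.5, fm.n_features)
        y = fm.values @ weights / fm.values.shape[1]
        table = ss.screen_indices(
            seqs, land.variants["id"], y, [*decoys, generating], mode="fft"
        )
        assert table.iloc[0]["accession"] == generating.accession

    def test_degenerate_index_skipped(self, toy_index, caplog):
        # an index assigning equal values to the residues that differ
        # between the variants yields identical rows and must be skipped
        degenerate = ss.EncodingIndex(
            accession="DEGEN00001",
            values={aa: (5.0 if aa in "CGN" else float(i)) for i, aa in enumerate(ss.AA_ORDER)},
        )
        seqs = ["ACD", "AGD", "AND"]
        y = np.array([1.0, 2.0, 1.5])
        table = ss.screen_indices(
            seqs, ["a", "b", "c"], y, [toy_index, degenerate], mode="no_fft",
            max_components=1,
        )
        assert table["accession"].tolist() == [toy_index.accession]

    def test_single_index_gives_one_row(self, toy_index):
        seqs = ["ACD", "AGD", "AND"]
        y = np.array([1.0, 2.0, 1.5])
        table = ss.screen_indices(
            seqs, ["a", "b", "c"], y, [toy_index], mode="no_fft", max_components=1
        )
        assert len(table) == 1
        assert set(table.columns) >= {
            "accession",
            "n_components",
            "loocv_r2",
            "loocv_rmse",
            "full_set_r2",
            "full_set_rmse",
        }

    def test_empty_usable_db_rejected(self):
        constant = ss.EncodingIndex(
            accession="CONST00001", values={aa: 0.5 for aa in ss.AA_ORDER}
        )
        with pytest.raises(ValueError, match="usable"):
            ss.screen_indices(["ACD"], ["a"], [1.0], [constant])


class TestAdditivityTheorem:
    def test_no_fft_interpolating_model_predicts_additively(self, additive_landscape):
        """Linear features + interpolating fit = exactly additive predictions.

        Trained on the wild type and the 9 single mutants only, the
        no-FFT model reproduces the additive baseline for all 512
        genotypes, including on landscapes whose observed activities are
        epistatic (the model can only ever see the additive component).
        """
        from conftest import singles_subtable

        land = additive_landscape
        train = singles_subtable(land)
        index = ss.make_fixture_index(seed=11)
        model = ss.SequenceActivityModel.from_variant_table(
            land.wt_sequence, train, index, mode="no_fft"
        )
        res = model.fit(n_components=len(train) - 1)
        preds = res.predict_genotypes(land.genotypes)
        additive = res.additive_baseline(land.genotypes)
        np.testing.assert_allclose(preds, additive, atol=1e-6)
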