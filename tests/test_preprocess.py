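"""SMOTE, symmetric [-1, 1] scaling, and variance-retained PCA, with
brute-force nearest-neighbor and independent eigensolver oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from tonguelab import (
    LabeledDatasetSpec,
    SMOTE,
    SymmetricMinMaxScaler,
    VarianceRetainedPCA,
    make_feature_dataset,
)
from tonguelab.preprocess import smote_balance


def brute_force_knn(X, i, k):
    """Indices of the k nearest rows to X[i] (self excluded), Euclidean."""
    d = np.linalg.norm(X - X[i], axis=1)
    d[i] = np.inf
    return set(np.argsort(d, kind="stable")[:k])


class TestSmote:
    def test_study_counts_balanced_exactly(self):
        """296/531 in -> 531/531 out."""
        df = make_feature_dataset(LabeledDatasetSpec(n_minority=296, n_majority=531, seed=0))
        out = smote_balance(df, seed=0)
        counts = out["label"].value_counts()
        assert counts[0] == 531 and counts[1] == 531
        assert out["synthetic"].sum() == 531 - 296

    def test_balanced_input_is_noop(self):
        df = make_feature_dataset(LabeledDatasetSpec(n_minority=50, n_majority=50, seed=1))
        sm = SMOTE(random_state=0)
        X, y = sm.fit_resample(df.drop(columns="label"), df["label"], target=50)
        assert len(X) == 100 and not sm.synthetic_.any()
        assert np.allclose(X.to_numpy(), df.drop(columns="label").to_numpy())

    def test_originals_preserved_and_determinism(self):
        df = make_feature_dataset(LabeledDatasetSpec(n_minority=30, n_majority=80, seed=2))
        X0 = df.drop(columns="label")
        sm = SMOTE(random_state=5)
        Xa, ya = sm.fit_resample(X0, df["label"])
        Xb, yb = SMOTE(random_state=5).fit_resample(X0, df["label"])
        assert np.allclose(Xa.to_numpy(), Xb.to_numpy()) and (ya == yb).all()
        assert np.allclose(Xa.to_numpy()[: len(df)], X0.to_numpy())

    def test_synthetics_lie_on_neighbor_segments(self):
        """Every synthetic point is a convex combination of a minority point
        and one of its k=5 brute-force nearest minority neighbors (distances
        on the min-max scaled copy, as generated)."""
        df = make_feature_dataset(
            LabeledDatasetSpec(n_minority=40, n_majority=90, n_features=4, seed=3)
        )
        X = df.drop(columns="label").to_numpy()
        y = df["label"].to_numpy()
        sm = SMOTE(k_neighbors=5, random_state=1)
        X_out, y_out = sm.fit_resample(X, y)
        X_min = X[y == 1]
        lo, hi = X_min.min(axis=0), X_min.max(axis=0)
        X_min_scaled = (X_min - lo) / np.where(hi > lo, hi - lo, 1.0)
        synth = X_out[sm.synthetic_]
        for s in synth:
            ok = False
            for i in range(len(X_min)):
                for j in brute_force_knn(X_min_scaled, i, 5):
                    seg = X_min[j] - X_min[i]
                    rel = s - X_min[i]
                    denom = seg[np.abs(seg) > 1e-12]
                    if len(denom) == 0:
                        continue
                    u = (rel[np.abs(seg) > 1e-12] / denom)
                    if np.allclose(u, u[0], atol=1e-8) and -1e-9 <= u[0] <= 1 + 1e-9:
                        ok = True
                        break
                if ok:
                    break
            assert ok, f"synthetic point {s} is on no minority neighbor segment"

    def test_minority_too_small_for_k(self):
        df = make_feature_dataset(LabeledDatasetSpec(n_minority=4, n_majority=20, seed=4))
        with pytest.raises(ValueError, match="smaller k"):
            SMOTE(k_neighbors=5).fit_resample(df.drop(columns="label"), df["label"])

    def test_integer_columns_rounded(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            {"gender": rng.integers(0, 2, 60).astype(float), "x": rng.normal(size=60)}
        )
        y = np.r_[np.ones(20, int), np.zeros(40, int)]
        Xo, _ = SMOTE(random_state=0, integer_columns=("gender",)).fit_resample(X, y)
        assert np.all(Xo["gender"] == np.rint(Xo["gender"]))


class TestScaler:
    def test_affine_endpoints(self):
        X = np.array([[2.0], [6.0], [10.0]])
        out = SymmetricMinMaxScaler().fit(X).transform(X)
        assert np.allclose(out.ravel(), [-1.0, 0.0, 1.0])

    def test_constant_feature_maps_to_zero(self):
        X = np.array([[3.0, 1.0], [3.0, 2.0], [3.0, 3.0]])
        out = SymmetricMinMaxScaler().fit(X).transform(X)
        assert np.all(out[:, 0] == 0.0)

    def test_extrapolation_not_clipped(self):
        scaler = SymmetricMinMaxScaler().fit(np.array([[2.0], [10.0]]))
        assert scaler.transform(np.array([[12.0]]))[0, 0] == pytest.approx(1.5)

    def test_training_data_in_unit_interval(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 7)) * rng.uniform(0.1, 100, 7)
        out = SymmetricMinMaxScaler().fit(X).transform(X)
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_json_round_trip(self):
        X = np.random.default_rng(2).normal(size=(20, 3))
        scaler = SymmetricMinMaxScaler().fit(X)
        clone = SymmetricMinMaxScaler.from_dict(scaler.to_dict())
        assert np.allclose(scaler.transform(X), clone.transform(X))


class TestPca:
    def test_rank_one_data_single_component(self):
        rng = np.random.default_rng(3)
        direction = rng.normal(size=6)
        X = np.outer(rng.normal(size=100), direction)
        pca = VarianceRetainedPCA(retain=0.95).fit(X)
        assert pca.n_components_ == 1

    def test_isotropic_gaussian_needs_19_of_20(self):
        """Equal population eigenvalues: 19 components to reach 95%,
        checked against an independent eigensolver."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(4000, 20))
        pca = VarianceRetainedPCA(retain=0.95).fit(X)
        evals = np.sort(scipy.linalg.eigh(np.cov(X.T), eigvals_only=True))[::-1]
        ratios = evals / evals.sum()
        k_oracle = int(np.searchsorted(np.cumsum(ratios), 0.95 - 1e-12) + 1)
        assert k_oracle == 19
        assert pca.n_components_ == k_oracle
        assert np.allclose(
            pca.all_explained_variance_ratio_, ratios, atol=1e-10
        )

    def test_retained_variance_and_reconstruction_bound(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 12)) @ np.diag(np.linspace(0.2, 3.0, 12))
        pca = VarianceRetainedPCA(retain=0.95).fit(X)
        assert pca.explained_variance_ratio_.sum() >= 0.95
        Z = pca.transform(X)
        recon = Z @ pca.components_ + pca.mean_
        total_var = ((X - X.mean(0)) ** 2).sum()
        assert ((X - recon) ** 2).sum() <= (1 - 0.95) * total_var + 1e-9

    def test_components_orthonormal_and_projections_decorrelated(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 8)) @ rng.normal(size=(8, 8))
        pca = VarianceRetainedPCA(retain=0.95).fit(X)
        gram = pca.components_ @ pca.components_.T
        assert np.allclose(gram, np.eye(pca.n_components_), atol=1e-8)
        cov = np.cov(pca.transform(X).T)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-8

    def test_more_features_than_samples_warns_and_caps(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 30))
        with pytest.warns(UserWarning, match="rank"):
            pca = VarianceRetainedPCA(retain=0.999).fit(X)
        assert pca.n_components_ <= 10

    def test_no_leakage_train_only_fit(self):
        """Applying the fitted scaler+PCA to a held-out copy of the training
        rows gives identical output (fit state frozen)."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 5))
        scaler = SymmetricMinMaxScaler().fit(X)
        pca = VarianceRetainedPCA().fit(scaler.transform(X))
        a = pca.transform(scaler.transform(X.copy()))
        b = pca.transform(scaler.transform(X))
        assert np.array_equal(a, b)
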