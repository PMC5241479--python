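"""Class balancing, feature scaling, and dimension reduction.

The study population is imbalanced (diabetes-analog minority vs. control
majority), so the training set is balanced with SMOTE before model fitting.
Features are then mapped to [-1, 1] by a symmetric min-max scaler fitted on
training data only, and reduced with PCA keeping the smallest number of
components that explains at least 95% of the variance.

All three steps are scikit-learn-style estimators (``fit`` /
``transform`` or ``fit_resample``) so they compose with pipelines and model
selection; the module-level functions are thin wrappers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "SMOTE",
    "SymmetricMinMaxScaler",
    "VarianceRetainedPCA",
    "smote_balance",
    "fit_scaler",
    "apply_scaler",
    "fit_pca",
    "apply_pca",
]


class SMOTE(BaseEstimator):
    """Synthetic Minority Oversampling Technique.

    Each synthetic minority sample is ``x + u * (x_nn - x)`` with
    ``u ~ Uniform(0, 1)`` and ``x_nn`` one of the ``k_neighbors`` nearest
    minority neighbors of ``x`` (Euclidean distance computed on a min-max
    scaled copy so no single feature dominates; interpolation happens on the
    raw features).  A non-integer oversampling rate is hit exactly: every
    minority point contributes ``floor(rate)`` synthetics and a seeded random
    subset contributes one more.

    Parameters
    ----------
    k_neighbors : int
        Number of nearest minority neighbors to interpolate towards.
    random_state : int
        Seed for neighbor choice, interpolation weights, and the extra
        subset.
    integer_columns : sequence of str, optional
        Columns (e.g. a 0/1 gender code) rounded to the nearest integer
        after interpolation.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int = 0, integer_columns=()):
        self.k_neighbors = k_neighbors
        self.random_state = random_state
        self.integer_columns = integer_columns

    def fit_resample(self, X, y, target: int | None = None):
        """Oversample the minority class of (X, y) up to ``target`` rows.

        ``target`` defaults to the majority count.  Returns ``(X_out,
        y_out)`` with all original rows first, synthetic rows appended;
        ``self.synthetic_`` flags the synthetic rows.
        """
        is_frame = isinstance(X, pd.DataFrame)
        cols = list(X.columns) if is_frame else None
        Xa = np.asarray(X, dtype=float)
        ya = np.asarray(y).astype(int)
        classes, counts = np.unique(ya, return_counts=True)
        if len(classes) != 2:
            raise ValueError("SMOTE expects exactly two classes")
        minority = classes[np.argmin(counts)]
        n_min, n_maj = counts.min(), counts.max()
        if target is None:
            target = int(n_maj)
        if target < n_min:
            raise ValueError("target must be >= the minority count")
        if n_min < self.k_neighbors + 1:
            raise ValueError(
                f"minority class has {n_min} samples, too few for "
                f"k_neighbors={self.k_neighbors}; use a smaller k"
            )

        n_new = int(target - n_min)
        self.synthetic_ = np.zeros(len(ya) + n_new, dtype=bool)
        if n_new == 0:
            self.synthetic_ = np.zeros(len(ya), dtype=bool)
            return (X.copy() if is_frame else Xa.copy()), ya.copy()

        rng = np.random.default_rng(self.random_state)
        X_min = Xa[ya == minority]

        # neighbor search on a [0, 1]-scaled copy
        lo, hi = X_min.min(axis=0), X_min.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        X_scaled = (X_min - lo) / span
        nn = NearestNeighbors(n_neighbors=self.k_neighbors + 1).fit(X_scaled)
        neighbor_idx = nn.kneighbors(X_scaled, return_distance=False)[:, 1:]

        per_point = np.full(n_min, n_new // n_min, dtype=int)
        extra = n_new % n_min
        if extra:
            per_point[rng.choice(n_min, size=extra, replace=False)] += 1

        synth = []
        for i in range(n_min):
            for _ in range(per_point[i]):
                j = neighbor_idx[i, rng.integers(0, self.k_neighbors)]
                u = rng.random()
                synth.append(X_min[i] + u * (X_min[j] - X_min[i]))
        synth = np.asarray(synth)

        X_out = np.vstack([Xa, synth])
        y_out = np.concatenate([ya, np.full(n_new, minority, dtype=int)])
        self.synthetic_[len(ya):] = True
        if is_frame:
            X_out = pd.DataFrame(X_out, columns=cols)
            for c in self.integer_columns:
                if c in X_out.columns:
                    X_out[c] = np.rint(X_out[c])
        elif self.integer_columns:
            for c in self.integer_columns:
                X_out[:, int(c)] = np.rint(X_out[:, int(c)])
        return X_out, y_out


class SymmetricMinMaxScaler(BaseEstimator, TransformerMixin):
    """Map each feature affinely so the training range becomes [-1, 1].

    ``x' = 2 (x - min) / (max - min) - 1``; features constant on the
    training data map to 0.  Test values outside the training range
    extrapolate beyond [-1, 1] (no clipping).
    """

    def fit(self, X, y=None):
        Xa = np.asarray(X, dtype=float)
        self.data_min_ = Xa.min(axis=0)
        self.data_max_ = Xa.max(axis=0)
        self.n_features_in_ = Xa.shape[1]
        return self

    def transform(self, X):
        Xa = np.asarray(X, dtype=float)
        span = self.data_max_ - self.data_min_
        constant = span <= 0
        span = np.where(constant, 1.0, span)
        out = 2.0 * (Xa - self.data_min_) / span - 1.0
        out[:, constant] = 0.0
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, columns=X.columns, index=X.index)
        return out

    def to_dict(self) -> dict:
        return {
            "data_min": self.data_min_.tolist(),
            "data_max": self.data_max_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SymmetricMinMaxScaler":
        obj = cls()
        obj.data_min_ = np.asarray(d["data_min"], dtype=float)
        obj.data_max_ = np.asarray(d["data_max"], dtype=float)
        obj.n_features_in_ = len(obj.data_min_)
        return obj


class VarianceRetainedPCA(BaseEstimator, TransformerMixin):
    """PCA keeping the fewest components whose cumulative explained-variance
    ratio reaches ``retain`` (default 0.95).

    The projection is centering followed by multiplication with the retained
    orthonormal components.  When there are fewer samples than features the
    component count is capped at the data rank, with a warning.
    """

    def __init__(self, retain: float = 0.95):
        self.retain = retain

    def fit(self, X, y=None):
        if not 0.0 < self.retain <= 1.0:
            raise ValueError("retain must lie in (0, 1]")
        Xa = np.asarray(X, dtype=float)
        n, d = Xa.shape
        if n < d:
            warnings.warn(
                f"fewer samples ({n}) than features ({d}); "
                "component count capped at the data rank",
                stacklevel=2,
            )
        self._pca = PCA(n_components=min(n, d), svd_solver="full").fit(Xa)
        ratios = self._pca.explained_variance_ratio_
        cum = np.cumsum(ratios)
        self.n_components_ = int(np.searchsorted(cum, self.retain - 1e-12) + 1)
        self.n_components_ = min(self.n_components_, len(ratios))
        self.mean_ = self._pca.mean_
        self.components_ = self._pca.components_[: self.n_components_]
        self.explained_variance_ratio_ = ratios[: self.n_components_]
        self.all_explained_variance_ratio_ = ratios
        return self

    def transform(self, X):
        Xa = np.asarray(X, dtype=float)
        out = (Xa - self.mean_) @ self.components_.T
        if isinstance(X, pd.DataFrame):
            cols = [f"pc{i + 1}" for i in range(self.n_components_)]
            return pd.DataFrame(out, columns=cols, index=X.index)
        return out

    def to_dict(self) -> dict:
        return {
            "mean": self.mean_.tolist(),
            "components": self.components_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "n_components": self.n_components_,
            "retain": self.retain,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VarianceRetainedPCA":
        obj = cls(retain=d.get("retain", 0.95))
        obj.mean_ = np.asarray(d["mean"], dtype=float)
        obj.components_ = np.asarray(d["components"], dtype=float)
        obj.explained_variance_ratio_ = np.asarray(
            d["explained_variance_ratio"], dtype=float
        )
        obj.n_components_ = int(d["n_components"])
        return obj


def smote_balance(table: pd.DataFrame, k_neighbors=5, target=None, seed=0,
                  label_col="label", integer_columns=("gender",)):
    """Balance a labeled feature table; returns the table with a
    ``synthetic`` flag column appended."""
    X = table.drop(columns=[label_col])
    y = table[label_col]
    sm = SMOTE(k_neighbors=k_neighbors, random_state=seed,
               integer_columns=integer_columns)
    X_out, y_out = sm.fit_resample(X, y, target=target)
    out = X_out.copy()
    out[label_col] = y_out
    out["synthetic"] = sm.synthetic_
    return out


def fit_scaler(train: pd.DataFrame) -> SymmetricMinMaxScaler:
    return SymmetricMinMaxScaler().fit(train)


def apply_scaler(model: SymmetricMinMaxScaler, table):
    return model.transform(table)


def fit_pca(train, retain: float = 0.95) -> VarianceRetainedPCA:
    return VarianceRetainedPCA(retain=retain).fit(train)


def apply_pca(model: VarianceRetainedPCA, table):
    return model.transform(table)
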