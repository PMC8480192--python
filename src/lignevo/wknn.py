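"""Weighted k-nearest-neighbor lifestyle classification with LOOCV tuning.

The classifier mirrors the kknn-style algorithm: features are z-scored
(parameters learned from the training fold), distances are Minkowski with
exponent ``d``, the k+1-th neighbor's distance normalizes the k nearest
(u_i = dist_i / dist_(k+1)), a kernel turns u into a weight, and the
predicted class maximizes the class-summed weights.  Tuning evaluates a
grid of k = 1..25, six kernels and d in {1, 2} — 300 candidate models — by
leave-one-out cross-validation and keeps the most accurate one
(deterministic tie-break: smaller k, kernel order as listed, smaller d).
The fitted model applied to birth-death-reconstructed ancestral gene
counts yields lifestyle calls for the internal nodes of the species tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KERNELS",
    "WknnModel",
    "TuningResult",
    "wknn_predict",
    "loocv_accuracy",
    "tune",
    "predict_ancestral_lifestyles",
]

KERNELS = ("rectangular", "triangular", "epanechnikov", "gaussian",
           "rank", "optimal")


def _kernel_weights(u: np.ndarray, kernel: str, k: int, dim: int) -> np.ndarray:
    """Weights for the k nearest neighbors given normalized distances u."""
    u = np.minimum(u, 1.0)
    if kernel == "rectangular":
        return np.full_like(u, 0.5)
    if kernel == "triangular":
        return 1.0 - u
    if kernel == "epanechnikov":
        return 0.75 * (1.0 - u ** 2)
    if kernel == "gaussian":
        return np.exp(-(u ** 2) / 2.0)
    if kernel == "rank":
        return np.clip((k + 1) - (np.arange(len(u)) + 1.0), 0.0, None)
    if kernel == "optimal":
        # Samworth-optimal weights on neighbor ranks, clipped at zero
        i = np.arange(1, len(u) + 1, dtype=float)
        dd = float(dim)
        w = (1.0 / k) * (1.0 + dd / 2.0
                         - dd / (2.0 * k ** (2.0 / dd))
                         * (i ** (1.0 + 2.0 / dd) - (i - 1.0) ** (1.0 + 2.0 / dd)))
        return np.clip(w, 0.0, None)
    raise ValueError(f"unknown kernel {kernel!r}")


@dataclass
class WknnModel:
    """A fitted weighted-kNN model: hyperparameters, feature scaling
    learned from the training data, and the training set itself."""

    k: int
    kernel: str
    d: float
    features: list[str]
    scale: bool = True
    mean_: np.ndarray | None = None
    std_: np.ndarray | None = None
    train_X_: np.ndarray | None = None
    train_y_: np.ndarray | None = None
    classes_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.d < 1:
            raise ValueError("Minkowski exponent d must be >= 1")
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")

    # -- fitting ------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "WknnModel":
        X = X[self.features]
        y = y.reindex(X.index)
        if y.isna().any():
            raise ValueError("label missing for some training rows")
        if len(X) < self.k + 1:
            raise ValueError("training set smaller than k+1")
        M = X.to_numpy(float)
        if self.scale:
            self.mean_ = M.mean(axis=0)
            sd = M.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            self.std_ = sd
        else:
            self.mean_ = np.zeros(M.shape[1])
            self.std_ = np.ones(M.shape[1])
        self.train_X_ = (M - self.mean_) / self.std_
        self.train_y_ = y.to_numpy()
        self.classes_ = sorted(set(self.train_y_))
        return self

    # -- prediction ---------------------------------------------------------

    def _check_fitted(self) -> None:
        if self.train_X_ is None:
            raise RuntimeError("model is not fitted")

    def predict_one(self, x) -> tuple[str, dict[str, float]]:
        """Predict one query vector; returns (label, per-class weights)."""
        self._check_fitted()
        q = (np.asarray(x, float) - self.mean_) / self.std_
        diff = np.abs(self.train_X_ - q)
        dist = (diff ** self.d).sum(axis=1) ** (1.0 / self.d)
        order = np.argsort(dist, kind="stable")
        k = self.k
        d_norm = dist[order[k]] if len(dist) > k else dist[order[-1]]
        near = order[:k]
        # when the k-th and (k+1)-th distances tie, the cutoff is ambiguous:
        # every point at that distance joins with u = 1
        if (len(dist) > k and d_norm > 0
                and np.isclose(dist[order[k - 1]], d_norm, rtol=1e-12)):
            tied = np.array([i for i in order[k:]
                             if np.isclose(dist[i], d_norm, rtol=1e-12)], int)
        else:
            tied = np.array([], int)
        if d_norm > 0:
            u = dist[near] / d_norm
        else:
            u = np.zeros(k)
        idx = np.concatenate([near, tied]).astype(int)
        u_all = np.concatenate([u, np.ones(len(tied))])
        wts = _kernel_weights(u_all, self.kernel, k, len(self.features))
        weights = {c: 0.0 for c in self.classes_}
        for i, wt in zip(idx, wts):
            weights[self.train_y_[i]] += float(wt)
        if all(v == 0 for v in weights.values()):
            best = self.train_y_[order[0]]  # kernel vanished: plain 1-NN
        else:
            top = max(weights.values())
            best = sorted(c for c in self.classes_ if weights[c] == top)[0]
        return best, weights

    def predict(self, X: pd.DataFrame) -> pd.Series:
        X = X[self.features]
        labels = [self.predict_one(row)[0] for _, row in X.iterrows()]
        return pd.Series(labels, index=X.index, name="lifestyle")

    def predict_weights(self, X: pd.DataFrame) -> pd.DataFrame:
        X = X[self.features]
        rows = [self.predict_one(row)[1] for _, row in X.iterrows()]
        return pd.DataFrame(rows, index=X.index)


def wknn_predict(train_X: pd.DataFrame, train_y: pd.Series, query_x,
                 k: int = 5, kernel: str = "rectangular", d: float = 1.0,
                 scale: bool = True) -> tuple[str, dict[str, float]]:
    """One-shot prediction: fit on the training set, classify one query."""
    model = WknnModel(k=k, kernel=kernel, d=d,
                      features=list(train_X.columns), scale=scale)
    model.fit(train_X, train_y)
    return model.predict_one(query_x)


def loocv_accuracy(X: pd.DataFrame, y: pd.Series, k: int, kernel: str,
                   d: float, scale: bool = True) -> float:
    """Leave-one-out accuracy; scaling is re-learned inside every fold."""
    y = y.reindex(X.index)
    n = len(X)
    if n < k + 2:
        raise ValueError("need at least k+2 points for LOOCV")
    hits = 0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        model = WknnModel(k=k, kernel=kernel, d=d,
                          features=list(X.columns), scale=scale)
        model.fit(X.iloc[mask], y.iloc[mask])
        pred, _ = model.predict_one(X.iloc[i].to_numpy(float))
        hits += int(pred == y.iloc[i])
    return hits / n


@dataclass
class TuningResult:
    """LOOCV accuracy grid and the selected, fully fitted model."""

    grid: pd.DataFrame          # columns k, kernel, d, accuracy
    model: WknnModel
    best_accuracy: float

    @property
    def n_models(self) -> int:
        return len(self.grid)


def tune(X: pd.DataFrame, y: pd.Series,
         ks=range(1, 26), kernels=KERNELS, ds=(1.0, 2.0),
         scale: bool = True) -> TuningResult:
    """Evaluate the k x kernel x d grid by LOOCV and keep the best model.

    The default grid is 25 x 6 x 2 = 300 candidate models.  Ties resolve
    to the smaller k, then the kernel order of ``KERNELS``, then smaller d.
    """
    rows = []
    for k in ks:
        for kern in kernels:
            for d in ds:
                acc = loocv_accuracy(X, y, k=k, kernel=kern, d=d, scale=scale)
                rows.append((int(k), kern, float(d), acc))
    grid = pd.DataFrame(rows, columns=["k", "kernel", "d", "accuracy"])
    kern_rank = {kk: i for i, kk in enumerate(kernels)}
    best = min(range(len(grid)),
               key=lambda i: (-grid.accuracy[i], grid.k[i],
                              kern_rank[grid.kernel[i]], grid.d[i]))
    row = grid.iloc[best]
    model = WknnModel(k=int(row.k), kernel=row.kernel, d=float(row.d),
                      features=list(X.columns), scale=scale)
    model.fit(X, y)
    return TuningResult(grid=grid, model=model,
                        best_accuracy=float(row.accuracy))


def predict_ancestral_lifestyles(model: WknnModel,
                                 ancestral_counts: pd.DataFrame
                                 ) -> tuple[pd.Series, pd.DataFrame]:
    """Classify ancestral nodes from their reconstructed gene counts.

    ``ancestral_counts``: internal-node rows x family columns; must carry
    the model's feature families.  Returns the per-node labels and the
    per-node class-weight table for auditability.
    """
    missing = set(model.features) - set(ancestral_counts.columns)
    if missing:
        raise ValueError(f"ancestral counts missing features: {sorted(missing)}")
    labels = model.predict(ancestral_counts)
    weights = model.predict_weights(ancestral_counts)
    return labels, weights
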