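"""Shared statistical machinery.

Shrinkage-regularized linear discriminant analysis (the workhorse
classifier for event-related potential features, where the feature
dimension rivals the epoch count), PCA dimensionality reduction, a
shuffle-based chance-level engine, and channel x time Wilcoxon maps
with Benjamini-Hochberg false-discovery control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.covariance import ledoit_wolf
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# shrinkage LDA
# ---------------------------------------------------------------------------


@dataclass
class SldaModel:
    """Binary LDA with Ledoit-Wolf shrinkage towards scaled identity.

    Posterior probabilities come from the Gaussian equal-covariance model,
    i.e. a logistic function of the discriminant score — calibrated, which
    matters because downstream detection rules threshold the posteriors.
    """

    classes_: np.ndarray      # (2,)
    means: np.ndarray         # (2, d)
    covariance: np.ndarray    # (d, d) shrunk pooled covariance
    shrinkage: float          # gamma in [0, 1]
    weights: np.ndarray       # (d,)
    bias: float
    priors: np.ndarray        # (2,)

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.weights + self.bias

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) posteriors for classes_ [0] and [1]; rows sum to 1."""
        p1 = 1.0 / (1.0 + np.exp(-np.clip(self.decision(X), -500, 500)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[(self.decision(X) > 0).astype(int)]

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def train_slda(features: np.ndarray, labels: np.ndarray,
               shrinkage: float | None = None) -> SldaModel:
    """Fit the shrinkage LDA.

    Parameters
    ----------
    features : (n, d) array.
    labels : binary labels (any two values).
    shrinkage : fixed shrinkage intensity; ``None`` (default) estimates it
        analytically (Ledoit-Wolf) from the pooled within-class data.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    mask1 = y == classes[1]
    mu = np.vstack([X[~mask1].mean(axis=0), X[mask1].mean(axis=0)])
    centered = X - mu[mask1.astype(int)]
    d = X.shape[1]
    if shrinkage is None:
        cov, gamma = ledoit_wolf(centered, assume_centered=True)
    else:
        gamma = float(shrinkage)
        S = centered.T @ centered / centered.shape[0]
        cov = (1.0 - gamma) * S + gamma * (np.trace(S) / d) * np.eye(d)
    priors = np.array([np.mean(~mask1), np.mean(mask1)])
    w = np.linalg.solve(cov, mu[1] - mu[0])
    b = float(-0.5 * (mu[0] + mu[1]) @ w + np.log(priors[1] / priors[0]))
    return SldaModel(classes_=classes, means=mu, covariance=cov,
                     shrinkage=float(gamma), weights=w, bias=b, priors=priors)


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------


def pca_reduce(features: np.ndarray, variance_target: float = 0.99,
               ) -> tuple[PCA, np.ndarray]:
    """Center and project onto the smallest basis explaining the target
    variance fraction. Returns the fitted (orthonormal) basis and the
    projected features."""
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must lie in (0, 1]")
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples for PCA")
    n_comp = None if variance_target == 1.0 else variance_target
    pca = PCA(n_components=n_comp, svd_solver="full")
    return pca, pca.fit_transform(X)


# ---------------------------------------------------------------------------
# shuffle-based chance levels
# ---------------------------------------------------------------------------


@dataclass
class ShuffleNullResult:
    """Null metric distribution from label shuffling inside a repeated CV."""

    values: dict[str, np.ndarray]   # per metric, length reps*folds*shuffles
    bounds: dict[str, float]        # requested percentile per metric
    percentile: float
    n_repetitions: int
    n_folds: int
    n_shuffles: int
    seed: int

    @property
    def n_iterations(self) -> int:
        return self.n_repetitions * self.n_folds * self.n_shuffles

    def to_csv(self, path) -> None:
        """Per-iteration null values, one column per metric."""
        import pandas as pd

        pd.DataFrame(self.values).to_csv(path, index=False)


def shuffle_null(labels: np.ndarray, evaluate, *, n_repetitions: int = 5,
                 n_folds: int = 5, n_shuffles: int = 20,
                 percentile: float = 95.0, seed: int = 0) -> ShuffleNullResult:
    """Chance-level engine: repeated stratified CV with shuffled labels.

    For every repetition x fold, the label vector is globally permuted
    ``n_shuffles`` times; ``evaluate(train_idx, test_idx, shuffled_labels,
    rng)`` retrains the model of interest and returns the test metric
    (a float, or a dict of named metrics). The requested upper percentile
    of each metric distribution is the chance bound. Bit-reproducible
    from the seed.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    collected: dict[str, list[float]] = {}
    for rep in range(n_repetitions):
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True,
                             random_state=int(rng.integers(0, 2 ** 31 - 1)))
        for train_idx, test_idx in cv.split(np.zeros(len(y)), y):
            for _ in range(n_shuffles):
                y_sh = y[rng.permutation(len(y))]
                out = evaluate(train_idx, test_idx, y_sh, rng)
                if not isinstance(out, dict):
                    out = {"metric": float(out)}
                for k, v in out.items():
                    collected.setdefault(k, []).append(float(v))
    values = {k: np.asarray(v) for k, v in collected.items()}
    bounds = {k: float(np.percentile(v, percentile)) for k, v in values.items()}
    return ShuffleNullResult(values=values, bounds=bounds, percentile=percentile,
                             n_repetitions=n_repetitions, n_folds=n_folds,
                             n_shuffles=n_shuffles, seed=seed)


def slda_accuracy_evaluator(X: np.ndarray):
    """Standard evaluate() for :func:`shuffle_null`: retrain the shrinkage LDA
    on the (shuffled) training labels, score accuracy on the test portion."""
    X = np.asarray(X, dtype=float)

    def evaluate(train_idx, test_idx, y_sh, rng):
        y_tr = y_sh[train_idx]
        if np.unique(y_tr).size < 2:
            return 0.5
        model = train_slda(X[train_idx], y_tr)
        return model.accuracy(X[test_idx], y_sh[test_idx])

    return evaluate


# ---------------------------------------------------------------------------
# Wilcoxon + Benjamini-Hochberg maps
# ---------------------------------------------------------------------------


def save_mask_tsv(path, mask: np.ndarray) -> None:
    """Write a channel x time significance mask as a 0/1 TSV matrix."""
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d", delimiter="\t")


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float).ravel(),
                         method="fdr_bh")[1].reshape(np.shape(pvals))


def wilcoxon_bh_map(cond_a: np.ndarray, cond_b: np.ndarray, alpha: float = 0.05,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired two-sided Wilcoxon signed-rank test per (channel, time) cell,
    with FDR control across all cells.

    Parameters are paired ``subjects x channels x time`` arrays. Returns
    ``(mask, p_adjusted, p_raw)`` with cell shape ``channels x time``;
    ``mask`` marks cells whose BH-adjusted p-value falls below ``alpha``.
    Zero differences are dropped (Wilcoxon convention); all-zero cells get
    p = 1.
    """
    A = np.asarray(cond_a, dtype=float)
    B = np.asarray(cond_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"paired arrays must share a shape, got {A.shape} vs {B.shape}")
    if A.ndim != 3:
        raise ValueError("expected subjects x channels x time arrays")
    if A.shape[0] < 5:
        raise ValueError("need at least 5 subjects for the paired test")
    n_sub, n_ch, n_t = A.shape
    p = np.ones((n_ch, n_t))
    diff = A - B
    for c in range(n_ch):
        for t in range(n_t):
            d = diff[:, c, t]
            if np.allclose(d, 0.0):
                continue
            p[c, t] = stats.wilcoxon(d, zero_method="wilcox",
                                     alternative="two-sided", method="auto").pvalue
    p_adj = bh_adjust(p)
    return p_adj < alpha, p_adj, p
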