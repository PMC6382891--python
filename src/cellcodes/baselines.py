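"""Dimensionality-reduction baselines with a shared encode/inverse interface.

Each reducer maps profiles to an ``n_components``-dimensional space (the
same width as a cell identity code) and back, so its reconstruction MSE is
directly comparable with an autoencoder's GEP-REP error.  Samples are the
observations, genes the features.

PCA and NMF have exact linear inverse maps.  The kernel PCAs have no exact
pre-image; inversion uses scikit-learn's learned ridge-regression pre-image
map fitted on the training projections, which is an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.decomposition import NMF, PCA, KernelPCA

from .expression import ExpressionMatrix

__all__ = ["ReducerSpec", "Reducer", "fit_transform", "inverse_transform", "METHODS"]

METHODS = ("pca", "nmf", "kpca_poly", "kpca_cosine", "kpca_rbf")


@dataclass
class ReducerSpec:
    """Which reducer to run and with what hyperparameters."""

    method: str = "pca"
    n_components: int = 30
    degree: int = 3  # polynomial kernel
    gamma: Optional[float] = None  # rbf kernel (None: 1/n_features)
    alpha: float = 1e-3  # ridge strength of the kernel pre-image map
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


class NotFittedError(RuntimeError):
    pass


class Reducer:
    """A fitted dimensionality reducer over expression profiles."""

    def __init__(self, spec: ReducerSpec):
        self.spec = spec
        self._est = None
        self._gene_ids: Optional[list] = None

    def fit(self, train: ExpressionMatrix) -> "Reducer":
        spec = self.spec
        n_obs, n_feat = train.n_samples, train.n_genes
        if spec.n_components > min(n_obs, n_feat):
            raise ValueError(
                f"n_components={spec.n_components} exceeds "
                f"min(n_samples={n_obs}, n_genes={n_feat})"
            )
        X = train.values.T  # samples x genes
        if spec.method == "pca":
            est = PCA(n_components=spec.n_components, random_state=spec.seed)
        elif spec.method == "nmf":
            if np.any(X < 0):
                raise ValueError(
                    "NMF requires non-negative input; min-max scale or shift "
                    "the matrix first"
                )
            est = NMF(
                n_components=spec.n_components,
                init="nndsvda",
                random_state=spec.seed,
                max_iter=2000,
                tol=1e-8,
            )
        else:
            kernel = {"kpca_poly": "poly", "kpca_cosine": "cosine", "kpca_rbf": "rbf"}[
                spec.method
            ]
            est = KernelPCA(
                n_components=spec.n_components,
                kernel=kernel,
                degree=spec.degree,
                gamma=spec.gamma,
                fit_inverse_transform=True,
                alpha=spec.alpha,
                random_state=spec.seed,
            )
        est.fit(X)
        self._est = est
        self._gene_ids = list(train.gene_ids)
        return self

    def _require_fitted(self):
        if self._est is None:
            raise NotFittedError("reducer is not fitted; call fit() first")

    def transform(self, m: ExpressionMatrix) -> np.ndarray:
        self._require_fitted()
        if list(m.gene_ids) != self._gene_ids:
            raise ValueError("gene ids differ from the training matrix")
        X = m.values.T
        if self.spec.method == "nmf":
            return self._est.transform(X)
        return self._est.transform(X)

    def inverse_transform(self, codes: np.ndarray, sample_ids=None) -> ExpressionMatrix:
        """Map codes back to expression space (the baseline's REPs)."""
        self._require_fitted()
        codes = np.atleast_2d(np.asarray(codes, dtype=float))
        if self.spec.method == "nmf":
            rec = codes @ self._est.components_
        else:
            rec = self._est.inverse_transform(codes)
        if sample_ids is None:
            sample_ids = [f"rep{i}" for i in range(rec.shape[0])]
        return ExpressionMatrix(rec.T, self._gene_ids, sample_ids)

    def reconstruction_mse(self, m: ExpressionMatrix) -> float:
        rep = self.inverse_transform(self.transform(m), sample_ids=m.sample_ids)
        return float(np.mean((rep.values - m.values) ** 2))


def fit_transform(
    spec: ReducerSpec, train: ExpressionMatrix, test: ExpressionMatrix
) -> np.ndarray:
    """Fit on `train` only, return the reduced test codes (samples x k)."""
    return Reducer(spec).fit(train).transform(test)


def inverse_transform(reducer: Reducer, codes: np.ndarray) -> ExpressionMatrix:
    return reducer.inverse_transform(codes)
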