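"""Covariance patterns of regional damage via independent component analysis.

Subjects x regions matrices (regional grey-matter volumes, or regional
disconnection proportions) are decomposed with FastICA into spatial
components: covarying sets of regions whose volumes or disconnection
levels rise and fall together across subjects. The fixed-point algorithm
runs in symmetric mode with the logcosh contrast (robust default),
tolerance 1e-4 and at most 200 iterations; data are column-centered and
whitened onto the top-n_components principal subspace first.

ICA signs and component order are arbitrary, so components are oriented
to make the largest-magnitude region loading positive, and
:func:`match_components` aligns an estimated set with a reference
(planted) set by maximum-|correlation| assignment. Variance explained is
defined on the whitening (PCA) subspace, since independent components do
not individually partition variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CovariancePatternICA",
    "ComponentSet",
    "fit_fastica",
    "variance_explained",
    "match_components",
]


@dataclass
class ComponentSet:
    """Fitted ICA decomposition of a subjects x regions matrix."""

    loadings: np.ndarray  # (n_components, n_regions), rows unit-norm
    scores: np.ndarray  # (n_subjects, n_components)
    mixing: np.ndarray  # (n_regions, n_components): X_centered ~ scores @ mixing.T
    whitening: np.ndarray  # (n_components, n_regions)
    mean: np.ndarray  # (n_regions,) column means removed before whitening
    variance_explained: float  # fraction captured by the whitening subspace
    converged: bool
    n_iter: int


class CovariancePatternICA(TransformerMixin, BaseEstimator):
    """FastICA transformer for regional neuroimaging feature matrices.

    Parameters
    ----------
    n_components : int
        Number of independent components (20 mirrors common neuroimaging
        practice for ~123-region parcellations).
    fun : str
        Contrast function; "logcosh" (alpha = 1).
    tol, max_iter : float, int
        Fixed-point convergence tolerance and iteration cap.
    random_state : int
        Seed for the initial unmixing matrix.

    Attributes (fitted)
    -------------------
    components_ : (n_components, n_regions) unit-norm region loadings,
        oriented so each component's largest-|loading| region is positive.
    mixing_ : (n_regions, n_components) mixing matrix on the same
        orientation; ``X - mean_ ~ scores @ mixing_.T``.
    variance_explained_ : fraction of centered variance in the whitening
        subspace.
    converged_, n_iter_ : fixed-point convergence flag and iterations.
    """

    def __init__(
        self,
        n_components: int = 20,
        fun: str = "logcosh",
        tol: float = 1e-4,
        max_iter: int = 200,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.fun = fun
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        n, d = X.shape
        if not 1 <= self.n_components <= min(n, d):
            raise ValueError(
                f"n_components={self.n_components} outside 1..min(n, d)={min(n, d)}"
            )
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        rank = np.linalg.matrix_rank(Xc)
        if self.n_components > rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds data rank {rank}"
            )
        ica = FastICA(
            n_components=self.n_components,
            algorithm="parallel",  # symmetric mode: all sources estimated jointly
            fun=self.fun,
            whiten="unit-variance",
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            scores = ica.fit_transform(Xc)
        self.converged_ = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
        self.n_iter_ = int(ica.n_iter_)

        comps = ica.components_  # (k, d) unmixing rows
        mixing = ica.mixing_  # (d, k)
        # orient: largest-|loading| region of each component positive
        load = mixing.T.copy()  # component loadings over regions
        signs = np.sign(load[np.arange(load.shape[0]), np.abs(load).argmax(axis=1)])
        signs[signs == 0] = 1.0
        load *= signs[:, None]
        scores = scores * signs[None, :]
        comps = comps * signs[:, None]
        mixing = mixing * signs[None, :]
        norms = np.linalg.norm(load, axis=1)
        norms[norms == 0] = 1.0
        self.components_ = load / norms[:, None]
        self.mixing_ = mixing
        self.unmixing_ = comps
        # rescale so whitened data (Xc @ whitening_.T) has unit variance
        self.whitening_ = ica.whitening_ * np.sqrt(n)
        self.scores_ = scores

        total_var = (Xc**2).sum()
        # variance in the top-k principal subspace used for whitening
        svals = np.linalg.svd(Xc, compute_uv=False)
        kept = (svals[: self.n_components] ** 2).sum()
        self.variance_explained_ = float(kept / total_var) if total_var > 0 else 1.0
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.unmixing_.T

    def as_component_set(self) -> ComponentSet:
        check_is_fitted(self, "components_")
        return ComponentSet(
            loadings=self.components_,
            scores=self.scores_,
            mixing=self.mixing_,
            whitening=self.whitening_,
            mean=self.mean_,
            variance_explained=self.variance_explained_,
            converged=self.converged_,
            n_iter=self.n_iter_,
        )


def fit_fastica(
    X,
    n_components: int = 20,
    fun: str = "logcosh",
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int = 0,
) -> ComponentSet:
    """Fit FastICA on a subjects x regions matrix; functional wrapper."""
    est = CovariancePatternICA(
        n_components=n_components, fun=fun, tol=tol, max_iter=max_iter, random_state=seed
    ).fit(X)
    return est.as_component_set()


def variance_explained(X, components: ComponentSet) -> float:
    """Fraction of centered variance captured by the retained subspace."""
    X = np.asarray(X, dtype=float)
    Xc = X - components.mean
    total = (Xc**2).sum()
    if total == 0:
        return 1.0
    k = components.loadings.shape[0]
    svals = np.linalg.svd(Xc, compute_uv=False)
    return float((svals[:k] ** 2).sum() / total)


def match_components(
    estimated: np.ndarray, planted: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align estimated component loadings with a reference set.

    Solves the assignment problem maximizing total |Pearson correlation|
    between loading rows. Returns ``(permutation, signs, correlations)``
    where ``estimated[permutation[i]] * signs[i]`` corresponds to
    ``planted[i]`` and ``correlations[i]`` is the matched |r|.
    """
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(planted, dtype=float)
    if est.shape != ref.shape:
        raise ValueError(f"component sets differ in shape: {est.shape} vs {ref.shape}")
    k = est.shape[0]
    est_c = est - est.mean(axis=1, keepdims=True)
    ref_c = ref - ref.mean(axis=1, keepdims=True)
    est_n = est_c / np.linalg.norm(est_c, axis=1, keepdims=True)
    ref_n = ref_c / np.linalg.norm(ref_c, axis=1, keepdims=True)
    corr = ref_n @ est_n.T  # (k_ref, k_est)
    rows, cols = linear_sum_assignment(-np.abs(corr))
    perm = np.empty(k, dtype=int)
    signs = np.empty(k)
    corrs = np.empty(k)
    for r, c in zip(rows, cols):
        perm[r] = c
        signs[r] = np.sign(corr[r, c]) or 1.0
        corrs[r] = abs(corr[r, c])
    return perm, signs, corrs
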