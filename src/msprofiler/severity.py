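"""ECDF severity normalization of clinical measures.

Maps each raw clinical score onto a common 0–1 severity scale using the
empirical cumulative distribution of that measure within the analysis
cohort: 0 is the best observed performance, 1 the worst. Measures where a
higher raw score means better performance (SDMT, BVMT-R) are negated
before ranking so that severity is always worseness-oriented.

The rank convention is the midrank transform ``(r - 1) / (n - 1)`` with
ties sharing the average rank, so both endpoints (0 and 1) are attained
whenever at least two distinct values exist; the textbook ``r / n`` ECDF
cannot reach 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["MeasureSpec", "DEFAULT_MEASURES", "ECDFNormalizer", "ecdf_normalize"]


@dataclass(frozen=True)
class MeasureSpec:
    """A clinical measure and the direction of its scale.

    ``higher_is_worse=True`` for disability/time scores (EDSS, timed
    25-foot walk, 9-hole peg test) and ``False`` for performance scores
    (SDMT, BVMT-R).
    """

    name: str
    higher_is_worse: bool = True


#: The five measures entering the latent profile analysis.
DEFAULT_MEASURES: tuple[MeasureSpec, ...] = (
    MeasureSpec("edss", True),
    MeasureSpec("t25fw", True),
    MeasureSpec("nhpt", True),
    MeasureSpec("sdmt", False),
    MeasureSpec("bvmtr", False),
)


def _midrank_severity(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    if n == 1:
        return np.array([0.5])
    ranks = rankdata(x, method="average")
    return (ranks - 1.0) / (n - 1.0)


class ECDFNormalizer(BaseEstimator, TransformerMixin):
    """Percentile-rank (ECDF) severity transformer.

    Severity is computed *within* the cohort passed to :meth:`fit`; when
    the same data are transformed, every column spans exactly [0, 1]
    (given two distinct values). ``transform`` on new data interpolates
    into the fitted cohort's empirical distribution, clipping outside the
    observed range.

    Parameters
    ----------
    measures : sequence of MeasureSpec, optional
        Measures (columns) to normalize, with their directions. Defaults
        to the five-progressive-MS battery (EDSS, 25FWT, 9HPT, SDMT,
        BVMT-R).
    """

    def __init__(self, measures: tuple[MeasureSpec, ...] = DEFAULT_MEASURES):
        self.measures = measures

    def _validate(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=[m.name for m in self.measures])
        for m in self.measures:
            if m.name not in X.columns:
                raise ValueError(f"measure column missing: {m.name!r}")
            col = X[m.name]
            if col.isna().any():
                raise ValueError(f"missing values in measure {m.name!r}")
        if len(X) < 2:
            raise ValueError("need at least 2 subjects per measure to form an ECDF")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        # store worseness-oriented sorted values and their severities per measure
        self.reference_: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for m in self.measures:
            v = X[m.name].to_numpy(dtype=float)
            w = v if m.higher_is_worse else -v
            sev = _midrank_severity(w)
            order = np.argsort(w, kind="stable")
            self.reference_[m.name] = (w[order], sev[order])
        self.n_samples_ = len(X)
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "reference_")
        X = self._validate(X)
        out = {}
        for m in self.measures:
            v = X[m.name].to_numpy(dtype=float)
            w = v if m.higher_is_worse else -v
            ref_w, ref_s = self.reference_[m.name]
            out[m.name] = np.interp(w, ref_w, ref_s)
        return pd.DataFrame(out, index=X.index)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        """Severity of the cohort itself (exact midranks, not interpolated)."""
        X = self._validate(X)
        self.fit(X)
        out = {}
        for m in self.measures:
            v = X[m.name].to_numpy(dtype=float)
            w = v if m.higher_is_worse else -v
            out[m.name] = _midrank_severity(w)
        return pd.DataFrame(out, index=X.index)


def ecdf_normalize(
    raw: pd.DataFrame, measures: tuple[MeasureSpec, ...] = DEFAULT_MEASURES
) -> pd.DataFrame:
    """Normalize raw scores to the 0–1 severity scale within the cohort.

    Thin wrapper over :class:`ECDFNormalizer.fit_transform`.
    """
    return ECDFNormalizer(measures).fit_transform(raw)
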