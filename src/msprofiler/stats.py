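"""Profile comparisons: adjusted contrasts, FDR, chi-square, matching.

Implements the group-comparison layer of the profiling analysis:

* per-feature linear models with profile indicators and the standard
  covariates (age, sex, disease duration), optionally with a random
  intercept per scanner for MRI-derived features, reporting all pairwise
  profile contrasts (beta, SE, p);
* Benjamini–Hochberg FDR adjustment within a declared family;
* Pearson chi-square tests of independence on contingency tables;
* 1:1 nearest-neighbour propensity-score matching without replacement
  under a caliper expressed in SDs of the pooled propensity scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import mixedlm, ols
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError
import statsmodels.api as sm

__all__ = [
    "ContrastResult",
    "MatchResult",
    "adjusted_contrasts",
    "bh_fdr",
    "chi_square",
    "propensity_match",
]


@dataclass
class ContrastResult:
    """One pairwise profile comparison for one feature."""

    feature: str
    contrast: str  # e.g. "cognitive-motor": second minus first group mean
    beta: float
    se: float
    p_raw: float
    p_fdr: float | None
    model: str  # "random-scanner" or "fixed-only"
    family: str


@dataclass
class MatchResult:
    """1:1 propensity-matched pairs."""

    pairs: list[tuple[int, int]]  # (treated positional index, control positional index)
    propensity: np.ndarray
    caliper: float
    n_treated_matched: int
    n_control_matched: int


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def _pairwise_from_fit(params, cov, levels, ref, term):
    """Pairwise (b - a) differences from treatment-coded fits.

    The reference level has coefficient 0 with zero (co)variance.
    """
    names = list(params.index)
    out = {}
    for lev in levels:
        key = f"{term}[T.{lev}]"
        out[lev] = names.index(key) if key in names else None  # None = reference
    results = []
    for a, b in combinations(levels, 2):
        ia, ib = out[a], out[b]
        beta = (params.iloc[ib] if ib is not None else 0.0) - (
            params.iloc[ia] if ia is not None else 0.0
        )
        va = cov[ia, ia] if ia is not None else 0.0
        vb = cov[ib, ib] if ib is not None else 0.0
        cab = cov[ia, ib] if (ia is not None and ib is not None) else 0.0
        se = float(np.sqrt(max(va + vb - 2 * cab, 0.0)))
        results.append((f"{b}-{a}", float(beta), se))
    return results


def adjusted_contrasts(
    outcomes: pd.DataFrame,
    assignment,
    covariates: pd.DataFrame,
    random: pd.Series | None = None,
    family: str = "default",
    apply_fdr: bool = True,
) -> list[ContrastResult]:
    """Covariate-adjusted pairwise profile contrasts for each feature.

    Parameters
    ----------
    outcomes : DataFrame
        Features to compare (one column per feature), aligned by row
        with ``assignment`` and ``covariates``.
    assignment : array-like
        Profile labels per subject (any hashable values).
    covariates : DataFrame
        Adjustment variables; numeric columns enter linearly, object or
        categorical columns (e.g. sex) as factors.
    random : Series, optional
        Scanner identifier for a random intercept. Falls back to fixed
        scanner effects (flagged ``fixed-only``) when fewer than 3
        scanners are present or the variance component degenerates.
    family : str
        FDR family label; BH adjustment is applied across every contrast
        in this call.
    """
    labels = pd.Series(np.asarray(assignment, dtype=object), name="profile")
    levels = sorted(pd.unique(labels), key=str)
    if len(levels) < 2:
        raise ValueError("need at least 2 profiles to form contrasts")
    cov_terms = []
    df = pd.DataFrame({"profile": labels.astype(str).to_numpy()})
    for c in covariates.columns:
        col = covariates[c]
        df[c] = col.to_numpy()
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            cov_terms.append(f"C({c})")
        else:
            cov_terms.append(c)
    use_random = random is not None and pd.Series(random).nunique() >= 3
    if random is not None:
        df["_scanner"] = pd.Series(random).astype(str).to_numpy()
        if not use_random:
            cov_terms.append("C(_scanner)")
    rhs = " + ".join(["C(profile)"] + cov_terms) if cov_terms else "C(profile)"
    levels_str = [str(x) for x in levels]

    results: list[ContrastResult] = []
    for feat in outcomes.columns:
        y = outcomes[feat].to_numpy(dtype=float)
        d = df.copy()
        d["_y"] = y
        if np.ptp(y) == 0:
            # constant outcome: no group effect by construction
            for a, b in combinations(levels_str, 2):
                results.append(
                    ContrastResult(feat, f"{b}-{a}", 0.0, np.nan, 1.0, None, "constant", family)
                )
            continue
        fitted = None
        model_kind = "fixed-only"
        if use_random:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    mres = mixedlm(f"_y ~ {rhs}", d, groups=d["_scanner"]).fit(reml=True)
                if np.all(np.isfinite(mres.fe_params)) and float(mres.cov_re.iloc[0, 0]) > 1e-10:
                    k_fe = len(mres.fe_params)
                    fitted = (mres.fe_params, np.asarray(mres.cov_params())[:k_fe, :k_fe], None)
                    model_kind = "random-scanner"
            except (np.linalg.LinAlgError, ValueError):
                fitted = None
        if fitted is None:
            rhs_f = rhs if use_random is False else rhs + " + C(_scanner)"
            ores = ols(f"_y ~ {rhs_f}", d).fit()
            if ores.df_resid <= 0 or np.linalg.matrix_rank(ores.model.exog) < ores.model.exog.shape[1]:
                raise ValueError(f"singular design for feature {feat!r}")
            fitted = (ores.params, np.asarray(ores.cov_params()), float(ores.df_resid))
        params, cov, dof = fitted
        for contrast, beta, se in _pairwise_from_fit(params, cov, levels_str, levels_str[0], "C(profile)"):
            if se == 0:
                p = 1.0 if beta == 0 else 0.0
            elif dof is None:
                p = 2.0 * sps.norm.sf(abs(beta / se))
            else:
                p = 2.0 * sps.t.sf(abs(beta / se), dof)
            results.append(
                ContrastResult(feat, contrast, beta, se, float(p), None, model_kind, family)
            )
    if apply_fdr and results:
        adj = bh_fdr([r.p_raw for r in results])
        for r, q in zip(results, adj):
            r.p_fdr = float(q)
    return results


def contrasts_frame(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "contrast": [r.contrast for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_fdr": [r.p_fdr for r in results],
            "model": [r.model for r in results],
            "family": [r.family for r in results],
        }
    )


def propensity_match(
    cohort: pd.DataFrame,
    group_col: str = "phenotype",
    treated_label: str = "SPMS",
    covariates: tuple[str, ...] = ("edss", "disease_duration"),
    caliper_sd: float = 0.2,
    seed: int = 0,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour propensity matching without replacement.

    Propensity = P(treated | covariates) from a logistic regression; the
    caliper is ``caliper_sd`` times the SD of the pooled propensity
    scores. Treated units are processed in random order (``seed``), each
    taking the nearest unmatched control within the caliper.
    """
    g = cohort[group_col].to_numpy()
    treated_idx = np.flatnonzero(g == treated_label)
    control_idx = np.flatnonzero(g != treated_label)
    if len(treated_idx) == 0 or len(control_idx) == 0:
        raise ValueError("both groups must be non-empty")
    X = sm.add_constant(cohort.loc[:, list(covariates)].to_numpy(dtype=float))
    y = (g == treated_label).astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(f"propensity logistic regression failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise ValueError("propensity logistic regression did not converge (separation?)")
    ps = np.asarray(fit.predict(X))
    caliper = caliper_sd * float(np.std(ps, ddof=1)) if len(ps) > 1 else 0.0

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(treated_idx))
    available = dict.fromkeys(control_idx.tolist())  # insertion-ordered set
    pairs: list[tuple[int, int]] = []
    for t in treated_idx[order]:
        if not available:
            break
        ctrl = np.fromiter(available.keys(), dtype=int)
        dist = np.abs(ps[ctrl] - ps[t])
        j = int(np.argmin(dist))
        if dist[j] <= caliper:
            c = int(ctrl[j])
            pairs.append((int(t), c))
            del available[c]
    return MatchResult(
        pairs=pairs,
        propensity=ps,
        caliper=caliper,
        n_treated_matched=len(pairs),
        n_control_matched=len(pairs),
    )
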