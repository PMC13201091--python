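"""FDR arithmetic, chi-square closed forms, contrasts, matching invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from msprofiler.stats import (
    adjusted_contrasts,
    bh_fdr,
    chi_square,
    propensity_match,
)


class TestBHFDR:
    @pytest.mark.parametrize(
        "p, expected",
        [
            # step-up arithmetic by hand: p_(i) * m / i with monotone cummin
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.04, 0.9], [0.015, 0.06, 0.9]),
            ([0.5], [0.5]),
        ],
    )
    def test_hand_worked(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected)

    def test_monotone_and_idempotent(self):
        rng = np.random.default_rng(0)
        p = rng.random(40)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        # a constant adjusted vector is a fixed point of the step-up rule
        const = np.full(10, 0.3)
        np.testing.assert_allclose(bh_fdr(const), const)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestChiSquare:
    def test_proportional_table_is_null(self):
        stat, df, p = chi_square([[10, 20], [5, 10]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        # 2x2 with perfect association: statistic = n = 20, df 1
        stat, df, p = chi_square([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert df == 1
        assert p == pytest.approx(sps.chi2.sf(20.0, 1))

    def test_permutation_invariance(self):
        t = np.array([[5, 9, 2], [7, 1, 6]])
        s1, _, _ = chi_square(t)
        s2, _, _ = chi_square(t[:, ::-1][::-1, :])
        assert s1 == pytest.approx(s2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square([[0, 0], [1, 2]])


def _toy_cohort(rng, n=300, delta=(0.0, 1.0, 2.0), noise=1.0):
    profile = rng.integers(0, 3, size=n)
    age = rng.normal(48, 9, n)
    sex = rng.choice(["F", "M"], n)
    dur = rng.normal(10, 5, n)
    scanner = rng.choice([f"s{i}" for i in range(5)], n)
    y = np.asarray(delta)[profile] + 0.01 * age + rng.normal(0, noise, n)
    return profile, pd.DataFrame({"age": age, "sex": sex, "disease_duration": dur}), pd.Series(scanner), y


class TestAdjustedContrasts:
    def test_constant_outcome_null(self):
        rng = np.random.default_rng(1)
        profile, cov, scanner, _ = _toy_cohort(rng, n=90)
        res = adjusted_contrasts(
            pd.DataFrame({"f": np.ones(90)}), profile, cov, random=scanner
        )
        assert all(r.beta == 0.0 and r.p_raw == 1.0 for r in res)

    @pytest.mark.parametrize("use_random", [False, True])
    def test_planted_shift_recovered(self, use_random):
        rng = np.random.default_rng(2)
        profile, cov, scanner, y = _toy_cohort(rng, n=400, delta=(0.0, 0.8, 2.0), noise=0.3)
        res = adjusted_contrasts(
            pd.DataFrame({"f": y}),
            profile,
            cov,
            random=scanner if use_random else None,
        )
        got = {r.contrast: r for r in res}
        for contrast, truth in [("1-0", 0.8), ("2-0", 2.0), ("2-1", 1.2)]:
            r = got[contrast]
            assert abs(r.beta - truth) < 3 * r.se
        assert got["2-0"].p_fdr < 0.001

    def test_null_calibration(self):
        """With permuted labels, raw p < 0.05 in ~5% of simulated features."""
        rng = np.random.default_rng(3)
        profile, cov, scanner, _ = _toy_cohort(rng, n=200)
        feats = pd.DataFrame(
            rng.normal(size=(200, 60)), columns=[f"f{i}" for i in range(60)]
        )
        res = adjusted_contrasts(feats, rng.permutation(profile), cov, apply_fdr=False)
        rate = np.mean([r.p_raw < 0.05 for r in res])
        assert 0.02 < rate < 0.09

    def test_fdr_applied_within_family(self):
        rng = np.random.default_rng(4)
        profile, cov, scanner, y = _toy_cohort(rng, n=150)
        res = adjusted_contrasts(pd.DataFrame({"f": y}), profile, cov, family="fam-A")
        assert all(r.p_fdr >= r.p_raw - 1e-12 for r in res)
        assert all(r.family == "fam-A" for r in res)


class TestPropensityMatch:
    def _cohort(self, edss_t, edss_c, dur_t=None, dur_c=None):
        nt, nc = len(edss_t), len(edss_c)
        dur_t = [10] * nt if dur_t is None else list(dur_t)
        dur_c = [10] * nc if dur_c is None else list(dur_c)
        return pd.DataFrame(
            {
                "phenotype": ["SPMS"] * nt + ["PPMS"] * nc,
                "edss": list(edss_t) + list(edss_c),
                "disease_duration": dur_t + dur_c,
            }
        )

    def test_identical_rows_all_matched_distance_zero(self):
        df = self._cohort([4, 4], [4, 4, 4])
        res = propensity_match(df, seed=0)
        assert res.n_treated_matched == 2
        for t, c in res.pairs:
            assert res.propensity[t] == pytest.approx(res.propensity[c])

    def test_zero_caliper_all_distinct_no_matches(self):
        # interleaved covariates: no separation, but all scores distinct
        df = self._cohort([2.0, 4.5, 6.0], [3.0, 5.0, 7.0], [5, 9, 7], [8, 6, 11])
        res = propensity_match(df, caliper_sd=0.0, seed=0)
        assert res.pairs == []

    def test_each_subject_in_at_most_one_pair_within_caliper(self):
        rng = np.random.default_rng(5)
        df = self._cohort(
            rng.normal(5, 1, 40), rng.normal(4, 1, 50),
            rng.normal(12, 4, 40), rng.normal(9, 4, 50),
        )
        res = propensity_match(df, seed=1)
        used = [i for pair in res.pairs for i in pair]
        assert len(used) == len(set(used))
        for t, c in res.pairs:
            assert abs(res.propensity[t] - res.propensity[c]) <= res.caliper + 1e-12

    def test_greedy_rule_matches_enumeration_on_toy(self):
        """6-subject toy: replay the stated greedy rule independently."""
        df = self._cohort([3.0, 5.0, 7.0], [3.2, 5.1, 6.0], [8, 10, 12], [8, 10, 12])
        seed = 9
        res = propensity_match(df, caliper_sd=10.0, seed=seed)
        # oracle: same propensity model, explicit greedy replay
        import statsmodels.api as sm

        X = sm.add_constant(df[["edss", "disease_duration"]].to_numpy())
        y = (df["phenotype"] == "SPMS").astype(float)
        ps = sm.Logit(y, X).fit(disp=0).predict(X)
        treated = [0, 1, 2]
        controls = {3, 4, 5}
        order = np.random.default_rng(seed).permutation(3)
        expected = []
        for t in np.array(treated)[order]:
            c = min(controls, key=lambda j: abs(ps[j] - ps[t]))
            expected.append((int(t), int(c)))
            controls.remove(c)
        assert sorted(res.pairs) == sorted(expected)

    def test_balance_improves_on_unbalanced_cohort(self):
        rng = np.random.default_rng(6)
        df = self._cohort(
            rng.normal(6, 1, 80), rng.normal(4, 1, 120),
            rng.normal(14, 4, 80), rng.normal(8, 4, 120),
        )
        res = propensity_match(df, seed=2)
        assert len(res.pairs) > 10

        def smd(col, idx_t, idx_c):
            a, b = df[col].to_numpy()[idx_t], df[col].to_numpy()[idx_c]
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            return abs(a.mean() - b.mean()) / pooled

        all_t = np.flatnonzero(df["phenotype"] == "SPMS")
        all_c = np.flatnonzero(df["phenotype"] == "PPMS")
        mt = np.array([t for t, _ in res.pairs])
        mc = np.array([c for _, c in res.pairs])
        for col in ("edss", "disease_duration"):
            assert smd(col, mt, mc) < smd(col, all_t, all_c)
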