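"""Alteration-activity association: ridge oracle, permutation p-values,
scoring filters and the pairwise interaction rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge

from arpan.cohort import AlterationMatrix
from arpan.association import (
    InteractionTest,
    classify_interaction,
    fit_alteration_regression,
    fit_pairwise_interaction,
    permutation_coefficient_pvalues,
    score_associations,
    select_eligible_pairs,
)


def _alterations(arr, ids=None):
    arr = np.asarray(arr)
    ids = ids or [f"alt{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=ids, index=[f"s{i}" for i in range(arr.shape[0])])


class TestRidgeFit:
    def test_matches_sklearn_ridge_with_intercept(self, rng):
        X = _alterations(rng.integers(0, 2, size=(15, 3)))
        X.iloc[0] = [1, 0, 1]  # guard against constant columns
        X.iloc[1] = [0, 1, 0]
        y = rng.normal(size=15)
        beta = fit_alteration_regression(y, X, lam=2.5)
        ref = Ridge(alpha=2.5, fit_intercept=True).fit(X.to_numpy(), y)
        np.testing.assert_allclose(beta.to_numpy(), ref.coef_, rtol=1e-10)

    def test_matches_dense_normal_equations(self, rng):
        X = _alterations([[1, 0], [0, 1], [1, 1], [0, 0], [1, 0]])
        y = np.array([2.0, -1.0, 1.5, 0.0, 2.2])
        lam = 1.0
        beta = fit_alteration_regression(y, X, lam)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        yc = y - y.mean()
        expected = np.linalg.solve(Xc.T @ Xc + lam * np.eye(2), Xc.T @ yc)
        np.testing.assert_allclose(beta.to_numpy(), expected, rtol=1e-12)

    def test_constant_activity_gives_zero_coefficients(self):
        X = _alterations([[1, 0], [0, 1], [1, 1], [0, 0]])
        beta = fit_alteration_regression(np.full(4, 7.0), X, lam=1.0)
        np.testing.assert_allclose(beta.to_numpy(), 0.0, atol=1e-12)

    def test_planted_effect_recovered(self, rng):
        carriers = rng.integers(0, 2, size=200)
        X = _alterations(carriers.reshape(-1, 1))
        y = 2.0 * carriers + rng.normal(scale=0.05, size=200)
        beta = fit_alteration_regression(y, X, lam=1e-6)
        assert beta.iloc[0] == pytest.approx(2.0, abs=0.05)

    def test_zero_variance_column_is_an_error(self):
        X = _alterations([[1, 1], [0, 1], [1, 1]])
        with pytest.raises(ValueError, match="zero-variance"):
            fit_alteration_regression(np.ones(3), X, lam=1.0)


class TestPermutationPvalues:
    def test_worked_six_sample_instance_converges_to_enumerated_value(self):
        """Exhaustive enumeration over the 20 balanced splits gives p = 0.1;
        the Monte-Carlo estimate must agree within 3 MC standard deviations."""
        X = _alterations(np.array([1, 1, 1, 0, 0, 0]).reshape(-1, 1))
        _, p = permutation_coefficient_pvalues(
            [1, 2, 3, 4, 5, 6], X, lam=1.0, n_permutations=10000, seed=2
        )
        mc_sd = np.sqrt(0.1 * 0.9 / 10000)
        assert abs(p.iloc[0] - 0.1) <= 3 * mc_sd

    def test_null_pvalues_roughly_uniform(self, rng):
        X = _alterations(rng.integers(0, 2, size=(40, 2)))
        X.iloc[0] = [1, 0]
        X.iloc[1] = [0, 1]
        pvals = []
        for rep in range(100):
            y = rng.normal(size=40)
            _, p = permutation_coefficient_pvalues(
                y, X, lam=1.0, n_permutations=200, seed=rep
            )
            pvals.extend(p.tolist())
        frac = np.mean(np.array(pvals) < 0.05)
        assert abs(frac - 0.05) <= 2 * np.sqrt(0.05 * 0.95 / len(pvals)) + 0.01

    def test_same_seed_identical_pvalues(self, rng):
        X = _alterations(rng.integers(0, 2, size=(20, 3)))
        X.iloc[0] = [1, 0, 1]
        X.iloc[1] = [0, 1, 0]
        y = rng.normal(size=20)
        _, p1 = permutation_coefficient_pvalues(y, X, n_permutations=100, seed=5)
        _, p2 = permutation_coefficient_pvalues(y, X, n_permutations=100, seed=5)
        pd.testing.assert_series_equal(p1, p2)


class TestScoring:
    @staticmethod
    def _raw_table(rng, n_reg=10, n_alt=10):
        rows = []
        for r in range(n_reg):
            for a in range(n_alt):
                rows.append(
                    {
                        "regulator": f"r{r}",
                        "regulator_kind": "tf",
                        "alteration": f"alt{a}",
                        "coefficient": rng.normal(),
                        "nominal_p": float(rng.uniform(0.001, 1.0)),
                    }
                )
        return pd.DataFrame(rows)

    def test_low_prevalence_regulator_excluded(self, rng):
        table = self._raw_table(rng)
        prevalence = pd.Series(0.5, index=[f"r{i}" for i in range(10)])
        prevalence["r3"] = 0.005
        out = score_associations(table, prevalence, min_prevalence=0.01, alteration_fdr=1.0)
        assert "r3" not in set(out["regulator"])

    def test_display_score_convention(self):
        table = pd.DataFrame(
            [{"regulator": "r", "regulator_kind": "tf", "alteration": "a",
              "coefficient": -1.2, "nominal_p": 0.01}]
        )
        out = score_associations(table, alteration_fdr=1.0)
        assert out.loc[0, "adjusted_p"] == pytest.approx(0.01)  # single test, c(1)=1
        assert out.loc[0, "display_score"] == pytest.approx(-2.0)
        assert out.loc[0, "signed_score"] == pytest.approx(-0.01)

    def test_scores_agree_in_sign(self, rng):
        out = score_associations(self._raw_table(rng), alteration_fdr=1.0)
        assert (np.sign(out["signed_score"]) == np.sign(out["display_score"]) )[
            out["adjusted_p"] < 1.0
        ].all()

    def test_filters_match_brute_force(self, rng):
        table = self._raw_table(rng)
        prevalence = pd.Series(
            rng.uniform(0, 0.05, size=10), index=[f"r{i}" for i in range(10)]
        )
        out = score_associations(table, prevalence, min_prevalence=0.01, alteration_fdr=0.15)
        # brute force: BY per (alteration, family) then both filters by hand
        from arpan.significance import adjust_by

        exp = table.copy()
        for a, idx in exp.groupby("alteration").groups.items():
            exp.loc[idx, "adjusted_p"] = adjust_by(exp.loc[idx, "nominal_p"].to_numpy())
        ok_reg = set(prevalence[prevalence >= 0.01].index)
        exp = exp[exp["regulator"].isin(ok_reg)]
        ok_alt = set(exp.loc[exp["adjusted_p"] < 0.15, "alteration"])
        exp = exp[exp["alteration"].isin(ok_alt)]
        assert len(out) == len(exp)
        merged = out.merge(exp, on=["regulator", "alteration"], suffixes=("", "_exp"))
        np.testing.assert_allclose(merged["adjusted_p"], merged["adjusted_p_exp"])


class TestEligiblePairs:
    @staticmethod
    def _matrix_with_counts(n_a, n_b, n_co, n=60):
        a = np.zeros(n, dtype=int)
        b = np.zeros(n, dtype=int)
        a[:n_a] = 1
        b[:n_co] = 1
        b[n_a : n_a + (n_b - n_co)] = 1
        calls = pd.DataFrame({"A": a, "B": b}, index=[f"s{i}" for i in range(n)])
        return AlterationMatrix(calls)

    @pytest.mark.parametrize(
        "counts,eligible",
        [((25, 22, 12), True), ((25, 22, 9), False), ((19, 30, 15), False)],
    )
    def test_threshold_rules(self, counts, eligible):
        alt = self._matrix_with_counts(*counts)
        pairs = select_eligible_pairs(alt, min_single=20, min_co=10)
        assert (("A", "B") in pairs) == eligible


class TestInteraction:
    def test_additive_truth_has_zero_interaction(self, rng):
        a = rng.integers(0, 2, size=100).astype(float)
        b = rng.integers(0, 2, size=100).astype(float)
        y = 1.0 * a + 1.0 * b
        t = fit_pairwise_interaction(y, a, b)
        assert t.coef_ab == pytest.approx(0.0, abs=1e-10)

    def test_planted_interaction_recovered(self, rng):
        a = rng.integers(0, 2, size=200).astype(float)
        b = rng.integers(0, 2, size=200).astype(float)
        y = a + b + 2.0 * a * b + rng.normal(scale=0.3, size=200)
        t = fit_pairwise_interaction(y, a, b)
        assert t.coef_ab == pytest.approx(2.0, abs=0.3)
        assert t.interaction_p < 0.05

    def test_matches_normal_equations_oracle(self, rng):
        a = np.array([1, 1, 0, 0, 1, 0, 1, 0], dtype=float)
        b = np.array([1, 0, 1, 0, 1, 1, 0, 0], dtype=float)
        y = rng.normal(size=8)
        t = fit_pairwise_interaction(y, a, b)
        X = np.column_stack([np.ones(8), a, b, a * b])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(
            [t.intercept, t.coef_a, t.coef_b, t.coef_ab], beta, rtol=1e-8
        )

    def test_identical_alterations_rejected(self, rng):
        a = rng.integers(0, 2, size=30).astype(float)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_pairwise_interaction(rng.normal(size=30), a, a)

    @pytest.mark.parametrize(
        "coefs,p,expected",
        [
            ((0.1, 0.2, 0.5), 0.01, "synergistic"),
            ((-0.1, -0.2, -0.5), 0.01, "antagonistic"),
            ((0.6, 0.2, 0.5), 0.01, "none"),
            ((0.1, 0.2, 0.5), 0.2, "none"),
        ],
    )
    def test_classification_rule_examples(self, coefs, p, expected):
        t = InteractionTest(("A", "B"), None, 0.0, *coefs, p, 10, 6.0)
        assert classify_interaction(t, alpha=0.05) == expected

    def test_rule_matches_brute_force_grid(self):
        """Exhaustive agreement with a literal re-statement of the rule over
        a coefficient grid and both significance regimes."""
        grid = (-1.0, -0.5, 0.0, 0.5, 1.0)
        for ca, cb, cab, p in itertools.product(grid, grid, grid, (0.01, 0.2)):
            t = InteractionTest(("A", "B"), None, 0.0, ca, cb, cab, p, 10, 6.0)
            got = classify_interaction(t, alpha=0.05)
            if p >= 0.05:
                want = "none"
            elif cab > 0 and cab > ca and cab > cb:
                want = "synergistic"
            elif cab < 0 and cab < ca and cab < cb:
                want = "antagonistic"
            else:
                want = "none"
            assert got == want
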