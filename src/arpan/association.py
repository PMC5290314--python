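"""Associating binary somatic alterations with inferred regulator activities.

Each regulator's activity vector is regressed on the full binary alteration
matrix by ridge regression (unpenalized intercept, predictors kept 0/1, the
outcome centred).  Coefficient significance comes from a permutation test:
the activity vector is shuffled across samples and the model refit; the
nominal p of a coefficient is the smoothed fraction of null coefficients at
least as large in absolute value.  Nominal p-values are BY-corrected across
regulators (TF and protein families separately) and the adjusted p carries
the coefficient's sign, yielding the signed association score.

Pairwise alteration interactions use ordinary least squares with an
interaction term,

    activity = intercept + A_i + B_j + (AB)_ij + eps,

restricted to pairs altered in >= 20 samples each and co-altered in >= 10;
a significant interaction coefficient exceeding (falling below) both main
effects is called synergistic (antagonistic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .cohort import AlterationMatrix
from .model import ActivityMatrix
from .significance import adjust_by

logger = logging.getLogger(__name__)

__all__ = [
    "fit_alteration_regression",
    "permutation_coefficient_pvalues",
    "associate_regulators",
    "score_associations",
    "select_eligible_pairs",
    "fit_pairwise_interaction",
    "classify_interaction",
    "InteractionTest",
]


class _RidgeDesign:
    """Closed-form ridge with unpenalized intercept, factorized once so that
    refits against permuted outcomes are a single matrix product."""

    def __init__(self, X: np.ndarray, lam: float):
        X = np.asarray(X, dtype=float)
        if (X.std(axis=0) == 0).any():
            j = int(np.flatnonzero(X.std(axis=0) == 0)[0])
            raise ValueError(f"zero-variance alteration column at index {j}")
        self.x_means = X.mean(axis=0)
        Xc = X - self.x_means
        k = X.shape[1]
        # hat matrix for coefficients: beta = G y_centred
        self.G = scipy.linalg.solve(
            Xc.T @ Xc + lam * np.eye(k), Xc.T, assume_a="pos"
        )

    def coefficients(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return self.G @ (y - y.mean(axis=0))


def fit_alteration_regression(
    activity: np.ndarray, alterations: pd.DataFrame, lam: float = 1.0
) -> pd.Series:
    """Ridge coefficients of one regulator's activity on all alterations."""
    design = _RidgeDesign(alterations.to_numpy(), lam)
    beta = design.coefficients(np.asarray(activity, dtype=float).ravel())
    return pd.Series(beta, index=alterations.columns)


def permutation_coefficient_pvalues(
    activity: np.ndarray,
    alterations: pd.DataFrame,
    lam: float = 1.0,
    n_permutations: int = 10000,
    seed: int = 0,
) -> Tuple[pd.Series, pd.Series]:
    """Two-sided permutation p per coefficient: shuffle the outcome across
    samples, refit, and count null coefficients with |beta_null| >= |beta_obs|
    using the smoothed (1 + count) / (B + 1) convention.

    Returns (coefficients, nominal_p).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = np.asarray(activity, dtype=float).ravel()
    design = _RidgeDesign(alterations.to_numpy(), lam)
    beta_obs = design.coefficients(y)
    rng = np.random.default_rng(seed)
    # permute y columns-wise in blocks to vectorize the refits; ties in |beta|
    # are compared with a relative tolerance so that exact rearrangements of
    # the observed split are not lost to summation roundoff
    block = 2000
    threshold = np.abs(beta_obs) - 1e-9 * np.maximum(np.abs(beta_obs), 1e-300)
    exceed = np.zeros_like(beta_obs)
    done = 0
    while done < n_permutations:
        b = min(block, n_permutations - done)
        Yp = np.empty((len(y), b))
        for i in range(b):
            Yp[:, i] = y[rng.permutation(len(y))]
        beta_null = design.coefficients(Yp)  # k x b
        exceed += (np.abs(beta_null) >= threshold[:, None]).sum(axis=1)
        done += b
    pvals = (1.0 + exceed) / (n_permutations + 1.0)
    return (
        pd.Series(beta_obs, index=alterations.columns),
        pd.Series(pvals, index=alterations.columns),
    )


def associate_regulators(
    activities: ActivityMatrix,
    alterations: AlterationMatrix,
    lam: float = 1.0,
    n_permutations: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the ridge + permutation screen for every regulator.

    Returns a long table with one row per (regulator, alteration):
    regulator, regulator_kind, alteration, coefficient, nominal_p.
    Permutations use fresh seeded draws per regulator.
    """
    if not activities.sample_ids.equals(alterations.sample_ids):
        raise ValueError("activities and alterations must share sample order")
    calls = alterations.calls
    keep = calls.columns[(calls.std(axis=0) > 0)]
    dropped = calls.columns.difference(keep)
    if len(dropped):
        logger.warning("dropping constant alteration columns: %s", list(dropped))
    calls = calls[keep]
    seeds = np.random.SeedSequence(seed).spawn(len(activities.regulators))
    rows = []
    for i, reg in enumerate(activities.regulators):
        y = activities.values.loc[reg].to_numpy()
        child_seed = int(seeds[i].generate_state(1)[0] % (2**31))
        beta, pvals = permutation_coefficient_pvalues(
            y, calls, lam=lam, n_permutations=n_permutations, seed=child_seed
        )
        for alt in calls.columns:
            rows.append(
                {
                    "regulator": reg,
                    "regulator_kind": activities.regulator_kind.loc[reg],
                    "alteration": alt,
                    "coefficient": float(beta[alt]),
                    "nominal_p": float(pvals[alt]),
                }
            )
    return pd.DataFrame(rows)


def score_associations(
    table: pd.DataFrame,
    prevalence: Optional[pd.Series] = None,
    min_prevalence: float = 0.01,
    alteration_fdr: float = 0.15,
) -> pd.DataFrame:
    """BY-adjust, score and filter the raw association table.

    Adjustment runs across regulators separately within each (alteration,
    regulator-family) group.  Two scores are emitted: ``signed_score`` =
    sign(coefficient) * adjusted_p (the literal association score) and
    ``display_score`` = sign(coefficient) * -log10(adjusted_p).  Regulators
    must be significantly active in at least ``min_prevalence`` of samples;
    an alteration is retained when at least one regulator reaches
    ``adjusted_p < alteration_fdr``.
    """
    out = table.copy()
    out["adjusted_p"] = np.nan
    for (_, _), idx in out.groupby(["alteration", "regulator_kind"]).groups.items():
        out.loc[idx, "adjusted_p"] = adjust_by(out.loc[idx, "nominal_p"].to_numpy())
    sign = np.sign(out["coefficient"]).replace(0, 1)
    out["signed_score"] = sign * out["adjusted_p"]
    out["display_score"] = sign * (-np.log10(out["adjusted_p"]))
    if prevalence is not None:
        ok_reg = prevalence[prevalence >= min_prevalence].index
        out = out[out["regulator"].isin(ok_reg)]
    hit_alts = out.loc[out["adjusted_p"] < alteration_fdr, "alteration"].unique()
    out = out[out["alteration"].isin(hit_alts)]
    return out.reset_index(drop=True)


def select_eligible_pairs(
    alterations: AlterationMatrix, min_single: int = 20, min_co: int = 10
) -> list[Tuple[str, str]]:
    """Alteration pairs altered in >= ``min_single`` samples each and
    co-altered in >= ``min_co`` samples."""
    calls = alterations.calls
    counts = calls.sum(axis=0)
    cols = [c for c in calls.columns if counts[c] >= min_single]
    pairs = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            co = int((calls[a] & calls[b]).sum())
            if co >= min_co:
                pairs.append((a, b))
    return pairs


@dataclass
class InteractionTest:
    """OLS fit of activity on two alterations and their interaction."""

    pair: Tuple[str, str]
    regulator: Optional[str]
    intercept: float
    coef_a: float
    coef_b: float
    coef_ab: float
    interaction_p: float
    n: int
    df_resid: float
    classification: str = "none"


def fit_pairwise_interaction(
    activity: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    pair: Tuple[str, str] = ("A", "B"),
    regulator: Optional[str] = None,
) -> InteractionTest:
    """OLS of activity on intercept + a + b + a*b; the interaction p is the
    classical two-sided t-test of the interaction coefficient."""
    y = np.asarray(activity, dtype=float).ravel()
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    X = np.column_stack([a, b, a * b])
    if np.linalg.matrix_rank(np.column_stack([np.ones_like(a), X])) < 4:
        raise ValueError(f"rank-deficient interaction design for pair {pair}")
    res = sm.OLS(y, sm.add_constant(X)).fit()
    return InteractionTest(
        pair=pair,
        regulator=regulator,
        intercept=float(res.params[0]),
        coef_a=float(res.params[1]),
        coef_b=float(res.params[2]),
        coef_ab=float(res.params[3]),
        interaction_p=float(res.pvalues[3]),
        n=len(y),
        df_resid=float(res.df_resid),
    )


def classify_interaction(test: InteractionTest, alpha: float = 0.05) -> str:
    """Synergy/antagonism call for a fitted pair.

    Significant positive interaction exceeding both main effects ->
    synergistic; significant negative interaction below both -> antagonistic;
    anything else -> none.  Sets and returns ``test.classification``.
    """
    if test.interaction_p >= alpha:
        label = "none"
    elif test.coef_ab > 0 and test.coef_ab > test.coef_a and test.coef_ab > test.coef_b:
        label = "synergistic"
    elif test.coef_ab < 0 and test.coef_ab < test.coef_a and test.coef_ab < test.coef_b:
        label = "antagonistic"
    else:
        label = "none"
    test.classification = label
    return label


def interaction_screen(
    activities: ActivityMatrix,
    alterations: AlterationMatrix,
    min_single: int = 20,
    min_co: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit and classify every eligible pair against every regulator."""
    pairs = select_eligible_pairs(alterations, min_single, min_co)
    rows = []
    for a_id, b_id in pairs:
        a = alterations.calls[a_id].to_numpy()
        b = alterations.calls[b_id].to_numpy()
        if np.array_equal(a, b):
            logger.warning("skipping identical pair %s/%s", a_id, b_id)
            continue
        for reg in activities.regulators:
            t = fit_pairwise_interaction(
                activities.values.loc[reg].to_numpy(), a, b, (a_id, b_id), reg
            )
            classify_interaction(t, alpha)
            rows.append(
                {
                    "alteration_a": a_id,
                    "alteration_b": b_id,
                    "regulator": reg,
                    "intercept": t.intercept,
                    "coef_a": t.coef_a,
                    "coef_b": t.coef_b,
                    "coef_ab": t.coef_ab,
                    "interaction_p": t.interaction_p,
                    "classification": t.classification,
                }
            )
    return pd.DataFrame(rows)
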