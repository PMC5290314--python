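"""Permutation-based significance of inferred regulator activities.

The empirical null is built by shuffling the sample labels of the expression
matrix (breaking the expression–protein pairing while preserving each
expression profile intact), refitting the interaction matrix against the
true motif and protein matrices, and recomputing both activity mappings.
Repeating this many times yields, for every (regulator, sample) cell, a null
distribution against which the observed activity gets smoothed left- and
right-tail p-values.  Two-tailed p-values are corrected per sample across
regulators — TF and protein families separately — with the
Benjamini–Hochberg–Yekutieli (BY) step-up procedure, which remains valid
under the arbitrary dependence these activities exhibit.  Cohort-size-banded
FDR thresholds (0.10 above 300 samples, 0.15 between 100 and 300, 0.25
below 100) convert adjusted p-values into significance flags, and
per-regulator prevalence (fraction of samples flagged) feeds the downstream
association filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohort import AlignmentError, CohortBundle
from .model import ActivityMatrix, AffinityRegression, BilinearSolver

logger = logging.getLogger(__name__)

__all__ = [
    "NullEnsemble",
    "ActivitySignificance",
    "CohortFdrPolicy",
    "build_null_ensemble",
    "empirical_tail_pvalues",
    "adjust_by",
    "flag_significant_regulators",
    "regulator_prevalence",
]


@dataclass
class NullEnsemble:
    """Permutation draws of activities, indexed (permutation, regulator, sample)."""

    draws: np.ndarray
    regulators: pd.Index
    regulator_kind: pd.Series
    sample_ids: pd.Index
    permutation_seed: int

    @property
    def n_permutations(self) -> int:
        return self.draws.shape[0]


@dataclass
class ActivitySignificance:
    """Per-cell tail p-values with BY-adjusted two-tailed values and flags."""

    left_p: pd.DataFrame
    right_p: pd.DataFrame
    two_p: pd.DataFrame
    regulator_kind: pd.Series
    adjusted_p: Optional[pd.DataFrame] = None
    significant: Optional[pd.DataFrame] = None
    direction: Optional[pd.DataFrame] = None  # -1 low tail, +1 high tail
    fdr_threshold: Optional[float] = None


@dataclass
class CohortFdrPolicy:
    """Cohort-size-banded FDR thresholds for flagging significant activities."""

    large: float = 0.10   # > 300 samples
    mid: float = 0.15     # 100..300 samples
    small: float = 0.25   # < 100 samples

    def threshold(self, cohort_size: int) -> float:
        if cohort_size > 300:
            return self.large
        if cohort_size >= 100:
            return self.mid
        return self.small


def build_null_ensemble(
    bundle_or_model,
    n_permutations: int = 200,
    seed: int = 0,
    lam: float = 1.0,
    scheme: str = "sample_columns",
) -> NullEnsemble:
    """Refit the model against permuted expression and collect null activities.

    ``scheme='sample_columns'`` shuffles whole expression columns (sample
    labels), preserving each profile and the gene–gene covariance while
    destroying the pairing with the protein data; ``'per_gene'`` shuffles
    each gene row independently.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if scheme not in {"sample_columns", "per_gene"}:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    model = (
        AffinityRegression.from_bundle(bundle_or_model)
        if isinstance(bundle_or_model, CohortBundle)
        else bundle_or_model
    )
    rng = np.random.default_rng(seed)
    Y = model.Y.to_numpy()
    D = model.D.to_numpy()
    P = model.P.to_numpy()
    solver = model.solver
    DtY = D.T @ Y  # Q x M, reusable: column permutation commutes with D'
    Q, S, M = D.shape[1], P.shape[1], Y.shape[1]
    draws = np.empty((n_permutations, Q + S, M))
    for b in range(n_permutations):
        if scheme == "sample_columns":
            perm = rng.permutation(M)
            DtYp = DtY[:, perm]
        else:
            Yp = np.empty_like(Y)
            for g in range(Y.shape[0]):
                Yp[g] = Y[g, rng.permutation(M)]
            DtYp = D.T @ Yp
        W = solver.solve_core(DtYp @ P, lam)
        draws[b, :Q] = W @ P.T
        draws[b, Q:] = W.T @ DtYp
    regulators = model.tf_ids.append(model.feature_ids)
    kind = pd.Series(["tf"] * Q + ["protein"] * S, index=regulators)
    return NullEnsemble(draws, regulators, kind, model.sample_ids, seed)


def empirical_tail_pvalues(
    observed: ActivityMatrix, null: NullEnsemble
) -> ActivitySignificance:
    """Smoothed empirical tail p-values of observed activities against the null.

    right_p = (1 + #{draws >= obs}) / (B + 1), left_p symmetric with <=;
    the two-tailed p is min(1, 2 min(left, right)).  The +1 smoothing keeps
    p-values strictly positive; ties count toward both tails.
    """
    if null.n_permutations == 0:
        raise ValueError("null ensemble has no permutations")
    if not observed.values.index.equals(null.regulators) or not observed.values.columns.equals(
        null.sample_ids
    ):
        raise AlignmentError("observed activities do not match the null ensemble indices")
    obs = observed.values.to_numpy()
    B = null.n_permutations
    ge = (null.draws >= obs[None, :, :]).sum(axis=0)
    le = (null.draws <= obs[None, :, :]).sum(axis=0)
    right = (1.0 + ge) / (B + 1.0)
    left = (1.0 + le) / (B + 1.0)
    two = np.minimum(1.0, 2.0 * np.minimum(left, right))
    idx, cols = observed.values.index, observed.values.columns
    return ActivitySignificance(
        left_p=pd.DataFrame(left, index=idx, columns=cols),
        right_p=pd.DataFrame(right, index=idx, columns=cols),
        two_p=pd.DataFrame(two, index=idx, columns=cols),
        regulator_kind=observed.regulator_kind.copy(),
    )


def adjust_by(pvalues) -> np.ndarray:
    """Benjamini–Hochberg–Yekutieli step-up adjustment.

    Sorted p_(i) map to p_(i) * m * c(m) / i with c(m) the m-th harmonic
    number, made monotone non-decreasing and capped at 1; the original order
    is restored.  Valid under arbitrary dependence of the tests.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_by")[1]


def adjust_bh(pvalues) -> np.ndarray:
    """Plain Benjamini–Hochberg step-up adjustment."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def flag_significant_regulators(
    sig: ActivitySignificance,
    policy: CohortFdrPolicy = CohortFdrPolicy(),
    cohort_size: Optional[int] = None,
) -> ActivitySignificance:
    """BY-adjust two-tailed p-values per sample (TF and protein families
    separately) and flag cells whose adjusted p falls under the cohort-size
    threshold.  The direction of each flagged departure is the sign of the
    smaller tail (+1 for unusually high activity, -1 for low)."""
    if cohort_size is None:
        cohort_size = sig.two_p.shape[1]
    threshold = policy.threshold(cohort_size)
    adjusted = sig.two_p.copy()
    for kind in sig.regulator_kind.unique():
        rows = sig.regulator_kind[sig.regulator_kind == kind].index
        block = sig.two_p.loc[rows].to_numpy()
        adj = np.column_stack([adjust_by(block[:, j]) for j in range(block.shape[1])])
        adjusted.loc[rows] = adj
    significant = adjusted < threshold
    direction = np.where(
        sig.right_p.to_numpy() <= sig.left_p.to_numpy(), 1, -1
    )
    sig.adjusted_p = adjusted
    sig.significant = significant
    sig.direction = pd.DataFrame(direction, index=sig.two_p.index, columns=sig.two_p.columns)
    sig.fdr_threshold = threshold
    return sig


def regulator_prevalence(sig: ActivitySignificance) -> pd.Series:
    """Fraction of samples in which each regulator is flagged significant."""
    if sig.significant is None:
        raise ValueError("flags not computed; call flag_significant_regulators first")
    return sig.significant.mean(axis=1)
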