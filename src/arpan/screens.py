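"""Cohort-level screens over inferred activities.

Covers subgroup differential-activity testing (t or rank-sum, BH-corrected),
rank-set enrichment for cross-cohort replication, per-regulator Cox
proportional-hazards screens with a categorical background covariate,
activity-versus-expression model comparison (one-sided paired Wilcoxon),
40/40 risk stratification, transfer of a trained interaction matrix to an
external cohort, and concordance-index validation of externally trained
risk scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index

from .cohort import AlignmentError, ClinicalTable
from .model import ActivityMatrix, AffinityRegressionResults
from .preprocess import mean_center
from .significance import adjust_bh

logger = logging.getLogger(__name__)

__all__ = [
    "compare_activity_groups",
    "rank_set_enrichment",
    "survival_screen",
    "compare_model_families",
    "stratify_risk_groups",
    "transfer_to_external_cohort",
    "concordance_validation",
    "SurvivalScreenResult",
]


def compare_activity_groups(
    activities: ActivityMatrix,
    labels: pd.Series,
    test: str = "t",
) -> pd.DataFrame:
    """Per-regulator two-sided comparison of activities between two groups.

    ``labels`` maps sample id to one of exactly two group labels; the mean
    difference is reported as group1 - group2 in sorted label order.
    ``test='t'`` uses Welch-free two-sample t; ``'wilcoxon'`` the two-sided
    rank-sum test.  P-values are BH-corrected across regulators.
    """
    labels = labels.loc[activities.sample_ids]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    g1 = activities.sample_ids[labels == groups[0]]
    g2 = activities.sample_ids[labels == groups[1]]
    for name, g in ((groups[0], g1), (groups[1], g2)):
        if len(g) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    rows = []
    for reg in activities.regulators:
        x = activities.values.loc[reg, g1].to_numpy()
        y = activities.values.loc[reg, g2].to_numpy()
        diff = float(x.mean() - y.mean())
        if np.array_equal(np.sort(x), np.sort(y)):
            stat, p = 0.0, 1.0
        elif test == "t":
            stat, p = scipy.stats.ttest_ind(x, y)
        elif test == "wilcoxon":
            stat, p = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {"regulator": reg, "mean_diff": diff, "statistic": float(stat),
             "nominal_p": float(p), "test": test}
        )
    out = pd.DataFrame(rows)
    out["fdr_p"] = adjust_bh(out["nominal_p"].to_numpy())
    return out


def rank_set_enrichment(ranking: Sequence, query_set: Sequence) -> float:
    """One-sided Mann–Whitney p that ``query_set`` members sit near the top
    of ``ranking`` (position 0 = best)."""
    ranking = list(ranking)
    query = set(query_set)
    if not query or query == set(ranking):
        raise ValueError("query set must be a proper non-empty subset of the ranking")
    if not query.issubset(ranking):
        raise ValueError("query set contains items absent from the ranking")
    positions = {r: i for i, r in enumerate(ranking)}
    q_pos = [positions[r] for r in query]
    o_pos = [positions[r] for r in set(ranking) - query]
    # smaller position = better rank -> alternative 'less'
    res = scipy.stats.mannwhitneyu(q_pos, o_pos, alternative="less")
    return float(res.pvalue)


@dataclass
class SurvivalScreenResult:
    """Per-regulator Cox screen output plus per-sample risk scores."""

    table: pd.DataFrame  # regulator, coefficient, model_p, logrank_p, fdr_p
    risks: pd.DataFrame  # regulators x samples, Cox linear predictor
    family: str          # 'activity' or 'expression'


def survival_screen(
    values: pd.DataFrame,
    clinical: ClinicalTable,
    covariate: Optional[str] = "covariate",
    prevalence: Optional[pd.Series] = None,
    prevalence_min: float = 0.05,
    family: str = "activity",
    stratify_fraction: float = 0.40,
) -> SurvivalScreenResult:
    """One Cox proportional-hazards model per regulator.

    Each model regresses survival on the regulator's continuous values plus
    reference-level indicator contrasts of the categorical background
    covariate (reference = most frequent level).  Reported per regulator:
    the hazard coefficient, its Wald p, a log-rank p between the top/bottom
    ``stratify_fraction`` risk groups, and BH-corrected model p-values.
    Samples with missing covariate are excluded with a logged count.
    """
    clin = clinical.table.loc[values.columns].copy()
    if int(clin["event"].sum()) == 0:
        raise ValueError("no observed events; survival screen undefined")
    if prevalence is not None:
        keep = prevalence[prevalence >= prevalence_min].index
        values = values.loc[values.index.intersection(keep)]
    cov_cols: list[str] = []
    if covariate is not None and covariate in clin.columns:
        missing = clin[covariate].isna()
        if missing.any():
            logger.warning("excluding %d samples with missing covariate", int(missing.sum()))
            clin = clin[~missing]
        ref = clin[covariate].mode().iloc[0]
        dummies = pd.get_dummies(clin[covariate], prefix="cov").astype(float)
        ref_col = f"cov_{ref}"
        dummies = dummies.drop(columns=[ref_col])
        clin = pd.concat([clin, dummies], axis=1)
        cov_cols = list(dummies.columns)
    rows = []
    risk_rows = {}
    for reg in values.index:
        x = values.loc[reg, clin.index]
        if x.std() == 0:
            logger.warning("regulator %s has constant values; skipped", reg)
            continue
        df = clin[["time_months", "event"] + cov_cols].copy()
        df["x"] = x.to_numpy()
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time_months", event_col="event")
        except Exception as exc:  # convergence failure on degenerate input
            logger.warning("Cox fit failed for %s: %s", reg, exc)
            continue
        coef = float(cph.params_["x"])
        model_p = float(cph.summary.loc["x", "p"])
        risk = pd.Series(cph.predict_partial_hazard(df).to_numpy().ravel(), index=df.index)
        lp = pd.Series(np.log(risk), index=df.index)
        groups = stratify_risk_groups(lp, stratify_fraction)
        hi = groups[groups == "high"].index
        lo = groups[groups == "low"].index
        lr = logrank_test(
            df.loc[hi, "time_months"], df.loc[lo, "time_months"],
            event_observed_A=df.loc[hi, "event"], event_observed_B=df.loc[lo, "event"],
        )
        rows.append(
            {"regulator": reg, "coefficient": coef, "model_p": model_p,
             "logrank_p": float(lr.p_value)}
        )
        risk_rows[reg] = lp
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr_p"] = adjust_bh(table["model_p"].to_numpy())
    risks = pd.DataFrame(risk_rows).T
    return SurvivalScreenResult(table, risks, family)


def compare_model_families(
    p_activity: Sequence[float], p_expression: Sequence[float]
) -> float:
    """One-sided paired Wilcoxon signed-rank p that activity-model p-values
    are smaller than the matched expression-model p-values.  Zero
    differences are dropped; if all differences are zero the comparison is
    reported non-significant (p = 1)."""
    pa = np.asarray(p_activity, dtype=float)
    pe = np.asarray(p_expression, dtype=float)
    if pa.shape != pe.shape:
        raise ValueError("paired vectors must have equal length")
    if np.all(pa == pe):
        logger.warning("all paired differences are zero; reporting p = 1")
        return 1.0
    res = scipy.stats.wilcoxon(pa, pe, alternative="less", zero_method="wilcox")
    return float(res.pvalue)


def stratify_risk_groups(risks: pd.Series, fraction: float = 0.40) -> pd.Series:
    """Label the top ``floor(fraction * n)`` samples by risk as 'high', the
    bottom as 'low', the remainder 'excluded'.  Boundary ties are broken by
    position in the input index (logged)."""
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    n = len(risks)
    k = int(np.floor(fraction * n))
    if k < 1:
        raise ValueError("groups would be empty at this fraction")
    vals = risks.to_numpy()
    order = np.lexsort((np.arange(n), -vals))  # descending risk, index-order ties
    boundary_tied = (
        (n > k and vals[order[k - 1]] == vals[order[k]])
        or (n > k and vals[order[n - k]] == vals[order[n - k - 1]])
    )
    if boundary_tied:
        logger.info("tied risks at a stratification boundary; broken by sample order")
    labels = pd.Series("excluded", index=risks.index, dtype=object)
    labels.iloc[order[:k]] = "high"
    labels.iloc[order[n - k:]] = "low"
    return labels


def transfer_to_external_cohort(
    results: AffinityRegressionResults,
    external_P: Optional[pd.DataFrame] = None,
    external_Y: Optional[pd.DataFrame] = None,
    center: str = "external",
) -> Tuple[ActivityMatrix, float]:
    """Apply a trained model to an external cohort on the shared features.

    With protein data, W is restricted to the protein features present in
    the external cohort and TF activities W P' are computed; with expression
    data, D and W rows are restricted to shared genes and protein activities
    Y' D W are computed.  ``center='external'`` (default) centres the
    external matrix by its own feature means; ``'training'`` applies the
    stored training means.  Returns the activities and the fraction of
    training features retained.
    """
    if (external_P is None) == (external_Y is None):
        raise ValueError("provide exactly one of external_P or external_Y")
    if external_P is not None:
        shared = results.W.columns.intersection(external_P.columns)
        if len(shared) == 0:
            raise AlignmentError("no shared protein features with the training model")
        retention = len(shared) / results.W.shape[1]
        P = external_P[shared]
        if center == "external":
            P, _ = mean_center(P, axis=0)
        else:
            P, _ = mean_center(P, axis=0, reference_means=results.model.protein_means.loc[shared])
        act = results.W[shared].to_numpy() @ P.to_numpy().T
        values = pd.DataFrame(act, index=results.W.index, columns=P.index)
        out = ActivityMatrix(values, pd.Series("tf", index=values.index))
    else:
        shared = results.model.gene_ids.intersection(external_Y.index)
        if len(shared) == 0:
            raise AlignmentError("no shared genes with the training model")
        retention = len(shared) / len(results.model.gene_ids)
        Y = external_Y.loc[shared]
        if center == "external":
            Y, _ = mean_center(Y, axis=1)
        else:
            Y, _ = mean_center(Y, axis=1, reference_means=results.model.gene_means.loc[shared])
        D = results.model.D.loc[shared].to_numpy()
        act = results.W.to_numpy().T @ D.T @ Y.to_numpy()
        values = pd.DataFrame(act, index=results.W.columns, columns=Y.columns)
        out = ActivityMatrix(values, pd.Series("protein", index=values.index))
    if retention < 1.0:
        logger.info("external transfer retained %.1f%% of training features", 100 * retention)
    return out, retention


def concordance_validation(
    risks: pd.Series,
    clinical: ClinicalTable,
    n_permutations: int = 1000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Harrell's concordance index of externally derived risk scores, with a
    two-sided seeded permutation p against C = 0.5.

    Higher risk is expected to mean earlier events, so concordance is
    computed on the negated risks.
    """
    clin = clinical.table.loc[risks.index]
    t = clin["time_months"].to_numpy()
    e = clin["event"].to_numpy()
    if e.sum() == 0:
        raise ValueError("no comparable pairs: no events observed")
    r = risks.to_numpy()
    c = concordance_index(t, -r, e)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = concordance_index(t, -r[rng.permutation(len(r))], e)
    p = (1.0 + np.sum(np.abs(null - 0.5) >= abs(c - 0.5))) / (n_permutations + 1.0)
    return float(c), float(p)


def km_export(
    groups: pd.Series, clinical: ClinicalTable
) -> pd.DataFrame:
    """Kaplan–Meier-ready table: per group, event times with at-risk and
    event counts (for plotting or external tools)."""
    clin = clinical.table.loc[groups.index]
    rows = []
    for g in groups.unique():
        if g == "excluded":
            continue
        idx = groups[groups == g].index
        t = clin.loc[idx, "time_months"].to_numpy()
        e = clin.loc[idx, "event"].to_numpy()
        order = np.argsort(t)
        t, e = t[order], e[order]
        at_risk = len(t)
        for ti, ei in zip(t, e):
            rows.append({"group": g, "time": float(ti), "at_risk": at_risk, "event": int(ei)})
            at_risk -= 1
    return pd.DataFrame(rows)
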