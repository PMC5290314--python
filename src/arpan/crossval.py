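"""Cross-validated held-out prediction of expression from protein profiles.

For each fold, gene selection, centring and the interaction matrix are
computed on the training samples only; each held-out sample's expression is
predicted by mapping its (training-centred) protein profile to similarities
with the training samples and reconstructing through their span.  Model
quality is summarized as the per-sample rank correlation between predicted
and measured (training-centred) expression.

Baselines sharing the identical fold structure: a nearest-neighbour
predictor in protein space, and control fits with motif rows and/or protein
rows randomized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .cohort import CohortBundle, ExpressionMatrix
from .model import AffinityRegression, nearest_neighbour_baseline
from .preprocess import mean_center, select_top_variable_genes

logger = logging.getLogger(__name__)

__all__ = ["cross_validate", "PredictionReport", "MODEL_LABELS"]

MODEL_LABELS = ("true", "motif", "rppa", "both", "nn")

DEFAULT_LAMBDA_GRID = (1.0,)


@dataclass
class PredictionReport:
    """Per-held-out-sample prediction quality for one model variant."""

    records: pd.DataFrame  # sample_id, fold, correlation, rmse, model
    metric: str
    model: str
    seed: int

    @property
    def mean_correlation(self) -> float:
        return float(self.records["correlation"].mean())

    @property
    def mean_rmse(self) -> float:
        return float(self.records["rmse"].mean())

    def summary(self) -> str:
        return (
            f"CV report [{self.model}] metric={self.metric} seed={self.seed}: "
            f"mean r={self.mean_correlation:.4f} rmse={self.mean_rmse:.4f} "
            f"({len(self.records)} held-out samples)"
        )


def _fold_assignment(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(order, folds)):
        assignment[chunk] = f
    return assignment


def _metric_value(pred: np.ndarray, meas: np.ndarray, metric: str):
    if metric == "rmse":
        return None
    if np.ptp(pred) == 0 or np.ptp(meas) == 0:
        logger.warning("constant profile: correlation undefined, recorded as missing")
        return np.nan
    if metric == "spearman":
        return float(scipy.stats.spearmanr(pred, meas).statistic)
    if metric == "pearson":
        return float(scipy.stats.pearsonr(pred, meas).statistic)
    raise ValueError(f"unknown metric {metric!r}")


def _shuffled(arr: np.ndarray, do: bool, rng: np.random.Generator) -> np.ndarray:
    return arr[rng.permutation(arr.shape[0])] if do else arr


def cross_validate(
    bundle: CohortBundle,
    folds: int = 10,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    metric: str = "spearman",
    seed: int = 0,
    model: str = "true",
    n_genes: Optional[int] = 5000,
) -> PredictionReport:
    """K-fold held-out evaluation of expression prediction.

    Parameters
    ----------
    model : one of ``'true'``, ``'motif'``, ``'rppa'``, ``'both'``, ``'nn'``
        The affinity-regression model, its randomized controls (motif rows
        and/or protein rows shuffled within the training set), or the
        nearest-neighbour baseline.
    lambda_grid : candidate ridge penalties; with more than one value the
        penalty is chosen per fold on an inner 80/20 split of the training
        samples by mean held-out correlation.
    n_genes : restrict to this many top-variance genes per training fold
        (``None`` keeps all genes).
    """
    if model not in MODEL_LABELS:
        raise ValueError(f"model must be one of {MODEL_LABELS}")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    Y_raw = bundle.expression.values
    D_all = bundle.motifs.hits
    P_raw = bundle.proteins.values
    M = Y_raw.shape[1]
    if M < folds:
        raise ValueError("more folds than samples")

    rng = np.random.default_rng(seed)
    assignment = _fold_assignment(M, folds, rng)
    shuffle_rng = np.random.default_rng(rng.integers(2**31))

    rows = []
    for f in range(folds):
        test_mask = assignment == f
        train_ids = Y_raw.columns[~test_mask]
        test_ids = Y_raw.columns[test_mask]

        Y_tr_raw = Y_raw[train_ids]
        if n_genes is not None and n_genes < Y_tr_raw.shape[0]:
            expr_tr = select_top_variable_genes(ExpressionMatrix(Y_tr_raw), n_genes)
            genes = expr_tr.values.index
        else:
            genes = Y_tr_raw.index
        Y_tr, gene_means = mean_center(Y_raw.loc[genes, train_ids], axis=1)
        P_tr, prot_means = mean_center(P_raw.loc[train_ids], axis=0)
        Y_te, _ = mean_center(Y_raw.loc[genes, test_ids], axis=1, reference_means=gene_means)
        P_te, _ = mean_center(P_raw.loc[test_ids], axis=0, reference_means=prot_means)
        D_tr = D_all.loc[genes]

        if model == "nn":
            for sid in test_ids:
                pred = nearest_neighbour_baseline(P_tr, Y_tr, P_te.loc[sid].to_numpy())
                meas = Y_te[sid].to_numpy()
                rows.append(_record(sid, f, pred, meas, metric, model))
            continue

        D_use = pd.DataFrame(
            _shuffled(D_tr.to_numpy(), model in ("motif", "both"), shuffle_rng),
            index=D_tr.index, columns=D_tr.columns,
        )
        P_use = pd.DataFrame(
            _shuffled(P_tr.to_numpy(), model in ("rppa", "both"), shuffle_rng),
            index=P_tr.index, columns=P_tr.columns,
        )
        ar = AffinityRegression(Y_tr, D_use, P_use, center=False)
        lam = _select_lambda(ar, lambda_grid, metric, shuffle_rng)
        res = ar.fit(lam)
        for sid in test_ids:
            pred = res.predict(P_te.loc[sid].to_numpy())
            meas = Y_te[sid].to_numpy()
            rows.append(_record(sid, f, pred, meas, metric, model))

    records = pd.DataFrame(rows)
    return PredictionReport(records, metric, model, seed)


def _record(sid, fold, pred, meas, metric, model) -> dict:
    corr = _metric_value(pred, meas, metric if metric != "rmse" else "spearman")
    rmse = float(np.sqrt(np.mean((pred - meas) ** 2)))
    return {"sample_id": sid, "fold": fold, "correlation": corr, "rmse": rmse, "model": model}


def _select_lambda(
    ar: AffinityRegression,
    lambda_grid: Sequence[float],
    metric: str,
    rng: np.random.Generator,
) -> float:
    """Pick the ridge penalty on an inner 80/20 split of the training samples."""
    grid = list(lambda_grid)
    if len(grid) == 1:
        return float(grid[0])
    M = len(ar.sample_ids)
    n_val = max(1, M // 5)
    order = rng.permutation(M)
    val_ids = ar.sample_ids[order[:n_val]]
    inner_ids = ar.sample_ids[order[n_val:]]
    Y_in, g_means = mean_center(ar.Y[inner_ids], axis=1)
    P_in, p_means = mean_center(ar.P.loc[inner_ids], axis=0)
    Y_val, _ = mean_center(ar.Y[val_ids], axis=1, reference_means=g_means)
    P_val, _ = mean_center(ar.P.loc[val_ids], axis=0, reference_means=p_means)
    inner = AffinityRegression(Y_in, ar.D, P_in, center=False)
    best_lam, best_score = grid[0], -np.inf
    for lam in grid:
        res = inner.fit(lam)
        scores = []
        for sid in val_ids:
            pred = res.predict(P_val.loc[sid].to_numpy())
            val = _metric_value(pred, Y_val[sid].to_numpy(), metric if metric != "rmse" else "spearman")
            if val is not None and not np.isnan(val):
                scores.append(val if metric != "rmse" else -np.sqrt(np.mean((pred - Y_val[sid].to_numpy()) ** 2)))
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score:
            best_lam, best_score = lam, score
    logger.info("inner-split selected lambda=%g (score %.4f)", best_lam, best_score)
    return float(best_lam)
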