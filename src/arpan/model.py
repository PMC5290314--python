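"""Bilinear ridge (affinity) regression linking protein profiles to gene
expression through transcription-factor binding sites.

The model explains a mean-centred expression matrix ``Y`` (N genes x M
samples) as

    Y = D W P' + E

where ``D`` (N x Q) holds binary TF binding-site calls per gene promoter,
``P`` (M x S) holds mean-centred (phospho)protein abundances per sample, and
``W`` (Q x S) is the learned TF-by-protein interaction matrix.  ``W`` is the
minimizer of the ridge objective

    || Y - D W P' ||_F^2 + lambda || W ||_F^2 ,

whose normal equations, via the Kronecker identity
vec(D W P' ) = (P ⊗ D) vec(W), read

    vec(W) = (P'P ⊗ D'D + lambda I)^-1 vec(D' Y P).

The solver diagonalizes D'D and P'P once, so refits against new response
matrices (cross-validation folds, permutation nulls) cost only two small
matrix products.

Fitted models expose the two activity mappings:

* TF activities ``W P'`` — a Q x M matrix scoring each TF's regulatory
  output per sample from the sample's protein profile;
* (phospho)protein activities ``Y' D W`` — an expression-informed S x M
  score of each protein feature per sample;

plus held-out prediction (sample similarities ``Y' D W p`` reconstructed
into an expression profile through the span of the training profiles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.linalg

from .cohort import AlignmentError, CohortBundle, ExpressionMatrix, MotifHitMatrix, ProteinMatrix
from .preprocess import mean_center

logger = logging.getLogger(__name__)

__all__ = [
    "AffinityRegression",
    "AffinityRegressionResults",
    "ActivityMatrix",
    "BilinearSolver",
    "nearest_neighbour_baseline",
    "randomized_control_fit",
]


@dataclass
class ActivityMatrix:
    """Inferred regulator activities, regulators x samples, with a per-row
    kind tag ('tf' or 'protein')."""

    values: pd.DataFrame
    regulator_kind: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.regulator_kind.index):
            raise AlignmentError("regulator_kind index must match activity rows")

    @property
    def regulators(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @staticmethod
    def concat(parts: list["ActivityMatrix"]) -> "ActivityMatrix":
        return ActivityMatrix(
            pd.concat([p.values for p in parts]),
            pd.concat([p.regulator_kind for p in parts]),
        )


class BilinearSolver:
    """Pre-factorized solver for min_W ||Y - D W P'||^2 + lambda ||W||^2.

    Eigendecompositions of D'D (Q x Q) and P'P (S x S) are computed once at
    construction; :meth:`solve` then handles any response matrix Y in
    O(NQM + QS) — essential when the same design is refit thousands of times
    against permuted responses.
    """

    def __init__(self, D: np.ndarray, P: np.ndarray):
        self.D = np.asarray(D, dtype=float)
        self.P = np.asarray(P, dtype=float)
        self._dd_vals, self._dd_vecs = scipy.linalg.eigh(self.D.T @ self.D)
        self._pp_vals, self._pp_vecs = scipy.linalg.eigh(self.P.T @ self.P)
        # clip tiny negative eigenvalues from roundoff
        self._dd_vals = np.clip(self._dd_vals, 0.0, None)
        self._pp_vals = np.clip(self._pp_vals, 0.0, None)
        # outer product of eigenvalues = spectrum of P'P ⊗ D'D
        self._denom_base = np.outer(self._dd_vals, self._pp_vals)

    def solve(self, Y: np.ndarray, lam: float) -> np.ndarray:
        """Return the Q x S minimizer for response Y (N x M)."""
        if lam < 0:
            raise ValueError("lambda must be non-negative")
        denom = self._denom_base + lam
        scale = max(self._denom_base.max(), 1.0)
        if denom.min() <= scale * 1e-12:
            raise np.linalg.LinAlgError(
                "normal equations are singular at lambda=0; use a positive ridge penalty"
            )
        C = self.D.T @ np.asarray(Y, dtype=float) @ self.P  # D' Y P, Q x S
        Ct = self._dd_vecs.T @ C @ self._pp_vecs
        Wt = Ct / denom
        return self._dd_vecs @ Wt @ self._pp_vecs.T

    def solve_core(self, DtYP: np.ndarray, lam: float) -> np.ndarray:
        """Like :meth:`solve` but takes the precomputed cross-product D'YP."""
        denom = self._denom_base + lam
        Ct = self._dd_vecs.T @ np.asarray(DtYP, dtype=float) @ self._pp_vecs
        return self._dd_vecs @ (Ct / denom) @ self._pp_vecs.T


def _as_frame(obj, attr: str) -> pd.DataFrame:
    return getattr(obj, attr) if not isinstance(obj, pd.DataFrame) else obj


class AffinityRegression:
    """Bilinear ridge regression model of an expression cohort.

    Parameters
    ----------
    Y : ExpressionMatrix or DataFrame (genes x samples)
        Log-scale expression.  Centred per gene at fit time unless
        ``center=False``.
    D : MotifHitMatrix or DataFrame (genes x TFs)
        Binary binding-site calls; gene order must match ``Y``.
    P : ProteinMatrix or DataFrame (samples x protein features)
        (Phospho)protein abundances; sample order must match ``Y`` columns.

    Examples
    --------
    >>> model = AffinityRegression.from_bundle(bundle)   # doctest: +SKIP
    >>> res = model.fit(lam=1.0)                         # doctest: +SKIP
    >>> res.tf_activities().values                       # doctest: +SKIP
    """

    def __init__(
        self,
        Y: Union[ExpressionMatrix, pd.DataFrame],
        D: Union[MotifHitMatrix, pd.DataFrame],
        P: Union[ProteinMatrix, pd.DataFrame],
        center: bool = True,
    ):
        Ydf = _as_frame(Y, "values")
        Ddf = _as_frame(D, "hits")
        Pdf = _as_frame(P, "values")
        if not Ydf.index.equals(Ddf.index):
            raise AlignmentError("Y and D must share an identical gene order")
        if not Ydf.columns.equals(Pdf.index):
            raise AlignmentError("Y columns and P rows must share an identical sample order")
        self.gene_ids = Ydf.index
        self.sample_ids = Ydf.columns
        self.tf_ids = Ddf.columns
        self.feature_ids = Pdf.columns
        if center:
            Yc, y_means = mean_center(Ydf, axis=1)
            Pc, p_means = mean_center(Pdf, axis=0)
        else:
            Yc, y_means = Ydf, pd.Series(0.0, index=Ydf.index)
            Pc, p_means = Pdf, pd.Series(0.0, index=Pdf.columns)
        self.Y = Yc
        self.D = Ddf
        self.P = Pc
        self.gene_means = y_means
        self.protein_means = p_means
        self._solver: Optional[BilinearSolver] = None

    @classmethod
    def from_bundle(cls, bundle: CohortBundle, center: bool = True) -> "AffinityRegression":
        bundle.validate_aligned()
        return cls(bundle.expression, bundle.motifs, bundle.proteins, center=center)

    @property
    def solver(self) -> BilinearSolver:
        if self._solver is None:
            self._solver = BilinearSolver(self.D.to_numpy(), self.P.to_numpy())
        return self._solver

    def fit(self, lam: float = 1.0) -> "AffinityRegressionResults":
        """Fit the interaction matrix at ridge penalty ``lam``."""
        W = self.solver.solve(self.Y.to_numpy(), lam)
        return AffinityRegressionResults(self, W, lam)


class AffinityRegressionResults:
    """Fitted interaction matrix plus the mappings it induces.

    Attributes
    ----------
    W : DataFrame, TFs x protein features
        The learned interaction matrix.
    lam : float
        Ridge penalty used.
    """

    def __init__(self, model: AffinityRegression, W: np.ndarray, lam: float):
        if not np.isfinite(W).all():
            raise np.linalg.LinAlgError("non-finite entries in fitted W")
        self.model = model
        self.W = pd.DataFrame(W, index=model.tf_ids, columns=model.feature_ids)
        self.lam = float(lam)

    # -- activity mappings -------------------------------------------------

    def tf_activities(self, P: Optional[pd.DataFrame] = None) -> ActivityMatrix:
        """Infer per-sample TF activities W P' (TFs x samples).

        ``P`` must be centred with the training protein means; by default
        the training matrix itself is used.
        """
        Pdf = self.model.P if P is None else _as_frame(P, "values")
        if not Pdf.columns.equals(self.W.columns):
            raise AlignmentError("protein features do not match W columns")
        act = self.W.to_numpy() @ Pdf.to_numpy().T
        values = pd.DataFrame(act, index=self.W.index, columns=Pdf.index)
        return ActivityMatrix(values, pd.Series("tf", index=values.index))

    def protein_activities(self, Y: Optional[pd.DataFrame] = None) -> ActivityMatrix:
        """Infer per-sample (phospho)protein activities Y' D W, stored as
        features x samples.

        ``Y`` must be centred with the training gene means and share the
        training gene order; by default the training matrix is used.
        """
        Ydf = self.model.Y if Y is None else _as_frame(Y, "values")
        if not Ydf.index.equals(self.model.gene_ids):
            raise AlignmentError("gene order does not match the training matrix")
        act = self.W.to_numpy().T @ self.model.D.to_numpy().T @ Ydf.to_numpy()
        values = pd.DataFrame(act, index=self.W.columns, columns=Ydf.columns)
        return ActivityMatrix(values, pd.Series("protein", index=values.index))

    def activities(self) -> ActivityMatrix:
        """Both regulator families stacked (TF rows then protein rows)."""
        return ActivityMatrix.concat([self.tf_activities(), self.protein_activities()])

    # -- held-out prediction ----------------------------------------------

    def predict_similarities(self, p_new: np.ndarray) -> np.ndarray:
        """Map one centred protein profile to predicted similarities with the
        training samples: s = Y' D W p."""
        p = np.asarray(p_new, dtype=float).ravel()
        if p.shape[0] != self.W.shape[1]:
            raise AlignmentError(
                f"expected {self.W.shape[1]} protein features, got {p.shape[0]}"
            )
        return self.model.Y.to_numpy().T @ (
            self.model.D.to_numpy() @ (self.W.to_numpy() @ p)
        )

    def reconstruct_expression(
        self, s: np.ndarray, ridge_eps: Optional[float] = None
    ) -> np.ndarray:
        """Convert a similarity vector into an expression profile via the
        span of the training profiles: solve (Y'Y + eps I) a = s, return Y a.
        """
        Y = self.model.Y.to_numpy()
        s = np.asarray(s, dtype=float).ravel()
        if s.shape[0] != Y.shape[1]:
            raise AlignmentError("similarity vector length must equal training samples")
        G = Y.T @ Y
        if ridge_eps is None:
            ridge_eps = 1e-6 * np.trace(G) / G.shape[0]
        a = scipy.linalg.solve(G + ridge_eps * np.eye(G.shape[0]), s, assume_a="pos")
        return Y @ a

    def predict(self, p_new: np.ndarray, ridge_eps: Optional[float] = None) -> np.ndarray:
        """Predict the centred expression profile of a new sample from its
        centred protein profile."""
        return self.reconstruct_expression(self.predict_similarities(p_new), ridge_eps)

    # -- diagnostics -------------------------------------------------------

    def fitted_values(self) -> pd.DataFrame:
        """In-sample reconstruction D W P' (genes x samples)."""
        fit = self.model.D.to_numpy() @ self.W.to_numpy() @ self.model.P.to_numpy().T
        return pd.DataFrame(fit, index=self.model.gene_ids, columns=self.model.sample_ids)

    def resid(self) -> pd.DataFrame:
        return self.model.Y - self.fitted_values()

    def rsquared(self) -> float:
        ss_res = float((self.resid().to_numpy() ** 2).sum())
        ss_tot = float((self.model.Y.to_numpy() ** 2).sum())
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    def summary(self) -> str:
        m = self.model
        lines = [
            "Affinity Regression Results",
            "=" * 45,
            f"Genes (N):              {len(m.gene_ids)}",
            f"Samples (M):            {len(m.sample_ids)}",
            f"TFs (Q):                {len(m.tf_ids)}",
            f"Protein features (S):   {len(m.feature_ids)}",
            f"Ridge penalty lambda:   {self.lam:g}",
            f"||W||_F:                {np.linalg.norm(self.W.to_numpy()):.4f}",
            f"In-sample R^2:          {self.rsquared():.4f}",
            "=" * 45,
        ]
        return "\n".join(lines)


def nearest_neighbour_baseline(
    P_train: pd.DataFrame, Y_train: pd.DataFrame, p_test: np.ndarray
) -> np.ndarray:
    """Predict a test sample's expression as that of the training sample
    nearest in (centred) protein space; ties go to the lowest index."""
    if P_train.shape[0] == 0:
        raise ValueError("empty training set")
    diffs = P_train.to_numpy() - np.asarray(p_test, dtype=float).ravel()
    d2 = (diffs**2).sum(axis=1)
    j = int(np.argmin(d2))  # argmin returns the first minimum -> lowest index
    if (d2 == d2[j]).sum() > 1:
        logger.info("nearest-neighbour tie broken by lowest sample index (%s)", j)
    return Y_train.to_numpy()[:, j]


def randomized_control_fit(
    model: AffinityRegression, mode: str, seed: int, lam: float = 1.0
) -> AffinityRegressionResults:
    """Fit a degraded control model with shuffled inputs.

    ``mode='motif'`` permutes D's rows (gene labels of the binding-site
    calls), ``'rppa'`` permutes P's rows (sample labels of the protein
    profiles), ``'both'`` does both.  The row multiset of each matrix is
    unchanged; only the pairing with Y is destroyed.
    """
    if mode not in {"motif", "rppa", "both"}:
        raise ValueError(f"unknown randomization mode {mode!r}")
    rng = np.random.default_rng(seed)
    D = model.D.to_numpy()
    P = model.P.to_numpy()
    if mode in {"motif", "both"}:
        D = D[rng.permutation(D.shape[0])]
    if mode in {"rppa", "both"}:
        P = P[rng.permutation(P.shape[0])]
    ctrl = AffinityRegression(
        model.Y,
        pd.DataFrame(D, index=model.gene_ids, columns=model.tf_ids),
        pd.DataFrame(P, index=model.sample_ids, columns=model.feature_ids),
        center=False,  # Y and P already centred by the parent model
    )
    ctrl.gene_means = model.gene_means
    ctrl.protein_means = model.protein_means
    return ctrl.fit(lam)
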