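"""Aligned data containers for a proteogenomic cohort.

A cohort couples four molecular matrices and a clinical table:

* expression ``Y`` — genes x samples, log-scale RNA abundance;
* motif hits ``D`` — genes x TFs, binary promoter binding-site calls;
* proteins ``P`` — samples x antibody features, RPPA-style log abundance;
* alterations — samples x binary somatic-event calls;
* clinical — survival time, event indicator, background covariate, subgroup.

All containers wrap :class:`pandas.DataFrame` and validate uniqueness,
completeness and mutual alignment.  ``CohortBundle.align`` re-sorts every
component to a single canonical sample order (the expression column order)
and a single gene order (the expression row order), so downstream code can
rely on positional agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "MotifHitMatrix",
    "ProteinMatrix",
    "AlterationMatrix",
    "ClinicalTable",
    "CohortBundle",
    "ValidationError",
    "AlignmentError",
]


class ValidationError(ValueError):
    """An input matrix violates a structural invariant (duplicates, NA, range)."""


class AlignmentError(ValueError):
    """Two components that must share an index do not."""


def _check_frame(df: pd.DataFrame, name: str) -> None:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{name}: duplicate row id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"{name}: duplicate column id {dup!r}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ValidationError(f"{name}: missing values (e.g. in column {col!r})")


@dataclass
class ExpressionMatrix:
    """Log-scale gene expression, genes x samples.

    ``centring_means`` holds the per-gene offsets subtracted during
    mean-centring; they are required to centre held-out or external samples
    relative to the training set.
    """

    values: pd.DataFrame
    centring_means: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        _check_frame(self.values, "expression")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class MotifHitMatrix:
    """Binary genes x TFs matrix of promoter binding-site calls."""

    hits: pd.DataFrame

    def __post_init__(self) -> None:
        _check_frame(self.hits, "motifs")
        vals = self.hits.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("motifs: entries must be 0/1")

    @property
    def gene_ids(self) -> pd.Index:
        return self.hits.index

    @property
    def tf_ids(self) -> pd.Index:
        return self.hits.columns

    @property
    def n_tfs(self) -> int:
        return self.hits.shape[1]


@dataclass
class ProteinMatrix:
    """RPPA-style (phospho)protein abundance, samples x antibody features."""

    values: pd.DataFrame
    centring_means: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        _check_frame(self.values, "proteins")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


#: allowed alteration kinds
ALTERATION_KINDS = ("mutation", "amplification", "deletion")


@dataclass
class AlterationMatrix:
    """Binary samples x alterations matrix of somatic-event calls.

    ``meta`` (indexed by alteration id) carries the gene symbol and the event
    kind (mutation / amplification / deletion) for each column.
    """

    calls: pd.DataFrame
    meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        _check_frame(self.calls, "alterations")
        vals = self.calls.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("alterations: entries must be 0/1")
        if self.meta is None:
            self.meta = pd.DataFrame(
                {"gene": list(self.calls.columns), "kind": "mutation"},
                index=self.calls.columns,
            )
        if not self.meta.index.equals(self.calls.columns):
            raise AlignmentError("alteration meta index does not match call columns")

    @property
    def sample_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def alteration_ids(self) -> pd.Index:
        return self.calls.columns


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation.

    Expected columns: ``time_months`` (>= 0), ``event`` (0/1; 1 =
    disease-specific death), ``covariate`` (categorical background factor,
    e.g. stage or histology) and optionally ``subgroup``.
    """

    table: pd.DataFrame

    REQUIRED = ("time_months", "event")

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValidationError(f"clinical: duplicate sample id {dup!r}")
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"clinical: missing column {col!r}")
        t = self.table["time_months"]
        if (t < 0).any():
            raise ValidationError("clinical: negative survival time")
        ev = self.table["event"]
        if not ev.isin((0, 1)).all():
            raise ValidationError("clinical: event must be 0/1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class CohortBundle:
    """All cohort components aligned on one sample order and one gene order."""

    expression: ExpressionMatrix
    motifs: MotifHitMatrix
    proteins: ProteinMatrix
    alterations: Optional[AlterationMatrix] = None
    clinical: Optional[ClinicalTable] = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.sample_ids

    @property
    def gene_ids(self) -> pd.Index:
        return self.expression.gene_ids

    def align(self) -> "CohortBundle":
        """Return a bundle with every component re-sorted to the expression
        matrix's sample and gene order.

        Samples must be shared by expression and proteins (and alterations /
        clinical when present); genes must be shared by expression and motifs.
        """
        samples = self.expression.sample_ids
        genes = self.expression.gene_ids

        def _need(have: pd.Index, what: str) -> None:
            missing = samples.difference(have) if what != "genes" else genes.difference(have)
            if len(missing):
                raise AlignmentError(f"{what}: missing ids, e.g. {missing[0]!r}")

        _need(self.proteins.sample_ids, "proteins")
        _need(self.motifs.gene_ids, "genes")
        motifs = MotifHitMatrix(self.motifs.hits.loc[genes])
        proteins = ProteinMatrix(
            self.proteins.values.loc[samples], self.proteins.centring_means
        )
        alterations = None
        if self.alterations is not None:
            _need(self.alterations.sample_ids, "alterations")
            alterations = AlterationMatrix(
                self.alterations.calls.loc[samples], self.alterations.meta
            )
        clinical = None
        if self.clinical is not None:
            _need(self.clinical.sample_ids, "clinical")
            clinical = ClinicalTable(self.clinical.table.loc[samples])
        return CohortBundle(self.expression, motifs, proteins, alterations, clinical)

    def validate_aligned(self) -> None:
        if not self.proteins.sample_ids.equals(self.sample_ids):
            raise AlignmentError("proteins not aligned to expression samples")
        if not self.motifs.gene_ids.equals(self.gene_ids):
            raise AlignmentError("motifs not aligned to expression genes")
        if self.alterations is not None and not self.alterations.sample_ids.equals(
            self.sample_ids
        ):
            raise AlignmentError("alterations not aligned to expression samples")
        if self.clinical is not None and not self.clinical.sample_ids.equals(
            self.sample_ids
        ):
            raise AlignmentError("clinical not aligned to expression samples")
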