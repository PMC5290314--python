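"""Cohort preprocessing: variance filtering, centring, alteration encoding,
TF-expression filtering and motif de-duplication.

These transforms reproduce the standard preparation of a TCGA-style cohort
for bilinear modelling: restrict expression to the most variable genes,
mean-centre genes and protein features on the training set, binarize somatic
events (non-silent driver mutations, homozygous deletions and high-level
amplifications recurrent in >= 10 samples), drop TFs whose own gene is
expressed in fewer than 40% of samples, and collapse motif columns with
near-identical target sets.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import (
    AlterationMatrix,
    AlignmentError,
    ExpressionMatrix,
    MotifHitMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "select_top_variable_genes",
    "mean_center",
    "build_alteration_matrix",
    "filter_tf_columns",
    "deduplicate_motifs",
]


def select_top_variable_genes(expr: ExpressionMatrix, k: int = 5000) -> ExpressionMatrix:
    """Keep the ``k`` genes with largest variance across samples.

    Ties are broken by input order; surviving genes keep their original
    relative order.  ``k`` larger than the gene count returns everything
    with a logged warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = expr.values
    n = values.shape[0]
    if k >= n:
        if k > n:
            logger.warning("requested %d genes but only %d available; keeping all", k, n)
        return ExpressionMatrix(values.copy(), expr.centring_means)
    variances = values.var(axis=1, ddof=1).to_numpy()
    # stable sort on descending variance -> earlier rows win ties
    order = np.argsort(-variances, kind="stable")[:k]
    keep = np.sort(order)  # preserve original gene order among survivors
    return ExpressionMatrix(values.iloc[keep], None)


def mean_center(
    matrix: pd.DataFrame,
    axis: int = 1,
    reference_means: Optional[pd.Series] = None,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Centre each profile of ``matrix`` and return (centred, offsets).

    ``axis=1`` centres each row over its columns (per-gene centring of a
    genes x samples matrix); ``axis=0`` centres each column over its rows
    (per-feature centring of a samples x features matrix).  When
    ``reference_means`` is given (e.g. training means applied to held-out
    samples) those offsets are subtracted instead of the matrix's own means.
    """
    if matrix.size == 0:
        raise ValueError("cannot centre an empty matrix")
    profile_index = matrix.index if axis == 1 else matrix.columns
    if reference_means is not None:
        if not profile_index.equals(reference_means.index):
            missing = profile_index.difference(reference_means.index)
            raise AlignmentError(
                "reference means do not cover all profiles"
                + (f", e.g. {missing[0]!r}" if len(missing) else " (order mismatch)")
            )
        means = reference_means
    else:
        means = matrix.mean(axis=axis)
        means.index = profile_index
    if axis == 1:
        centred = matrix.sub(means, axis=0)
    else:
        centred = matrix.sub(means, axis=1)
    return centred, means


def build_alteration_matrix(
    mutations: pd.DataFrame,
    cna_calls: Optional[pd.DataFrame] = None,
    cna_q: Optional[pd.Series] = None,
    sample_ids: Optional[Sequence] = None,
    min_recurrence: int = 10,
    mut_q_threshold: float = 0.05,
    cna_q_threshold: float = 0.001,
) -> AlterationMatrix:
    """Binarize somatic events into a samples x alterations 0/1 matrix.

    Mutations
        A long table with columns ``sample_id``, ``gene``, ``variant_class``
        and optionally ``q_value`` (driver-significance q, MutSigCV-style).
        Silent mutations are removed; a gene is kept only when its driver q
        is below ``mut_q_threshold`` and it is mutated in at least
        ``min_recurrence`` samples.

    Copy number
        ``cna_calls`` is a gene x sample matrix of discrete calls in
        {-2,-1,0,1,2}; a sample is altered iff its call is -2 (homozygous
        loss) or +2 (high-level amplification).  A gene is kept only when
        its region q (``cna_q``) is below ``cna_q_threshold`` and it is
        altered in at least ``min_recurrence`` samples.  Amplification and
        deletion events of one gene become separate columns.
    """
    if sample_ids is None:
        ids = set(mutations["sample_id"]) if len(mutations) else set()
        if cna_calls is not None:
            ids |= set(cna_calls.columns)
        sample_index = pd.Index(sorted(ids))
    else:
        sample_index = pd.Index(sample_ids)

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []

    mut = mutations[mutations["variant_class"].str.lower() != "silent"].copy()
    if len(mut) == 0 and len(mutations) > 0:
        logger.info("all mutations were silent; mutation block is empty")
    if len(mut):
        if "q_value" in mut.columns:
            mut = mut[mut["q_value"] < mut_q_threshold]
        for gene in pd.unique(mut["gene"]):
            carriers = set(mut.loc[mut["gene"] == gene, "sample_id"])
            carriers &= set(sample_index)
            if len(carriers) < min_recurrence:
                logger.info(
                    "dropping mutation %s: %d carriers < %d", gene, len(carriers), min_recurrence
                )
                continue
            vec = sample_index.isin(carriers).astype(int)
            columns[f"{gene}_mut"] = vec
            meta_rows.append({"id": f"{gene}_mut", "gene": gene, "kind": "mutation"})

    if cna_calls is not None:
        arr = cna_calls.to_numpy()
        if not np.isin(arr, (-2, -1, 0, 1, 2)).all():
            raise ValidationError("CNA calls must be discrete in -2..2")
        calls = cna_calls.reindex(columns=sample_index)
        for gene in calls.index:
            if cna_q is not None:
                q = cna_q.get(gene, np.nan)
                if not (q < cna_q_threshold):
                    continue
            row = calls.loc[gene]
            for call_value, kind, suffix in ((2, "amplification", "amp"), (-2, "deletion", "del")):
                vec = (row == call_value).astype(int).to_numpy()
                if vec.sum() < min_recurrence:
                    continue
                cid = f"{gene}_{suffix}"
                columns[cid] = vec
                meta_rows.append({"id": cid, "gene": gene, "kind": kind})

    calls_df = pd.DataFrame(columns, index=sample_index, dtype=int)
    # deterministic column order regardless of dict insertion quirks
    calls_df = calls_df[sorted(calls_df.columns)]
    meta = (
        pd.DataFrame(meta_rows).set_index("id").loc[calls_df.columns]
        if meta_rows
        else pd.DataFrame(columns=["gene", "kind"])
    )
    return AlterationMatrix(calls_df, meta)


def filter_tf_columns(
    motifs: MotifHitMatrix,
    raw_expression: pd.DataFrame,
    min_fraction: float = 0.40,
    expressed_threshold: Optional[float] = None,
    tf_to_gene: Optional[dict] = None,
) -> MotifHitMatrix:
    """Drop TFs whose own gene is expressed in fewer than ``min_fraction``
    of samples (boundary inclusive: exactly 40% is kept).

    "Expressed" means the raw (pre-centring) log value exceeds
    ``expressed_threshold``; by default the threshold is the matrix's global
    minimum, i.e. the dataset's zero floor.  TFs whose id cannot be resolved
    to a gene row are reported and dropped.
    """
    if expressed_threshold is None:
        expressed_threshold = float(raw_expression.to_numpy().min())
    keep = []
    for tf in motifs.tf_ids:
        gene = tf_to_gene.get(tf, tf) if tf_to_gene else tf
        if gene not in raw_expression.index:
            logger.warning("TF %s not resolvable to an expression row; dropped", tf)
            continue
        frac = float((raw_expression.loc[gene] > expressed_threshold).mean())
        if frac >= min_fraction:
            keep.append(tf)
        else:
            logger.info("TF %s expressed in %.1f%% of samples; dropped", tf, 100 * frac)
    return MotifHitMatrix(motifs.hits[keep])


def deduplicate_motifs(
    motifs: MotifHitMatrix, similarity_threshold: float = 0.8
) -> MotifHitMatrix:
    """Greedy de-duplication of motif columns by target-set Jaccard similarity.

    Walk the columns in order; a column is removed when its Jaccard
    similarity with any previously retained column reaches the threshold.
    Two all-zero columns have Jaccard 0 by convention.
    """
    if not 0 < similarity_threshold <= 1:
        raise ValueError("similarity_threshold must be in (0, 1]")
    hits = motifs.hits.to_numpy().astype(bool)
    retained: list[int] = []
    for j in range(hits.shape[1]):
        col = hits[:, j]
        dropped = False
        for i in retained:
            inter = np.logical_and(col, hits[:, i]).sum()
            union = np.logical_or(col, hits[:, i]).sum()
            jac = inter / union if union else 0.0
            if jac >= similarity_threshold:
                logger.info(
                    "motif %s removed (Jaccard %.3f with retained %s)",
                    motifs.tf_ids[j], jac, motifs.tf_ids[i],
                )
                dropped = True
                break
        if not dropped:
            retained.append(j)
    return MotifHitMatrix(motifs.hits.iloc[:, retained])
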