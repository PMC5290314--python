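"""Reading and writing cohort matrices as tab-delimited text.

Dialect: UTF-8 TSV, one header row of column ids, first column of row ids,
``.`` decimal separator.  Mutation calls come as a long table
(sample_id, gene, variant_class[, q_value]); discrete copy-number calls as a
gene x sample TSV of integers in -2..2 with a per-gene q-value table.

A :class:`~arpan.cohort.CohortBundle` serializes to a directory of TSVs plus
a JSON manifest recording component shapes.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .cohort import (
    AlterationMatrix,
    ClinicalTable,
    CohortBundle,
    ExpressionMatrix,
    MotifHitMatrix,
    ProteinMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

__all__ = ["read_matrix", "write_matrix", "read_bundle", "write_bundle"]


def read_matrix(
    path: PathLike, orientation: str = "row", binary: bool = False
) -> pd.DataFrame:
    """Read a TSV matrix with row ids in the first column.

    Parameters
    ----------
    path : file path
    orientation : label for the row entity, used only in error messages.
    binary : when True, validate that every entry is 0 or 1.

    Raises
    ------
    ValidationError
        On duplicate row/column ids, non-numeric cells (with location) or,
        for ``binary=True``, out-of-range entries.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path.name}: duplicate {orientation} id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"{path.name}: duplicate column id {dup!r}")
    try:
        out = df.astype(float)
    except ValueError:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ValidationError(
                    f"{path.name}: non-numeric cell at row {row!r}, column {col!r}"
                ) from None
        raise
    if out.isna().any().any():
        col = out.columns[out.isna().any()][0]
        raise ValidationError(f"{path.name}: missing value in column {col!r}")
    if binary and not np.isin(out.to_numpy(), (0.0, 1.0)).all():
        raise ValidationError(f"{path.name}: expected a 0/1 matrix")
    return out


def write_matrix(df: pd.DataFrame, path: PathLike) -> None:
    """Write a matrix as TSV; float formatting uses repr round-trip precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_mutation_calls(path: PathLike) -> pd.DataFrame:
    """Read a long-format mutation table with columns sample_id, gene,
    variant_class and optionally q_value."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "gene", "variant_class"):
        if col not in df.columns:
            raise ValidationError(f"mutation table: missing column {col!r}")
    return df


def read_clinical(path: PathLike) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValidationError("clinical table: missing column 'sample_id'")
    return ClinicalTable(df.set_index("sample_id"))


_FILES = {
    "expression": "expression.tsv",
    "motifs": "motifs.tsv",
    "proteins": "proteins.tsv",
    "alterations": "alterations.tsv",
    "alteration_meta": "alteration_meta.tsv",
    "clinical": "clinical.tsv",
    "manifest": "manifest.json",
}


def write_bundle(bundle: CohortBundle, outdir: PathLike) -> Path:
    """Serialize an aligned bundle to a directory of TSVs plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(bundle.expression.values, outdir / _FILES["expression"])
    write_matrix(bundle.motifs.hits.astype(int), outdir / _FILES["motifs"])
    write_matrix(bundle.proteins.values, outdir / _FILES["proteins"])
    manifest = {
        "n_genes": int(bundle.expression.n_genes),
        "n_samples": int(bundle.expression.n_samples),
        "n_tfs": int(bundle.motifs.n_tfs),
        "n_protein_features": int(bundle.proteins.n_features),
        "has_alterations": bundle.alterations is not None,
        "has_clinical": bundle.clinical is not None,
    }
    if bundle.alterations is not None:
        write_matrix(bundle.alterations.calls.astype(int), outdir / _FILES["alterations"])
        bundle.alterations.meta.to_csv(outdir / _FILES["alteration_meta"], sep="\t")
    if bundle.clinical is not None:
        bundle.clinical.table.to_csv(
            outdir / _FILES["clinical"], sep="\t", index_label="sample_id"
        )
    (outdir / _FILES["manifest"]).write_text(json.dumps(manifest, indent=2))
    return outdir


def read_bundle(indir: PathLike) -> CohortBundle:
    """Load a bundle directory written by :func:`write_bundle` and align it."""
    indir = Path(indir)
    expr = ExpressionMatrix(read_matrix(indir / _FILES["expression"], "gene"))
    motifs = MotifHitMatrix(
        read_matrix(indir / _FILES["motifs"], "gene", binary=True).astype(int)
    )
    proteins = ProteinMatrix(read_matrix(indir / _FILES["proteins"], "sample"))
    alterations = None
    alt_path = indir / _FILES["alterations"]
    if alt_path.exists():
        calls = read_matrix(alt_path, "sample", binary=True).astype(int)
        meta = None
        meta_path = indir / _FILES["alteration_meta"]
        if meta_path.exists():
            meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        alterations = AlterationMatrix(calls, meta)
    clinical = None
    clin_path = indir / _FILES["clinical"]
    if clin_path.exists():
        clinical = read_clinical(clin_path)
    bundle = CohortBundle(expr, motifs, proteins, alterations, clinical)
    return bundle.align()
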