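"""Readers, writers and filters for the compendium inputs.

Expression matrices travel as GCT v1.2 text files (genes x samples, TPM);
sample attributes as a TSV with columns ``SAMPID``, ``SMTSD``, ``SMRIN``,
``SUBJID``.  In memory an expression matrix is a :class:`pandas.DataFrame`
with gene ids on the index and sample ids on the columns, and a tissue
design is a :class:`pandas.DataFrame` indexed by sample id with columns
``tissue``, ``donor`` and ``rin``.

The filters mirror a standard multi-tissue compendium protocol: drop
non-tissue sample classes (e.g. cultured cell lines), keep samples with
RIN >= 6.0, keep tissues with at least 30 distinct donors, then keep genes
expressed above a TPM floor in a minimum fraction of samples and above a
median floor in the focal tissue.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GctParseError",
    "read_gct",
    "write_gct",
    "read_sample_attributes",
    "write_sample_attributes",
    "validate_expression",
    "validate_design",
    "filter_samples",
    "filter_genes",
    "tissue_medians",
    "strip_gene_version",
]

DESIGN_COLUMNS = ("tissue", "donor", "rin")


class GctParseError(ValueError):
    """Raised when a GCT file violates the v1.2 dialect."""


def read_gct(path_or_buffer) -> pd.DataFrame:
    """Read a GCT v1.2 file into a genes x samples DataFrame.

    The ``Description`` column is parsed and discarded; the ``Name`` column
    becomes the index.  Values must be finite and non-negative.
    """
    if hasattr(path_or_buffer, "read"):
        handle = path_or_buffer
        close = False
    else:
        handle = open(path_or_buffer, "rt")
        close = True
    try:
        version = handle.readline().rstrip("\n")
        if version != "#1.2":
            raise GctParseError(
                f"line 1: expected GCT version line '#1.2', got {version!r}"
            )
        dims = handle.readline().rstrip("\n").split("\t")
        if len(dims) < 2:
            raise GctParseError("line 2: expected 'n_rows<TAB>n_cols'")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise GctParseError(f"line 2: non-integer dimensions {dims[:2]}") from exc
        body = pd.read_csv(handle, sep="\t", header=0, index_col=0)
    finally:
        if close:
            handle.close()
    if "Description" in body.columns:
        body = body.drop(columns="Description")
    else:
        raise GctParseError("line 3: missing 'Description' column")
    if body.shape != (n_rows, n_cols):
        raise GctParseError(
            f"dimension mismatch: header declares {n_rows}x{n_cols}, "
            f"body is {body.shape[0]}x{body.shape[1]}"
        )
    body.index.name = "Name"
    matrix = body.astype(float)
    validate_expression(matrix)
    return matrix


def write_gct(matrix: pd.DataFrame, path_or_buffer, descriptions=None) -> None:
    """Write a genes x samples DataFrame as GCT v1.2.

    Round-trips bit-identically with :func:`read_gct` for finite values
    (full float precision is written).
    """
    validate_expression(matrix)
    if descriptions is None:
        descriptions = pd.Series("na", index=matrix.index)
    out = matrix.copy()
    out.insert(0, "Description", descriptions)
    buf = io.StringIO()
    buf.write("#1.2\n")
    buf.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
    out.to_csv(buf, sep="\t", index_label="Name", float_format="%.17g")
    text = buf.getvalue()
    if hasattr(path_or_buffer, "write"):
        path_or_buffer.write(text)
    else:
        with open(path_or_buffer, "wt") as fh:
            fh.write(text)


def validate_expression(matrix: pd.DataFrame) -> None:
    """Check the expression-matrix invariants; raise ``ValueError`` on failure."""
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    if matrix.columns.has_duplicates:
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes[:5]}")
    values = matrix.to_numpy()
    if values.size and not np.all(np.isfinite(values)):
        raise ValueError("expression values must be finite")
    if values.size and (values < 0).any():
        raise ValueError("expression values must be non-negative")


def read_sample_attributes(path_or_buffer) -> pd.DataFrame:
    """Read a sample-attributes TSV (SAMPID, SMTSD, SMRIN, SUBJID) into a design."""
    raw = pd.read_csv(path_or_buffer, sep="\t", dtype={"SAMPID": str, "SUBJID": str})
    required = {"SAMPID", "SMTSD", "SMRIN", "SUBJID"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"sample attributes missing columns: {sorted(missing)}")
    design = pd.DataFrame(
        {
            "tissue": raw["SMTSD"].astype(str).to_numpy(),
            "donor": raw["SUBJID"].astype(str).to_numpy(),
            "rin": raw["SMRIN"].astype(float).to_numpy(),
        },
        index=pd.Index(raw["SAMPID"].astype(str), name="SAMPID"),
    )
    validate_design(design)
    return design


def write_sample_attributes(design: pd.DataFrame, path_or_buffer) -> None:
    validate_design(design)
    out = pd.DataFrame(
        {
            "SAMPID": design.index,
            "SMTSD": design["tissue"].to_numpy(),
            "SMRIN": design["rin"].to_numpy(),
            "SUBJID": design["donor"].to_numpy(),
        }
    )
    out.to_csv(path_or_buffer, sep="\t", index=False)


def validate_design(design: pd.DataFrame) -> None:
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValueError(f"design missing columns: {sorted(missing)}")
    if design.index.has_duplicates:
        raise ValueError("duplicate sample ids in design")


def filter_samples(
    design: pd.DataFrame,
    min_donors: int = 30,
    min_rin: float = 6.0,
    excluded_labels: Iterable[str] = (),
) -> pd.DataFrame:
    """Apply the sample-level filters, returning the retained design rows.

    Order of operations: excluded (non-tissue) labels are removed first,
    then samples with RIN below ``min_rin``, then whole tissues whose
    distinct-donor count (after the RIN filter) falls below ``min_donors``.

    Raises ``ValueError`` if every sample is removed.
    """
    validate_design(design)
    if design.empty:
        raise ValueError("design is empty")
    excluded = set(excluded_labels)
    keep = ~design["tissue"].isin(excluded)
    keep &= design["rin"] >= min_rin
    retained = design.loc[keep]
    donor_counts = retained.groupby("tissue")["donor"].nunique()
    good_tissues = donor_counts.index[donor_counts >= min_donors]
    retained = retained.loc[retained["tissue"].isin(good_tissues)]
    if retained.empty:
        raise ValueError(
            "sample filters removed every sample "
            f"(min_donors={min_donors}, min_rin={min_rin})"
        )
    return retained


def filter_genes(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    heart_tissues: Sequence[str],
    tpm_floor: float = 0.1,
    min_fraction: float = 0.2,
    heart_median_floor: float = 0.5,
    fraction_scope: str = "global",
) -> dict[str, pd.DataFrame]:
    """Apply the gene-level filters, one filtered matrix per focal tissue.

    A gene is kept for a focal tissue iff

    * its TPM is strictly above ``tpm_floor`` in at least ``min_fraction``
      of samples (``fraction_scope='global'``: across all retained samples;
      ``'per_tissue'``: in at least one tissue), and
    * its median TPM within the focal tissue is strictly above
      ``heart_median_floor``.

    Returns ``{focal_tissue: filtered expression matrix}``.  Idempotent.
    """
    validate_expression(expr)
    validate_design(design)
    common = expr.columns.intersection(design.index)
    if len(common) == 0:
        raise ValueError("no overlap between expression samples and design")
    expr = expr[common]
    design = design.loc[common]
    for tissue in heart_tissues:
        if tissue not in set(design["tissue"]):
            raise ValueError(f"focal tissue {tissue!r} absent from design")
    values = expr.to_numpy()
    if fraction_scope == "global":
        frac = (values > tpm_floor).mean(axis=1)
        detect = frac >= min_fraction
    elif fraction_scope == "per_tissue":
        detect = np.zeros(expr.shape[0], dtype=bool)
        for tissue, cols in design.groupby("tissue").groups.items():
            sub = expr[list(cols)].to_numpy()
            detect |= (sub > tpm_floor).mean(axis=1) >= min_fraction
    else:
        raise ValueError(f"unknown fraction_scope {fraction_scope!r}")
    result: dict[str, pd.DataFrame] = {}
    for tissue in heart_tissues:
        cols = design.index[design["tissue"] == tissue]
        med = np.median(expr[cols].to_numpy(), axis=1)
        keep = detect & (med > heart_median_floor)
        result[tissue] = expr.loc[keep]
    return result


def tissue_medians(expr: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-gene per-tissue median TPM (genes x tissues).

    Medians of even-sized samples use the midpoint (mean of the two central
    order statistics).  Invariant to sample ordering within a tissue.
    """
    validate_expression(expr)
    validate_design(design)
    common = expr.columns.intersection(design.index)
    if len(common) < len(expr.columns):
        raise ValueError("expression contains samples absent from design")
    design = design.loc[expr.columns]
    tissues = sorted(design["tissue"].unique())
    out = np.empty((expr.shape[0], len(tissues)))
    for j, tissue in enumerate(tissues):
        cols = design.index[design["tissue"] == tissue]
        if len(cols) == 0:
            raise ValueError(f"tissue {tissue!r} has no samples")
        out[:, j] = np.median(expr[cols].to_numpy(), axis=1)
    return pd.DataFrame(out, index=expr.index, columns=tissues)


def strip_gene_version(gene_ids: pd.Index | Sequence[str]) -> pd.Index:
    """Drop trailing ``.N`` accession-version suffixes (``ENSG...123.4`` -> ``ENSG...123``).

    Used when joining TPM and count matrices annotated at different times.
    """
    return pd.Index([gid.rsplit(".", 1)[0] if "." in gid else gid for gid in gene_ids])
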