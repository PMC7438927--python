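"""Differential expression between the two heart tissues from read counts.

Counts are filtered (>= 6 reads in at least 20% of samples within either
group, union retained), depth-normalised with median-of-ratios size
factors, transformed to ``log2(normalized count + 0.5)``, and tested with
the package's moderated-t machinery.  A gene is a DEG when its
Benjamini-Hochberg FDR is below the cutoff *and* its |log2 fold change|
exceeds the threshold (default 3, i.e. 8-fold); the fold change is
expressed AA over LV, so positive values mean higher in the atrial
appendage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import modstats

__all__ = [
    "DegResult",
    "filter_counts",
    "size_factors",
    "call_degs",
]


@dataclass
class DegResult:
    """Per-gene DEG table plus the thresholds that produced the calls."""

    table: pd.DataFrame  # columns: log2fc, p, fdr, call
    lfc_threshold: float
    fdr_cutoff: float

    @property
    def up_in_first(self) -> pd.Index:
        return self.table.index[self.table["call"] == "up_AA"]

    @property
    def up_in_second(self) -> pd.Index:
        return self.table.index[self.table["call"] == "up_LV"]


def _validate_counts(counts: pd.DataFrame, groups: pd.Series) -> pd.Series:
    values = counts.to_numpy()
    if values.size and (values < 0).any():
        raise ValueError("counts must be non-negative")
    if values.size and not np.allclose(values, np.round(values)):
        raise ValueError("counts must be integers")
    groups = groups.loc[counts.columns]
    labels = groups.unique()
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(labels)}")
    return groups


def filter_counts(
    counts: pd.DataFrame,
    groups: pd.Series,
    min_count: int = 6,
    min_fraction: float = 0.2,
) -> pd.DataFrame:
    """Keep genes passing the count criterion within either group (union rule).

    A gene passes within a group when at least ``min_fraction`` of that
    group's samples have ``count >= min_count`` (both bounds inclusive).
    """
    groups = _validate_counts(counts, groups)
    keep = np.zeros(counts.shape[0], dtype=bool)
    for label in groups.unique():
        cols = groups.index[groups == label]
        sub = counts[cols].to_numpy()
        keep |= (sub >= min_count).mean(axis=1) >= min_fraction
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios sequencing-depth factors, one per sample.

    The reference for each gene is its geometric mean across samples,
    computed over genes with strictly positive counts in every sample;
    each sample's factor is the median of its count-to-reference ratios.
    """
    values = counts.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "apply filter_counts first or relax the filter"
        )
    ref = values[all_positive]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geo_mean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def call_degs(
    counts: pd.DataFrame,
    groups: pd.Series,
    first_group: str = "AA",
    second_group: str = "LV",
    lfc_threshold: float = 3.0,
    fdr: float = 0.01,
    lfc_inclusive: bool = False,
    pseudocount: float = 0.5,
) -> DegResult:
    """Call DEGs between the two groups on the normalized log2 scale.

    ``log2fc`` is the difference of group means of
    ``log2(count / size_factor + pseudocount)``, first group minus second
    (positive = higher in the first group).  P-values come from the
    moderated t on that scale; BH correction runs across the tested genes
    only (genes removed by :func:`filter_counts` never enter).  Boundary
    behaviour of the fold-change gate is strict by default
    (``|log2fc| > threshold``); set ``lfc_inclusive`` for ``>=``.
    """
    groups = _validate_counts(counts, groups)
    for label in (first_group, second_group):
        n = int((groups == label).sum())
        if n < 2:
            raise ValueError(f"group {label!r} has {n} samples; need >= 2")

    sf = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    log_norm = pd.DataFrame(
        np.log2(norm + pseudocount), index=counts.index, columns=counts.columns
    )
    design = pd.DataFrame({"tissue": groups, "donor": groups.index, "rin": 10.0})
    fit = modstats.fit_tissue_model(log_norm, design)
    prior = modstats.ebayes_shrink(fit.s2, fit.df_residual)
    contrast = modstats.pairwise_contrasts(
        fit.tissues, first_group, [second_group]
    )
    tests = modstats.contrast_tests(fit, contrast, prior)

    log2fc = tests.estimates.iloc[:, 0]
    p = tests.p.iloc[:, 0]
    fdr_vals = pd.Series(
        multipletests(p.to_numpy(), method="fdr_bh")[1], index=p.index, name="fdr"
    )
    if lfc_inclusive:
        big = log2fc.abs() >= lfc_threshold
    else:
        big = log2fc.abs() > lfc_threshold
    significant = fdr_vals < fdr
    call = np.where(
        big & significant & (log2fc > 0),
        "up_AA",
        np.where(big & significant & (log2fc < 0), "up_LV", "not_de"),
    )
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": fdr_vals, "call": call},
        index=counts.index,
    )
    return DegResult(table=table, lfc_threshold=lfc_threshold, fdr_cutoff=fdr)
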