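"""Relative median values, top-K ranking and specific/enhanced classification.

A gene's *relative median value* (RMV) is its median expression in the
focal tissue divided by the mean of its medians across the comparison
tissues.  Its *fold change of medians* (FCM) against one comparison tissue
is the ratio of the two tissue medians.  A gene is called

* ``specific`` when its FCM is strictly above the fold cutoff (default 5)
  against every comparison tissue and the focal-vs-tissue contrast is
  significant (FDR below the cutoff) for every comparison tissue;
* ``enhanced_except_1`` / ``enhanced_except_2`` when the FCM criterion
  fails for exactly 1 or 2 "exception" tissues, the focal median is still
  strictly greater than each exception tissue's median, and significance
  holds against every non-exception tissue;
* ``none`` otherwise.

Division conventions: a positive numerator over a zero denominator is
``+inf`` (exclusive expression, the strongest evidence); ``0/0`` is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpecificityCall",
    "compute_rmv",
    "top_k",
    "classify_specificity",
    "classify_one",
    "rmv_zscore_matrix",
    "CALL_LEVELS",
]

CALL_LEVELS = ("specific", "enhanced_except_1", "enhanced_except_2", "none")


@dataclass
class SpecificityCall:
    """Classification of one gene for one focal tissue."""

    gene_id: str
    call: str
    fcm: Mapping[str, float]
    exception_tissues: tuple[str, ...] = field(default_factory=tuple)
    significant: bool = False

    def __post_init__(self) -> None:
        if self.call not in CALL_LEVELS:
            raise ValueError(f"unknown call {self.call!r}")
        if self.call == "specific" and self.exception_tissues:
            raise ValueError("specific call cannot carry exception tissues")
        if self.call.startswith("enhanced_except_"):
            k = int(self.call[-1])
            if len(self.exception_tissues) != k:
                raise ValueError(
                    f"{self.call} requires exactly {k} exception tissues"
                )


def _ratio(numer: np.ndarray, denom: np.ndarray) -> np.ndarray:
    """Elementwise ratio with x/0 = +inf for x > 0 and 0/0 = 0."""
    numer = np.asarray(numer, dtype=float)
    denom = np.asarray(denom, dtype=float)
    out = np.empty(np.broadcast(numer, denom).shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.true_divide(numer, denom)
    out = np.where((denom == 0) & (numer > 0), np.inf, out)
    out = np.where((denom == 0) & (numer == 0), 0.0, out)
    return out


def compute_rmv(
    medians: pd.DataFrame,
    focal_tissue: str,
    comparison_tissues: Sequence[str],
) -> pd.DataFrame:
    """RMV per gene: focal median / mean of comparison-tissue medians.

    Returns a DataFrame indexed by gene with columns ``rmv`` and ``rank``
    (1-based, descending RMV, ties broken by lexicographic gene id).
    """
    comparison_tissues = list(comparison_tissues)
    if not comparison_tissues:
        raise ValueError("comparison tissue set is empty")
    if focal_tissue in comparison_tissues:
        raise ValueError(f"focal tissue {focal_tissue!r} in comparison set")
    focal = medians[focal_tissue].to_numpy()
    others = medians[comparison_tissues].to_numpy().mean(axis=1)
    rmv = _ratio(focal, others)
    table = pd.DataFrame({"rmv": rmv}, index=medians.index)
    # stable two-key sort: descending rmv, ties by ascending gene id
    order = np.lexsort((np.asarray(medians.index.astype(str)), -rmv))
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    table["rank"] = ranks
    return table


def top_k(rmv_table: pd.DataFrame, k: int = 500) -> list[str]:
    """The ``k`` gene ids with largest RMV; boundary ties broken by gene id."""
    if k > len(rmv_table):
        raise ValueError(f"k={k} exceeds the {len(rmv_table)} ranked genes")
    ordered = rmv_table.sort_values("rank")
    return list(ordered.index[:k])


def classify_one(
    focal_median: float,
    comparison_medians: Mapping[str, float],
    significant: Mapping[str, bool],
    fold: float = 5.0,
) -> tuple[str, tuple[str, ...]]:
    """Classify a single gene from its medians and per-contrast significance.

    Returns ``(call, exception_tissues)``.  This is the rule kernel the
    vectorised :func:`classify_specificity` must agree with; it is written
    as a direct transcription of the definitions.
    """
    tissues = list(comparison_medians)
    if len(tissues) < 3:
        raise ValueError("need at least 3 comparison tissues for exception logic")
    fails = [
        t
        for t in tissues
        if not _ratio(focal_median, comparison_medians[t]) > fold
    ]
    if not fails:
        if all(significant[t] for t in tissues):
            return "specific", ()
        return "none", ()
    if len(fails) <= 2:
        higher = all(focal_median > comparison_medians[t] for t in fails)
        non_exc_sig = all(significant[t] for t in tissues if t not in fails)
        if higher and non_exc_sig:
            return f"enhanced_except_{len(fails)}", tuple(sorted(fails))
    return "none", ()


def classify_specificity(
    medians: pd.DataFrame,
    focal_tissue: str,
    comparison_tissues: Sequence[str],
    significance: pd.DataFrame,
    fold: float = 5.0,
    genes: Sequence[str] | None = None,
) -> list[SpecificityCall]:
    """Classify every gene (or the ``genes`` subset) for one focal tissue.

    Parameters
    ----------
    medians
        Genes x tissues median table.
    significance
        Boolean genes x comparison-tissues frame: True where the
        focal-vs-tissue contrast passed the FDR cutoff.  Must cover every
        (gene, comparison tissue) pair.
    genes
        Optional restriction (e.g. the top-500 RMV genes); classification
        can be run on all filtered genes or only on a pre-ranked subset.
    """
    comparison_tissues = list(comparison_tissues)
    if len(comparison_tissues) < 3:
        raise ValueError("need at least 3 comparison tissues for exception logic")
    if focal_tissue in comparison_tissues:
        raise ValueError(f"focal tissue {focal_tissue!r} in comparison set")
    if genes is None:
        genes = medians.index
    missing = set(comparison_tissues) - set(significance.columns)
    if missing:
        raise ValueError(f"significance lacks comparison tissues: {sorted(missing)}")

    med = medians.loc[genes]
    sig = significance.loc[genes, comparison_tissues].to_numpy(dtype=bool)
    focal = med[focal_tissue].to_numpy()[:, None]
    comp = med[comparison_tissues].to_numpy()
    fcm = _ratio(focal, comp)

    pass_fold = fcm > fold
    n_fail = (~pass_fold).sum(axis=1)
    all_sig = sig.all(axis=1)
    # exceptions: fold test failed; enhanced requires focal strictly higher
    higher = focal > comp
    exc_ok = (~pass_fold & ~higher).sum(axis=1) == 0
    # significance required only against the non-exception tissues
    non_exc_sig = (sig | ~pass_fold).all(axis=1)

    calls: list[SpecificityCall] = []
    tissue_arr = np.array(comparison_tissues)
    for i, gene in enumerate(med.index):
        if n_fail[i] == 0:
            call = "specific" if all_sig[i] else "none"
            exc: tuple[str, ...] = ()
        elif n_fail[i] <= 2 and exc_ok[i] and non_exc_sig[i]:
            call = f"enhanced_except_{n_fail[i]}"
            exc = tuple(sorted(tissue_arr[~pass_fold[i]]))
        else:
            call, exc = "none", ()
        calls.append(
            SpecificityCall(
                gene_id=str(gene),
                call=call,
                fcm=dict(zip(comparison_tissues, fcm[i])),
                exception_tissues=exc,
                significant=bool(all_sig[i]) if call == "specific" else bool(
                    non_exc_sig[i]
                ),
            )
        )
    return calls


def calls_to_frame(calls: Sequence[SpecificityCall]) -> pd.DataFrame:
    """Tabulate calls for TSV export."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "call": [c.call for c in calls],
            "exception_tissues": [";".join(c.exception_tissues) for c in calls],
            "min_fcm": [min(c.fcm.values()) for c in calls],
        }
    ).set_index("gene_id")


def rmv_zscore_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Row z-scores (mean 0, sample SD 1) of an RMV or median table.

    Raises ``ValueError`` naming the offending genes if any row is constant
    (its SD would be zero).
    """
    values = table.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 columns to z-score rows")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        offenders = list(table.index[constant][:5])
        raise ValueError(f"constant rows cannot be z-scored: {offenders}")
    z = (values - mean) / sd
    return pd.DataFrame(z, index=table.index, columns=table.columns)
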