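"""Moderated linear-model statistics for the tissue contrasts.

The model is a one-way group-means fit per gene on the log scale
(``log2(TPM + 1)`` by default): the coefficient for each tissue is the
group mean, and the residual variance ``s2_g`` is the pooled within-group
variance on ``d_g = N - T`` degrees of freedom.

Empirical-Bayes moderation shrinks each ``s2_g`` towards a prior ``s0^2``
with ``d0`` prior degrees of freedom,

    s2_tilde_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g),

where ``(d0, s0^2)`` are estimated by moment matching on ``log s2`` under
a scaled-F marginal model (digamma/trigamma inversion).  Moderated t
statistics for tissue contrasts then use ``s2_tilde_g`` with ``d0 + d_g``
degrees of freedom, a moderated F tests all contrasts jointly, and
Benjamini-Hochberg correction is applied *globally* to the pooled vector
of all gene x contrast p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupMeansFit",
    "EBayesPrior",
    "ContrastTests",
    "fit_tissue_model",
    "ebayes_shrink",
    "trigamma_inverse",
    "contrast_tests",
    "pairwise_contrasts",
    "global_adjust",
    "log_transform",
]

D0_CAP = 1e7  # estimated prior dof beyond this is reported as infinite


def log_transform(expr: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """``log2(x + pseudocount)``; the fitting scale for TPM matrices."""
    return np.log2(expr + pseudocount)


@dataclass
class GroupMeansFit:
    """One-way fit: per-gene tissue means and pooled residual variance."""

    coefficients: pd.DataFrame  # genes x tissues, group means
    s2: pd.Series  # pooled residual variance per gene
    df_residual: float  # N - T
    group_sizes: pd.Series  # samples per tissue

    @property
    def tissues(self) -> list[str]:
        return list(self.coefficients.columns)


@dataclass
class EBayesPrior:
    """Estimated variance prior and the shrunken variances."""

    d0: float  # prior degrees of freedom; may be inf
    s0_2: float  # prior variance
    s2_post: pd.Series  # shrunken variance per gene


@dataclass
class ContrastTests:
    """Moderated per-contrast t tests plus the joint moderated F."""

    estimates: pd.DataFrame  # genes x contrasts
    t: pd.DataFrame
    p: pd.DataFrame  # raw two-sided p per contrast
    f: pd.Series
    f_p: pd.Series
    df_numerator: int
    df_total: float  # d0 + d_g


def fit_tissue_model(expr_log: pd.DataFrame, design: pd.DataFrame) -> GroupMeansFit:
    """Fit the one-way group-means model on the transformed scale.

    ``expr_log`` is genes x samples; ``design`` maps each sample to a
    tissue.  Every tissue needs >= 2 samples so the pooled variance is
    defined.
    """
    design = design.loc[expr_log.columns]
    tissues = sorted(design["tissue"].unique())
    sizes = design["tissue"].value_counts()
    small = sizes[sizes < 2]
    if not small.empty:
        raise ValueError(f"tissues with <2 samples: {sorted(small.index)}")
    values = expr_log.to_numpy(dtype=float)
    n_genes = values.shape[0]
    means = np.empty((n_genes, len(tissues)))
    rss = np.zeros(n_genes)
    for j, tissue in enumerate(tissues):
        cols = np.flatnonzero((design["tissue"] == tissue).to_numpy())
        sub = values[:, cols]
        means[:, j] = sub.mean(axis=1)
        rss += ((sub - means[:, [j]]) ** 2).sum(axis=1)
    df = values.shape[1] - len(tissues)
    s2 = rss / df
    return GroupMeansFit(
        coefficients=pd.DataFrame(means, index=expr_log.index, columns=tissues),
        s2=pd.Series(s2, index=expr_log.index, name="s2"),
        df_residual=float(df),
        group_sizes=pd.Series(
            [int(sizes[t]) for t in tissues], index=pd.Index(tissues), name="n"
        ),
    )


def trigamma_inverse(x: np.ndarray | float) -> np.ndarray:
    """Solve ``trigamma(y) = x`` for ``y > 0`` by Newton iteration.

    Monotone decreasing trigamma makes the iteration globally convergent
    from the asymptotic start ``y ~ 1/x + 0.5``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(np.abs(dif) / y) < 1e-10:
            break
    return y if y.size > 1 else float(y[0])


def ebayes_shrink(
    s2: pd.Series | np.ndarray,
    df: float,
    d0_override: float | None = None,
    s0_2_override: float | None = None,
) -> EBayesPrior:
    """Estimate the variance prior and shrink per-gene variances.

    Moment matching on ``z = log s2``: under the scaled-F model,
    ``E[z] = log s0^2 + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2)``
    and ``Var[z] = trigamma(d/2) + trigamma(d0/2)``.  When the observed
    variance of ``z`` does not exceed ``trigamma(d/2)``, the prior degrees
    of freedom are infinite and every shrunken variance equals ``s0^2``.

    ``d0_override`` / ``s0_2_override`` pin the hyperparameters (use
    ``d0_override=0`` for no shrinkage, ``np.inf`` for full shrinkage).
    """
    index = s2.index if isinstance(s2, pd.Series) else None
    s2_arr = np.asarray(s2, dtype=float)
    if np.any(s2_arr < 0):
        raise ValueError("negative variances")
    if df < 1:
        raise ValueError("residual degrees of freedom must be >= 1")

    if d0_override is None or s0_2_override is None:
        if s2_arr.size < 3 and np.ptp(s2_arr) > 0:
            raise ValueError("need >= 3 genes to estimate the variance prior")
        d0, s0_2 = _fit_f_dist(s2_arr, df)
    if d0_override is not None:
        d0 = float(d0_override)
    if s0_2_override is not None:
        s0_2 = float(s0_2_override)

    if d0 == 0:
        post = s2_arr.copy()
    elif np.isinf(d0):
        post = np.full_like(s2_arr, s0_2)
    else:
        post = (d0 * s0_2 + df * s2_arr) / (d0 + df)
    return EBayesPrior(
        d0=d0,
        s0_2=s0_2,
        s2_post=pd.Series(post, index=index, name="s2_post"),
    )


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F distribution to observed variances."""
    if np.ptp(s2) == 0.0:
        # degenerate: all residual variances identical
        return np.inf, float(s2[0])
    positive = s2[s2 > 0]
    if positive.size < s2.size:
        # log of zero variances is -inf; follow the standard practice of
        # offsetting by a tiny quantile so the moment equations stay finite
        floor = np.quantile(positive, 0.01) * 1e-4 if positive.size else 1e-12
        s2 = np.maximum(s2, floor)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    resid_var = e_var - special.polygamma(1, df / 2.0)
    if resid_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(resid_var)
    if d0 > D0_CAP:
        return np.inf, float(np.exp(e_mean))
    s0_2 = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_2)


def pairwise_contrasts(
    tissues: Sequence[str], focal_tissue: str, comparison_tissues: Sequence[str]
) -> pd.DataFrame:
    """Contrast matrix (tissues x contrasts) for focal-minus-each-comparison."""
    tissues = list(tissues)
    names = []
    cols = []
    for other in comparison_tissues:
        if other not in tissues:
            raise ValueError(f"contrast references unknown tissue {other!r}")
        c = np.zeros(len(tissues))
        c[tissues.index(focal_tissue)] = 1.0
        c[tissues.index(other)] = -1.0
        cols.append(c)
        names.append(f"{focal_tissue}-vs-{other}")
    return pd.DataFrame(np.column_stack(cols), index=tissues, columns=names)


def contrast_tests(
    fit: GroupMeansFit, contrasts: pd.DataFrame, prior: EBayesPrior
) -> ContrastTests:
    """Moderated t per contrast and moderated F over the contrast set.

    Each contrast is a linear combination of tissue coefficients.  With a
    balanced one-way design the coefficient covariance is diagonal
    (``s2/n_t``), so the standard error of contrast ``c`` is
    ``sqrt(sum_t c_t^2 / n_t) * s_tilde``.  The moderated F is the
    quadratic form over the (orthogonalised) contrast set divided by its
    rank.  Degenerate variances: a zero standard error yields t = 0 and
    p = 1 when the estimate is 0, else an infinite t with p = 0.
    """
    unknown = set(contrasts.index) - set(fit.tissues)
    if unknown:
        raise ValueError(f"contrast references unknown tissues: {sorted(unknown)}")
    C = contrasts.reindex(fit.tissues).fillna(0.0).to_numpy()  # tissues x q
    beta = fit.coefficients.to_numpy()  # genes x tissues
    n = fit.group_sizes.to_numpy(dtype=float)

    est = beta @ C  # genes x q
    unscaled_var = (C**2 / n[:, None]).sum(axis=0)  # q
    s_post = np.sqrt(prior.s2_post.to_numpy())
    df_total = (fit.df_residual + prior.d0) if np.isfinite(prior.d0) else np.inf

    se = s_post[:, None] * np.sqrt(unscaled_var)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    t = np.where((se == 0) & (est == 0), 0.0, t)
    signed_inf = np.where(est > 0, np.inf, -np.inf)
    t = np.where((se == 0) & (est != 0), signed_inf, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(np.isnan(t), 1.0, p)

    # moderated F: quadratic form in the contrast covariance, df = rank(C)
    cov = C.T @ (C / n[:, None])  # q x q unscaled covariance of estimates
    rank = np.linalg.matrix_rank(cov, tol=1e-12)
    cov_pinv = np.linalg.pinv(cov, rcond=1e-12)
    quad = np.einsum("gi,ij,gj->g", est, cov_pinv, est)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = quad / (rank * prior.s2_post.to_numpy())
    f = np.where((prior.s2_post.to_numpy() == 0) & (quad == 0), 0.0, f)
    f = np.where((prior.s2_post.to_numpy() == 0) & (quad > 0), np.inf, f)
    if np.isinf(df_total):
        f_p = stats.chi2.sf(rank * f, rank)
    else:
        f_p = stats.f.sf(f, rank, df_total)
    f_p = np.where(np.isinf(f), 0.0, f_p)

    genes = fit.coefficients.index
    names = contrasts.columns
    return ContrastTests(
        estimates=pd.DataFrame(est, index=genes, columns=names),
        t=pd.DataFrame(t, index=genes, columns=names),
        p=pd.DataFrame(p, index=genes, columns=names),
        f=pd.Series(f, index=genes, name="F"),
        f_p=pd.Series(f_p, index=genes, name="F_p"),
        df_numerator=int(rank),
        df_total=df_total,
    )


def global_adjust(p_matrix: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg over the pooled vector of all gene x contrast p-values.

    Pooling across contrasts (rather than adjusting each contrast column
    separately) is the 'global' multiple-testing strategy: one FDR level
    governs every test in the experiment.
    """
    values = p_matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        rows, cols = np.nonzero(np.isnan(values))
        offenders = [
            (str(p_matrix.index[r]), str(p_matrix.columns[c]))
            for r, c in zip(rows[:5], cols[:5])
        ]
        raise ValueError(f"NaN p-values at {offenders}")
    if ((values < 0) | (values > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    flat = values.ravel()
    adjusted = multipletests(flat, method="fdr_bh")[1]
    return pd.DataFrame(
        adjusted.reshape(values.shape), index=p_matrix.index, columns=p_matrix.columns
    )
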