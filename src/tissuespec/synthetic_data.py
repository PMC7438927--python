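"""Synthetic multi-tissue expression data with planted ground truth.

This module generates every input the pipeline consumes — a TPM matrix
with a tissue design, a two-group read-count matrix, a pathway database
and an abstract corpus — with the statistical structure the analysis
assumes, so each downstream stage can be verified against a known planted
design at desk scale.

The TPM generator draws a log-normal baseline per gene (heavy right tail,
as in real TPM distributions), sets per-tissue means by multiplying the
baseline by planted folds, and applies mean-preserving multiplicative
log-normal noise with a configurable coefficient of variation; ``cv=0``
yields exact tissue medians for truth-table tests.  Counts are
negative-binomial (gamma-Poisson) around group means with planted log2
fold changes and varying library sizes.  Pathways are gene sets of which
a stated fraction is enriched for planted genes.  Abstracts pair a chosen
subset of gene symbols with heart keywords; genes outside the subset
never co-occur with a heart keyword.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment, gtex_io, litmine

__all__ = [
    "PlantedSpecific",
    "PlantedEnhanced",
    "PlantedDeg",
    "SimConfig",
    "tissue_names",
    "simulate_tpm",
    "simulate_counts",
    "simulate_pathways",
    "simulate_abstracts",
    "write_inputs",
    "AA_TISSUE",
    "LV_TISSUE",
]

AA_TISSUE = "Heart - Atrial Appendage"
LV_TISSUE = "Heart - Left Ventricle"


@dataclass(frozen=True)
class PlantedSpecific:
    """A gene elevated ``fold``-fold in one target tissue only."""

    gene: int
    tissue: int
    fold: float


@dataclass(frozen=True)
class PlantedEnhanced:
    """A gene elevated in its target tissue plus 1-2 exception tissues."""

    gene: int
    tissue: int
    exceptions: tuple[int, ...]
    fold: float
    exception_fold: float


@dataclass(frozen=True)
class PlantedDeg:
    """A gene with a planted AA-over-LV log2 fold change in the counts."""

    gene: int
    log2_fold: float


@dataclass
class SimConfig:
    """Parameters of the synthetic compendium.

    The first two tissues are the focal heart tissues (atrial appendage
    and left ventricle); remaining tissues are generic.  Defaults emulate
    a filtered multi-tissue compendium at desk scale: 20 tissues of 30
    donors each, log-normal baselines around 2^3 = 8 TPM with log2 SD 1.5,
    30% multiplicative noise, and moderate negative-binomial dispersion.
    """

    n_tissues: int = 20
    samples_per_tissue: int = 30
    n_genes: int = 2000
    baseline_log_mean: float = 3.0  # log2 TPM
    baseline_log_sd: float = 1.5
    cv: float = 0.3  # multiplicative noise CV; 0 = noiseless
    planted_specific: tuple[PlantedSpecific, ...] = ()
    planted_enhanced: tuple[PlantedEnhanced, ...] = ()
    planted_deg: tuple[PlantedDeg, ...] = ()
    nb_dispersion: float = 0.05
    count_log_mean: float = 6.0  # log2 scale of count means
    lib_size_range: tuple[float, float] = (0.5, 2.0)
    rin_range: tuple[float, float] = (6.0, 10.0)
    rin_low_fraction: float = 0.0  # fraction of samples with RIN below 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tissues < 2:
            raise ValueError("need at least the two focal heart tissues")
        if self.samples_per_tissue < 2:
            raise ValueError("need >= 2 samples per tissue")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be strictly positive")
        if not 0 <= self.rin_low_fraction <= 1:
            raise ValueError("rin_low_fraction must lie in [0, 1]")
        self.planted_specific = tuple(
            p if isinstance(p, PlantedSpecific) else PlantedSpecific(*p)
            for p in self.planted_specific
        )
        self.planted_enhanced = tuple(
            p if isinstance(p, PlantedEnhanced) else PlantedEnhanced(
                p[0], p[1], tuple(p[2]), p[3], p[4]
            )
            for p in self.planted_enhanced
        )
        self.planted_deg = tuple(
            p if isinstance(p, PlantedDeg) else PlantedDeg(*p)
            for p in self.planted_deg
        )
        for p in self.planted_specific:
            self._check_gene(p.gene)
            self._check_tissue(p.tissue)
            if p.fold <= 0:
                raise ValueError(f"planted fold must be positive (gene {p.gene})")
        for p in self.planted_enhanced:
            self._check_gene(p.gene)
            self._check_tissue(p.tissue)
            if not 1 <= len(p.exceptions) <= 2:
                raise ValueError(
                    f"gene {p.gene}: exception list must have length 1 or 2"
                )
            if p.tissue in p.exceptions:
                raise ValueError(
                    f"gene {p.gene}: target tissue cannot be its own exception"
                )
            for t in p.exceptions:
                self._check_tissue(t)
            if p.fold <= 0 or p.exception_fold <= 0:
                raise ValueError(f"planted folds must be positive (gene {p.gene})")
        for p in self.planted_deg:
            self._check_gene(p.gene)

    def _check_gene(self, idx: int) -> None:
        if not 0 <= idx < self.n_genes:
            raise ValueError(f"planted gene index {idx} out of range [0, {self.n_genes})")

    def _check_tissue(self, idx: int) -> None:
        if not 0 <= idx < self.n_tissues:
            raise ValueError(
                f"planted tissue index {idx} out of range [0, {self.n_tissues})"
            )


def tissue_names(config: SimConfig) -> list[str]:
    """Tissue labels; indices 0 and 1 are the focal heart tissues."""
    names = [AA_TISSUE, LV_TISSUE]
    names += [f"Tissue_{i:02d}" for i in range(2, config.n_tissues)]
    return names


def gene_ids(config: SimConfig) -> pd.Index:
    return pd.Index([f"G{i:05d}" for i in range(config.n_genes)], name="Name")


def _tissue_mean_matrix(config: SimConfig, baseline: np.ndarray) -> np.ndarray:
    """Per-gene per-tissue means: baseline everywhere, planted folds applied."""
    means = np.tile(baseline[:, None], (1, config.n_tissues))
    for p in config.planted_specific:
        means[p.gene, p.tissue] = baseline[p.gene] * p.fold
    for p in config.planted_enhanced:
        means[p.gene, p.tissue] = baseline[p.gene] * p.fold
        for t in p.exceptions:
            means[p.gene, t] = baseline[p.gene] * p.exception_fold
    return means


def simulate_tpm(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the TPM matrix and its tissue design.

    Returns ``(expr, design)``: genes x samples TPM values and a design
    frame (sample -> tissue, donor, RIN).  Noise is multiplicative
    log-normal with CV ``config.cv``, mean-preserving, so planted fold
    ratios of tissue medians are exact at ``cv=0`` and unbiased otherwise.
    """
    rng = np.random.default_rng(config.seed)
    baseline = 2.0 ** rng.normal(
        config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes
    )
    means = _tissue_mean_matrix(config, baseline)

    names = tissue_names(config)
    n_samples = config.n_tissues * config.samples_per_tissue
    sample_ids = []
    tissue_col = []
    donor_col = []
    for t, name in enumerate(names):
        for s in range(config.samples_per_tissue):
            sample_ids.append(f"S-{t:02d}-{s:03d}")
            tissue_col.append(name)
            donor_col.append(f"D{s:04d}")

    if config.cv > 0:
        sigma2 = np.log1p(config.cv**2)
        noise = np.exp(
            rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=(config.n_genes, n_samples))
        )
    else:
        noise = np.ones((config.n_genes, n_samples))
    tissue_idx = np.repeat(np.arange(config.n_tissues), config.samples_per_tissue)
    values = means[:, tissue_idx] * noise

    rin = _simulate_rin(rng, config, n_samples)
    expr = pd.DataFrame(
        values, index=gene_ids(config), columns=pd.Index(sample_ids, name="SAMPID")
    )
    design = pd.DataFrame(
        {"tissue": tissue_col, "donor": donor_col, "rin": rin},
        index=expr.columns,
    )
    return expr, design


def _simulate_rin(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    lo, hi = config.rin_range
    rin = rng.uniform(max(lo, 6.0), max(hi, 6.0), size=n)
    if config.rin_low_fraction > 0:
        low = rng.random(n) < config.rin_low_fraction
        rin[low] = rng.uniform(min(lo, 6.0 - 1e-6), 6.0, size=int(low.sum()))
    return rin


def simulate_counts(
    config: SimConfig, group_labels: tuple[str, str] = ("AA", "LV")
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a two-group negative-binomial count matrix.

    Group means split the planted log2 fold symmetrically (AA mean =
    base * 2^(lfc/2), LV mean = base * 2^(-lfc/2)), library sizes vary
    uniformly over ``config.lib_size_range``, and counts are gamma-Poisson
    with dispersion alpha = ``config.nb_dispersion`` (variance
    mu + alpha * mu^2).  Returns ``(counts, groups)`` with
    ``config.samples_per_tissue`` samples per group.
    """
    rng = np.random.default_rng(config.seed + 1)
    base = 2.0 ** rng.normal(
        config.count_log_mean, config.baseline_log_sd, size=config.n_genes
    )
    lfc = np.zeros(config.n_genes)
    for p in config.planted_deg:
        lfc[p.gene] = p.log2_fold
    mean_first = base * 2.0 ** (lfc / 2.0)
    mean_second = base * 2.0 ** (-lfc / 2.0)

    n_per = config.samples_per_tissue
    lib = rng.uniform(*config.lib_size_range, size=2 * n_per)
    mu = np.concatenate(
        [np.tile(mean_first[:, None], (1, n_per)), np.tile(mean_second[:, None], (1, n_per))],
        axis=1,
    ) * lib[None, :]
    alpha = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    counts = rng.poisson(lam)

    sample_ids = [f"{group_labels[0]}-{i:03d}" for i in range(n_per)] + [
        f"{group_labels[1]}-{i:03d}" for i in range(n_per)
    ]
    groups = pd.Series(
        [group_labels[0]] * n_per + [group_labels[1]] * n_per,
        index=pd.Index(sample_ids, name="SAMPID"),
        name="group",
    )
    return (
        pd.DataFrame(counts, index=gene_ids(config), columns=groups.index),
        groups,
    )


def planted_gene_ids(config: SimConfig) -> list[str]:
    """Ids of genes carrying a planted specificity signal."""
    idx = sorted(
        {p.gene for p in config.planted_specific}
        | {p.gene for p in config.planted_enhanced}
    )
    ids = gene_ids(config)
    return [ids[i] for i in idx]


def simulate_pathways(
    config: SimConfig,
    gene_ids_all: Sequence[str],
    n_pathways: int = 308,
    planted_fraction: float = 0.25,
    set_size_mean: float = 92.0,
    planted_genes: Sequence[str] | None = None,
    planted_member_fraction: float = 0.5,
    seed: int | None = None,
) -> enrichment.PathwayDB:
    """Generate a pathway database with a fraction of planted-enriched sets.

    ``planted_fraction`` of the pathways draw ``planted_member_fraction``
    of their members from ``planted_genes`` (default: the genes carrying a
    planted specificity signal) and the rest uniformly; the remaining
    pathways draw members uniformly from ``gene_ids_all``, independent of
    planted status.  Set sizes are Poisson around ``set_size_mean``.
    """
    if not len(gene_ids_all):
        raise ValueError("gene id list is empty")
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must lie in [0, 1]")
    if planted_genes is None:
        planted_genes = planted_gene_ids(config)
    planted_genes = [g for g in planted_genes if g in set(gene_ids_all)]
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    genes = np.asarray(list(gene_ids_all), dtype=object)
    planted_arr = np.asarray(list(planted_genes), dtype=object)
    n_planted_sets = int(round(planted_fraction * n_pathways))
    sets: dict[str, frozenset[str]] = {}
    for i in range(n_pathways):
        size = max(2, rng.poisson(set_size_mean))
        size = min(size, len(genes))
        if i < n_planted_sets and len(planted_arr):
            n_from_planted = min(
                int(round(planted_member_fraction * size)), len(planted_arr)
            )
            chosen = set(
                rng.choice(planted_arr, size=n_from_planted, replace=False)
            )
            remaining = [g for g in genes if g not in chosen]
            n_rest = min(size - len(chosen), len(remaining))
            chosen |= set(
                rng.choice(np.asarray(remaining, dtype=object), n_rest, replace=False)
            )
        else:
            chosen = set(rng.choice(genes, size=size, replace=False))
        sets[f"PATH{i:04d}"] = frozenset(str(g) for g in chosen)
    return enrichment.PathwayDB(sets=sets, universe=frozenset(map(str, gene_ids_all)))


_FILLER_SENTENCES = (
    "The protein localises to the cytoplasm in cultured cells",
    "Expression was profiled across a panel of normal tissues",
    "Knockdown altered proliferation in a reporter assay",
    "Variants were genotyped in a population cohort",
)

_HEART_SENTENCES = (
    "mutations are associated with atrial fibrillation",
    "is required for cardiac contractility in model organisms",
    "expression marks the developing heart",
    "variants modify risk of coronary artery disease",
)


def simulate_abstracts(
    gene_symbols: Sequence[str],
    reported_subset: Iterable[str],
    n_records: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate an abstract corpus realising a chosen reported/unreported split.

    Every gene in ``reported_subset`` co-occurs with a heart keyword in at
    least one record (within one sentence); genes outside the subset may
    appear in records but never alongside a heart keyword.  Extra records
    are heart-themed fillers mentioning no gene.
    """
    reported = list(dict.fromkeys(reported_subset))
    unknown = set(reported) - set(gene_symbols)
    if unknown:
        raise ValueError(f"reported subset outside gene list: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    records = []
    pmid = 10_000_000
    for symbol in reported:
        sentence = _HEART_SENTENCES[rng.integers(len(_HEART_SENTENCES))]
        records.append(
            (
                str(pmid),
                f"{symbol} {sentence}",
                f"We report that {symbol} {sentence}. "
                f"{_FILLER_SENTENCES[rng.integers(len(_FILLER_SENTENCES))]}.",
            )
        )
        pmid += 1
    unreported = [g for g in gene_symbols if g not in set(reported)]
    for symbol in unreported:
        filler = _FILLER_SENTENCES[rng.integers(len(_FILLER_SENTENCES))]
        records.append(
            (
                str(pmid),
                f"Characterisation of {symbol}",
                f"{symbol} was studied in an unrelated context. {filler}.",
            )
        )
        pmid += 1
    while len(records) < n_records:
        sentence = _HEART_SENTENCES[rng.integers(len(_HEART_SENTENCES))]
        records.append(
            (
                str(pmid),
                "A heart study",
                f"An unnamed factor {sentence}.",
            )
        )
        pmid += 1
    corpus = pd.DataFrame(records, columns=["pmid", "title", "abstract"])
    return corpus


def write_inputs(
    config: SimConfig,
    outdir: str | Path,
    n_pathways: int = 50,
    pathway_planted_fraction: float = 0.2,
    pathway_size_mean: float = 20.0,
    reported_fraction: float = 0.5,
    n_abstracts: int = 50,
) -> dict[str, Path]:
    """Generate and write every pipeline input file under ``outdir``.

    Writes the TPM GCT, sample-attributes TSV, count GCT with a group
    table, pathway GMT and abstract-corpus TSV; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, design = simulate_tpm(config)
    counts, groups = simulate_counts(config)
    db = simulate_pathways(
        config,
        list(expr.index),
        n_pathways=n_pathways,
        planted_fraction=pathway_planted_fraction,
        set_size_mean=pathway_size_mean,
    )
    planted = planted_gene_ids(config)
    rng = np.random.default_rng(config.seed + 3)
    n_rep = int(round(reported_fraction * len(planted)))
    reported = sorted(
        rng.choice(np.asarray(planted, dtype=object), size=n_rep, replace=False)
    ) if planted else []
    corpus = simulate_abstracts(
        list(expr.index[: max(len(planted) * 2, 10)]),
        [str(g) for g in reported],
        n_records=n_abstracts,
        seed=config.seed + 4,
    )

    paths = {
        "tpm_gct": outdir / "tpm.gct",
        "attributes": outdir / "sample_attributes.tsv",
        "counts_gct": outdir / "counts.gct",
        "count_groups": outdir / "count_groups.tsv",
        "gmt": outdir / "pathways.gmt",
        "corpus": outdir / "abstracts.tsv",
        "truth": outdir / "planted_truth.tsv",
    }
    gtex_io.write_gct(expr, paths["tpm_gct"])
    gtex_io.write_sample_attributes(design, paths["attributes"])
    gtex_io.write_gct(counts.astype(float), paths["counts_gct"])
    groups.to_frame().assign(SAMPID=groups.index)[["SAMPID", "group"]].to_csv(
        paths["count_groups"], sep="\t", index=False
    )
    enrichment.write_gmt(db, paths["gmt"])
    litmine.write_corpus(corpus, paths["corpus"])
    _write_truth(config, paths["truth"])
    return paths


def _write_truth(config: SimConfig, path: Path) -> None:
    """Planted ground truth as TSV for downstream evaluation."""
    ids = gene_ids(config)
    names = tissue_names(config)
    rows = []
    for p in config.planted_specific:
        rows.append((ids[p.gene], "specific", names[p.tissue], "", p.fold))
    for p in config.planted_enhanced:
        rows.append(
            (
                ids[p.gene],
                f"enhanced_except_{len(p.exceptions)}",
                names[p.tissue],
                ";".join(names[t] for t in p.exceptions),
                p.fold,
            )
        )
    for p in config.planted_deg:
        rows.append((ids[p.gene], "deg", "", "", p.log2_fold))
    pd.DataFrame(
        rows, columns=["gene_id", "kind", "tissue", "exceptions", "fold"]
    ).to_csv(path, sep="\t", index=False)
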