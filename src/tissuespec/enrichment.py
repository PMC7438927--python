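"""Over-representation testing and cumulative random-selection curves.

For a query gene list and a pathway database, each pathway's Fisher exact
p-value is the one-sided hypergeometric upper tail P(X >= k) for the 2x2
query x pathway table over the gene universe.  The *combined score*
corrects that p-value by how far the pathway's p-value rank deviates from
its rank under random queries of the same size:

    combined = -ln(fisher_p) * rank_z,
    rank_z = (expected rank - observed rank) / rank SD,

with the expected rank and SD estimated from seeded resampling.  The
cumulative curve grows one random gene at a time from a pool and records,
at each query size, how many pathways an enrichment rule calls enriched —
contrasting a pool of top-ranked genes against the full gene background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PathwayDB",
    "CumulativeCurve",
    "read_gmt",
    "write_gmt",
    "fisher_enrich",
    "combined_scores",
    "cumulative_curve",
    "adjusted_p_rule",
]


@dataclass
class PathwayDB:
    """Named gene sets plus the universe they are tested against.

    The universe defaults to the union of all member genes; pass an
    explicit universe to restrict to the measured gene set.
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"pathway {name!r} is empty")
        if not self.universe:
            union: set[str] = set()
            for members in self.sets.values():
                union |= members
            self.universe = frozenset(union)

    def restricted_to(self, genes: Iterable[str]) -> "PathwayDB":
        """Intersect universe and sets with a measured gene list."""
        genes = frozenset(genes)
        sets = {
            name: members & genes
            for name, members in self.sets.items()
            if members & genes
        }
        return PathwayDB(sets=sets, universe=self.universe & genes)

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class CumulativeCurve:
    """Enriched-pathway counts along a growing random gene selection."""

    sizes: np.ndarray  # query sizes m_min..m_max, step 1
    counts: np.ndarray  # enriched pathways at each size
    seed: int
    selection: list[str] = field(default_factory=list)  # final query, in order added

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"m": self.sizes, "n_enriched": self.counts})


def read_gmt(path_or_buffer) -> PathwayDB:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    if hasattr(path_or_buffer, "read"):
        lines = path_or_buffer.read().splitlines()
    else:
        with open(path_or_buffer, "rt") as fh:
            lines = fh.read().splitlines()
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"line {lineno}: GMT line needs name, description and >=1 gene"
            )
        name = fields[0]
        if name in sets:
            raise ValueError(f"line {lineno}: duplicate pathway name {name!r}")
        members = frozenset(g for g in fields[2:] if g)
        if not members:
            raise ValueError(f"line {lineno}: pathway {name!r} has no genes")
        sets[name] = members
    return PathwayDB(sets=sets)


def write_gmt(db: PathwayDB, path_or_buffer, descriptions=None) -> None:
    lines = []
    for name, members in db.sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *sorted(members)]))
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buffer, "write"):
        path_or_buffer.write(text)
    else:
        with open(path_or_buffer, "wt") as fh:
            fh.write(text)


def _overlap_counts(query: frozenset[str], db: PathwayDB) -> np.ndarray:
    return np.array([len(query & members) for members in db.sets.values()])


def fisher_enrich(
    query: Iterable[str], db: PathwayDB, warn: Callable[[str], None] | None = None
) -> pd.DataFrame:
    """Fisher exact over-representation of a query against every pathway.

    Genes outside the universe are dropped (a warning with the count is
    emitted through ``warn`` when provided).  Returns a DataFrame indexed
    by pathway with columns ``k`` (overlap), ``K`` (set size), ``n``
    (query size), ``N`` (universe size), ``fisher_p`` and ``adj_p``
    (BH across pathways).
    """
    query_set = frozenset(query)
    dropped = len(query_set - db.universe)
    query_set &= db.universe
    if not query_set:
        raise ValueError("query empty after intersecting with the universe")
    if dropped and warn is not None:
        warn(f"{dropped} query genes outside the universe were dropped")
    N = len(db.universe)
    n = len(query_set)
    K = np.array([len(members & db.universe) for members in db.sets.values()])
    k = _overlap_counts(query_set, db)
    # upper tail P(X >= k); sf(k-1) includes the observed table
    p = stats.hypergeom.sf(k - 1, N, K, n)
    p = np.clip(p, 0.0, 1.0)
    adj = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    return pd.DataFrame(
        {"k": k, "K": K, "n": n, "N": N, "fisher_p": p, "adj_p": adj},
        index=pd.Index(db.names, name="pathway"),
    )


def _p_ranks(p: np.ndarray) -> np.ndarray:
    """Ascending p-value ranks with average tie handling (rank 1 = smallest)."""
    return stats.rankdata(p, method="average")


def combined_scores(
    query: Iterable[str],
    db: PathwayDB,
    n_resamples: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Fisher enrichment plus rank-corrected combined scores.

    For each pathway the expected rank and rank SD under random queries of
    the same size are estimated from ``n_resamples`` seeded draws from the
    universe; ``rank_z`` is the deviation of the observed rank below the
    expected one in SD units, and ``combined = -ln(fisher_p) * rank_z``.
    Pathways whose resampled rank SD is zero get a combined score of 0 and
    ``degenerate_rank=True``.
    """
    if n_resamples < 20:
        raise ValueError("need >= 20 resamples to estimate expected ranks")
    result = fisher_enrich(query, db)
    n = int(result["n"].iloc[0])
    universe = sorted(db.universe)
    rng = np.random.default_rng(seed)
    ranks = np.empty((n_resamples, len(db.sets)))
    N = len(universe)
    K = result["K"].to_numpy()
    for r in range(n_resamples):
        draw = frozenset(
            np.asarray(universe, dtype=object)[rng.choice(N, size=n, replace=False)]
        )
        k = _overlap_counts(draw, db)
        p = stats.hypergeom.sf(k - 1, N, K, n)
        ranks[r] = _p_ranks(p)
    expected = ranks.mean(axis=0)
    sd = ranks.std(axis=0, ddof=1)
    observed = _p_ranks(result["fisher_p"].to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        rank_z = (expected - observed) / sd
    degenerate = sd == 0
    rank_z = np.where(degenerate, 0.0, rank_z)
    combined = -np.log(result["fisher_p"].to_numpy()) * rank_z
    combined = np.where(degenerate, 0.0, combined)
    out = result.copy()
    out["rank_z"] = rank_z
    out["combined_score"] = combined
    out["degenerate_rank"] = degenerate
    return out


def adjusted_p_rule(cutoff: float = 0.05) -> Callable[[pd.DataFrame], np.ndarray]:
    """Default enrichment rule: BH-adjusted Fisher p below ``cutoff``."""

    def rule(result: pd.DataFrame) -> np.ndarray:
        return result["adj_p"].to_numpy() < cutoff

    return rule


def cumulative_curve(
    pool: Sequence[str],
    db: PathwayDB,
    m_min: int = 5,
    m_max: int | None = None,
    seed: int = 0,
    enriched_rule: Callable[[pd.DataFrame], np.ndarray] | None = None,
) -> CumulativeCurve:
    """Enriched-pathway counts along one growing random selection.

    One subset grows from ``m_min`` to ``m_max`` genes, adding a single
    uniformly drawn unseen pool gene per step; at each size the number of
    pathways satisfying ``enriched_rule`` (default: BH-adjusted Fisher
    p < 0.05) is recorded.
    """
    pool = list(dict.fromkeys(pool))
    if m_max is None:
        m_max = len(pool)
    if m_min > m_max:
        raise ValueError(f"m_min={m_min} exceeds m_max={m_max}")
    if m_max > len(pool):
        raise ValueError(f"m_max={m_max} exceeds pool size {len(pool)}")
    if enriched_rule is None:
        enriched_rule = adjusted_p_rule()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    selection = [pool[i] for i in order[:m_max]]
    sizes = np.arange(m_min, m_max + 1)
    counts = np.empty(len(sizes), dtype=int)
    for i, m in enumerate(sizes):
        result = fisher_enrich(selection[:m], db)
        counts[i] = int(enriched_rule(result).sum())
    return CumulativeCurve(sizes=sizes, counts=counts, seed=seed, selection=selection)
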