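import io
import math

import numpy as np
import pandas as pd
import pytest

from tissuespec import enrichment


def exact_upper_tail(N, K, n, k):
    """Hypergeometric P(X >= k) by direct integer enumeration."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total


def make_db(sets, universe=None):
    return enrichment.PathwayDB(
        sets={name: frozenset(members) for name, members in sets.items()},
        universe=frozenset(universe or ()),
    )


class TestGmt:
    def test_round_trip(self, tmp_path):
        db = make_db({"P1": {"a", "b"}, "P2": {"b", "c", "d"}})
        path = tmp_path / "sets.gmt"
        enrichment.write_gmt(db, path)
        back = enrichment.read_gmt(path)
        assert back.sets == db.sets
        assert back.universe == db.universe

    def test_short_line_rejected_with_line_number(self):
        with pytest.raises(ValueError, match="line 2"):
            enrichment.read_gmt(io.StringIO("P1\tna\ta\tb\nP2\tna\n"))

    def test_duplicate_genes_within_set_deduplicated(self):
        db = enrichment.read_gmt(io.StringIO("P1\tna\ta\ta\tb\n"))
        assert db.sets["P1"] == frozenset({"a", "b"})


class TestFisher:
    def test_worked_example_matches_enumeration(self):
        # N=20, K=5, n=5, k=4: [C(5,4)C(15,1) + C(5,5)] / C(20,5) = 76/15504
        universe = [f"u{i}" for i in range(20)]
        pathway = set(universe[:5])
        query = set(universe[:4]) | {universe[10]}
        db = make_db({"P": pathway}, universe)
        result = enrichment.fisher_enrich(query, db)
        assert result.loc["P", "k"] == 4
        np.testing.assert_allclose(result.loc["P", "fisher_p"], 76 / 15504, atol=1e-12)
        np.testing.assert_allclose(
            result.loc["P", "fisher_p"], exact_upper_tail(20, 5, 5, 4), atol=1e-12
        )

    def test_zero_overlap_gives_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        db = make_db({"P": set(universe[:3])}, universe)
        result = enrichment.fisher_enrich(set(universe[5:]), db)
        np.testing.assert_allclose(result.loc["P", "fisher_p"], 1.0)

    def test_degenerate_query_equals_universe(self):
        universe = ["a", "b", "c"]
        db = make_db({"P": set(universe)}, universe)
        result = enrichment.fisher_enrich(universe, db)
        np.testing.assert_allclose(result.loc["P", "fisher_p"], 1.0)

    def test_matches_enumeration_on_small_tables(self):
        for N in (6, 11, 17):
            universe = [f"u{i}" for i in range(N)]
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    db = make_db({"P": set(universe[:K])}, universe)
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        query = set(universe[:k]) | set(universe[K : K + n - k])
                        if len(query) != n:
                            continue
                        result = enrichment.fisher_enrich(query, db)
                        np.testing.assert_allclose(
                            result.loc["P", "fisher_p"],
                            exact_upper_tail(N, K, n, k),
                            atol=1e-12,
                        )

    def test_monotone_decreasing_in_overlap(self):
        ps = [exact_upper_tail(30, 10, 8, k) for k in range(0, 9)]
        from scipy import stats

        sf = stats.hypergeom.sf(np.arange(0, 9) - 1, 30, 10, 8)
        np.testing.assert_allclose(sf, ps, atol=1e-12)
        assert all(a >= b for a, b in zip(sf, sf[1:]))

    def test_empty_query_after_intersection_rejected(self):
        db = make_db({"P": {"a", "b"}})
        with pytest.raises(ValueError, match="empty"):
            enrichment.fisher_enrich({"zzz"}, db)


class TestCombinedScores:
    def build_db(self, n_universe=200, n_paths=20, seed=0):
        rng = np.random.default_rng(seed)
        universe = [f"u{i}" for i in range(n_universe)]
        sets = {
            f"P{i}": set(rng.choice(universe, size=15, replace=False))
            for i in range(n_paths)
        }
        return make_db(sets, universe), universe

    def test_null_queries_have_near_zero_mean_rank_z(self):
        db, universe = self.build_db()
        rng = np.random.default_rng(42)
        means = []
        for seed in range(8):
            query = rng.choice(universe, size=30, replace=False)
            result = enrichment.combined_scores(query, db, n_resamples=60, seed=seed)
            means.append(result["rank_z"].mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * max(se, 0.1)

    def test_fully_contained_pathway_dominates(self):
        rng = np.random.default_rng(1)
        universe = [f"u{i}" for i in range(500)]
        target = set(universe[:12])
        sets = {"TARGET": target}
        for i in range(10):
            sets[f"BG{i}"] = set(rng.choice(universe[100:], size=15, replace=False))
        db = make_db(sets, universe)
        result = enrichment.combined_scores(universe[:20], db, seed=3)
        assert result["combined_score"].idxmax() == "TARGET"

    def test_p_of_one_scores_zero(self):
        universe = [f"u{i}" for i in range(40)]
        db = make_db({"P": set(universe[:5]), "Q": set(universe[30:])}, universe)
        result = enrichment.combined_scores(universe[30:35], db, seed=0)
        # P has zero overlap -> fisher_p == 1 -> -ln(1) == 0
        assert result.loc["P", "fisher_p"] == 1.0
        assert result.loc["P", "combined_score"] == 0.0

    def test_too_few_resamples_rejected(self):
        db, universe = self.build_db()
        with pytest.raises(ValueError, match=">= 20"):
            enrichment.combined_scores(universe[:5], db, n_resamples=5)


class TestCumulativeCurve:
    def test_disjoint_pool_yields_zero_counts(self):
        universe = [f"u{i}" for i in range(30)] + [f"x{i}" for i in range(30)]
        db = make_db({"P": {f"u{i}" for i in range(10)}}, universe)
        pool = [f"x{i}" for i in range(30)]
        curve = enrichment.cumulative_curve(pool, db, m_min=5, m_max=15, seed=0)
        assert (curve.counts == 0).all()
        assert list(curve.sizes) == list(range(5, 16))

    def test_same_seed_reproduces_curve(self):
        rng = np.random.default_rng(9)
        universe = [f"u{i}" for i in range(100)]
        db = make_db(
            {
                f"P{i}": set(rng.choice(universe, size=12, replace=False))
                for i in range(8)
            },
            universe,
        )
        a = enrichment.cumulative_curve(universe, db, m_min=5, m_max=25, seed=4)
        b = enrichment.cumulative_curve(universe, db, m_min=5, m_max=25, seed=4)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert a.selection == b.selection

    def test_invalid_range_rejected(self):
        db = make_db({"P": {"a", "b", "c"}})
        with pytest.raises(ValueError, match="m_min"):
            enrichment.cumulative_curve(["a", "b", "c"], db, m_min=3, m_max=2)
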