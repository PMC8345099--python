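from math import comb

import numpy as np
import pandas as pd
import pytest

from enhancerkit import SimulationConfig, simulate_expression
from enhancerkit.gene_scores import (
    benjamini_hochberg,
    combined_rank_score,
    cumulative_signal_per_gene,
    enrich_gene_sets,
    resistance_index,
)
from enhancerkit.io import GeneSetCollection


class TestCumulativeSignal:
    def test_single_region(self):
        assert cumulative_signal_per_gene([("JAK1", 500.0)]) == {"JAK1": 500.0}

    def test_additivity(self):
        out = cumulative_signal_per_gene([("JAK1", 300.0), ("JAK1", 200.0)])
        assert out["JAK1"] == pytest.approx(500.0)

    def test_unassigned_genes_zero(self):
        out = cumulative_signal_per_gene([("A", 1.0)], genes=["A", "B"])
        assert out["B"] == 0.0

    def test_matches_groupby_oracle(self, rng):
        genes = [f"g{int(i)}" for i in rng.integers(0, 20, size=200)]
        signals = rng.uniform(0, 100, size=200)
        out = cumulative_signal_per_gene(zip(genes, signals))
        oracle = pd.DataFrame({"g": genes, "s": signals}).groupby("g")["s"].sum()
        for g, total in oracle.items():
            assert out[g] == pytest.approx(total)


def _panel(shift):
    sim = simulate_expression(SimulationConfig(seed=9, expression_shift=shift))
    return sim


class TestResistanceIndex:
    def test_constant_expression_null(self):
        lines = [f"L{i}" for i in range(8)]
        expr = pd.DataFrame(5.0, index=["A", "B"], columns=lines)
        gi50 = {s: (50.0 if i < 4 else 5.0) for i, s in enumerate(lines)}
        res = resistance_index(expr, ["A"], ["B"], gi50)
        assert (res.index == 0).all()
        assert res.p_value == 1.0

    def test_planted_shift_separates_groups(self):
        sim = _panel(1.0)
        res = resistance_index(
            sim.expression, sim.truth.signature_up, sim.truth.signature_down, sim.gi50
        )
        r_mean, s_mean = res.group_means
        assert r_mean > s_mean
        assert res.p_value <= 0.01
        assert len(res.resistant) == 11 and len(res.sensitive) == 7

    def test_swapping_signatures_negates_index(self):
        sim = _panel(1.0)
        a = resistance_index(
            sim.expression, sim.truth.signature_up, sim.truth.signature_down, sim.gi50
        )
        b = resistance_index(
            sim.expression, sim.truth.signature_down, sim.truth.signature_up, sim.gi50
        )
        np.testing.assert_allclose(a.index.to_numpy(), -b.index.to_numpy(), atol=1e-12)

    def test_missing_signature_genes_warn(self):
        sim = _panel(1.0)
        with pytest.warns(UserWarning, match="absent"):
            resistance_index(
                sim.expression,
                sim.truth.signature_up + ["NOT_A_GENE"],
                sim.truth.signature_down,
                sim.gi50,
            )

    def test_empty_signature_rejected(self):
        sim = _panel(1.0)
        with pytest.raises(ValueError, match="empty"):
            resistance_index(sim.expression, ["NOPE"], ["ALSO_NOPE"], sim.gi50)


class TestCombinedRankScore:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "log2fc", "fdr", "cumulative_signal"]
        )

    def test_zero_components_annihilate(self):
        df = combined_rank_score(
            self._table(
                [("a", 0.0, 0.01, 500.0), ("b", 2.0, 1.0, 500.0), ("c", 2.0, 0.01, 0.0)]
            )
        )
        assert (df["score"] == 0).all()

    def test_worked_arithmetic(self):
        df = combined_rank_score(self._table([("g", 2.0, 0.01, 999.0)]))
        assert df["score"].iloc[0] == pytest.approx(2 * 2 * 3)

    def test_linear_in_log_fdr(self):
        a = combined_rank_score(self._table([("g", 2.0, 0.01, 999.0)]))["score"].iloc[0]
        b = combined_rank_score(self._table([("g", 2.0, 0.0001, 999.0)]))["score"].iloc[0]
        assert b == pytest.approx(2 * a)

    def test_jointly_maximal_gene_ranks_first(self, rng):
        rows = [
            (f"g{i}", float(rng.uniform(-1, 1)), float(rng.uniform(0.01, 1)),
             float(rng.uniform(0, 100)))
            for i in range(50)
        ]
        rows.append(("winner", 5.0, 1e-10, 1e6))
        df = combined_rank_score(self._table(rows))
        assert df.loc[df["rank"] == 1, "gene"].iloc[0] == "winner"

    def test_fdr_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            df = combined_rank_score(self._table([("g", 1.0, 0.0, 10.0)]))
        assert np.isfinite(df["score"]).all()

    def test_rank_is_permutation(self, rng):
        rows = [
            (f"g{i}", float(rng.normal()), float(rng.uniform(0.001, 1)),
             float(rng.uniform(0, 100)))
            for i in range(30)
        ]
        df = combined_rank_score(self._table(rows))
        assert sorted(df["rank"]) == list(range(1, 31))


class TestBenjaminiHochberg:
    def test_monotone_and_dominates_p(self, rng):
        p = rng.uniform(size=40)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_all_significant_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01] * 5), [0.01] * 5)


def exact_hypergeom_upper_tail(N, m, n, k):
    """Enumeration oracle: P(X >= k) summed over the exact pmf."""
    total = comb(N, n)
    return sum(comb(m, i) * comb(N - m, n - i) for i in range(k, min(m, n) + 1)) / total


class TestEnrichGeneSets:
    def _collection(self, sets):
        return GeneSetCollection(sets, {k: "" for k in sets})

    def test_selected_equals_universe_saturates(self):
        universe = [f"g{i}" for i in range(10)]
        coll = self._collection({"s": universe[:4]})
        (res,) = enrich_gene_sets(universe, universe, coll)
        assert res.p_value == pytest.approx(1.0)

    def test_exact_combinatorial_value(self):
        # N=20, m=5, n=5, k=3 -> 1126/15504
        universe = [f"g{i}" for i in range(20)]
        members = universe[:5]
        selected = members[:3] + universe[10:12]
        (res,) = enrich_gene_sets(selected, universe, self._collection({"s": members}))
        assert res.overlap == 3
        assert res.p_value == pytest.approx(1126 / 15504, rel=1e-12)

    def test_matches_enumeration_oracle_small_universes(self, rng):
        for _ in range(20):
            N = int(rng.integers(8, 30))
            universe = [f"g{i}" for i in range(N)]
            m = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            members = list(rng.choice(universe, size=m, replace=False))
            selected = list(rng.choice(universe, size=n, replace=False))
            (res,) = enrich_gene_sets(
                selected, universe, self._collection({"s": members})
            )
            k = len(set(members) & set(selected))
            assert res.p_value == pytest.approx(
                exact_hypergeom_upper_tail(N, m, n, k), rel=1e-10
            )

    def test_zero_overlap_never_enriched(self):
        universe = [f"g{i}" for i in range(30)]
        coll = self._collection({"s": universe[:10]})
        (res,) = enrich_gene_sets(universe[20:25], universe, coll)
        assert res.p_value >= 0.5

    def test_disjoint_set_skipped_with_warning(self):
        universe = ["a", "b", "c", "d"]
        coll = self._collection({"out": ["zzz"], "in": ["a", "b"]})
        with pytest.warns(UserWarning, match="disjoint"):
            results = enrich_gene_sets(["a"], universe, coll)
        assert [r.set_name for r in results] == ["in"]

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            enrich_gene_sets(["x"], ["a", "b", "c"], self._collection({"s": ["a"]}))


def test_resistance_index_power_and_null_calibration(rng):
    """Planted shift detected with high power; null rejections near nominal."""
    power_hits = 0
    for seed in range(40):
        sim = simulate_expression(SimulationConfig(seed=seed))
        res = resistance_index(
            sim.expression, sim.truth.signature_up, sim.truth.signature_down, sim.gi50
        )
        power_hits += res.p_value <= 0.05
    assert power_hits >= 38
    null_rej = 0
    n_null = 300
    for seed in range(n_null):
        sim = simulate_expression(
            SimulationConfig(seed=seed, expression_shift=0.0, n_background_genes=0)
        )
        res = resistance_index(
            sim.expression, sim.truth.signature_up, sim.truth.signature_down, sim.gi50
        )
        null_rej += res.p_value < 0.05
    assert null_rej / n_null <= 0.06
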