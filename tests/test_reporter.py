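import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from reporternet.exceptions import DegenerateNullError, ValidationError
from reporternet.reporter import (
    GeneScores,
    aggregate,
    background,
    collapse_isozymes,
    p_to_z,
    score_metabolites,
    score_pathways,
    significant,
)


class TestPToZ:
    def test_two_tailed_anchor(self):
        assert p_to_z(0.05, "two_tailed") == pytest.approx(1.96, abs=5e-3)

    def test_one_tailed_median(self):
        assert p_to_z(0.5, "one_tailed") == pytest.approx(0.0, abs=1e-12)

    def test_one_tailed_quantile(self):
        assert p_to_z(0.01, "one_tailed") == pytest.approx(2.3263, abs=1e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            p_to_z(1.5)
        with pytest.raises(ValidationError):
            p_to_z(-0.1)

    def test_extreme_p_clamped_finite(self):
        assert math.isfinite(p_to_z(0.0))
        assert math.isfinite(p_to_z(1.0))

    @settings(max_examples=50, deadline=None)
    @given(st.floats(1e-12, 0.5), st.floats(1e-6, 0.49))
    def test_monotone_decreasing(self, p, delta):
        assert p_to_z(p) > p_to_z(min(p + delta, 1 - 1e-12))


class TestCollapseIsozymes:
    def test_reaction_min_rule(self, reaction_model):
        units = collapse_isozymes({"g1": 0.03, "g2": 0.2, "g3": 0.4}, reaction_model)
        assert units.level == "reaction"
        assert units.scores.loc["r1", "p"] == 0.03
        assert units.scores.loc["r2", "p"] == 0.4

    def test_flat_model_units_are_genes(self, toy_model):
        units = collapse_isozymes({"g1": 0.1, "g2": 0.2, "g3": 0.3}, toy_model)
        assert units.level == "gene"
        assert len(units.scores) == 3

    def test_no_overlap_gives_empty(self, toy_model):
        units = collapse_isozymes({"zz": 0.1}, toy_model)
        assert units.scores.empty


class TestAggregate:
    def test_single_value_both_modes(self):
        assert aggregate([1.3], "sqrt_k") == pytest.approx(1.3)
        assert aggregate([1.3], "mean") == pytest.approx(1.3)

    def test_sqrt_k(self):
        assert aggregate([1.0, 2.0], "sqrt_k") == pytest.approx(3 / math.sqrt(2))

    def test_zeros(self):
        assert aggregate([0.0] * 7) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            aggregate([])


class TestBackground:
    def test_exhaustive_small_pool(self):
        # all C(4,2) pairs of {0,1,2,3} under sum/sqrt(2)
        b = background([0, 1, 2, 3], 2, exhaustive=True)
        assert b.mu == pytest.approx(2.1213, abs=1e-4)
        assert b.sigma == pytest.approx(0.9129, abs=1e-4)

    def test_sampled_matches_exhaustive_within_3se(self):
        rng = np.random.default_rng(10)
        pool = rng.normal(size=12)
        for k in (2, 5):
            exact = background(pool, k, exhaustive=True)
            samp = background(pool, k, n_samples=10_000, seed=11)
            assert abs(samp.mu - exact.mu) < 3 * exact.sigma / math.sqrt(10_000)
            assert abs(samp.sigma - exact.sigma) < 3 * exact.sigma / math.sqrt(2 * 10_000)

    def test_exhaustive_matches_brute_force_oracle(self):
        pool = [0.3, -1.2, 0.7, 2.0, -0.5]
        for k in (1, 2, 3):
            b = background(pool, k, exhaustive=True)
            aggs = [sum(c) / math.sqrt(k) for c in itertools.combinations(pool, k)]
            assert b.mu == pytest.approx(np.mean(aggs), abs=1e-12)
            assert b.sigma == pytest.approx(np.std(aggs), abs=1e-12)

    def test_constant_pool_degenerate(self):
        with pytest.raises(DegenerateNullError):
            background([0.0, 0.0, 0.0, 0.0], 2, exhaustive=True)

    def test_pool_smaller_than_k(self):
        with pytest.raises(ValidationError):
            background([1.0, 2.0], 3)

    def test_deterministic_given_seed(self):
        pool = np.random.default_rng(12).normal(size=30)
        b1 = background(pool, 4, n_samples=500, seed=99)
        b2 = background(pool, 4, n_samples=500, seed=99)
        assert (b1.mu, b1.sigma) == (b2.mu, b2.sigma)


def _units(pvals: dict) -> GeneScores:
    df = pd.DataFrame({"p": pd.Series(pvals, dtype=float)})
    df["z"] = stats.norm.isf(df["p"].clip(1e-15, 1 - 1e-15))
    return GeneScores(df, "gene")


class TestScoreMetabolites:
    def test_constant_pool_is_degenerate(self, toy_model):
        # identical p everywhere leaves no spread to standardize against
        units = _units({g: 0.5 for g in ["g1", "g2", "g3", "g4"]})
        with pytest.raises(DegenerateNullError):
            score_metabolites(units, toy_model, n_samples=100, seed=0)

    def test_near_null_fixed_point(self):
        # p jittered around 0.5: corrected scores stay near 0, p near 0.5
        from reporternet.synthetic import make_model

        model = make_model(60, 15, 3, 3, 5, seed=8)
        rng = np.random.default_rng(9)
        units = _units({g: 0.5 + 0.01 * rng.normal() for g in sorted(model.genes)})
        scores = score_metabolites(units, model, n_samples=2000, seed=10)
        assert scores["p"].between(0.001, 0.999).all()
        assert abs(scores["z_corrected"].mean()) < 1.0

    def test_planted_metabolite_ranks_first(self):
        from reporternet.synthetic import make_model

        model = make_model(100, 20, 4, 3, 5, seed=3)
        rng = np.random.default_rng(4)
        pv = {g: rng.random() for g in sorted(model.genes)}
        target = next(m for m in sorted(model.metabolites) if len(model.neighbors(m)) >= 2)
        for g in model.neighbors(target):
            pv[g] = 0.001
        scores = score_metabolites(_units(pv), model, n_samples=5000, seed=5)
        assert scores["p"].idxmin() == target

    def test_unscored_metabolites_absent(self, toy_model):
        from reporternet.model import remove_currency

        model = remove_currency(toy_model, ["m_cur"])
        units = _units({"g1": 0.2, "g2": 0.9, "g3": 0.4})  # g4 unscored -> m3 has no scored neighbor
        scores = score_metabolites(units, model, n_samples=200, seed=1)
        assert set(scores.index) == {"m1", "m2"}
        assert "m3" not in scores.index

    def test_k_matches_neighbor_count(self, toy_model):
        from reporternet.model import remove_currency

        model = remove_currency(toy_model, ["m_cur"])
        units = _units({"g1": 0.2, "g2": 0.6, "g3": 0.4, "g4": 0.8})
        scores = score_metabolites(units, model, n_samples=200, seed=2)
        assert scores.loc["m1", "k"] == 2
        assert scores.loc["m2", "k"] == 1
        assert "m_cur" not in scores.index

    def test_monotone_in_neighbor_p(self, toy_model):
        from reporternet.model import remove_currency

        model = remove_currency(toy_model, ["m_cur"])
        units_a = _units({"g1": 0.2, "g2": 0.6, "g3": 0.4, "g4": 0.8})
        units_b = _units({"g1": 0.02, "g2": 0.6, "g3": 0.4, "g4": 0.8})
        a = score_metabolites(units_a, model, n_samples=300, seed=3)
        b = score_metabolites(units_b, model, n_samples=300, seed=3)
        assert b.loc["m1", "z_raw"] > a.loc["m1", "z_raw"]

    def test_reaction_level_units(self, reaction_model):
        units = collapse_isozymes({"g1": 0.01, "g2": 0.2, "g3": 0.5}, reaction_model)
        scores = score_metabolites(units, reaction_model, n_samples=300, seed=4)
        assert scores.loc["m1", "k"] == 1  # one reaction feeds m1


class TestScorePathways:
    def _met_scores(self, vals: dict) -> pd.DataFrame:
        df = pd.DataFrame({"z_corrected": pd.Series(vals, dtype=float)})
        df["z_raw"] = df["z_corrected"]
        df.index.name = "metabolite_id"
        return df

    def test_single_member_z_raw_equals_member(self, toy_model):
        ms = self._met_scores({"m1": 1.7, "m2": -0.4, "m3": 0.2, "m_cur": 0.1})
        ps = score_pathways(ms, toy_model, n_samples=300, seed=5)
        # pw1 members scored: m1, m2, m_cur -> n = 3
        assert ps.loc["pw1", "n"] == 3

    def test_two_member_sqrt_aggregation(self):
        from reporternet.model import MetabolicModel

        model = MetabolicModel(
            genes=frozenset({"g"}),
            metabolites=frozenset({"a", "b", "c", "d"}),
            pathways=frozenset({"pw"}),
            gene_metabolite=frozenset({("g", "a")}),
            metabolite_pathway=frozenset({("a", "pw"), ("b", "pw")}),
        )
        ms = self._met_scores({"a": 1.0, "b": 1.0, "c": -1.0, "d": 0.3})
        ps = score_pathways(ms, model, n_samples=400, seed=6)
        assert ps.loc["pw", "z_raw"] == pytest.approx(2 / math.sqrt(2), abs=1e-12)

    def test_pathway_without_scored_members_absent(self, toy_model):
        ms = self._met_scores({"m3": 0.5})  # m3 belongs to no pathway
        ps = score_pathways(ms, toy_model, n_samples=100, seed=7)
        assert ps.empty


class TestSignificant:
    def test_inclusive_threshold(self):
        df = pd.DataFrame({"p": [0.05, 0.051, 0.0]})
        out = significant(df, 0.05)
        assert list(out["p"]) == [0.05, 0.0]

    def test_empty_and_zero_alpha(self):
        assert significant(pd.DataFrame({"p": []})).empty
        assert significant(pd.DataFrame({"p": [0.01]}), alpha=0).empty


class TestNullBehavior:
    def test_stouffer_aggregate_is_standard_normal_for_mixed_k(self):
        rng = np.random.default_rng(20)
        zs = [aggregate(rng.normal(size=rng.integers(1, 11)), "sqrt_k") for _ in range(10_000)]
        assert stats.kstest(zs, "norm").pvalue > 0.01

    def test_mean_aggregate_is_not_standard_normal(self):
        rng = np.random.default_rng(21)
        zs = [aggregate(rng.normal(size=rng.integers(2, 11)), "mean") for _ in range(10_000)]
        assert stats.kstest(zs, "norm").pvalue < 0.01
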