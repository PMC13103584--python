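import numpy as np
import pandas as pd
import pytest

from teaterroir import (
    CoreDefinition,
    audit_grid,
    audit_null,
    classify_genera,
    effect_size_per_genus,
)
from teaterroir.coretaxa import (
    CLASS_CORE,
    CLASS_GAP,
    CLASS_INTERMITTENT,
    CLASS_TRANSIENT,
    shortlist,
)
from teaterroir.tables import FeatureTable, MatchedDesign

from conftest import toy_table


def _relabund(rows, genera, samples):
    x = np.asarray(rows, float)
    x = x / x.sum(axis=0, keepdims=True)
    return FeatureTable(pd.DataFrame(x, index=genera, columns=samples), "genus_relabund")


def _mk_table(design8):
    """3-genus toy: one clear core, one transient, one in the definitional gap."""
    samples = design8.sample_ids
    core = np.full(16, 0.5)
    transient = np.r_[np.full(4, 0.2), np.zeros(12)]  # prevalence 25%
    gap = np.full(16, 2e-4)
    gap[:2] = 0.0  # prevalence 87.5%, median 0.02%
    filler = 1.0 - (core + transient + gap)
    return _relabund(
        [core, transient, gap, filler], ["g_core", "g_trans", "g_gap", "g_fill"],
        samples,
    )


class TestClassify:
    def test_rule_application(self, design8):
        t = _mk_table(design8)
        cls = classify_genera(t, CoreDefinition())
        assert cls["g_core"] == CLASS_CORE
        assert cls["g_trans"] == CLASS_TRANSIENT
        assert cls["g_gap"] == CLASS_GAP

    def test_intermittent_band(self, design8):
        samples = design8.sample_ids
        mid = np.r_[np.full(8, 0.3), np.zeros(8)]  # prevalence 50%
        rest = 1 - mid
        t = _relabund([mid, rest], ["g_mid", "g_rest"], samples)
        assert classify_genera(t, CoreDefinition())["g_mid"] == CLASS_INTERMITTENT

    def test_column_order_invariance(self, cohort):
        rel = cohort.bacteria.relative_abundance()
        shuffled = FeatureTable(
            rel.data[list(rel.data.columns[::-1])], "genus_relabund"
        )
        a = classify_genera(rel, CoreDefinition())
        b = classify_genera(shuffled, CoreDefinition())
        assert (a.sort_index() == b.sort_index()).all()

    def test_nested_shortlists_in_both_dimensions(self, cohort):
        rel = cohort.bacteria.relative_abundance()
        for at in (0.0005, 0.001):
            lists = [
                set(shortlist(rel, CoreDefinition(pt, at)))
                for pt in (0.60, 0.70, 0.80)
            ]
            assert lists[2] <= lists[1] <= lists[0]
        for pt in (0.60, 0.70):
            lists = [
                set(shortlist(rel, CoreDefinition(pt, at)))
                for at in (0.0005, 0.001, 0.002)
            ]
            assert lists[2] <= lists[1] <= lists[0]


class TestEffectSizes:
    def test_region_identical_gives_zero_effect(self, design4):
        vals = np.tile(np.array([[0.4], [0.6]]), (1, 8))
        t = _relabund(vals, ["a", "b"], design4.sample_ids)
        eff = effect_size_per_genus(t, design4)
        np.testing.assert_allclose(eff["effect"], 0.0, atol=1e-12)

    def test_hand_arithmetic_two_genera(self, design4):
        a = [0.6, 0.4, 0.7, 0.5, 0.6, 0.6, 0.8, 0.4]
        vals = np.array([a, [1 - x for x in a]])
        t = _relabund(vals, ["up", "down"], design4.sample_ids)
        eff = effect_size_per_genus(t, design4)
        expected_up = np.mean([0.2, 0.2, 0.0, 0.4])
        assert eff.loc["up", "effect"] == pytest.approx(expected_up)
        assert eff.loc["down", "effect"] == pytest.approx(-expected_up)

    def test_antisymmetry_ranks_unchanged(self, design4):
        rng = np.random.default_rng(0)
        vals = rng.dirichlet(np.ones(5), size=8).T
        t = _relabund(vals, [f"g{i}" for i in range(5)], design4.sample_ids)
        swapped = MatchedDesign(
            tuple((p, b, a) for p, a, b in design4.pairs), ("B", "A")
        )
        e1 = effect_size_per_genus(t, design4).sort_index()
        e2 = effect_size_per_genus(t, swapped).sort_index()
        np.testing.assert_allclose(e1["effect"], -e2["effect"], atol=1e-15)
        np.testing.assert_allclose(e1["rank"], e2["rank"])


class TestAuditGrid:
    def test_grid_shape_and_self_concordance(self, cohort):
        rel = cohort.bacteria.relative_abundance()
        res = audit_grid(rel, cohort.design)
        assert len(res.cells) == 20
        v1_cell = res.cells.query(
            "prevalence_threshold == 0.70 and abundance_threshold == 0.001"
        ).iloc[0]
        assert v1_cell["rank_concordance"] == pytest.approx(1.0)

    def test_all_same_sign_deltas_give_consistency_one(self, design8):
        up = np.array([0.6, 0.4] * 8)  # region A always higher
        t = _relabund([up, 1 - up], ["up", "down"], design8.sample_ids)
        res = audit_grid(t, design8, CoreDefinition(0.5, 0.0))
        cell = res.cells.iloc[0]
        assert cell["direction_consistency"] == pytest.approx(1.0)

    def test_three_genus_toy_matches_hand_computation(self, design4):
        a = np.array([0.5, 0.3, 0.6, 0.2, 0.5, 0.4, 0.7, 0.3])
        b = np.array([0.2, 0.4, 0.1, 0.5, 0.3, 0.2, 0.1, 0.3])
        c = 1 - a - b
        t = _relabund([a, b, c], ["ga", "gb", "gc"], design4.sample_ids)
        v1 = CoreDefinition(0.5, 0.0)
        res = audit_grid(
            t, design4, v1, prevalence_grid=(0.5,), abundance_grid=(0.0,)
        )
        # hand: deltas per pair
        da = [0.2, 0.4, 0.1, 0.4]          # 4/4 positive → consistency 1
        db = [-0.2, -0.4, 0.1, -0.2]       # 3/4 negative → 0.75
        cons_a, cons_b = 1.0, 0.75
        dc = res.cells.iloc[0]["direction_consistency"]
        # third genus: delta = -(da+db) per pair = (0, 0, -0.2, -0.2) → 2/4 = 0.5
        assert dc == pytest.approx(np.mean([cons_a, cons_b, 0.5]))
        assert res.cells.iloc[0]["rank_concordance"] == pytest.approx(1.0)

    def test_empty_shortlist_flagged(self, design8):
        t = _mk_table(design8)
        res = audit_grid(
            t, design8, CoreDefinition(0.7, 0.001),
            prevalence_grid=(0.9,), abundance_grid=(0.9,),
        )
        assert res.cells.iloc[0]["flag"] == "empty_shortlist"


class TestAuditNull:
    def test_identity_reproduces_observed(self, cohort):
        rel = cohort.bacteria.relative_abundance()
        res = audit_null(rel, cohort.design)
        assert res.null_direction_consistency[0] == pytest.approx(
            res.observed_direction_consistency
        )
        assert res.null_rank_concordance[0] == pytest.approx(1.0)
        assert len(res.null_direction_consistency) == 256

    def test_equal_magnitude_deltas_null_symmetric_about_chance(self, design4):
        """All-|equal| deltas: the consistency null over 16 sign patterns is the
        symmetric Binomial(4, ½) max-count distribution."""
        up = np.array([0.6, 0.4] * 4)
        t = _relabund([up, 1 - up], ["up", "down"], design4.sample_ids)
        res = audit_null(t, design4, CoreDefinition(0.5, 0.0))
        null = res.null_direction_consistency
        # expected: consistency = max(k, 4-k)/4 with k ~ Binomial(4, ½)
        from itertools import product

        expected = [
            max(sum(s), 4 - sum(s)) / 4 for s in product([0, 1], repeat=4)
        ]
        assert sorted(null) == pytest.approx(sorted(expected))

    def test_real_labels_in_upper_tail_under_effect(self, cohort):
        rel = cohort.bacteria.relative_abundance()
        res = audit_null(rel, cohort.design)
        assert res.exceedance_direction <= 0.25
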