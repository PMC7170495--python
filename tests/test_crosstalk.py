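"""Condition comparisons and cross-talk / co-activation classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyncross.containers import CONDITIONS
from dyncross.crosstalk import (
    bin_correlations,
    classify_crosstalk,
    differential_activity,
    significant_variation,
    spearman_between_conditions,
)
from dyncross.rankstats import spearman


class TestSpearman:
    def test_identity_and_antisymmetry(self):
        x = np.array([0.1, 0.5, 1.2, 2.0, 3.3])
        assert spearman(x, x) == pytest.approx(1.0)
        assert spearman(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_rank_formula(self):
        """rho = 1 - 6*sum(d^2)/(n(n^2-1)) for distinct ranks: the permuted
        curve (3,1,2,5,4) has sum(d^2) = 8, so rho = 0.6."""
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([3.0, 1, 2, 5, 4])
        assert spearman(a, b) == pytest.approx(1 - 6 * 8 / (5 * 24))

    def test_constant_curve_is_undefined(self):
        rho = spearman_between_conditions(
            np.array([[1.0, 1, 1, 1]]), np.array([[1.0, 2, 3, 4]])
        )
        assert np.isnan(rho[0])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_strictly_increasing_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        assert spearman(np.exp(x), y) == pytest.approx(spearman(x, y))
        assert spearman(x, 3 * y + 1) == pytest.approx(spearman(x, y))


class TestBins:
    def test_degenerate_all_similar(self):
        table = bin_correlations(np.ones(50))
        assert table.counts["similar"] == 50
        assert table.percentages["similar"] == pytest.approx(100.0)

    def test_one_value_per_bin(self):
        table = bin_correlations(np.array([0.8, -0.8, 0.0, 0.5]))
        assert list(table.counts.values()) == [1, 1, 1, 1]

    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(0)
        rhos = rng.uniform(-1, 1, 3000)
        table = bin_correlations(rhos)
        assert sum(table.counts.values()) == 3000
        assert table.n_undefined == 0

    def test_percentages_are_direct_division(self):
        rng = np.random.default_rng(1)
        rhos = rng.uniform(-1, 1, 3000)
        table = bin_correlations(rhos)
        for key, count in table.counts.items():
            assert table.percentages[key] == pytest.approx(100 * count / 3000)

    def test_undefined_values_excluded_with_count(self):
        table = bin_correlations(np.array([0.9, np.nan, -0.9]))
        assert table.n == 2 and table.n_undefined == 1


class TestDifferentialActivity:
    def test_identical_not_differential(self):
        x = np.sin(np.linspace(0, 3, 10))
        assert not differential_activity(x, x)

    def test_negated_monotone_is_differential(self):
        x = np.linspace(0, 2, 10)
        assert differential_activity(x, -x)

    def test_rho_exactly_at_threshold_is_not_differential(self):
        """Constructed permutation with sum(d^2) = 6 at n = 5 gives
        rho = 0.7 exactly; the inequality is strict."""
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([3.0, 1, 2, 4, 5])
        assert spearman(a, b) == pytest.approx(0.7)
        assert not differential_activity(a, b)

    def test_constant_curve_is_treated_as_differential(self):
        assert differential_activity(np.ones(6), np.arange(6.0))

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = rng.normal(size=(2, 9))
            assert differential_activity(a, b) == differential_activity(b, a)


class TestSignificantVariation:
    def test_constant_false(self):
        assert not significant_variation(np.zeros(8))

    def test_boundary_inclusive(self):
        curve = np.zeros(8)
        curve[3] = 1.96
        assert significant_variation(curve)

    def test_forced_arithmetic(self):
        curve = np.array([-1.5, 0.0, 0.5])
        assert significant_variation(curve)  # range 2.0


class TestClassify:
    def _flat_study(self, k=14):
        return {c: np.zeros(k) for c in CONDITIONS}

    def test_identical_everywhere_is_neither(self):
        x = 3 * np.sin(np.linspace(0, 3, 14))
        rec = classify_crosstalk({c: x for c in CONDITIONS})
        assert rec.classification == "neither"

    def test_missing_condition_raises_with_name(self):
        curves = self._flat_study()
        del curves["EGF"]
        with pytest.raises(ValueError, match="EGF"):
            classify_crosstalk(curves)

    def test_planted_crosstalk_gene_classified(self, small_study):
        _, study, truth = small_study
        for g in sorted(truth.crosstalk_genes)[:5]:
            curves = {c: truth.true_curves[c].loc[g].to_numpy() for c in CONDITIONS}
            rec = classify_crosstalk(curves, g)
            assert rec.classification == "crosstalk"
            assert all(rec.crosstalk_flags.values())

    def test_planted_coactivation_gene_classified(self, small_study):
        _, study, truth = small_study
        for g in sorted(truth.coactivation_genes)[:5]:
            curves = {c: truth.true_curves[c].loc[g].to_numpy() for c in CONDITIONS}
            assert classify_crosstalk(curves, g).classification == "coactivation"

    def test_single_rule_veto(self, small_study):
        """A gene flat under SHH fails the variation rule and cannot be
        cross-talk, whatever the other conditions do."""
        _, study, truth = small_study
        g = sorted(truth.crosstalk_genes)[0]
        curves = {c: truth.true_curves[c].loc[g].to_numpy() for c in CONDITIONS}
        curves["SHH"] = np.zeros_like(curves["SHH"])
        rec = classify_crosstalk(curves, g)
        assert not rec.crosstalk_flags["var_SHH"]
        assert rec.classification != "crosstalk"

    def test_classes_mutually_exclusive_by_construction(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            curves = {c: rng.normal(size=10) * rng.uniform(0.5, 3) for c in CONDITIONS}
            rec = classify_crosstalk(curves)
            assert not (
                all(rec.crosstalk_flags.values()) and all(rec.coactivation_flags.values())
            )

    def test_literal_rho_mode_exposed(self):
        x = np.linspace(-2, 2, 14)
        curves = {"CTRL": np.zeros(14), "SHH": x, "EGF": x, "EGF_SHH": x}
        lit = classify_crosstalk(curves, differential_mode="rho")
        comp = classify_crosstalk(curves, differential_mode="rho_or_variation")
        # under both readings the flat CTRL counts as differential
        assert lit.crosstalk_flags["diff_SHH_vs_CTRL"]
        assert comp.crosstalk_flags["diff_SHH_vs_CTRL"]


class TestScreen:
    def test_round_trip_on_planted_study(self, small_study):
        from dyncross.clustering import ihc_cluster
        from dyncross.crosstalk import screen_grms
        from dyncross.drg import detect_drgs, top_k_by_fratio
        from dyncross.expression_io import center_profiles, median_over_replicates

        cfg, study, truth = small_study
        centered = {c: center_profiles(median_over_replicates(x)) for c, x in study.items()}
        records = detect_drgs(centered["SHH"], seed=0)
        drgs = [r.gene_id for r in top_k_by_fratio(records, 3000)]
        grms = ihc_cluster(centered["SHH"].subset(drgs).profiles(), drgs, condition="SHH")
        report = screen_grms(grms, centered)
        found_ct = set(report.crosstalk_genes)
        found_ca = set(report.coactivation_genes)
        assert len(found_ct & truth.crosstalk_genes) / len(truth.crosstalk_genes) >= 0.9
        assert len(found_ca & truth.coactivation_genes) / len(truth.coactivation_genes) >= 0.9
        # the two classes are never confused
        assert not (found_ct & truth.coactivation_genes)
        assert not (found_ca & truth.crosstalk_genes)

    def test_no_planted_signal_returns_empty(self):
        from dyncross.clustering import ihc_cluster
        from dyncross.crosstalk import screen_grms
        from dyncross.expression_io import center_profiles, median_over_replicates
        from dyncross.synthetic import SimulationConfig, simulate_study

        cfg = SimulationConfig(n_genes=100, n_dynamic=60, n_crosstalk=0,
                               n_coactivation=0, seed=2)
        study, truth = simulate_study(cfg)
        centered = {c: center_profiles(median_over_replicates(x)) for c, x in study.items()}
        drgs = sorted(truth.module_labels["SHH"].index)
        grms = ihc_cluster(centered["SHH"].subset(drgs).profiles(), drgs, condition="SHH")
        report = screen_grms(grms, centered)
        assert report.crosstalk_genes == []
        assert report.coactivation_genes == []

    def test_missing_condition_named(self, small_study):
        from dyncross.crosstalk import screen_grms

        _, study, _ = small_study
        with pytest.raises(ValueError, match="EGF_SHH"):
            screen_grms([], {c: study[c] for c in ("CTRL", "SHH", "EGF")})
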