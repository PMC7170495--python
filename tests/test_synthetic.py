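"""Synthetic study generator: determinism, calibration, plant validity."""

import numpy as np
import pytest
from scipy.stats import rankdata

from dyncross.containers import CONDITIONS
from dyncross.synthetic import (
    SimulationConfig,
    make_template_curves,
    simulate_condition,
    simulate_linear_ode_modules,
    simulate_study,
)


def rank_rho(a, b):
    """Independent Spearman oracle: Pearson on average ranks."""
    ra, rb = rankdata(a), rankdata(b)
    ra, rb = ra - ra.mean(), rb - rb.mean()
    return float(ra @ rb / np.sqrt((ra @ ra) * (rb @ rb)))


class TestTemplates:
    def test_single_template(self, time_grid_24h):
        t = make_template_curves(1, time_grid_24h, amplitude=3.0, seed=0)
        assert t.shape == (1, 14)
        assert np.ptp(t[0]) == pytest.approx(3.0)

    def test_pairwise_separability_against_rank_oracle(self, time_grid_24h):
        t = make_template_curves(2, time_grid_24h, amplitude=3.0, seed=1)
        assert rank_rho(t[0], t[1]) < 0.7

    def test_many_templates_all_separable(self, time_grid_24h):
        t = make_template_curves(9, time_grid_24h, amplitude=3.0, seed=2)
        for i in range(9):
            for j in range(i + 1, 9):
                assert rank_rho(t[i], t[j]) < 0.7

    def test_zero_amplitude_is_an_error(self, time_grid_24h):
        with pytest.raises(ValueError):
            make_template_curves(2, time_grid_24h, amplitude=0.0, seed=0)

    def test_impossible_separability_raises(self, time_grid_24h):
        with pytest.raises(RuntimeError):
            make_template_curves(200, time_grid_24h, amplitude=1.0, seed=0,
                                 max_rho=-0.99, max_tries=50)


class TestSimulateCondition:
    def test_null_dataset_is_pure_noise(self):
        cfg = SimulationConfig(n_genes=50, n_dynamic=0, seed=4)
        templates = make_template_curves(cfg.n_modules, cfg.time_grid, 3.0, seed=4)
        etc, truth = simulate_condition(cfg, templates, np.full(50, -1), seed=1)
        assert np.all(truth.to_numpy() == 0.0)
        assert abs(etc.values.mean()) < 0.05

    def test_noiseless_limit_reproduces_templates(self):
        cfg = SimulationConfig(n_genes=10, n_dynamic=10, noise_sd=0.0, seed=4)
        templates = make_template_curves(cfg.n_modules, cfg.time_grid, 3.0, seed=4)
        assignment = np.arange(10) % cfg.n_modules
        etc, truth = simulate_condition(cfg, templates, assignment, seed=1)
        for r in range(cfg.n_replicates):
            np.testing.assert_allclose(etc.values[:, :, r], templates[assignment])

    def test_noise_calibration_against_empirical_variance_oracle(self):
        """Pooled residual variance around the planted signal approaches
        noise_sd^2 (5% tolerance at 1,000 genes)."""
        cfg = SimulationConfig(n_genes=1000, n_dynamic=500, noise_sd=0.5, seed=7)
        templates = make_template_curves(cfg.n_modules, cfg.time_grid, 3.0, seed=7)
        assignment = np.where(np.arange(1000) < 500, np.arange(1000) % cfg.n_modules, -1)
        etc, truth = simulate_condition(cfg, templates, assignment, seed=7)
        resid = etc.values - truth.to_numpy()[:, :, None]
        # direct-summation oracle for the empirical variance
        var = float((resid**2).sum() / resid.size)
        assert abs(var - 0.25) / 0.25 < 0.05

    def test_determinism(self):
        cfg = SimulationConfig(n_genes=20, n_dynamic=10, seed=3)
        templates = make_template_curves(cfg.n_modules, cfg.time_grid, 3.0, seed=3)
        assignment = np.where(np.arange(20) < 10, 0, -1)
        a, _ = simulate_condition(cfg, templates, assignment, seed=9)
        b, _ = simulate_condition(cfg, templates, assignment, seed=9)
        np.testing.assert_array_equal(a.values, b.values)


class TestSimulateStudy:
    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=10, n_dynamic=20)
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=10, n_dynamic=5, n_crosstalk=4, n_coactivation=2)
        with pytest.raises(ValueError):
            SimulationConfig(n_timepoints=7)
        with pytest.raises(ValueError):
            SimulationConfig(noise_sd=-0.1)

    def test_study_shape_and_determinism(self, small_study):
        cfg, study, truth = small_study
        assert set(study) == set(CONDITIONS)
        for etc in study.values():
            assert etc.values.shape == (cfg.n_genes, cfg.n_timepoints, cfg.n_replicates)
        study2, _ = simulate_study(cfg)
        for c in CONDITIONS:
            np.testing.assert_array_equal(study[c].values, study2[c].values)

    def test_planted_crosstalk_satisfies_all_rules_on_noiseless_curves(self):
        """Criteria re-check oracle: every planted cross-talk gene passes a
        direct test-local evaluation of the six rules on its planted curves."""
        cfg = SimulationConfig(
            n_genes=120, n_dynamic=80, n_crosstalk=20, n_coactivation=0, seed=3
        )
        study, truth = simulate_study(cfg)
        assert len(truth.crosstalk_genes) == 20
        for g in truth.crosstalk_genes:
            curves = {c: truth.true_curves[c].loc[g].to_numpy() for c in CONDITIONS}
            # flat under CTRL, responsive under stimulation
            assert np.ptp(curves["CTRL"]) == 0.0
            assert np.ptp(curves["SHH"]) >= 1.96
            assert np.ptp(curves["EGF"]) >= 1.96
            # combined-stimulation curve dissimilar to both single stimuli
            assert rank_rho(curves["EGF_SHH"], curves["SHH"]) < 0.7
            assert rank_rho(curves["EGF_SHH"], curves["EGF"]) < 0.7
            # and the single-stimulus curves differ from each other
            assert rank_rho(curves["SHH"], curves["EGF"]) < 0.7

    def test_planted_coactivation_satisfies_rules_on_noiseless_curves(self):
        cfg = SimulationConfig(
            n_genes=120, n_dynamic=80, n_crosstalk=0, n_coactivation=10, seed=5
        )
        study, truth = simulate_study(cfg)
        assert len(truth.coactivation_genes) == 10
        for g in truth.coactivation_genes:
            curves = {c: truth.true_curves[c].loc[g].to_numpy() for c in CONDITIONS}
            assert rank_rho(curves["SHH"], curves["CTRL"]) > 0.7
            assert rank_rho(curves["EGF"], curves["CTRL"]) > 0.7
            assert rank_rho(curves["EGF_SHH"], curves["SHH"]) < 0.7

    def test_ground_truth_bookkeeping(self, small_study):
        cfg, study, truth = small_study
        assert not (truth.crosstalk_genes & truth.coactivation_genes)
        for c in CONDITIONS:
            flagged = set(truth.drg_flags.index[truth.drg_flags[c]])
            labelled = set(truth.module_labels[c].index)
            assert flagged == labelled
        # cross-talk genes are flat (not dynamic) under CTRL
        for g in truth.crosstalk_genes:
            assert not truth.drg_flags.loc[g, "CTRL"]
            assert truth.drg_flags.loc[g, "SHH"]


class TestPlantedOde:
    def test_planted_system_shape_and_determinism(self):
        noisy, clean, a = simulate_linear_ode_modules(10, seed=13)
        noisy2, clean2, a2 = simulate_linear_ode_modules(10, seed=13)
        np.testing.assert_array_equal(noisy, noisy2)
        np.testing.assert_array_equal(a, a2)
        assert noisy.shape == (10, 14)
        # sparse: at most 3 regulators per target, at least the rotation partner
        per_target = (a != 0).sum(axis=0)
        assert per_target.max() <= 3
        assert per_target.min() >= 1

    def test_trajectories_solve_the_planted_system(self):
        """The clean curves satisfy dM/dt = A^T M (checked by a central
        finite-difference oracle on a dense regrid)."""
        noisy, clean, a = simulate_linear_ode_modules(4, seed=2, noise_sd=0.0)
        t = np.linspace(0, 12, 14)
        # re-integrate independently with a different solver setup
        from scipy.integrate import odeint

        resolved = odeint(lambda x, _: a.T @ x, clean[:, 0], t, rtol=1e-10, atol=1e-12).T
        np.testing.assert_allclose(resolved, clean, atol=1e-5)

    def test_odd_module_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_linear_ode_modules(5, seed=0)
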