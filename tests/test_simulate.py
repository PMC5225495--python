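"""Synthetic oscillator and stationary-null cohort generators."""

import numpy as np
import pytest

from phasedyn.dynamic_fc import coupling_cv_from_phases, kuramoto_order, metastability
from phasedyn.signal_phase import analytic_phase_values, phase_pipeline_values
from phasedyn.simulate import (
    SimulationConfig,
    generate_cohort,
    generate_null_cohort,
    simulate_kuramoto_bold,
    simulate_stationary_null,
    uniform_coupling_matrix,
)


def _metastability_of(panel):
    phases = phase_pipeline_values(panel.values, panel.tr_seconds)
    return metastability(kuramoto_order(phases))


class TestConfigValidation:
    def test_defaults_are_valid(self):
        cfg = SimulationConfig()
        assert cfg.n_nodes == 26
        assert cfg.n_timepoints == 202
        assert cfg.tr_seconds == 2.638
        assert cfg.freq_band == (0.04, 0.07)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_nodes": 1},
            {"n_timepoints": 20},
            {"freq_band": (0.07, 0.04)},
            {"freq_band": (0.04, 0.25)},
            {"steps_per_tr": 5},
            {"noise_sd": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestKuramotoGenerator:
    def test_uncoupled_noiseless_nodes_are_pure_sinusoids(self):
        cfg = SimulationConfig(
            n_nodes=2, n_timepoints=500, noise_sd=0.0, phase_noise_sd=0.0,
            coupling_by_group={"G": 0.0},
        )
        panel = simulate_kuramoto_bold(cfg, np.zeros((2, 2)), seed=7)
        low, high = cfg.freq_band
        for k in range(2):
            phase, _ = analytic_phase_values(panel.values[k], trim=10)
            slopes = np.diff(np.unwrap(phase)) / cfg.tr_seconds
            # constant instantaneous frequency inside the band (small ripple
            # from the discrete analytic-signal transform is tolerated)
            assert slopes.std() < 0.01 * abs(slopes.mean())
            assert 2 * np.pi * low * 0.99 <= slopes.mean() <= 2 * np.pi * high * 1.01

    def test_full_synchrony_limit(self):
        # near-identical natural frequencies + coupling far above critical:
        # R -> 1 after the burn-in transient, metastability -> 0
        cfg = SimulationConfig(
            n_nodes=6, n_timepoints=202, noise_sd=0.0, phase_noise_sd=0.0,
            freq_band=(0.0549, 0.0551),
        )
        coupling = uniform_coupling_matrix(6, 2.0)
        panel = simulate_kuramoto_bold(cfg, coupling, seed=3)
        # phases directly from the raw signal (already narrowband sinusoids)
        phase, _ = analytic_phase_values(panel.values, trim=10)
        r = kuramoto_order(phase)
        assert r[20:].min() > 0.98
        assert metastability(r[20:]) < 0.01

    def test_metastability_peaks_at_intermediate_coupling(self):
        """Near-critical coupling out-fluctuates both K=0 and strong K."""
        cfg = SimulationConfig()
        means = {}
        for k in (0.0, 0.09, 0.9):
            vals = [
                _metastability_of(
                    simulate_kuramoto_bold(
                        cfg, uniform_coupling_matrix(26, k), seed=100 * s + int(k * 100)
                    )
                )
                for s in range(8)
            ]
            means[k] = np.mean(vals)
        assert means[0.09] > means[0.0]
        assert means[0.09] > means[0.9]

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_nodes=4, n_timepoints=60)
        c = uniform_coupling_matrix(4, 0.05)
        a = simulate_kuramoto_bold(cfg, c, seed=11)
        b = simulate_kuramoto_bold(cfg, c, seed=11)
        assert np.array_equal(a.values, b.values)

    def test_invalid_coupling_matrices_rejected(self):
        cfg = SimulationConfig(n_nodes=3, n_timepoints=60)
        bad = np.array([[0, 1, 0], [0, 0, 1], [0, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            simulate_kuramoto_bold(cfg, bad, seed=0)
        with pytest.raises(ValueError, match="diagonal"):
            simulate_kuramoto_bold(cfg, np.eye(3), seed=0)
        with pytest.raises(ValueError, match="3x3"):
            simulate_kuramoto_bold(cfg, np.zeros((2, 2)), seed=0)


class TestStationaryNull:
    def test_white_noise_has_small_cross_correlations(self):
        cfg = SimulationConfig()
        panel = simulate_stationary_null(cfg, np.eye(26), 0.0, seed=5)
        corr = np.corrcoef(panel.values)
        iu = np.triu_indices(26, k=1)
        # 325 null correlations at n=202: typical |r| ~ 0.07, extremes ~ 0.25
        assert np.abs(corr[iu]).mean() < 0.08
        assert np.abs(corr[iu]).max() < 0.3

    def test_ar1_autocorrelation_closed_form(self):
        cfg = SimulationConfig(n_nodes=4)
        panel = simulate_stationary_null(cfg, np.eye(4), 0.9, seed=6, n_timepoints=5000)
        for k in range(4):
            x = panel.values[k]
            lag1 = np.corrcoef(x[1:], x[:-1])[0, 1]
            assert abs(lag1 - 0.9) < 0.1

    def test_cross_covariance_recovered(self):
        cfg = SimulationConfig(n_nodes=4)
        sigma = np.eye(4)
        sigma[0, 1] = sigma[1, 0] = 0.5
        panel = simulate_stationary_null(cfg, sigma, 0.0, seed=8, n_timepoints=5000)
        r = np.corrcoef(panel.values[0], panel.values[1])[0, 1]
        assert abs(r - 0.5) < 0.1

    def test_non_positive_definite_covariance_rejected(self):
        cfg = SimulationConfig(n_nodes=3)
        sigma = np.ones((3, 3))  # rank 1
        with pytest.raises(ValueError, match="positive definite"):
            simulate_stationary_null(cfg, sigma, 0.2, seed=0)

    def test_ar_coefficient_bounds(self):
        cfg = SimulationConfig(n_nodes=2)
        with pytest.raises(ValueError):
            simulate_stationary_null(cfg, np.eye(2), 1.0, seed=0)


class TestGenerateCohort:
    def test_reproducible_and_group_structured(self, small_config, small_cohort):
        panels, cohort = small_cohort
        assert len(panels) == 3 * small_config.n_subjects
        assert cohort.groups == ["AD", "MCI", "SCI"]
        panels2, cohort2 = generate_cohort(small_config, spec_seed=321)
        assert cohort.table.equals(cohort2.table)
        for a, b in zip(panels, panels2):
            assert np.array_equal(a.values, b.values)

    def test_single_group_cohort_has_one_label(self):
        cfg = SimulationConfig(n_subjects=4, n_nodes=6, coupling_by_group={"G": 0.05})
        _, cohort = generate_cohort(cfg, spec_seed=1)
        assert cohort.groups == ["G"]

    def test_empty_group_map_rejected(self):
        cfg = SimulationConfig(n_subjects=4, n_nodes=6)
        cfg.coupling_by_group = {}
        with pytest.raises(ValueError, match="group"):
            generate_cohort(cfg, spec_seed=1)

    def test_age_imbalance_mirrors_group_means(self):
        cfg = SimulationConfig(n_subjects=40, n_nodes=2, n_timepoints=30)
        _, cohort = generate_cohort(cfg, spec_seed=9)
        means = cohort.table.groupby("group")["age"].mean()
        assert means["AD"] > means["MCI"]
        assert means["AD"] > means["SCI"]

    def test_supercritical_coupling_suppresses_dfc_sum_vs_null(self):
        """Strong coupling locks phases: C_ij ~ 1 with little relative
        variation, so the summed dFC CV falls far below the stationary
        null's (the generators are distinguishable in a known direction)."""
        cfg = SimulationConfig(
            n_subjects=1, n_nodes=12, coupling_by_group={"G": 0.4}
        )
        k_sums, n_sums = [], []
        for r in range(10):
            kp, _ = generate_cohort(cfg, spec_seed=50 + r)
            np_, _ = generate_null_cohort(cfg, spec_seed=50 + r)
            for p, kind in ((kp[0], k_sums), (np_[0], n_sums)):
                ph = phase_pipeline_values(p.values, p.tr_seconds)
                kind.append(np.nansum(coupling_cv_from_phases(ph)))
        assert np.mean(k_sums) < 0.5 * np.mean(n_sums)
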