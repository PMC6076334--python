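"""MLE statistics: diffusion, MSD, mixtures, pharmacology, time courses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from autosmi import stats
from autosmi.simulate import (SimulationConfig, simulate_response_tables,
                              simulate_trajectories)


@pytest.fixture
def config():
    return SimulationConfig(rng_seed=0)


class TestStepDiffusion:
    def test_stationary_track_gives_zero(self):
        track = np.zeros((10, 2))
        assert stats.step_diffusion([track])[0] == 0.0

    def test_short_tracks_excluded(self):
        assert len(stats.step_diffusion([np.zeros((2, 2))])) == 0

    def test_estimator_unbiased_on_brownian_motion(self, config):
        """Bias below 1% at 1e5 displacements (analytic E[dr^2] = 4 D T)."""
        d_true = 0.11
        pos, _ = simulate_trajectories(config, [(d_true, 1.0)],
                                       n_tracks=25000, n_frames=6,
                                       rng=np.random.default_rng(1))
        d_mol = stats.step_diffusion(list(pos))
        n_disp = 25000 * 4
        assert n_disp >= 10 ** 5
        assert abs(np.mean(d_mol) - d_true) / d_true < 0.01

    def test_per_cell_mean_recovers_truth_within_3se(self, config):
        d_true = 0.11
        pos, _ = simulate_trajectories(config, [(d_true, 1.0)],
                                       n_tracks=10000, n_frames=5,
                                       rng=np.random.default_rng(2))
        d_mol = stats.step_diffusion(list(pos))
        se = d_mol.std(ddof=1) / np.sqrt(len(d_mol))
        assert abs(d_mol.mean() - d_true) < 3 * se


class TestMsd:
    def test_stationary_is_identically_zero(self):
        curve = stats.msd([np.zeros((20, 2))])
        assert np.all(curve.values[curve.n_pairs > 0] == 0.0)

    def test_ballistic_closed_form(self):
        """Straight-line motion with step s per frame: MSD(n dt) = (n s)^2."""
        s = 0.05
        track = np.column_stack([s * np.arange(30), np.zeros(30)])
        curve = stats.msd([track])
        for n in range(1, 16):
            assert curve.values[n - 1] == pytest.approx((n * s) ** 2)

    def test_brownian_matches_4dnt_within_3se(self, config):
        d = 0.1
        pos, _ = simulate_trajectories(config, [(d, 1.0)], n_tracks=3000,
                                       n_frames=20,
                                       rng=np.random.default_rng(3))
        curve = stats.msd(list(pos))
        dt = config.frame_interval
        for n in (1, 5, 10):
            expected = 4 * d * n * dt
            # SE of a mean of ~n_pairs chi^2-ish terms
            se = expected * np.sqrt(2.0 / curve.n_pairs[n - 1]) * 3
            assert abs(curve.values[n - 1] - expected) < 3 * se


class TestConfinedFit:
    LAGS = 0.033 * np.arange(1, 16)

    def test_exact_curves_recovered(self):
        m = stats.confined_msd(self.LAGS, 0.05, 0.264)
        fit = stats.fit_confined(np.tile(m, (5, 1)))
        assert fit.d == pytest.approx(0.05, rel=1e-4)
        assert fit.c == pytest.approx(0.264, rel=1e-4)

    def test_lognormal_scatter_recovery_within_5pct(self):
        """100 synthetic cells scattered log-normally around the confined
        model: (D, C) recovered within 5% (generator truth oracle)."""
        rng = np.random.default_rng(4)
        d_true, c_true, sig = 0.05, 0.264, 0.2
        m = stats.confined_msd(self.LAGS, d_true, c_true)
        d_mat = m[None, :] * np.exp(sig * rng.standard_normal((100, 15))
                                    - sig ** 2 / 2)
        fit = stats.fit_confined(d_mat)
        assert fit.d == pytest.approx(d_true, rel=0.05)
        assert fit.c == pytest.approx(c_true, rel=0.05)

    def test_lognormal_model_preferred_on_lognormal_data(self):
        rng = np.random.default_rng(5)
        m = stats.confined_msd(self.LAGS, 0.08, 0.3)
        d_mat = m[None, :] * np.exp(0.4 * rng.standard_normal((60, 15)) - 0.08)
        fit = stats.fit_confined(d_mat)
        assert fit.logl_log > fit.logl_norm
        assert fit.error_model == "lognormal"

    def test_free_diffusion_limit_tracks_4dt(self):
        """On free-diffusion curves the fitted model follows 4 D t across
        the lag window (plateau pushed beyond it)."""
        rng = np.random.default_rng(6)
        d_true = 0.05
        m = 4 * d_true * self.LAGS
        d_mat = m[None, :] * np.exp(0.05 * rng.standard_normal((50, 15)))
        fit = stats.fit_confined(d_mat)
        fitted = stats.confined_msd(self.LAGS, fit.d, fit.c)
        np.testing.assert_allclose(fitted, m, rtol=0.05)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            stats.fit_confined(np.ones((1, 15)))


class TestStateMixture:
    def test_single_state_data_selects_one_state(self, config):
        pos, _ = simulate_trajectories(config, [(0.1, 1.0)], n_tracks=1500,
                                       n_frames=8,
                                       rng=np.random.default_rng(7))
        model = stats.select_states(stats.step_displacements(list(pos)))
        assert model.n_states == 1
        assert model.d_values[0] == pytest.approx(0.1, rel=0.05)

    def test_three_state_recovery(self, config):
        """AIC selects N=3 and the fractions come back within +/-0.05
        (generator truth oracle, 1e4+ displacements)."""
        states = [(0.01, 0.3), (0.08, 0.4), (0.3, 0.3)]
        pos, _ = simulate_trajectories(config, states, n_tracks=10000,
                                       n_frames=3,
                                       rng=np.random.default_rng(8))
        r = stats.step_displacements(list(pos))
        assert len(r) >= 10 ** 4
        model = stats.select_states(r)
        assert model.n_states == 3
        for (d_true, f_true), f_hat in zip(states, model.fractions):
            assert abs(f_hat - f_true) <= 0.05
        assert model.d_values[0] < model.d_values[1] < model.d_values[2]

    def test_aic_equals_brute_force_over_candidates(self, config):
        pos, _ = simulate_trajectories(config, [(0.05, 0.5), (0.3, 0.5)],
                                       n_tracks=800, n_frames=8,
                                       rng=np.random.default_rng(9))
        r = stats.step_displacements(list(pos))
        models = [stats.fit_state_mixture(r, n) for n in range(1, 5)]
        for m in models:
            assert m.aic == pytest.approx(-2 * m.logl + 2 * m.k)
        best = stats.select_states(r)
        assert best.aic == min(m.aic for m in models)

    @given(seed=st.integers(0, 50))
    def test_fractions_sum_to_one(self, seed):
        r = np.random.default_rng(seed).rayleigh(0.1, size=400)
        for n in (1, 2, 3):
            model = stats.fit_state_mixture(r, n)
            assert np.sum(model.fractions) == pytest.approx(1.0, abs=1e-12)


class TestClusterSizes:
    def test_pure_monomer(self):
        rng = np.random.default_rng(10)
        x = np.abs(rng.normal(1000, 200, size=2000))
        model = stats.fit_cluster_sizes([x])
        assert model.fractions[0, 0] > 0.95
        assert model.mean_sizes[0] == pytest.approx(1.0, abs=0.1)

    def test_monomer_dimer_trimer_fractions_within_005(self):
        rng = np.random.default_rng(11)
        mu, sg = 1000.0, 200.0
        ns = rng.choice([1, 2, 3], size=10 ** 4, p=[0.6, 0.3, 0.1])
        x = rng.normal(ns * mu, np.sqrt(ns) * sg)
        x = x[x > 0]
        model = stats.fit_cluster_sizes([x])
        assert model.mu == pytest.approx(mu, rel=0.05)
        assert model.sigma == pytest.approx(sg, rel=0.15)
        for n, f_true in [(1, 0.6), (2, 0.3), (3, 0.1)]:
            assert abs(model.fractions[0, n - 1] - f_true) <= 0.05

    def test_pre_post_stimulation_mean_sizes(self):
        """Joint fit of two conditions (shared mu, sigma) recovers mean
        cluster sizes 1.5 and 2.1 used as generator truth."""
        rng = np.random.default_rng(12)
        mu, sg = 1000.0, 200.0
        pre_p = [0.6, 0.3, 0.1]                      # mean 1.5
        post_p = [0.35, 0.35, 0.18, 0.09, 0.03]      # mean 2.1
        pre = rng.normal(0, 1, 0)
        pre_n = rng.choice([1, 2, 3], size=6000, p=pre_p)
        post_n = rng.choice([1, 2, 3, 4, 5], size=6000, p=post_p)
        pre = np.abs(rng.normal(pre_n * mu, np.sqrt(pre_n) * sg))
        post = np.abs(rng.normal(post_n * mu, np.sqrt(post_n) * sg))
        model = stats.fit_cluster_sizes({"pre": pre, "post": post})
        mean_pre, mean_post = model.mean_sizes
        assert mean_pre == pytest.approx(1.5, abs=0.15)
        assert mean_post == pytest.approx(2.1, abs=0.2)
        assert np.allclose(model.fractions.sum(axis=1), 1.0)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            stats.fit_cluster_sizes([np.array([-1.0, 2.0])])


class TestDoseResponse:
    TRUTH = {"msd_max": 0.09, "msd_min": 0.04, "ec50": 6.6, "h": 1.0}
    CONC = np.concatenate([[0.0], np.geomspace(0.06, 60.0, 9)])

    def test_noise_free_exact_recovery(self):
        table = simulate_response_tables(self.CONC, self.TRUTH, 0.0,
                                         n_cells=5,
                                         rng=np.random.default_rng(13))
        fit = stats.fit_dose_response(table)
        assert fit.ec50 == pytest.approx(6.6, rel=1e-3)
        assert fit.h == pytest.approx(1.0, abs=1e-3)
        assert fit.msd_max == pytest.approx(0.09, rel=1e-3)
        assert fit.msd_min == pytest.approx(0.04, rel=1e-3)

    def test_zero_ligand_pins_msd_max(self):
        from autosmi.stats import hill_msd
        assert hill_msd(0.0, **self.TRUTH) == pytest.approx(0.09)

    def test_lognormal_scatter_recovery(self):
        """18 cells x 10 concentrations as in the study conditions; median
        estimates over replicates land near the generator truth."""
        rng = np.random.default_rng(14)
        ecs, hs = [], []
        for rep in range(10):
            table = simulate_response_tables(self.CONC, self.TRUTH, 0.15,
                                             n_cells=18, rng=rng)
            fit = stats.fit_dose_response(table, seed=rep)
            ecs.append(fit.ec50)
            hs.append(fit.h)
        assert np.median(ecs) == pytest.approx(6.6, rel=0.25)
        assert abs(np.median(hs) - 1.0) <= 0.2

    def test_lognormal_model_adopted_on_lognormal_scatter(self):
        table = simulate_response_tables(self.CONC, self.TRUTH, 0.3,
                                         n_cells=30,
                                         rng=np.random.default_rng(15))
        fit = stats.fit_dose_response(table)
        assert fit.logl_log > fit.logl_norm
        assert fit.error_model == "lognormal"

    def test_flat_data_flagged(self):
        rng = np.random.default_rng(16)
        table = pd.DataFrame({"ligand_nM": np.repeat(self.CONC, 3),
                              "msd": rng.normal(0.09, 1e-4,
                                                3 * len(self.CONC))})
        with pytest.warns(UserWarning):
            stats.fit_dose_response(table)


class TestInhibition:
    TRUTH = {"msd_max": 0.09, "msd_min": 0.04, "ec50": 4.7, "ic50": 2300.0}
    L = np.array([0.3, 1.0, 3.0, 10.0, 30.0, 60.0])
    I = np.array([0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0])

    def test_zero_inhibitor_reduces_to_hill_with_unit_coefficient(self):
        from autosmi.stats import hill_msd, inhibition_msd
        lig = np.array([0.5, 5.0, 50.0])
        np.testing.assert_allclose(
            inhibition_msd(lig, 0.0, 0.09, 0.04, 4.7, 2300.0),
            hill_msd(lig, 0.09, 0.04, 4.7, 1.0))

    def test_infinite_inhibitor_restores_msd_max(self):
        from autosmi.stats import inhibition_msd
        lig = np.array([0.5, 5.0, 50.0])
        out = inhibition_msd(lig, 1e12, 0.09, 0.04, 4.7, 2300.0)
        np.testing.assert_allclose(out, 0.09, rtol=1e-6)

    def test_noise_free_exact_recovery(self):
        table = simulate_response_tables(self.L, self.TRUTH, 0.0, n_cells=3,
                                         inhibitor_concentrations=self.I,
                                         rng=np.random.default_rng(17))
        fit = stats.fit_inhibition(table)
        assert fit.ec50 == pytest.approx(4.7, rel=1e-3)
        assert fit.ic50 == pytest.approx(2300.0, rel=1e-3)

    def test_grid_recovery_with_scatter(self):
        """6x6 grid x 3 cells (study conditions): estimates bracket the
        generator truth across replicates."""
        rng = np.random.default_rng(18)
        ecs, ics = [], []
        for rep in range(6):
            table = simulate_response_tables(
                self.L, self.TRUTH, 0.12, n_cells=3,
                inhibitor_concentrations=self.I, rng=rng)
            fit = stats.fit_inhibition(table, seed=rep)
            ecs.append(fit.ec50)
            ics.append(fit.ic50)
        assert min(ecs) <= 4.7 <= max(ecs) or np.median(ecs) == pytest.approx(4.7, rel=0.25)
        assert min(ics) <= 2300.0 <= max(ics) or np.median(ics) == pytest.approx(2300.0, rel=0.25)


class TestCompareConditions:
    def test_separated_distributions_flagged_below_0005(self):
        rng = np.random.default_rng(22)
        a = rng.normal(0.11, 0.01, 60)
        b = rng.normal(0.05, 0.01, 60)
        p, sig = stats.compare_conditions(a, b)
        assert sig and p < 0.005

    def test_identical_distributions_not_flagged(self):
        rng = np.random.default_rng(23)
        a = rng.normal(0.11, 0.01, 60)
        b = rng.normal(0.11, 0.01, 60)
        p, sig = stats.compare_conditions(a, b)
        assert not sig and p > 0.005


class TestResidenceTimecourse:
    def test_ten_frame_tracks_give_0297_s(self):
        tracks = [np.zeros((10, 2))] * 7
        mean, se = stats.residence_time(tracks)
        assert mean == pytest.approx(9 * 0.033)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_geometric_lifetimes_recovered(self):
        rng = np.random.default_rng(19)
        dt = 0.033
        mean_s = 0.5
        lengths = 1 + rng.geometric(dt / mean_s, size=4000)
        tracks = [np.zeros((n, 2)) for n in lengths]
        mean, se = stats.residence_time(tracks)
        assert abs(mean - mean_s) < 3 * max(se, 1e-6)

    def test_cell_success_requires_one_second_track(self):
        assert stats.cell_success([np.zeros((32, 2))])      # 31 steps = 1.02 s
        assert not stats.cell_success([np.zeros((20, 2))])  # 0.63 s
        assert not stats.cell_success([])

    def test_timecourse_step_change_in_correct_bin(self, config):
        """A change in diffusion at t0=80 s shows up in the right 40-s bin,
        and pre-stimulus bins are flagged baseline."""
        rng = np.random.default_rng(20)
        slow_pos, _ = simulate_trajectories(config, [(0.02, 1.0)],
                                            n_tracks=150, n_frames=8, rng=rng)
        fast_pos, _ = simulate_trajectories(config, [(0.3, 1.0)],
                                            n_tracks=150, n_frames=8, rng=rng)
        trajs = list(fast_pos) + list(slow_pos)
        starts = np.concatenate([rng.uniform(0, 80, 150),
                                 rng.uniform(80, 160, 150)])
        table = stats.timecourse(trajs, starts, n_states=1,
                                 stimulus_time=80.0)
        assert len(table) == 4
        assert list(table["baseline"]) == [True, True, False, False]
        d_per_bin = [v[0] for v in table["state_d_values"]]
        assert min(d_per_bin[:2]) > 5 * max(d_per_bin[2:])

    def test_timecourse_stationary_bins_consistent(self, config):
        rng = np.random.default_rng(21)
        pos, _ = simulate_trajectories(config, [(0.1, 1.0)], n_tracks=300,
                                       n_frames=8, rng=rng)
        starts = rng.uniform(0, 120, 300)
        table = stats.timecourse(list(pos), starts, n_states=1)
        d_vals = [v[0] for v in table["state_d_values"]]
        assert max(d_vals) / min(d_vals) < 1.5
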