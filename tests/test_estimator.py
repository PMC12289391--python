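from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import scrthin as st
from scrthin.estimator import MCMCConfig, PoissonSCR, PriorSpec, compute_rhat, initialize_state


@pytest.fixture(scope="module")
def fitted_pair(ref_grid, ref_space, ref_config):
    """Two fits of the same control dataset with the same seed."""
    _, _, control, _ = st.generate_replicate(ref_config, 1)
    mk = lambda: PoissonSCR(
        grid=ref_grid, space=ref_space, n_iter=1500, n_burnin=300, M=60, random_state=7
    )
    return control, mk().fit(control), mk().fit(control)


class TestInitialization:
    def test_constraints_on_initial_state(self, ref_grid, ref_space, ref_config):
        _, _, control, _ = st.generate_replicate(ref_config, 0)
        cfg = MCMCConfig(M=50)
        state = initialize_state(control, ref_grid, cfg, ref_space, 0)
        assert state.n_included >= control.n_detected
        assert ref_space.contains(state.s).all()
        assert state.z[: control.n_detected].all()

    def test_single_detector_individual_starts_at_detector(self, ref_grid, ref_space):
        y = np.zeros((1, 64), dtype=int)
        y[0, 10] = 3
        state = initialize_state(y, ref_grid, MCMCConfig(M=10), ref_space, 0, K=5)
        np.testing.assert_allclose(state.s[0], ref_grid.coords[10])

    def test_different_seeds_overdisperse_chains(self, ref_grid, ref_space, ref_config):
        _, _, control, _ = st.generate_replicate(ref_config, 0)
        a = initialize_state(control, ref_grid, MCMCConfig(M=50), ref_space, 1)
        b = initialize_state(control, ref_grid, MCMCConfig(M=50), ref_space, 2)
        assert not np.array_equal(a.s, b.s)
        assert a.params.lam0 != b.params.lam0

    def test_M_not_exceeding_detected_rejected(self, ref_grid, ref_space, ref_config):
        _, _, control, _ = st.generate_replicate(ref_config, 0)
        with pytest.raises(ValueError):
            initialize_state(
                control, ref_grid, MCMCConfig(M=control.n_detected), ref_space, 0
            )


class TestKernels:
    def _state(self, grid, space, M=8, n_obs=2, psi=0.5, lam0=0.1, seed=0):
        rng = np.random.default_rng(seed)
        s = np.column_stack(
            [rng.uniform(space.xmin, space.xmax, M), rng.uniform(space.ymin, space.ymax, M)]
        )
        z = np.zeros(M, dtype=int)
        z[:n_obs] = 1
        params = st.DetectionParams(lam0=lam0, sigma=1000.0, K=5)
        return st.AugmentedState(M=M, z=z, s=s, psi=psi, params=params)

    def _y(self, grid, M, n_obs, rng):
        y = np.zeros((M, grid.n_detectors), dtype=int)
        for i in range(n_obs):
            y[i, rng.integers(grid.n_detectors)] = 1 + rng.integers(3)
        return y

    def test_inclusion_tiny_psi_excludes_undetected(self, ref_grid, ref_space):
        state = self._state(ref_grid, ref_space, psi=1e-12)
        y = self._y(ref_grid, state.M, 2, np.random.default_rng(0))
        out = st.update_inclusion(state, y, ref_grid, ref_space, seed=1)
        assert out.z[2:].sum() == 0
        assert out.z[:2].all()  # detected keep z=1

    def test_inclusion_probability_is_psi_when_likelihood_flat(self, ref_grid, ref_space):
        # lam0 -> 0 makes L0 = 1, so P(z=1) = psi exactly
        psi = 0.37
        state = self._state(ref_grid, ref_space, M=2000, n_obs=0, psi=psi, lam0=1e-300)
        y = np.zeros((2000, 64), dtype=int)
        out = st.update_inclusion(state, y, ref_grid, ref_space, seed=3)
        frac = out.z.mean()
        assert abs(frac - psi) < 3 * np.sqrt(psi * (1 - psi) / 2000)

    def test_inclusion_far_from_detectors_approaches_psi(self, ref_grid, ref_space):
        psi = 0.6
        state = self._state(ref_grid, ref_space, M=3000, n_obs=0, psi=psi)
        state.s[:] = [1e7, 1e7]  # likelihood of zero counts -> 1
        y = np.zeros((3000, 64), dtype=int)
        out = st.update_inclusion(state, y, ref_grid, ref_space, seed=4)
        assert abs(out.z.mean() - psi) < 3 * np.sqrt(psi * (1 - psi) / 3000)

    def test_psi_conjugate_posterior_moments(self, ref_grid, ref_space):
        # long-run mean of psi draws matches Beta(1+n, 1+M-n) mean; and the
        # draw distribution passes a KS test against that Beta
        state = self._state(ref_grid, ref_space, M=10, n_obs=3)
        state.z[:] = 0
        state.z[:3] = 1
        draws = np.array(
            [st.update_psi(state, seed=s).psi for s in range(4000)]
        )
        a, b = 1 + 3, 1 + 7
        assert abs(draws.mean() - a / (a + b)) < 3 * np.sqrt(
            a * b / ((a + b) ** 2 * (a + b + 1)) / len(draws)
        )
        assert stats.kstest(draws, stats.beta(a, b).cdf).pvalue > 0.01

    def test_psi_boundary_cases(self, ref_grid, ref_space):
        state = self._state(ref_grid, ref_space, M=10, n_obs=0)
        state.z[:] = 1
        mean_full = np.mean([st.update_psi(state, seed=s).psi for s in range(2000)])
        assert abs(mean_full - 11 / 12) < 0.02  # Beta(11, 1) mean
        state.z[:] = 0
        mean_none = np.mean([st.update_psi(state, seed=s).psi for s in range(2000)])
        assert abs(mean_none - 1 / 12) < 0.02  # Beta(1, 11) mean

    def test_excluded_centers_redrawn_uniformly(self, ref_grid, ref_space):
        state = self._state(ref_grid, ref_space, M=4000, n_obs=0)
        state.z[:] = 0
        y = np.zeros((4000, 64), dtype=int)
        out = st.update_activity_centers(state, y, ref_grid, ref_space, seed=5)
        assert ref_space.contains(out.s).all()
        # uniformity: x-coordinates pass a KS test against U(xmin, xmax)
        u = (out.s[:, 0] - ref_space.xmin) / ref_space.width
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_included_center_proposals_stay_inside(self, ref_grid, ref_space):
        state = self._state(ref_grid, ref_space, M=500, n_obs=0, seed=2)
        state.z[:] = 1
        y = np.zeros((500, 64), dtype=int)
        out = st.update_activity_centers(
            state, y, ref_grid, ref_space, seed=6, s_step=5000.0
        )
        assert ref_space.contains(out.s).all()

    def test_point_mass_prior_freezes_detection_params(self, ref_grid, ref_space):
        state = self._state(ref_grid, ref_space)
        y = self._y(ref_grid, state.M, 2, np.random.default_rng(1))
        priors = PriorSpec(lam0=(0.1, 0.1), sigma=(1000.0, 1000.0))
        out = st.update_detection_params(
            state, y, ref_grid, ref_space, priors=priors, seed=7
        )
        assert out.params.lam0 == 0.1 and out.params.sigma == 1000.0

    def test_detection_param_update_moves_under_vague_prior(self, ref_grid, ref_space):
        state = self._state(ref_grid, ref_space, M=12, n_obs=4, seed=3)
        y = self._y(ref_grid, 12, 4, np.random.default_rng(2))
        moved = 0
        cur = state
        for s in range(50):
            cur = st.update_detection_params(cur, y, ref_grid, ref_space, seed=s)
        assert cur.params.lam0 != state.params.lam0 or cur.params.sigma != state.params.sigma


class TestRhat:
    def test_identical_chains_give_exactly_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=500)
        assert compute_rhat(np.stack([chain, chain, chain])) == 1.0

    def test_disjoint_constant_chains_diverge(self):
        chains = np.stack([np.zeros(100), np.ones(100)])
        assert compute_rhat(chains) == np.inf

    def test_iid_normal_chains_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(3, 10_000))
        assert compute_rhat(chains) < 1.01

    def test_single_chain_split_variant(self):
        rng = np.random.default_rng(2)
        # trending chain: first and second half differ -> R-hat well above 1
        trend = np.linspace(0, 5, 2000) + rng.normal(size=2000)
        assert compute_rhat(trend[None, :]) > 1.5
        assert compute_rhat(rng.normal(size=(1, 2000))) < 1.05

    def test_agrees_with_arviz_on_well_mixed_chains(self):
        import arviz as az

        rng = np.random.default_rng(3)
        chains = rng.normal(size=(4, 2000))
        ours = compute_rhat(chains)
        theirs = float(az.rhat(chains))
        assert abs(ours - theirs) < 0.01


class TestFit:
    def test_duplicate_seed_bit_identical(self, fitted_pair):
        _, a, b = fitted_pair
        for p in ("N", "lam0", "sigma", "psi"):
            np.testing.assert_array_equal(a.samples_[p], b.samples_[p])

    def test_draw_bookkeeping_and_bounds(self, fitted_pair):
        control, a, _ = fitted_pair
        N = a.samples_["N"]
        assert N.shape == (3, 1200)
        assert N.min() >= control.n_detected and N.max() <= 60
        assert a.result_.n_ci[0] <= a.n_hat_ <= a.result_.n_ci[1]

    def test_all_zero_data_not_identifiable(self, ref_grid, ref_space):
        est = PoissonSCR(grid=ref_grid, space=ref_space, n_iter=200, n_burnin=50)
        with pytest.raises(st.NotIdentifiableError):
            est.fit(np.zeros((5, 64), dtype=int))

    def test_fixed_true_params_recover_abundance(self, ref_grid, ref_space, ref_config):
        # lam0, sigma fixed at truth: posterior mean N within 3 posterior SD of 10
        _, _, control, _ = st.generate_replicate(ref_config, 1)
        res = st.fit_scr(
            control,
            ref_grid,
            ref_space,
            priors=PriorSpec(lam0=(0.1, 0.1), sigma=(1000.0, 1000.0)),
            config=MCMCConfig(n_iter=2000, n_burnin=400, M=60, seed=3),
        )
        assert abs(res.n_hat - 10) < 3 * res.posterior_sd

    def test_acceptance_rates_in_healthy_band(self, fitted_pair):
        _, a, _ = fitted_pair
        for key, rate in a.acceptance_.items():
            assert 0.1 < rate < 0.6, (key, rate)

    def test_invariance_to_individual_reordering(self, ref_grid, ref_space, ref_config):
        _, _, control, _ = st.generate_replicate(ref_config, 2)
        y = control.observed()
        perm = np.random.default_rng(0).permutation(len(y))
        kw = dict(grid=ref_grid, space=ref_space, K=5, n_iter=1500, n_burnin=300,
                  M=60, random_state=11)
        a = PoissonSCR(**kw).fit(y)
        b = PoissonSCR(**kw).fit(y[perm])
        assert abs(a.n_hat_ - b.n_hat_) < 0.5

    def test_invariance_to_rigid_translation(self, ref_config):
        _, _, control, _ = st.generate_replicate(ref_config, 2)
        shift = np.array([1e5, -2e4])
        grid = st.build_detector_grid(8, 8, 800.0)
        grid_shifted = st.build_detector_grid(8, 8, 800.0, origin=tuple(shift))
        a = PoissonSCR(grid=grid, space=st.build_state_space(grid, 2500.0),
                       n_iter=1500, n_burnin=300, random_state=5).fit(control)
        b = PoissonSCR(grid=grid_shifted,
                       space=st.build_state_space(grid_shifted, 2500.0),
                       n_iter=1500, n_burnin=300, random_state=5).fit(control)
        np.testing.assert_array_equal(a.samples_["N"], b.samples_["N"])

    def test_augmentation_size_beyond_saturation_is_inert(self, ref_grid, ref_space, ref_config):
        _, _, control, _ = st.generate_replicate(ref_config, 1)
        kw = dict(grid=ref_grid, space=ref_space, n_iter=2500, n_burnin=500,
                  random_state=13)
        a = PoissonSCR(M=60, **kw).fit(control)
        b = PoissonSCR(M=100, **kw).fit(control)
        mc_err = 3 * (a.posterior_sd_ / np.sqrt(min(a.ess_["N"], b.ess_["N"])) * 2 + 0.1)
        assert abs(a.n_hat_ - b.n_hat_) < mc_err
        assert not a.saturated_

    def test_engines_agree_distributionally(self, ref_grid, ref_space, ref_config):
        # numba and numpy engines implement the same kernels: posterior
        # summaries should agree within Monte Carlo error
        _, _, control, _ = st.generate_replicate(ref_config, 1)
        kw = dict(grid=ref_grid, space=ref_space, n_iter=2500, n_burnin=500, M=60)
        a = PoissonSCR(engine="numba", random_state=1, **kw).fit(control)
        b = PoissonSCR(engine="numpy", random_state=1, **kw).fit(control)
        se = a.posterior_sd_ * np.sqrt(1 / a.ess_["N"] + 1 / b.ess_["N"])
        assert abs(a.n_hat_ - b.n_hat_) < 4 * se + 0.2

    def test_sklearn_param_interface(self, ref_grid, ref_space):
        est = PoissonSCR(grid=ref_grid, space=ref_space, n_iter=100)
        params = est.get_params()
        assert params["n_iter"] == 100
        est.set_params(n_iter=200)
        assert est.n_iter == 200

    def test_posterior_export_roundtrip(self, fitted_pair):
        _, a, _ = fitted_pair
        df = a.result_.to_frame()
        assert set(df.columns) == {"chain", "iteration", "N", "lam0", "sigma", "psi"}
        assert len(df) == 3 * 1200
        summ = a.result_.summary()
        assert summ["n_detected"] == a.n_detected_
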