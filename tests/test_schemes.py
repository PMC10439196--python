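import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stochprey import (
    Discretization,
    FieldState,
    ModelParameters,
    make_initial_state,
    nsfd_step,
    reference_reaction_trajectory,
    sfe_step,
    simulate,
    wiener_increments,
)


class TestInitialState:
    def test_constant_profiles(self, base_disc):
        st0 = make_initial_state(base_disc, 0.6, 0.4)
        assert st0.P.shape == (101,) and st0.Q.shape == (101,)
        assert np.all(st0.P == 0.6) and np.all(st0.Q == 0.4)
        assert st0.step == 0

    def test_extinction_state_admissible(self, base_disc):
        st0 = make_initial_state(base_disc, 0.0, 0.0)
        assert np.all(st0.P == 0.0) and np.all(st0.Q == 0.0)

    def test_negative_density_rejected(self, base_disc):
        with pytest.raises(ValueError):
            make_initial_state(base_disc, -0.1, 0.4)

    def test_perturbation_is_alternating_mode(self, base_disc):
        st0 = make_initial_state(base_disc, 0.6, 0.4, perturbation=1e-3)
        assert st0.P[0] == pytest.approx(0.601)
        assert st0.P[1] == pytest.approx(0.599)
        assert st0.P.mean() == pytest.approx(0.6, abs=1e-4)


class TestDiscretization:
    def test_diffusion_numbers_derived(self, base_params, base_disc):
        D1, D2 = base_disc.diffusion_numbers(base_params)
        assert D1 == pytest.approx(1.0 / 9.0) and D2 == pytest.approx(1.0 / 9.0)
        assert base_disc.h == pytest.approx(0.3)
        assert base_disc.final_time == pytest.approx(500.0)

    @pytest.mark.parametrize("kw", [
        dict(domain_length=0.0), dict(n_intervals=0), dict(delta_tau=0.0), dict(n_steps=0),
    ])
    def test_rejects_degenerate_grids(self, kw):
        base = dict(domain_length=30.0, n_intervals=100, delta_tau=0.1, n_steps=10)
        with pytest.raises(ValueError):
            Discretization(**{**base, **kw})


class TestSingleSteps:
    def test_sfe_constant_field_matches_hand_arithmetic(self, base_params, base_disc):
        st0 = make_initial_state(base_disc, 0.6, 0.4)
        st1 = sfe_step(st0, base_params, base_disc, 0.0, 0.0)
        # diffusion cancels on a constant field; reaction-only update
        np.testing.assert_allclose(st1.P, 0.5904, atol=1e-12)
        np.testing.assert_allclose(st1.Q, 0.39896, atol=1e-12)

    def test_sfe_multiplicative_noise_term(self, base_params, base_disc):
        st0 = make_initial_state(base_disc, 0.6, 0.4)
        st1 = sfe_step(st0, base_params, base_disc, 0.1, 0.0)
        np.testing.assert_allclose(st1.P, 0.5904 + 0.01 * 0.6 * 0.1, atol=1e-12)

    def test_nsfd_constant_field_matches_hand_arithmetic(self, base_params, base_disc):
        st0 = make_initial_state(base_disc, 0.6, 0.4)
        st1 = nsfd_step(st0, base_params, base_disc, 0.0, 0.0)
        D = 1.0 / 9.0
        p_expect = (2 * D * 0.6 + 1.11 * 0.6) / (1 + 2 * D + 0.7 * 0.1 * 0.6 + 2.1 * 0.1 * 0.4)
        q_expect = (2 * D * 0.4 + 0.4 + 0.79 * 0.1 * 0.24) / (1 + 2 * D + 0.05)
        np.testing.assert_allclose(st1.P, p_expect, rtol=1e-12)
        np.testing.assert_allclose(st1.Q, q_expect, rtol=1e-12)
        assert p_expect == pytest.approx(0.592879, abs=1e-6)
        assert q_expect == pytest.approx(0.399183, abs=1e-6)

    @pytest.mark.parametrize("stepper", [sfe_step, nsfd_step])
    def test_origin_is_fixed_point_for_any_noise(self, base_params, base_disc, stepper):
        st0 = make_initial_state(base_disc, 0.0, 0.0)
        st1 = stepper(st0, base_params, base_disc, 0.7, -1.3)
        assert np.all(st1.P == 0.0) and np.all(st1.Q == 0.0)

    def test_nsfd_positive_even_at_absurd_time_step(self, base_params):
        disc = Discretization(30.0, 20, 10.0, 5)
        st0 = make_initial_state(disc, 0.6, 0.4)
        st1 = nsfd_step(st0, base_params, disc, 0.0, 0.0)
        assert np.all(st1.P >= 0.0) and np.all(st1.Q >= 0.0)

    @pytest.mark.parametrize("stepper", [sfe_step, nsfd_step])
    def test_homogeneity_preserved_without_noise(self, base_params, base_disc, stepper):
        p = base_params.replace(eta1=0.0, eta2=0.0)
        state = make_initial_state(base_disc, 0.6, 0.4)
        for _ in range(100):
            state = stepper(state, p, base_disc, 0.0, 0.0)
        assert np.ptp(state.P) == 0.0 and np.ptp(state.Q) == 0.0


class TestNsfdPositivity:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.1, 3.0), b=st.floats(0.1, 2.0), c=st.floats(0.1, 3.0),
        m=st.floats(0.3, 2.0), f=st.floats(0.1, 3.0), d=st.floats(0.1, 2.0),
        sigma=st.floats(0.01, 5.0), dt=st.floats(0.001, 50.0),
        state_seed=st.integers(0, 2**16),
    )
    def test_unconditional_positivity(self, a, b, c, m, f, d, sigma, dt, state_seed):
        p = ModelParameters(a=a, b=b, c=c, m=m, f=f, d=d,
                            sigma1=sigma, sigma2=sigma, eta1=0.0, eta2=0.0)
        disc = Discretization(10.0, 16, dt, 5)
        gen = np.random.default_rng(state_seed)
        state = FieldState(0, gen.uniform(0, 3, 17), gen.uniform(0, 3, 17))
        for _ in range(5):
            state = nsfd_step(state, p, disc, 0.0, 0.0)
            assert np.all(state.P >= 0.0) and np.all(state.Q >= 0.0)
            assert np.all(np.isfinite(state.P)) and np.all(np.isfinite(state.Q))

    def test_decoupled_logistic_limit_monotone_to_carrying_capacity(self):
        # predator-free dynamics: the prey update reduces to the exact
        # Mickens logistic map P' = (1+a*dt)P / (1+2D1+b*dt*P)
        p = ModelParameters(a=1.1, b=0.7, c=2.1, m=1.0, f=0.79, d=0.5,
                            sigma1=1e-12, sigma2=1e-12, eta1=0.0, eta2=0.0)
        disc = Discretization(10.0, 10, 0.5, 200)
        state = make_initial_state(disc, 0.05, 0.0)
        prev = state.P[0]
        for _ in range(200):
            state = nsfd_step(state, p, disc, 0.0, 0.0)
            assert state.P[0] >= prev  # monotone increase below a/b
            prev = state.P[0]
        assert prev == pytest.approx(p.a / p.b, rel=1e-6)


class TestSimulate:
    def test_noise_shorter_than_run_rejected(self, base_params, small_disc):
        init = make_initial_state(small_disc, 0.6, 0.4)
        noise = wiener_increments(10, small_disc.delta_tau, seed=0)
        with pytest.raises(ValueError):
            simulate("nsfd", base_params, small_disc, init, noise)

    def test_unknown_scheme_rejected(self, base_params, small_disc):
        init = make_initial_state(small_disc, 0.6, 0.4)
        noise = wiener_increments(50, small_disc.delta_tau, seed=0)
        with pytest.raises(ValueError):
            simulate("crank_nicolson", base_params, small_disc, init, noise)

    def test_records_probe_means_and_snapshots(self, base_params, small_disc):
        init = make_initial_state(small_disc, 0.6, 0.4)
        noise = wiener_increments(50, small_disc.delta_tau, seed=0)
        res = simulate("nsfd", base_params, small_disc, init, noise, snapshot_stride=10)
        assert res.completed_steps == 50
        assert res.probe_P.shape == (51,) and res.mean_P.shape == (51,)
        assert list(res.snapshot_steps) == [0, 10, 20, 30, 40, 50]
        assert res.snapshots.shape == (6, 21, 2)
        assert res.times[-1] == pytest.approx(5.0)
        assert not res.diverged and res.negative_count == 0

    def test_reproducible_from_seed(self, base_params, small_disc):
        init = make_initial_state(small_disc, 0.6, 0.4)
        runs = [
            simulate("nsfd", base_params, small_disc, init,
                     wiener_increments(50, small_disc.delta_tau, seed=42))
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].final_state.P, runs[1].final_state.P)
        np.testing.assert_array_equal(runs[0].probe_Q, runs[1].probe_Q)

    def test_divergence_halts_and_records_step(self, base_params):
        # large diffusion number drives the explicit scheme over the cap
        p = base_params.replace(sigma1=1.0, sigma2=1.0)
        disc = Discretization(10.0, 60, 0.1, 500)
        init = make_initial_state(disc, 0.6, 0.4, perturbation=1e-6)
        noise = wiener_increments(500, 0.1, seed=1)
        res = simulate("sfe", p.replace(f=0.7), disc, init, noise)
        assert res.diverged
        assert res.divergence_step is not None
        assert res.completed_steps == res.divergence_step < 500

    @pytest.mark.parametrize("scheme", ["sfe", "nsfd"])
    def test_matches_reaction_ode_at_first_order(self, base_params, scheme):
        # sigma irrelevant on homogeneous data; eta=0 makes the run deterministic
        p = base_params.replace(eta1=0.0, eta2=0.0)
        T = 5.0
        t_ref, P_ref, Q_ref = reference_reaction_trajectory(p, 0.6, 0.4, T, 20000)
        errs = []
        for dt in (0.1, 0.05):
            n = int(round(T / dt))
            disc = Discretization(30.0, 10, dt, n)
            init = make_initial_state(disc, 0.6, 0.4)
            noise = wiener_increments(n, dt, seed=0)
            res = simulate(scheme, p, disc, init, noise)
            errs.append(
                abs(res.probe_P[-1] - P_ref[-1]) + abs(res.probe_Q[-1] - Q_ref[-1])
            )
        assert errs[0] < 0.05  # small error at dt=0.1 already
        ratio = errs[0] / errs[1]
        assert 1.5 < ratio < 3.0  # first order: halving dt ~halves the error
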