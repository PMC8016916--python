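"""Unit and property tests of the firing-rate dynamics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from comnet import (
    NetworkParams,
    NetworkState,
    WeightMatrix,
    apply_noise,
    noise_schedule,
    rate_update,
    step,
    total_stimulation,
)
from comnet.network import A_NODES, N_NODES


class TestRateUpdate:
    @pytest.mark.parametrize(
        "r_prev, stim, tau, expected",
        [
            (10.0, 10.0, 100.0, 10.0),    # fixed point: rate equals drive
            (10.0, 60.0, 100.0, 10.5),    # relaxation toward stronger drive
            (100.0, 0.0, 100.0, 99.0),    # relaxation toward zero drive
        ],
    )
    def test_euler_relaxation(self, r_prev, stim, tau, expected):
        assert rate_update(r_prev, stim, tau) == pytest.approx(expected)

    def test_rejects_nonpositive_tau(self):
        with pytest.raises(ValueError):
            rate_update(10.0, 10.0, 0.0)


class TestNoiseSchedule:
    def test_half_maximum_intention_halves_variance(self):
        # an intention firing at 50 of its 100 Hz maximum with h=1 cuts
        # the action-node noise variance by exactly 50%
        assert noise_schedule(2.0, 1.0, 50.0) == pytest.approx(1.0)

    def test_no_hierarchy_leaves_baseline(self):
        assert noise_schedule(2.0, 0.0, 73.0) == pytest.approx(2.0)

    def test_full_intention_silences_noise(self):
        assert noise_schedule(2.0, 1.0, 100.0) == pytest.approx(0.0)

    def test_rejects_negative_h(self):
        with pytest.raises(ValueError):
            noise_schedule(2.0, -0.1, 50.0)

    @given(
        h=st.floats(0.0, 1.0),
        r=st.floats(0.0, 100.0),
        s0=st.floats(0.0, 10.0),
    )
    def test_variance_stays_in_band(self, h, r, s0):
        out = float(noise_schedule(s0, h, r))
        assert 0.0 <= out <= s0 + 1e-12

    @given(h=st.floats(1.0, 5.0), r=st.floats(0.0, 100.0))
    def test_never_negative_even_for_large_h(self, h, r):
        assert float(noise_schedule(2.0, h, r)) >= 0.0


class TestApplyNoise:
    def test_zero_variance_is_identity(self):
        rng = np.random.default_rng(0)
        assert apply_noise(42.0, 0.0, rng) == pytest.approx(42.0)

    def test_unbiased(self):
        rng = np.random.default_rng(1)
        draws = apply_noise(np.full(100_000, 50.0), np.full(100_000, 2.0), rng)
        assert draws.mean() == pytest.approx(50.0, abs=0.05)

    def test_clamped_to_bounds(self):
        rng = np.random.default_rng(2)
        hi = apply_noise(np.full(10_000, 99.9), np.full(10_000, 2.0), rng)
        lo = apply_noise(np.full(10_000, 0.1), np.full(10_000, 2.0), rng)
        assert hi.max() <= 100.0 and lo.min() >= 0.0

    def test_rejects_negative_variance(self):
        with pytest.raises(ValueError):
            apply_noise(10.0, -1.0, np.random.default_rng(0))


class TestTotalStimulation:
    def test_zero_rates_zero_input(self, fx):
        stim = total_stimulation(np.zeros(N_NODES), fx["weights"], np.zeros(N_NODES))
        assert np.allclose(stim, 0.0)

    def test_pure_external_passthrough(self, fx):
        ext = np.zeros(N_NODES)
        ext[2] = 108.0  # high-coherence drive onto S1
        stim = total_stimulation(np.zeros(N_NODES), fx["weights"], ext)
        assert stim[2] == pytest.approx(108.0)
        assert np.allclose(np.delete(stim, 2), 0.0)

    def test_matches_dot_product_oracle(self, fx):
        stim = total_stimulation(fx["rates"], fx["weights"], fx["external"])
        assert np.allclose(stim, fx["expected_stim"])

    @given(seed=st.integers(0, 10_000))
    def test_random_configurations_match_elementwise_sum(self, seed):
        rng = np.random.default_rng(seed)
        W = WeightMatrix(rng.normal(0, 0.5, (N_NODES, N_NODES)))
        r = rng.uniform(0, 100, N_NODES)
        ext = rng.uniform(0, 120, N_NODES)
        expected = np.array([
            ext[i] + sum(r[j] * W.W[i, j] for j in range(N_NODES))
            for i in range(N_NODES)
        ])
        assert np.allclose(total_stimulation(r, W, ext), expected)

    def test_dimension_mismatch_rejected(self, fx):
        with pytest.raises(ValueError):
            total_stimulation(np.zeros(5), fx["weights"], np.zeros(N_NODES))


class TestStep:
    def test_same_seed_bitwise_identical(self, fx):
        params = NetworkParams(h=0.5)
        ext = fx["external"]
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(123)
            state = NetworkState.initial(params)
            hist = []
            for _ in range(200):
                state = step(state, fx["weights"], ext, params, rng)
                hist.append(state.r.copy())
            runs.append(np.array(hist))
        assert np.array_equal(runs[0], runs[1])

    def test_zero_everything_decays_geometrically(self):
        params = NetworkParams(sigma0_sq=0.0)
        weights = WeightMatrix(np.zeros((N_NODES, N_NODES)))
        state = NetworkState.initial(params)
        prev = state.r.copy()
        for k in range(300):
            state = step(state, weights, np.zeros(N_NODES), params, np.random.default_rng(0))
            assert (state.r <= prev + 1e-12).all()
            assert np.allclose(state.r, prev * (1 - 1 / params.tau))
            prev = state.r.copy()
        assert state.r.max() < 0.6

    def test_500_steps_match_reference_integrator(self, fx):
        # independent step-by-step reference: explicit loops over the
        # update equations, sharing the noise stream with the library path
        params = NetworkParams(h=0.7)
        W = fx["weights"].W
        gov = fx["weights"].gov
        ext = fx["external"]

        rng_lib = np.random.default_rng(7)
        rng_ref = np.random.default_rng(7)
        state = NetworkState.initial(params)
        r_ref = np.full(N_NODES, params.r_init)
        for _ in range(500):
            state = step(state, fx["weights"], ext, params, rng_lib)

            stim = np.array([
                ext[i] + sum(r_ref[j] * W[i, j] for j in range(N_NODES))
                for i in range(N_NODES)
            ])
            r_new = r_ref + (stim - r_ref) / params.tau
            sig = np.full(N_NODES, params.sigma0_sq)
            for k in range(4):
                sig[8 + k] = max(
                    params.sigma0_sq
                    - params.h * (r_ref[gov[k]] / 100) * params.sigma0_sq,
                    0.0,
                )
            r_new = r_new + rng_ref.standard_normal(N_NODES) * np.sqrt(sig)
            r_ref = np.clip(r_new, 0, 100)
            assert np.allclose(state.r, r_ref)

    def test_rates_stay_in_bounds_and_nonaction_noise_constant(self, fx):
        params = NetworkParams(h=1.0)
        rng = np.random.default_rng(5)
        state = NetworkState.initial(params)
        for _ in range(500):
            state = step(state, fx["weights"], fx["external"] * 2, params, rng)
            assert state.r.min() >= 0.0 and state.r.max() <= 100.0
            assert np.allclose(state.sigma_sq[:8], params.sigma0_sq)
            assert (state.sigma_sq[A_NODES] <= params.sigma0_sq + 1e-12).all()
            assert (state.sigma_sq[A_NODES] >= 0.0).all()


class TestNetworkParamsValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"tau": 0.0},
            {"sigma0_sq": -1.0},
            {"h": -0.5},
            {"nondecision": 100.0},
            {"r_min": 100.0, "r_max": 0.0},
        ],
    )
    def test_invalid_constants_rejected(self, kw):
        with pytest.raises(ValueError):
            NetworkParams(**kw)

    def test_nondecision_is_sum_of_delays(self):
        p = NetworkParams()
        assert p.nondecision == p.sensory_delay + p.motor_delay == 380.0
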