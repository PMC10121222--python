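import numpy as np
import pytest

from tepsim import (
    ConnectomeGraph, JRParams, Leadfield, StimulusSpec,
    build_stimulus_from_field, decimate_tep, project_to_channels, simulate,
)
from tepsim.errors import IntegrationError, ParameterError
from tepsim.synthetic import SMALL_NETWORK_G


def _chain_graph(delay_ms: float, velocity: float = 5.0) -> ConnectomeGraph:
    """Two nodes, a single directed connection 0 -> 1 with the given delay."""
    weights = np.array([[0.0, 0.0], [1.0, 0.0]])
    lengths = np.array([[0.0, delay_ms * velocity],
                        [delay_ms * velocity, 0.0]])
    return ConnectomeGraph(weights=weights, lengths=lengths,
                           velocity=velocity)


def _pulse(weights, amplitude=1.0, onset=0.0, duration=1.0):
    return StimulusSpec(np.asarray(weights, dtype=float), onset=onset,
                        duration=duration, amplitude=amplitude)


class TestQuiescence:
    def test_flat_baseline_without_stimulus(self, small_graph):
        stim = _pulse(np.zeros(small_graph.n_regions), amplitude=0.0)
        ts = simulate(small_graph, JRParams(g=SMALL_NETWORK_G), stim,
                      epoch=(-100.0, 100.0), dt=0.1,
                      initial_state="equilibrium")
        dev = np.abs(ts.states - ts.states[:, :, :1])
        assert dev.max() < 1e-6

    def test_deterministic_given_seed(self, small_graph, small_stimulus):
        p = JRParams(g=SMALL_NETWORK_G)
        a = simulate(small_graph, p, small_stimulus, epoch=(-20, 50), dt=0.1,
                     seed=42)
        b = simulate(small_graph, p, small_stimulus, epoch=(-20, 50), dt=0.1,
                     seed=42)
        np.testing.assert_array_equal(a.states, b.states)
        c = simulate(small_graph, p, small_stimulus, epoch=(-20, 50), dt=0.1,
                     seed=43)
        assert np.abs(c.states - a.states).max() > 0


class TestPSPOracle:
    def test_isolated_impulse_matches_closed_form(self):
        """Closed-form damped-response oracle: with the intra-column
        feedback gain C1 = 0, the excitatory potential's response to a
        rectangular pulse is the difference of two critically damped step
        responses H tau m0 [1 - exp(-t/tau)(1 + t/tau)]."""
        graph = ConnectomeGraph(weights=np.zeros((1, 1)),
                                lengths=np.zeros((1, 1)), velocity=5.0)
        p = JRParams(C1=0.0, g=0.0)
        amp, dur, dt = 1.0, 1.0, 0.01
        stim = _pulse([1.0], amplitude=amp, duration=dur)
        ts = simulate(graph, p, stim, epoch=(0.0, 120.0), dt=dt,
                      initial_state="equilibrium")
        v1 = ts.v1[0] - ts.v1[0, 0]

        def step_response(t):
            t = np.maximum(t, 0.0)
            return p.H_e * p.tau_e * amp * (
                1.0 - np.exp(-t / p.tau_e) * (1.0 + t / p.tau_e))

        # forward Euler with piecewise-constant input delivers each input
        # sample over the following step; midpoint alignment (half a step)
        # removes that first-order phase offset from the comparison
        analytic = step_response(ts.time - dt / 2) \
            - step_response(ts.time - dt / 2 - dur)
        scale = np.abs(analytic).max()
        assert np.abs(v1 - analytic).max() / scale < 1e-3

    def test_impulse_peak_location_and_height(self):
        """A near-impulse of unit area reproduces the kernel peak H/e at
        t = tau."""
        graph = ConnectomeGraph(weights=np.zeros((1, 1)),
                                lengths=np.zeros((1, 1)), velocity=5.0)
        p = JRParams(C1=0.0, g=0.0)
        dt = 0.01
        stim = _pulse([1.0], amplitude=1.0 / dt, duration=dt)
        ts = simulate(graph, p, stim, epoch=(0.0, 80.0), dt=dt,
                      initial_state="equilibrium")
        v1 = ts.v1[0] - ts.v1[0, 0]
        assert ts.time[np.argmax(v1)] == pytest.approx(p.tau_e, abs=0.05)
        assert v1.max() == pytest.approx(p.H_e / np.e, rel=2e-3)


class TestDelayCausality:
    @pytest.mark.parametrize("delay", [5.0, 20.0, 50.0])
    def test_downstream_onset_matches_configured_delay(self, delay):
        dt = 0.1
        graph = _chain_graph(delay)
        p = JRParams(g=1e4)
        stim = _pulse([1.0, 0.0], amplitude=1.0)
        quiet = _pulse([1.0, 0.0], amplitude=0.0)
        a = simulate(graph, p, stim, epoch=(-20.0, 100.0), dt=dt,
                     initial_state="equilibrium")
        b = simulate(graph, p, quiet, epoch=(-20.0, 100.0), dt=dt,
                     initial_state="equilibrium")
        diff = np.abs(a.states - b.states).max(axis=0)  # (N, T)
        t_src = a.time[diff[0] > 1e-9][0]
        t_dst = a.time[diff[1] > 1e-9][0]
        measured_delay = t_dst - t_src
        assert abs(measured_delay - delay) <= dt + 1e-9
        # nothing downstream before the delay has elapsed
        pre = a.time < t_src + delay - 1e-9
        assert diff[1][pre].max() < 1e-9


class TestStimulusFromField:
    def test_direct_filter_example(self):
        stim = build_stimulus_from_field([1.0, 0.9, 0.5], 0.83)
        np.testing.assert_allclose(stim.region_weights, [1.0, 0.9, 0.0])

    def test_zero_threshold_keeps_all(self):
        stim = build_stimulus_from_field([0.2, 0.4], 0.0)
        np.testing.assert_allclose(stim.region_weights, [0.5, 1.0])

    def test_brute_force_threshold_oracle(self, rng):
        field = rng.random(200)
        stim = build_stimulus_from_field(field, 0.83)
        expected = np.array([f / field.max() if f >= 0.83 * field.max()
                             else 0.0 for f in field])
        np.testing.assert_allclose(stim.region_weights, expected)

    def test_all_zero_field_rejected(self):
        with pytest.raises(ParameterError):
            build_stimulus_from_field(np.zeros(5), 0.83)


class TestProjection:
    def test_identity_gain_returns_source_difference(self, small_graph,
                                                     small_stimulus):
        n = small_graph.n_regions
        ts = simulate(small_graph, JRParams(g=SMALL_NETWORK_G),
                      small_stimulus, epoch=(-20, 50), dt=0.1,
                      initial_state="equilibrium")
        lf = Leadfield(gain=np.eye(n))
        tep = project_to_channels(ts, lf)
        np.testing.assert_array_equal(tep.data, ts.v1 - ts.v2)

    def test_zero_gain(self, small_graph, small_stimulus):
        ts = simulate(small_graph, JRParams(g=SMALL_NETWORK_G),
                      small_stimulus, epoch=(-20, 50), dt=0.1,
                      initial_state="equilibrium")
        lf = Leadfield(gain=np.zeros((4, small_graph.n_regions)))
        assert (project_to_channels(ts, lf).data == 0).all()

    def test_random_gain_matmul_oracle(self, small_graph, small_stimulus,
                                       rng):
        ts = simulate(small_graph, JRParams(g=SMALL_NETWORK_G),
                      small_stimulus, epoch=(-20, 50), dt=0.1,
                      initial_state="equilibrium")
        g = rng.normal(size=(6, small_graph.n_regions))
        tep = project_to_channels(ts, Leadfield(gain=g))
        oracle = np.einsum("cr,rt->ct", g, ts.source_signal)
        np.testing.assert_allclose(tep.data, oracle, atol=1e-12)

    def test_observation_noise_seeded(self, small_graph, small_stimulus):
        ts = simulate(small_graph, JRParams(g=SMALL_NETWORK_G),
                      small_stimulus, epoch=(-20, 50), dt=0.1,
                      initial_state="equilibrium")
        lf = Leadfield(gain=np.eye(small_graph.n_regions), noise_sd=0.5)
        a = project_to_channels(ts, lf, seed=1)
        b = project_to_channels(ts, lf, seed=1)
        c = project_to_channels(ts, lf, seed=2)
        np.testing.assert_array_equal(a.data, b.data)
        assert np.abs(a.data - c.data).max() > 0

    def test_dimension_mismatch(self, small_graph, small_stimulus):
        ts = simulate(small_graph, JRParams(g=SMALL_NETWORK_G),
                      small_stimulus, epoch=(-20, 50), dt=0.1,
                      initial_state="equilibrium")
        with pytest.raises(ParameterError):
            project_to_channels(ts, Leadfield(gain=np.ones((3, 99))))


class TestIntegratorProperties:
    def test_halving_dt_changes_output_below_one_percent(
            self, small_graph, small_leadfield, small_stimulus):
        p = JRParams(g=SMALL_NETWORK_G)

        def run(dt):
            ts = simulate(small_graph, p, small_stimulus, dt=dt,
                          initial_state="equilibrium")
            return decimate_tep(project_to_channels(ts, small_leadfield),
                                1000.0).data

        y1, y2 = run(0.1), run(0.05)
        centered = y1 - y1.mean(axis=1, keepdims=True)
        assert np.sqrt(np.mean((y1 - y2) ** 2)) / centered.std() < 0.01

    def test_time_shift_equivariance_uncoupled(self, small_graph):
        p = JRParams(g=0.0)
        w = np.zeros(small_graph.n_regions)
        w[0] = 1.0
        dt = 0.1
        a = simulate(small_graph, p, _pulse(w, onset=0.0), epoch=(-20, 200),
                     dt=dt, initial_state="equilibrium")
        b = simulate(small_graph, p, _pulse(w, onset=30.0), epoch=(-20, 230),
                     dt=dt, initial_state="equilibrium")
        shift = int(round(30.0 / dt))
        np.testing.assert_allclose(b.states[:, :, shift:], a.states,
                                   atol=1e-12)

    def test_divergence_raises_integration_error(self, small_graph,
                                                 small_stimulus):
        # Euler is unstable when dt greatly exceeds the synaptic time
        # constants; the integrator must fail loudly with a time stamp
        bad = JRParams(tau_e=0.05, tau_i=0.05, g=0.0)
        with pytest.raises(IntegrationError) as err:
            with np.errstate(over="ignore", invalid="ignore"):
                simulate(small_graph, bad, small_stimulus, epoch=(-20, 300),
                         dt=1.0, seed=0)
        assert err.value.time_ms is not None

    def test_dt_larger_than_min_delay_warns(self, small_stimulus):
        graph = _chain_graph(0.5)
        stim = _pulse([1.0, 0.0])
        with pytest.warns(UserWarning, match="smallest positive delay"):
            simulate(graph, JRParams(g=0.0), stim, epoch=(0, 10), dt=1.0,
                     seed=0)


class TestDecimate:
    def test_factor_one_is_identity(self, small_graph, small_leadfield,
                                    small_stimulus):
        ts = simulate(small_graph, JRParams(g=SMALL_NETWORK_G),
                      small_stimulus, epoch=(-20, 50), dt=1.0,
                      initial_state="equilibrium")
        tep = project_to_channels(ts, small_leadfield)
        assert decimate_tep(tep, 1000.0) is tep

    def test_non_integer_factor_rejected(self, small_graph, small_leadfield,
                                         small_stimulus):
        ts = simulate(small_graph, JRParams(g=SMALL_NETWORK_G),
                      small_stimulus, epoch=(-20, 50), dt=0.1,
                      initial_state="equilibrium")
        tep = project_to_channels(ts, small_leadfield)
        with pytest.raises(ParameterError):
            decimate_tep(tep, 3333.0)
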