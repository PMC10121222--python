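"""Forward simulation of the delay-coupled Jansen-Rit network.

Fixed-step Euler integration (default dt = 0.1 ms) with per-connection
conduction delays served from a ring-buffer history of the excitatory
derivative state x1.  A burn-in interval (default 20 ms) is simulated and
discarded so that transients from the random initial conditions settle
before the recorded epoch, which by convention runs from -100 ms (baseline)
to +300 ms around the stimulus at t = 0.

Channel-space signals are obtained by projecting the per-region source
signal r(t) = v1(t) - v2(t) (excitatory minus inhibitory interneuron
potentials, differenced for their opposite polarities) through a leadfield
gain matrix: Y = G X + eps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectome import ConnectomeGraph
from .errors import IntegrationError, ParameterError
from .neural_mass import (
    JRParams, N_STATE_VARS, V1, V2, V3, X1, jr_derivatives, sigmoid,
)

logger = logging.getLogger(__name__)

DIVERGENCE_LIMIT = 1e6  # |state| beyond this aborts integration


@dataclass
class StimulusSpec:
    """Per-region stimulus injection (the perturbation p).

    ``region_weights`` are in [0, 1]; the rectangular pulse of the given
    amplitude is applied to region j scaled by ``region_weights[j]`` for
    ``onset <= t < onset + duration`` (ms, epoch convention t=0 at pulse).
    """

    region_weights: np.ndarray
    onset: float = 0.0
    duration: float = 1.0
    amplitude: float = 1.0

    def __post_init__(self):
        self.region_weights = np.asarray(self.region_weights, dtype=float)
        if (self.region_weights < 0).any():
            raise ParameterError("stimulus weights must be non-negative")
        if self.duration < 0:
            raise ParameterError("stimulus duration must be >= 0")


@dataclass
class Leadfield:
    """Linear gain from region sources to EEG channels, plus sensor noise."""

    gain: np.ndarray
    channel_labels: list[str] = field(default=None)  # type: ignore[assignment]
    noise_sd: float = 0.0

    def __post_init__(self):
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2 or self.gain.shape[0] < 1:
            raise ParameterError("leadfield gain must be a 2-D matrix with "
                                 ">= 1 channel row")
        if not np.isfinite(self.gain).all():
            raise ParameterError("leadfield gain has non-finite entries")
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i:02d}"
                                   for i in range(self.gain.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]


@dataclass
class RegionTimeSeries:
    """Region-space state trajectories on a uniform time grid."""

    time: np.ndarray        # (T,) ms
    states: np.ndarray      # (6, N, T)
    dt: float

    @property
    def n_regions(self) -> int:
        return self.states.shape[1]

    @property
    def v1(self) -> np.ndarray:
        return self.states[V1]

    @property
    def v2(self) -> np.ndarray:
        return self.states[V2]

    @property
    def v3(self) -> np.ndarray:
        """Pyramidal-cell membrane potential (N, T)."""
        return self.states[V3]

    @property
    def source_signal(self) -> np.ndarray:
        """EEG source signal r(t) = v1 - v2 per region, (N, T)."""
        return self.states[V1] - self.states[V2]


@dataclass
class TEPData:
    """Channel-space evoked epochs (trial-averaged TEP-like data)."""

    data: np.ndarray        # (channels, T)
    time: np.ndarray        # (T,) ms
    sfreq: float            # Hz
    channel_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.data.shape[1] != self.time.shape[0]:
            raise ParameterError(
                f"data has {self.data.shape[1]} samples but time axis has "
                f"{self.time.shape[0]}")
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i:02d}"
                                   for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


def build_stimulus_from_field(field_map, threshold_fraction: float = 0.83,
                              onset: float = 0.0, duration: float = 1.0,
                              amplitude: float = 1.0) -> StimulusSpec:
    """Stimulus weights from a per-region electric-field magnitude map.

    Regions below ``threshold_fraction`` of the field maximum get weight
    exactly 0 (tissue below the activation threshold); surviving regions are
    weighted by field strength normalised to the maximum.
    """
    f = np.asarray(field_map, dtype=float)
    if (f < 0).any():
        raise ParameterError("field map must be non-negative")
    fmax = f.max(initial=0.0)
    if fmax <= 0:
        raise ParameterError("field map is all zero; no region to stimulate")
    weights = np.where(f >= threshold_fraction * fmax, f / fmax, 0.0)
    return StimulusSpec(region_weights=weights, onset=onset,
                        duration=duration, amplitude=amplitude)


class NetworkSimulator:
    """Stateful fixed-step integrator with snapshot/restore support.

    The fitting loop integrates the epoch in short windows, carrying the
    full dynamical state (including the delay history buffer) across
    windows; ``snapshot``/``restore`` expose that state for gradient
    evaluations that must re-run a window from the same starting point.
    """

    def __init__(self, graph: ConnectomeGraph, params: JRParams,
                 stim: StimulusSpec, dt: float = 0.1, lesion=None,
                 coupling: np.ndarray | None = None):
        if dt <= 0:
            raise ParameterError(f"dt must be > 0, got {dt}")
        self.graph = graph
        self.params = params
        self.stim = stim
        self.dt = float(dt)
        self.n = graph.n_regions
        if stim.region_weights.shape[0] != self.n:
            raise ParameterError(
                f"stimulus has {stim.region_weights.shape[0]} weights for a "
                f"{self.n}-region network")
        base = graph.coupling if coupling is None else np.asarray(coupling)
        self._set_coupling(base)
        self.lesion_window = None      # (onset, offset) in ms
        self._w_lesioned = None
        if lesion is not None:
            self.set_lesion(lesion)
        # integration state
        self.state = np.zeros((N_STATE_VARS, self.n))
        self._hist = None
        self._ptr = 0
        self.t = 0.0

    # -- coupling / delays ------------------------------------------------
    def _set_coupling(self, coupling: np.ndarray) -> None:
        """Precompute the sparse delayed-coupling gather tables."""
        a = np.array(coupling, dtype=float)
        np.fill_diagonal(a, 0.0)   # network input sums over k != j
        dsteps = np.rint(self.graph.delays / self.dt).astype(np.int64)
        positive = self.graph.delays > 0
        if positive.any() and self.dt > self.graph.delays[positive].min():
            warnings.warn(
                f"dt={self.dt} ms exceeds the smallest positive delay "
                f"({self.graph.delays[positive].min():.3g} ms); delays "
                "rounded up to one integration step", stacklevel=2)
        dsteps[positive] = np.maximum(dsteps[positive], 1)
        rows, cols = np.nonzero(a)
        self._rows = rows
        self._cols = cols
        self._wvec = a[rows, cols]
        self._dvec = dsteps[rows, cols]
        self._histlen = int(self._dvec.max(initial=0)) + 1
        self._coupling_dense = a

    def set_params(self, params: JRParams) -> None:
        self.params = params

    def set_lesion(self, lesion) -> None:
        """Install a virtual lesion: a (mask, onset, offset) on couplings."""
        from .lesion import LesionSpec, lesioned_coupling  # local: avoid cycle
        if not isinstance(lesion, LesionSpec):
            raise ParameterError("lesion must be a LesionSpec")
        lesioned = lesioned_coupling(self._coupling_dense, lesion, self.n)
        self._w_lesioned = lesioned[self._rows, self._cols]
        offset = lesion.offset if lesion.offset is not None else np.inf
        self.lesion_window = (lesion.onset, offset)

    # -- state management -------------------------------------------------
    def reset(self, seed=None, t_start: float = 0.0,
              initial_state=None) -> None:
        """Initialise the state and delay history at ``t_start``.

        ``initial_state`` may be an explicit (6, N) array, the string
        ``"equilibrium"`` (deterministic start at the resting fixed point),
        or None for random initial conditions (v ~ U[0, 0.2] mV,
        derivatives 0, seeded).  The delay history is initialised by
        holding the initial drive state constant for all lags.
        """
        if isinstance(initial_state, str):
            if initial_state != "equilibrium":
                raise ParameterError(
                    f"unknown initial_state mode {initial_state!r}")
            from .neural_mass import equilibrium_state
            self.state = equilibrium_state(self.params, self.n)
        elif initial_state is not None:
            self.state = np.array(initial_state, dtype=float)
        else:
            rng = np.random.default_rng(seed)
            self.state = np.zeros((N_STATE_VARS, self.n))
            self.state[[V1, V2, V3]] = rng.uniform(0.0, 0.2, size=(3, self.n))
        self._hist = np.tile(self._drive_source(), (self._histlen, 1))
        self._ptr = 0
        self.t = float(t_start)

    def _drive_source(self) -> np.ndarray:
        row = X1 if self.params.drive_state == "x1" else V1
        return self.state[row].copy()

    def snapshot(self) -> dict:
        return {"state": self.state.copy(), "hist": self._hist.copy(),
                "ptr": self._ptr, "t": self.t}

    def restore(self, snap: dict) -> None:
        self.state = snap["state"].copy()
        self._hist = snap["hist"].copy()
        self._ptr = snap["ptr"]
        self.t = snap["t"]

    # -- integration ------------------------------------------------------
    def run(self, t_until: float, record: bool = False):
        """Integrate forward to ``t_until`` (exclusive of the end point).

        With ``record=True`` returns a :class:`RegionTimeSeries` holding the
        state at every step time in ``[self.t, t_until)``.
        """
        if self._hist is None:
            raise IntegrationError("simulator not initialised; call reset()")
        n_steps = int(round((t_until - self.t) / self.dt))
        if n_steps < 0:
            raise ParameterError("t_until precedes current simulator time")
        out = np.empty((N_STATE_VARS, self.n, n_steps)) if record else None
        times = self.t + self.dt * np.arange(n_steps)

        p = self.params
        stim_w = self.stim.region_weights * self.stim.amplitude
        s_on, s_off = self.stim.onset, self.stim.onset + self.stim.duration
        drive_row = X1 if p.drive_state == "x1" else V1
        half_dt = 0.5 * self.dt

        for i in range(n_steps):
            t = times[i]
            if record:
                out[:, :, i] = self.state
            wvec = self._wvec
            if (self._w_lesioned is not None
                    and self.lesion_window[0] <= t < self.lesion_window[1]):
                wvec = self._w_lesioned
            # delayed network input
            if self._rows.size:
                idx = (self._ptr - self._dvec) % self._histlen
                delayed = self._hist[idx, self._cols]
                summed = np.bincount(self._rows, weights=wvec * delayed,
                                     minlength=self.n)
            else:
                summed = np.zeros(self.n)
            drive = sigmoid(p.g * summed, p.e0, p.r, p.v0)
            stim_t = stim_w if (s_on - half_dt <= t < s_off - half_dt) else 0.0
            deriv = jr_derivatives(self.state, p, drive, stim_t)
            self.state = self.state + self.dt * deriv
            self._ptr = (self._ptr + 1) % self._histlen
            self._hist[self._ptr] = self.state[drive_row]
            if i % 50 == 0 or i == n_steps - 1:
                m = np.abs(self.state).max()
                if not np.isfinite(m) or m > DIVERGENCE_LIMIT:
                    reg = int(np.abs(self.state).max(axis=0).argmax())
                    raise IntegrationError(
                        f"state divergence (|state| = {m:.3g}) at "
                        f"t = {t:.2f} ms, region {reg}",
                        time_ms=float(t), region=reg)
        self.t = float(t_until)
        if record:
            return RegionTimeSeries(time=times, states=out, dt=self.dt)
        return None


def simulate(graph: ConnectomeGraph, params: JRParams, stim: StimulusSpec,
             epoch: tuple[float, float] = (-100.0, 300.0), dt: float = 0.1,
             burn_in: float = 20.0, seed=None, lesion=None,
             initial_state=None) -> RegionTimeSeries:
    """Simulate one evoked epoch and return the region-space trajectories.

    The burn-in interval ``[epoch[0] - burn_in, epoch[0])`` is integrated
    and discarded.  Deterministic given ``seed`` (the only randomness is in
    the initial conditions); ``initial_state="equilibrium"`` starts at the
    resting fixed point instead, making the run deterministic outright.

    Raises
    ------
    IntegrationError
        If any state magnitude exceeds ``1e6`` (divergence).
    """
    t0, t1 = epoch
    if t1 <= t0:
        raise ParameterError(f"epoch end {t1} must exceed start {t0}")
    sim = NetworkSimulator(graph, params, stim, dt=dt, lesion=lesion)
    sim.reset(seed=seed, t_start=t0 - burn_in, initial_state=initial_state)
    if burn_in > 0:
        sim.run(t0, record=False)
    return sim.run(t1, record=True)


def project_to_channels(region_ts: RegionTimeSeries, lf: Leadfield,
                        seed=None) -> TEPData:
    """Project region sources to channels: ``Y = G (v1 - v2) + eps``.

    Observation noise is i.i.d. Gaussian with sd ``lf.noise_sd``;
    ``noise_sd = 0`` gives deterministic output.
    """
    x = region_ts.source_signal
    if lf.gain.shape[1] != x.shape[0]:
        raise ParameterError(
            f"leadfield expects {lf.gain.shape[1]} regions, trajectory has "
            f"{x.shape[0]}")
    y = lf.gain @ x
    if lf.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, lf.noise_sd, size=y.shape)
    sfreq = 1000.0 / region_ts.dt
    return TEPData(data=y, time=region_ts.time.copy(), sfreq=sfreq,
                   channel_labels=list(lf.channel_labels))


def decimate_tep(tep: TEPData, target_sfreq: float,
                 alias_tol: float = 0.01) -> TEPData:
    """Downsample channel data to ``target_sfreq`` by decimation.

    The integrator output is smooth (synaptic low-pass with tau >= a few
    ms), so plain decimation is normally safe; a spectral check warns if
    more than ``alias_tol`` of the signal power lies above the new Nyquist
    frequency.
    """
    factor = int(round(tep.sfreq / target_sfreq))
    if factor < 1 or abs(tep.sfreq / factor - target_sfreq) > 1e-6 * target_sfreq:
        raise ParameterError(
            f"target sfreq {target_sfreq} is not an integer decimation of "
            f"{tep.sfreq}")
    if factor == 1:
        return tep
    spec = np.abs(np.fft.rfft(tep.data, axis=1)) ** 2
    freqs = np.fft.rfftfreq(tep.data.shape[1], d=1.0 / tep.sfreq)
    total = spec.sum()
    if total > 0:
        above = spec[:, freqs > target_sfreq / 2.0].sum() / total
        if above > alias_tol:
            warnings.warn(
                f"{100 * above:.1f}% of signal power above the target "
                "Nyquist; decimated output may alias", stacklevel=2)
    return TEPData(data=tep.data[:, ::factor], time=tep.time[::factor],
                   sfreq=target_sfreq, channel_labels=list(tep.channel_labels))
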