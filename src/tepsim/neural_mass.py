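"""Jansen-Rit neural mass dynamics of a single cortical region.

Each region contains three coupled populations — pyramidal projection
neurons, excitatory interneurons, and inhibitory interneurons.  Synaptic
filtering is a critically damped second-order operator

    v'' + (2/tau) v' + v/tau^2 = (H/tau) m(t)

whose impulse response is the alpha-function kernel ``(H/tau) t exp(-t/tau)``
(peak ``H/e`` at ``t = tau``).  Population output is the sigmoidal
wave-to-pulse operator ``S(v) = e0 / (1 + exp(r (v0 - v)))``.

All time quantities are in ms; potentials in mV; firing rates (and the
rate-like drive terms ``p`` and ``conn``) in ms^-1.  In the form used here
``e0`` is the ceiling of the sigmoid, i.e. the maximum population firing
rate (5 s^-1 = 0.005 ms^-1 in the classic parameter set, where the
half-maximum rate is 2.5 s^-1); with that convention the steady states
land on the familiar literature magnitudes.

State layout per region (used package-wide): ``(v1, v2, v3, x1, x2, x3)``
where 1 = excitatory interneurons, 2 = inhibitory interneurons,
3 = pyramidal cells, and ``x = dv/dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.special import expit

from .errors import ParameterError

# state-row indices
V1, V2, V3, X1, X2, X3 = range(6)
N_STATE_VARS = 6


@dataclass
class JRParams:
    """Jansen-Rit population constants plus network-level gain.

    Defaults are the canonical literature values (Jansen & Rit 1995
    lineage): ``H_e=3.25`` mV, ``H_i=22`` mV, ``tau_e=10`` ms,
    ``tau_i=20`` ms, intra-columnar gains ``C1..C4 = 135*(1, 0.8, 0.25,
    0.25)``, sigmoid ``r=0.56`` /mV, ``v0=6`` mV, and ``e0=0.005`` ms^-1
    (the sigmoid ceiling; the literature's 5 s^-1 maximum population rate
    in this package's ms-based units).

    ``g`` is the global gain applied inside the network-input sigmoid;
    ``p_baseline`` is a tonic drive (default 0, so the unstimulated system
    is quiescent).

    ``printed_eq6`` switches the excitatory-interneuron equation to the
    variant where the intra-columnar pyramidal feedback term ``C1 S(C2 v3)``
    sits outside the synaptic gain ``H_e/tau_e``; the default keeps it
    inside, which is the dimensionally consistent standard form.
    ``drive_state`` selects which delayed state the network input reads
    (``"x1"`` default; ``"v1"`` available for sensitivity analysis).
    """

    H_e: float = 3.25
    H_i: float = 22.0
    tau_e: float = 10.0
    tau_i: float = 20.0
    C1: float = 135.0
    C2: float = 108.0
    C3: float = 33.75
    C4: float = 33.75
    e0: float = 0.005
    r: float = 0.56
    v0: float = 6.0
    g: float = 1.0
    p_baseline: float = 0.0
    printed_eq6: bool = False
    drive_state: str = "x1"

    def __post_init__(self):
        for name in ("H_e", "H_i", "tau_e", "tau_i", "e0", "r"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive, "
                                     f"got {getattr(self, name)}")
        for name in ("C1", "C2", "C3", "C4", "g"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative, "
                                     f"got {getattr(self, name)}")
        if self.drive_state not in ("x1", "v1"):
            raise ParameterError("drive_state must be 'x1' or 'v1'")

    def replace(self, **kwargs) -> "JRParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "JRParams":
        return cls(**d)


def sigmoid(v, e0: float, r: float, v0: float):
    """Wave-to-pulse operator ``S(v) = e0 / (1 + exp(r (v0 - v)))``.

    Overflow-safe for arbitrarily large ``|v|``; strictly increasing and
    bounded in ``(0, e0)``.
    """
    return e0 * expit(r * (np.asarray(v, dtype=float) - v0))


def psp_kernel(t, H: float, tau: float):
    """Synaptic impulse response ``(H/tau) t exp(-t/tau)`` for ``t >= 0``.

    This is the Green's function of the second-order synaptic operator:
    critically damped, zero at ``t=0``, maximum ``H/e`` at ``t = tau``.
    """
    if H <= 0 or tau <= 0:
        raise ParameterError("psp_kernel requires H > 0 and tau > 0")
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ParameterError("psp_kernel is defined for t >= 0")
    return (H / tau) * t * np.exp(-t / tau)


def equilibrium_state(params: JRParams, n_regions: int = 1) -> np.ndarray:
    """Resting fixed point of the coupled network, shape (6, N).

    At any equilibrium all derivative states are zero, so every delayed
    network input is ``S(0)`` regardless of the coupling: the network fixed
    point equals the isolated-node fixed point, found by solving the scalar
    self-consistency equation for the pyramidal potential v3.  If the
    parameters admit several equilibria the lowest (resting) one is
    returned.
    """
    from scipy.optimize import brentq

    p = params
    conn0 = float(sigmoid(0.0, p.e0, p.r, p.v0))

    def v1_of(v3):
        fb = p.C1 * sigmoid(p.C2 * v3, p.e0, p.r, p.v0)
        return p.H_e * p.tau_e * (p.p_baseline + conn0 + fb)

    def v2_of(v3):
        return p.H_i * p.tau_i * p.C4 * sigmoid(p.C3 * v3, p.e0, p.r, p.v0)

    def f(v3):
        return p.H_e * p.tau_e * sigmoid(v1_of(v3) - v2_of(v3),
                                         p.e0, p.r, p.v0) - v3

    v3_max = p.H_e * p.tau_e * p.e0
    grid = np.linspace(0.0, v3_max * (1 + 1e-9), 2001)
    vals = np.array([f(v) for v in grid])
    sign_change = np.flatnonzero(np.diff(np.sign(vals)) != 0)
    if sign_change.size == 0:
        raise ParameterError("no resting equilibrium found for these "
                             "parameters")
    i = sign_change[0]
    v3_star = brentq(f, grid[i], grid[i + 1], xtol=1e-15)
    state = np.zeros((N_STATE_VARS, n_regions))
    state[V1] = v1_of(v3_star)
    state[V2] = v2_of(v3_star)
    state[V3] = v3_star
    return state


def network_drive(delayed_states, coupling_row, e0: float, r: float,
                  v0: float, g: float):
    """Network input to one region: sigmoid of the gained, delayed sum.

    ``conn_j = S( g * sum_k a_jk x1_k(t - m_jk) )`` where ``delayed_states``
    holds the appropriately lagged source state per connection.
    """
    delayed_states = np.asarray(delayed_states, dtype=float)
    coupling_row = np.asarray(coupling_row, dtype=float)
    if delayed_states.shape != coupling_row.shape:
        from .errors import HistoryUnderflowError
        raise HistoryUnderflowError(
            f"need one delayed state per coupling entry: got "
            f"{delayed_states.shape} states for {coupling_row.shape} couplings")
    return sigmoid(g * float(coupling_row @ delayed_states), e0, r, v0)


def jr_derivatives(state: np.ndarray, params: JRParams, drive,
                   stim) -> np.ndarray:
    """Time derivative of the six-variable Jansen-Rit state, vectorised.

    Parameters
    ----------
    state : (6, N) or (6,) ndarray
        Rows ``(v1, v2, v3, x1, x2, x3)``.
    drive : scalar or (N,) array
        Network input ``conn_j`` (already passed through the sigmoid).
    stim : scalar or (N,) array
        Perturbing voltage offset ``p`` applied to the excitatory
        interneuron population (the TMS term).

    Returns
    -------
    ndarray of the same shape as ``state``.
    """
    state = np.asarray(state, dtype=float)
    v1, v2, v3 = state[V1], state[V2], state[V3]
    x1, x2, x3 = state[X1], state[X2], state[X3]
    p = params
    ge = p.H_e / p.tau_e
    gi = p.H_i / p.tau_i
    total_p = np.asarray(stim, dtype=float) + p.p_baseline

    pyr_feedback = p.C1 * sigmoid(p.C2 * v3, p.e0, p.r, p.v0)
    if p.printed_eq6:
        dx1 = ge * (total_p + drive) + pyr_feedback \
            - (2.0 / p.tau_e) * x1 - v1 / p.tau_e**2
    else:
        dx1 = ge * (total_p + drive + pyr_feedback) \
            - (2.0 / p.tau_e) * x1 - v1 / p.tau_e**2
    dx2 = gi * (p.C4 * sigmoid(p.C3 * v3, p.e0, p.r, p.v0)) \
        - (2.0 / p.tau_i) * x2 - v2 / p.tau_i**2
    dx3 = ge * sigmoid(v1 - v2, p.e0, p.r, p.v0) \
        - (2.0 / p.tau_e) * x3 - v3 / p.tau_e**2

    out = np.empty_like(state)
    out[V1], out[V2], out[V3] = x1, x2, x3
    out[X1], out[X2], out[X3] = dx1, dx2, dx3
    return out
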