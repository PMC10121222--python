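"""Virtual-lesion experiments: time-windowed disconnection of hub nodes.

To dissect how much of a late evoked component reflects re-entrant network
activity (rather than purely local dynamics at the stimulated site), the
most strongly activated nodes are identified from a fitted simulation and
their incoming/outgoing connection weights are set to zero from a chosen
time after the pulse.  Comparing the lesioned and intact simulations —
identical seeds and initial conditions — isolates the recurrent
contribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .connectome import ConnectomeGraph
from .errors import ParameterError
from .neural_mass import JRParams
from .simulator import (
    Leadfield, RegionTimeSeries, StimulusSpec, TEPData, project_to_channels,
    simulate,
)

logger = logging.getLogger(__name__)


@dataclass
class LesionSpec:
    """Disconnection of ``node_ids`` during ``[onset, offset)`` ms.

    ``offset=None`` means the lesion persists to the end of the epoch (the
    default, matching a permanent post-pulse disconnection).  ``mode``
    selects which connections are severed: incoming rows, outgoing columns,
    or both.
    """

    node_ids: tuple[int, ...]
    onset: float
    offset: float | None = None
    mode: str = "both"

    def __post_init__(self):
        self.node_ids = tuple(int(i) for i in self.node_ids)
        if not self.node_ids:
            raise ParameterError("lesion node_ids must be non-empty")
        if self.mode not in ("in", "out", "both"):
            raise ParameterError("lesion mode must be 'in', 'out' or 'both'")
        if self.offset is not None and self.onset > self.offset:
            raise ParameterError(
                f"lesion onset {self.onset} must precede offset {self.offset}")


def lesioned_coupling(coupling: np.ndarray, lesion: LesionSpec,
                      n_regions: int) -> np.ndarray:
    """Coupling matrix with the lesioned rows/columns zeroed."""
    ids = np.asarray(lesion.node_ids)
    if (ids < 0).any() or (ids >= n_regions).any():
        raise ParameterError(
            f"lesion node ids {lesion.node_ids} out of range for "
            f"{n_regions} regions")
    out = np.array(coupling, dtype=float)
    if lesion.mode in ("in", "both"):
        out[ids, :] = 0.0
    if lesion.mode in ("out", "both"):
        out[:, ids] = 0.0
    return out


class TimeVaryingCoupling:
    """Accessor returning the effective coupling matrix at time t (ms)."""

    def __init__(self, graph: ConnectomeGraph, lesion: LesionSpec):
        self.base = graph.coupling.copy()
        self.lesioned = lesioned_coupling(self.base, lesion, graph.n_regions)
        self.onset = lesion.onset
        self.offset = math.inf if lesion.offset is None else lesion.offset

    def at(self, t: float) -> np.ndarray:
        if self.onset <= t < self.offset:
            return self.lesioned
        return self.base


def apply_lesion(graph: ConnectomeGraph, lesion: LesionSpec) -> TimeVaryingCoupling:
    """Build the time-dependent coupling accessor; the graph is unmodified."""
    return TimeVaryingCoupling(graph, lesion)


def find_max_activated_nodes(region_ts: RegionTimeSeries,
                             window: tuple[float, float],
                             top_fraction: float = 0.01,
                             sd_threshold: float = 2.0) -> np.ndarray:
    """Maximally activated nodes by integrated |pyramidal activity|.

    Per-node score = sum over the window of |v3(t)|.  Candidates must
    exceed ``mean + sd_threshold * sd`` of the scores across nodes; of
    those, the top ``ceil(top_fraction * N)`` by score are returned (fewer
    if fewer qualify, possibly none).
    """
    t_a, t_b = window
    mask = (region_ts.time >= t_a) & (region_ts.time < t_b)
    if not mask.any():
        raise ParameterError(
            f"window [{t_a}, {t_b}) ms contains no samples of the epoch")
    scores = np.abs(region_ts.v3[:, mask]).sum(axis=1)
    cutoff = scores.mean() + sd_threshold * scores.std()
    candidates = np.flatnonzero(scores > cutoff)
    k = math.ceil(top_fraction * region_ts.n_regions)
    if candidates.size < k:
        logger.info("only %d node(s) exceed the %.1f-sd screen (top-%d "
                    "requested)", candidates.size, sd_threshold, k)
    order = candidates[np.argsort(scores[candidates])[::-1]]
    return order[:k] if candidates.size >= k else order


def lmfp(tep: TEPData, channel_subset, baseline_correct: bool = False,
         baseline_window: tuple[float, float] | None = None) -> np.ndarray:
    """Local mean field power: RMS over a local electrode cluster.

    ``LMFP(t) = sqrt(mean_i y_i(t)^2)`` over the selected channels.  With
    ``baseline_correct`` the mean pre-stimulus LMFP over
    ``baseline_window`` (default: all t < 0) is subtracted.
    """
    subset = list(channel_subset)
    if not subset:
        raise ParameterError("channel subset must be non-empty")
    if all(isinstance(c, str) for c in subset):
        missing = [c for c in subset if c not in tep.channel_labels]
        if missing:
            raise ParameterError(f"unknown channel label(s): {missing}")
        idx = [tep.channel_labels.index(c) for c in subset]
    else:
        idx = [int(c) for c in subset]
        if any(i < 0 or i >= tep.n_channels for i in idx):
            raise ParameterError(f"channel index out of range: {idx}")
    power = np.sqrt(np.mean(tep.data[idx] ** 2, axis=0))
    if baseline_correct:
        if baseline_window is None:
            bmask = tep.time < 0
        else:
            bmask = (tep.time >= baseline_window[0]) & \
                (tep.time < baseline_window[1])
        if not bmask.any():
            raise ParameterError("baseline window contains no samples")
        power = power - power[bmask].mean()
    return power


def lesion_experiment(fitted, graph: ConnectomeGraph, stim: StimulusSpec,
                      lf: Leadfield, lesion_times,
                      epoch: tuple[float, float] = (-100.0, 300.0),
                      dt: float = 0.1, burn_in: float = 20.0, seed: int = 0,
                      selection_window_start: float = 0.0,
                      mode: str = "both",
                      initial_state="equilibrium") -> dict:
    """Run the lesion protocol: control plus one condition per lesion time.

    ``fitted`` is either a :class:`~tepsim.neural_mass.JRParams` or an
    object with a ``posterior_params`` attribute (a fit result).  For each
    lesion time the maximally activated nodes are selected from the control
    simulation over ``[selection_window_start, lesion_time)`` and their
    connections severed from ``lesion_time`` to the end of the epoch.  All
    conditions share the control's seed and initial conditions.

    Returns a dict mapping condition name (``"control"`` or ``"lesion_<t>"``)
    to ``{"region_ts", "tep", "lesion"}``.
    """
    params = fitted if isinstance(fitted, JRParams) else fitted.posterior_params
    control_ts = simulate(graph, params, stim, epoch=epoch, dt=dt,
                          burn_in=burn_in, seed=seed,
                          initial_state=initial_state)
    results = {"control": {
        "region_ts": control_ts,
        "tep": project_to_channels(control_ts, lf, seed=seed),
        "lesion": None,
    }}
    for t_les in lesion_times:
        sel_end = min(t_les, epoch[1])
        if sel_end <= selection_window_start:
            nodes = np.array([], dtype=int)
        else:
            nodes = find_max_activated_nodes(
                control_ts, (selection_window_start, sel_end))
        name = f"lesion_{t_les:g}ms"
        if nodes.size == 0 or t_les >= epoch[1]:
            # nothing to sever (or lesion starts after the epoch): condition
            # is dynamically identical to control
            logger.info("condition %s: no effective lesion", name)
            ts = simulate(graph, params, stim, epoch=epoch, dt=dt,
                          burn_in=burn_in, seed=seed,
                          initial_state=initial_state)
            spec = None
        else:
            spec = LesionSpec(node_ids=tuple(nodes), onset=t_les, mode=mode)
            ts = simulate(graph, params, stim, epoch=epoch, dt=dt,
                          burn_in=burn_in, seed=seed, lesion=spec,
                          initial_state=initial_state)
        results[name] = {
            "region_ts": ts,
            "tep": project_to_channels(ts, lf, seed=seed),
            "lesion": spec,
        }
    return results
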