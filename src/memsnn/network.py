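"""Leaky integrate-and-fire output layer with winner-take-all inhibition.

Each output (excitatory) neuron integrates weighted input spikes with an
exponentially leaking membrane potential

    tau * dU_j/dt = -U_j + sum_i w_ji * n_i(t)

discretised per 1-ms bin with the exact decay factor ``exp(-dt/tau)``.  When
a neuron crosses its (adaptive) threshold it fires, resets to rest, and is
refractory for ``t_ref`` ms, ignoring all input.  Every excitatory neuron
drives its own inhibitory partner, which projects back to all excitatory
neurons except its source; the partner is modeled as an instantaneous relay
that resets the losers to rest and holds them there for ``t_inhibit`` ms.
This realises the winner-take-all competition that forces different neurons
to specialise on different input features.

When two neurons cross threshold in the same bin, the one with the largest
supra-threshold margin wins (ties to the lowest index), so at most one
neuron fires per bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .device import SynapseArray
from .encoding import SpikeRaster
from .errors import ShapeError

__all__ = ["LIFParams", "NeuronState", "Topology", "step", "lateral_inhibit", "run_sample"]

#: Relative threshold floor applied by homeostasis (fraction of the initial
#: threshold); prevents sign flips under aggressive adaptation.
THRESHOLD_FLOOR_FRACTION = 1e-6


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire neuron constants (times in ms)."""

    tau: float = 100.0
    v_rest: float = 0.0
    threshold_init: float = 24.0
    t_ref: float = 5.0
    t_inhibit: float = 10.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.t_ref < 0 or self.t_inhibit < 0:
            raise ValueError("refractory and inhibition durations must be >= 0")
        if self.threshold_init <= self.v_rest:
            raise ValueError("threshold_init must exceed v_rest")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def decay(self) -> float:
        return math.exp(-self.dt / self.tau)


@dataclass(frozen=True)
class Topology:
    """Layer sizes and the winner-take-all inhibition wiring."""

    n_inputs: int = 576
    n_exc: int = 300

    def inhibition_matrix(self) -> np.ndarray:
        """Effective inhibitory connectivity: all-to-all minus self (zero diagonal)."""
        return np.ones((self.n_exc, self.n_exc)) - np.eye(self.n_exc)


@dataclass
class NeuronState:
    """Mutable per-neuron state of the output layer."""

    U: np.ndarray
    threshold: np.ndarray
    ref_timer: np.ndarray
    inh_timer: np.ndarray
    fire_count_window: np.ndarray
    fire_count_total: np.ndarray
    threshold_floor: float

    @classmethod
    def initial(cls, n_exc: int, params: LIFParams) -> "NeuronState":
        return cls(
            U=np.full(n_exc, params.v_rest, dtype=float),
            threshold=np.full(n_exc, params.threshold_init, dtype=float),
            ref_timer=np.zeros(n_exc),
            inh_timer=np.zeros(n_exc),
            fire_count_window=np.zeros(n_exc, dtype=np.int64),
            fire_count_total=np.zeros(n_exc, dtype=np.int64),
            threshold_floor=THRESHOLD_FLOOR_FRACTION * params.threshold_init,
        )

    @property
    def n_exc(self) -> int:
        return self.U.shape[0]

    def reset_sample(self, params: LIFParams) -> None:
        """Clear membrane potentials and timers between sample presentations.

        Thresholds and firing counters persist across samples.
        """
        self.U[:] = params.v_rest
        self.ref_timer[:] = 0.0
        self.inh_timer[:] = 0.0

    def copy(self) -> "NeuronState":
        return NeuronState(
            U=self.U.copy(),
            threshold=self.threshold.copy(),
            ref_timer=self.ref_timer.copy(),
            inh_timer=self.inh_timer.copy(),
            fire_count_window=self.fire_count_window.copy(),
            fire_count_total=self.fire_count_total.copy(),
            threshold_floor=self.threshold_floor,
        )


def step(
    state: NeuronState,
    input_spikes: np.ndarray,
    weights: SynapseArray,
    params: LIFParams,
) -> list[int]:
    """Advance the layer by one clock bin; return the firing neuron (if any).

    Non-refractory, non-inhibited neurons decay and integrate the weighted
    input; refractory or inhibited neurons ignore input entirely.  Among the
    neurons at or above threshold a single winner fires (largest margin,
    ties to the lowest index): it resets to rest, enters refractoriness and
    its counters increment.  Timers advance by ``dt`` at the end of the bin.
    """
    input_spikes = np.asarray(input_spikes)
    if input_spikes.shape[0] != weights.n_inputs:
        raise ShapeError(
            f"input vector length {input_spikes.shape[0]} != n_inputs {weights.n_inputs}"
        )
    if weights.n_outputs != state.n_exc:
        raise ShapeError(
            f"weights have {weights.n_outputs} outputs but state has {state.n_exc}"
        )
    responsive = (state.ref_timer <= 0.0) & (state.inh_timer <= 0.0)
    U = state.U
    U[responsive] *= params.decay
    active = np.flatnonzero(input_spikes)
    if active.size:
        drive = weights.weights[active].sum(axis=0)
        U[responsive] += drive[responsive]
    crossed = np.flatnonzero(responsive & (U >= state.threshold))
    fired: list[int] = []
    if crossed.size:
        winner = int(crossed[np.argmax(U[crossed] - state.threshold[crossed])])
        U[winner] = params.v_rest
        state.ref_timer[winner] = params.t_ref
        state.fire_count_window[winner] += 1
        state.fire_count_total[winner] += 1
        fired = [winner]
    np.maximum(state.ref_timer - params.dt, 0.0, out=state.ref_timer)
    np.maximum(state.inh_timer - params.dt, 0.0, out=state.inh_timer)
    return fired


def lateral_inhibit(state: NeuronState, fired: list[int], params: LIFParams) -> NeuronState:
    """Suppress all excitatory neurons except the winner(s).

    The losers' membrane potentials reset to rest and are held there for
    ``t_inhibit`` ms; winners are untouched (no self-inhibition path).
    """
    if not fired:
        return state
    mask = np.ones(state.n_exc, dtype=bool)
    mask[list(fired)] = False
    state.U[mask] = params.v_rest
    state.inh_timer[mask] = np.maximum(state.inh_timer[mask], params.t_inhibit)
    return state


def run_sample(
    raster: SpikeRaster,
    state: NeuronState,
    weights: SynapseArray,
    params: LIFParams,
    on_post_spike: Optional[Callable[[int, float, np.ndarray], None]] = None,
    record_times: bool = False,
):
    """Present one spike raster to the layer.

    Membrane potentials and timers are reset before the first bin; adaptive
    thresholds and firing counters carry over from previous samples.  For
    every bin :func:`step` runs and, if a neuron fired, lateral inhibition
    suppresses the rest.  ``on_post_spike(neuron, t_ms, last_pre_times)`` is
    invoked on each post-synaptic spike (``last_pre_times`` holds the most
    recent pre-spike time per input within this sample, ``-inf`` if none) —
    this is the hook through which learning rules observe spike timing.

    Returns ``(counts, times)``: per-neuron spike counts for this sample and,
    when ``record_times`` is set, a list of (neuron, t_ms) firing events.
    """
    spikes = raster.spikes
    if spikes.shape[0] != weights.n_inputs:
        raise ShapeError(
            f"raster has {spikes.shape[0]} inputs, weights expect {weights.n_inputs}"
        )
    if abs(raster.dt - params.dt) > 1e-12:
        raise ValueError(f"raster dt {raster.dt} != neuron dt {params.dt}")
    state.reset_sample(params)
    n_bins = spikes.shape[1]
    last_pre = np.full(weights.n_inputs, -np.inf)
    counts = np.zeros(state.n_exc, dtype=np.int64)
    times: list[tuple[int, float]] = []
    for t in range(n_bins):
        t_ms = t * params.dt
        col = spikes[:, t]
        pre = np.flatnonzero(col)
        if pre.size:
            last_pre[pre] = t_ms
        fired = step(state, col, weights, params)
        if fired:
            j = fired[0]
            counts[j] += 1
            if record_times:
                times.append((j, t_ms))
            if on_post_spike is not None:
                on_post_spike(j, t_ms, last_pre)
            lateral_inhibit(state, fired, params)
    return counts, times
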