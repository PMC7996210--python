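"""Simplified STDP through the device model, and homeostatic thresholds.

Learning uses the simplified spike-timing-dependent plasticity rule common
in memristive hardware proposals: when an output neuron fires at time
``t_post``, every afferent synapse receives exactly one programming pulse —
a potentiation (LTP) pulse if that input spiked within the preceding
``ltp_window`` ms (``0 <= t_post - t_pre <= ltp_window``, boundary
inclusive), otherwise a depression (LTD) pulse.  The pulse magnitudes are
whatever the device model yields at the synapse's current conductance, so
all device properties (bounds, saturation, non-linearity) shape learning
directly.  Nothing happens on pre-synaptic spikes alone.

Homeostasis keeps firing spread across the population by adapting each
neuron's threshold every ``homeo_interval`` samples:

    threshold += (f_actual - f_target) * threshold * gamma

where ``f_actual`` is the neuron's spike count in the elapsed window and
``f_target`` the desired count.  Over-active neurons become harder to fire,
silent ones easier, preventing a few neurons from capturing every input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .device import DeviceParams, Direction, apply_pulse
from .network import NeuronState

__all__ = ["PlasticityParams", "stdp_on_post_spike", "homeostasis_update"]


@dataclass(frozen=True)
class PlasticityParams:
    """STDP window and homeostasis constants.

    Parameters
    ----------
    ltp_window
        Pre-before-post coincidence window in ms; spikes up to this long
        before the post spike (inclusive) are potentiated.
    homeo_gamma
        Homeostasis rate; 0 disables threshold adaptation.
    homeo_target
        Target firing count per neuron per adjustment window.
    homeo_interval
        Number of sample presentations between threshold adjustments.
    """

    ltp_window: float = 45.0
    homeo_gamma: float = 0.01
    homeo_target: float = 10.0
    homeo_interval: int = 600

    def __post_init__(self) -> None:
        if self.ltp_window <= 0:
            raise ValueError(f"ltp_window must be positive, got {self.ltp_window}")
        if self.homeo_interval < 1:
            raise ValueError(f"homeo_interval must be >= 1, got {self.homeo_interval}")
        if self.homeo_gamma < 0:
            raise ValueError(f"homeo_gamma must be >= 0, got {self.homeo_gamma}")


def stdp_on_post_spike(
    post_time: float,
    last_pre_spike_times: np.ndarray,
    weights_column: np.ndarray,
    device: DeviceParams,
    params: PlasticityParams,
) -> np.ndarray:
    """One simplified-STDP update for the firing neuron's afferent weights.

    ``last_pre_spike_times`` holds, per input, the most recent pre-spike time
    within the current sample (``-inf`` when the input has not spiked yet).
    Returns the updated weight column; the input column is not modified.
    """
    last_pre = np.asarray(last_pre_spike_times, dtype=float)
    col = np.asarray(weights_column, dtype=float)
    if last_pre.shape != col.shape:
        raise ValueError("pre-spike times and weight column shapes differ")
    finite = np.isfinite(last_pre)
    if np.any(last_pre[finite] > post_time + 1e-12):
        raise ValueError("pre-spike time after the post spike within this sample")
    dt = post_time - last_pre
    ltp_mask = (dt >= 0.0) & (dt <= params.ltp_window)
    new = col.copy()
    if np.any(ltp_mask):
        new[ltp_mask] = apply_pulse(col[ltp_mask], Direction.LTP, device)
    ltd_mask = ~ltp_mask
    if np.any(ltd_mask):
        new[ltd_mask] = apply_pulse(col[ltd_mask], Direction.LTD, device)
    return new


def homeostasis_update(state: NeuronState, params: PlasticityParams) -> NeuronState:
    """Adapt thresholds toward the target firing count and reset the window.

    The multiplicative update ``(f_actual - f_target) * threshold * gamma``
    is applied per neuron; thresholds are floored at a small positive
    epsilon (a fraction of the initial threshold) so an aggressive ``gamma``
    cannot drive them to zero or negative values.
    """
    f_actual = state.fire_count_window.astype(float)
    state.threshold += (f_actual - params.homeo_target) * state.threshold * params.homeo_gamma
    np.maximum(state.threshold, state.threshold_floor, out=state.threshold)
    state.fire_count_window[:] = 0
    return state
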