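"""Memristive synapse model with non-linear conductance updates.

A memristor used as a synapse stores its weight as a normalized conductance
``g`` in ``[g_min, g_max]``.  Programming pulses move the conductance along
branch-specific response curves: potentiation (LTP) pulses climb an
exponential-saturation curve, depression (LTD) pulses descend a mirrored
curve.  Each branch is parameterised by a dimensionless non-linearity factor
``nu``:

* ``nu = 0`` — the linear limit; every pulse moves the weight by the same
  fixed amount.
* ``nu > 0`` — rapid change at the start of the branch, saturating later.
* ``nu < 0`` — slow start, rapid change near the end of the branch.

With pulse index ``p`` running from 0 to ``P`` (the device resolution, the
number of programmable states) the curves are::

    w_LTP(p) = alpha * (1 - exp(-nu_ltp * beta * p / P)) + g_min
    w_LTD(p) = g_max - alpha * (1 - exp(-nu_ltd * (1 - p / P)))
    alpha    = (g_max - g_min) / (1 - exp(-nu))        # per branch

``beta`` is the LTP/LTD asymmetry factor: in the linear limit a single LTP
pulse moves the weight ``beta`` times further than a single LTD pulse.  Note
the LTD branch is traversed *downward* in ``p`` during depression
(``p = P`` corresponds to ``g_max``, ``p = 0`` to ``g_min``).

The synapse state is tracked as the continuous normalized conductance; a
pulse inverts the relevant curve to recover the equivalent continuous pulse
index, advances it by one, and re-evaluates the curve.  This keeps pulse
application well-defined even when the LTP and LTD curves have different
shapes, and makes the single-pulse weight change a function of the current
weight alone, which is the quantity the profiling helpers below tabulate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import FittingError, RangeError

__all__ = [
    "LINEAR_NU_TOL",
    "Direction",
    "DeviceParams",
    "SynapseArray",
    "ltp_curve",
    "ltd_curve",
    "apply_pulse",
    "delta_w_profile",
    "ratio_profile",
    "fit_nonlinearity",
]

#: Below this magnitude of ``nu`` the exponential curve is numerically the
#: linear ramp (alpha is 0/0 at nu = 0), so the closed-form linear limit is
#: substituted.
LINEAR_NU_TOL = 1e-6


class Direction(str, Enum):
    """Pulse polarity: potentiation or depression."""

    LTP = "ltp"
    LTD = "ltd"


@dataclass(frozen=True)
class DeviceParams:
    """Parameters of the memristive conductance-update model.

    Parameters
    ----------
    nu_ltp, nu_ltd
        Non-linearity factors of the LTP and LTD branches.  Any real value
        is allowed; magnitudes below :data:`LINEAR_NU_TOL` select the linear
        limit.
    beta
        LTP/LTD asymmetry factor applied to the LTP exponent; in the linear
        limit one LTP pulse moves the weight ``beta`` times more than one
        LTD pulse.
    g_min, g_max
        Normalized conductance bounds.
    resolution
        Number of pulses ``P`` spanning the full range of the base (LTD)
        branch, i.e. the number of distinguishable device states.
    """

    nu_ltp: float
    nu_ltd: float
    beta: float = 4.0
    g_min: float = 0.0
    g_max: float = 1.0
    resolution: int = 256

    def __post_init__(self) -> None:
        if not self.g_min < self.g_max:
            raise ValueError(f"g_min must be < g_max, got [{self.g_min}, {self.g_max}]")
        if self.resolution < 2:
            raise ValueError(f"resolution must be >= 2, got {self.resolution}")
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")

    @property
    def g_range(self) -> float:
        return self.g_max - self.g_min

    @property
    def ltp_saturation_index(self) -> float:
        """Continuous pulse index at which the LTP branch reaches ``g_max``.

        Solving ``w_LTP(p) = g_max`` gives ``p = P / beta`` for every ``nu``;
        when ``beta < 1`` the branch never reaches ``g_max`` within the pulse
        range and the index saturates at ``P``.
        """
        return min(float(self.resolution), self.resolution / self.beta)


def _as_float_array(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def _check_pulse_range(p: np.ndarray, params: DeviceParams) -> None:
    if np.any(p < 0) or np.any(p > params.resolution):
        raise RangeError(f"pulse index outside [0, {params.resolution}]")


def _ltp_value(p: np.ndarray, params: DeviceParams) -> np.ndarray:
    P, d, nu = params.resolution, params.g_range, params.nu_ltp
    if abs(nu) < LINEAR_NU_TOL:
        w = params.g_min + d * params.beta * p / P
    else:
        # alpha * (1 - exp(...)) written as an expm1 ratio so the boundary
        # identities (p=0 -> g_min, exponent=-nu -> g_max) hold exactly.
        w = params.g_min + d * np.expm1(-nu * params.beta * p / P) / np.expm1(-nu)
    return np.clip(w, params.g_min, params.g_max)


def _ltd_value(p: np.ndarray, params: DeviceParams) -> np.ndarray:
    P, d, nu = params.resolution, params.g_range, params.nu_ltd
    if abs(nu) < LINEAR_NU_TOL:
        w = params.g_min + d * p / P
    else:
        w = params.g_max - d * np.expm1(-nu * (1.0 - p / P)) / np.expm1(-nu)
    return np.clip(w, params.g_min, params.g_max)


def ltp_curve(p, params: DeviceParams):
    """Normalized conductance after ``p`` potentiation pulses from ``g_min``.

    ``p`` may be a scalar or array of (continuous) pulse indices in
    ``[0, resolution]``.
    """
    arr, scalar = _as_float_array(p)
    _check_pulse_range(arr, params)
    w = _ltp_value(arr, params)
    return float(w) if scalar else w


def ltd_curve(p, params: DeviceParams):
    """Normalized conductance at LTD-branch pulse index ``p``.

    The branch is parameterised so that ``p = resolution`` is ``g_max`` and
    ``p = 0`` is ``g_min``; depression traverses it downward in ``p``.
    """
    arr, scalar = _as_float_array(p)
    _check_pulse_range(arr, params)
    w = _ltd_value(arr, params)
    return float(w) if scalar else w


def _ltp_index(w: np.ndarray, params: DeviceParams) -> np.ndarray:
    """Continuous pulse index of weight ``w`` on the LTP branch."""
    P, d, nu = params.resolution, params.g_range, params.nu_ltp
    x = (w - params.g_min) / d
    if abs(nu) < LINEAR_NU_TOL:
        p = x * P / params.beta
    else:
        p = -np.log1p(x * np.expm1(-nu)) * P / (nu * params.beta)
    return np.clip(p, 0.0, params.ltp_saturation_index)


def _ltd_index(w: np.ndarray, params: DeviceParams) -> np.ndarray:
    """Continuous pulse index of weight ``w`` on the LTD branch."""
    P, d, nu = params.resolution, params.g_range, params.nu_ltd
    x = (params.g_max - w) / d
    if abs(nu) < LINEAR_NU_TOL:
        p = (1.0 - x) * P
    else:
        p = P * (1.0 + np.log1p(x * np.expm1(-nu)) / nu)
    return np.clip(p, 0.0, float(P))


def apply_pulse(w, direction: Direction | str, params: DeviceParams):
    """Apply one programming pulse to weight(s) ``w``.

    The current weight is mapped to its continuous pulse index on the
    requested branch, the index advances by +1 (LTP) or -1 (LTD), and the
    branch curve is re-evaluated.  The result saturates at the conductance
    bounds: an LTP pulse at ``g_max`` (or LTD at ``g_min``) returns the
    boundary unchanged.  LTP never decreases the weight and LTD never
    increases it.
    """
    direction = Direction(direction)
    arr, scalar = _as_float_array(w)
    if np.any(arr < params.g_min) or np.any(arr > params.g_max):
        raise RangeError(f"weight outside [{params.g_min}, {params.g_max}]")
    if direction is Direction.LTP:
        p = np.minimum(_ltp_index(arr, params) + 1.0, float(params.resolution))
        new = np.maximum(_ltp_value(p, params), arr)
    else:
        p = np.maximum(_ltd_index(arr, params) - 1.0, 0.0)
        new = np.minimum(_ltd_value(p, params), arr)
    return float(new) if scalar else new


def delta_w_profile(params: DeviceParams, n_points: int = 100) -> pd.DataFrame:
    """Single-pulse weight change as a function of the current weight.

    Evaluates :func:`apply_pulse` in both directions on ``n_points`` weights
    evenly spaced strictly inside ``(g_min, g_max)``.  Returns a frame with
    columns ``w``, ``dw_ltp`` (>= 0) and ``dw_ltd`` (<= 0).
    """
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    w = np.linspace(params.g_min, params.g_max, n_points + 2)[1:-1]
    return pd.DataFrame(
        {
            "w": w,
            "dw_ltp": apply_pulse(w, Direction.LTP, params) - w,
            "dw_ltd": apply_pulse(w, Direction.LTD, params) - w,
        }
    )


def ratio_saturation_band(params: DeviceParams) -> tuple[float, float]:
    """Weight band on which neither a single LTP nor LTD pulse clips.

    Below ``ltd_curve(1)`` one depression pulse would saturate at ``g_min``;
    above ``ltp_curve(p_sat - 1)`` one potentiation pulse would saturate at
    ``g_max``.  Inside this band the single-pulse changes follow the curve
    shapes exactly, which is where the LTP/LTD ratio is meaningful.
    """
    lo = ltd_curve(1.0, params)
    hi = ltp_curve(params.ltp_saturation_index - 1.0, params)
    return lo, hi


def ratio_profile(params: DeviceParams, n_points: int = 100) -> pd.DataFrame:
    """LTP/LTD single-pulse magnitude ratio across the weight range.

    The grid spans the saturation-free band (see
    :func:`ratio_saturation_band`) so no pulse clips at a bound and the
    depression step is never zero.  Columns: ``w``, ``dw_ltp``, ``dw_ltd``,
    ``ratio`` where ``ratio = dw_ltp / |dw_ltd|``.

    For a linear device the ratio equals ``beta`` everywhere; for symmetric
    non-linearity pairs ``(nu, -nu)`` it is constant in ``w``; for
    same-signed pairs it varies with ``w``.
    """
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    lo, hi = ratio_saturation_band(params)
    if not lo < hi:
        raise ValueError(
            "degenerate ratio grid: single-pulse saturation bands overlap "
            f"(band [{lo}, {hi}])"
        )
    w = np.linspace(lo, hi, n_points)
    dw_ltp = apply_pulse(w, Direction.LTP, params) - w
    dw_ltd = apply_pulse(w, Direction.LTD, params) - w
    return pd.DataFrame(
        {"w": w, "dw_ltp": dw_ltp, "dw_ltd": dw_ltd, "ratio": dw_ltp / np.abs(dw_ltd)}
    )


def fit_nonlinearity(
    pulse_weights: Sequence[tuple[float, float]],
    branch: Direction | str,
    bounds: tuple[float, float] = (0.0, 1.0),
    beta: float = 4.0,
    resolution: int = 256,
    nu_search: tuple[float, float] = (-30.0, 30.0),
) -> float:
    """Least-squares estimate of the non-linearity factor from pulse data.

    Parameters
    ----------
    pulse_weights
        Measured ``(pulse index, normalized conductance)`` pairs along one
        branch, e.g. from a staircase programming experiment.
    branch
        Which branch the data follow (``"ltp"`` or ``"ltd"``).
    bounds, beta, resolution
        The fixed device parameters under which ``nu`` is estimated.
    nu_search
        Interval scanned for the initial bracket.

    On noiseless data generated by the model curves the generating ``nu`` is
    recovered to better than 1e-4 relative error.
    """
    branch = Direction(branch)
    pts = np.asarray(pulse_weights, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise FittingError("need at least 3 (pulse, weight) points")
    order = np.argsort(pts[:, 0])
    p, w = pts[order, 0], pts[order, 1]
    g_min, g_max = bounds
    if np.any(w < g_min) or np.any(w > g_max):
        raise RangeError(f"weights outside bounds [{g_min}, {g_max}]")
    if np.any(p < 0) or np.any(p > resolution):
        raise RangeError(f"pulse indices outside [0, {resolution}]")
    span = np.ptp(w)
    if span <= 0:
        raise FittingError("degenerate data: all weights identical")
    # Both branches increase with p; tolerate only tiny measurement wiggle.
    if np.any(np.diff(w) < -1e-9 * span):
        raise FittingError("weights are not monotone in pulse index")

    def model(nu: float) -> np.ndarray:
        dp = DeviceParams(
            nu_ltp=nu if branch is Direction.LTP else 0.0,
            nu_ltd=nu if branch is Direction.LTD else 0.0,
            beta=beta,
            g_min=g_min,
            g_max=g_max,
            resolution=resolution,
        )
        return _ltp_value(p, dp) if branch is Direction.LTP else _ltd_value(p, dp)

    def sse(nu: float) -> float:
        return float(np.sum((model(nu) - w) ** 2))

    grid = np.linspace(nu_search[0], nu_search[1], 241)
    best = grid[np.argmin([sse(nu) for nu in grid])]
    step = grid[1] - grid[0]
    res = optimize.minimize_scalar(
        sse,
        bounds=(best - step, best + step),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


@dataclass
class SynapseArray:
    """Matrix of normalized conductances sharing one device model.

    ``weights`` has shape ``(n_inputs, n_outputs)``; every entry stays inside
    ``[g_min, g_max]`` because all updates go through :func:`apply_pulse`.
    """

    weights: np.ndarray
    device: DeviceParams

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError(f"weights must be 2-D, got shape {self.weights.shape}")
        if np.any(self.weights < self.device.g_min) or np.any(
            self.weights > self.device.g_max
        ):
            raise RangeError("initial weights outside conductance bounds")

    @property
    def n_inputs(self) -> int:
        return self.weights.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.weights.shape[1]

    @classmethod
    def random_uniform(
        cls, n_inputs: int, n_outputs: int, device: DeviceParams, rng: np.random.Generator
    ) -> "SynapseArray":
        """Uniform random initial conductances over ``[g_min, g_max]``."""
        w = rng.uniform(device.g_min, device.g_max, size=(n_inputs, n_outputs))
        return cls(weights=w, device=device)

    def pulse_column(self, j: int, direction: Direction | str, mask: np.ndarray) -> None:
        """Apply one pulse of ``direction`` to the masked synapses of output ``j``."""
        col = self.weights[:, j]
        col[mask] = apply_pulse(col[mask], direction, self.device)
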