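"""Plasticity of a single effective-oligodendrocyte segment.

Each segment tracks, per myelinated axon ``a``, a myelin-promoting factor
``M_a`` and a local conduction delay ``tau_a``, plus one shared global
signal G and one myelin-removal rate ``lambda_R``:

* every spike arriving on axon ``a`` releases factor in proportion to the
  global signal at that instant: ``M_a += lambda_M * G(t_spike)``;
* between spikes the factor is converted to myelin at rate ``lambda_A``
  (exact exponential decay) while the delay follows

      d tau_a / dt = lambda_R F_sR(tau_a) - lambda_A F_sA(tau_a) M_a(t),

  where F_sR and F_sA are normalized saturation ramps vanishing at the
  attainable-delay bounds (myelin addition shortens the delay, removal
  lengthens it);
* the removal rate is regulated homeostatically toward a nominal total
  myelination level: ``d lambda_R / dt = lambda_H lambda_R (tau_nom - <tau>)``.

The *instantaneous myelination* limit (``lambda_A -> infinity``) eliminates
M: a spike directly shortens the delay by
``lambda_M F_sA(tau_a) G(t_spike)``, and only removal acts between spikes.

Numerics: M decays in closed form; the delay equation's only nonlinearity
is the piecewise-linear ramps, so a midpoint rule with the exact M integral
per sub-step keeps the between-spike error far below the spike-jump
magnitudes.  Sub-step sizes are chosen from the ramp and homeostatic
variation rates; over typical inter-spike gaps a single step suffices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .global_signal import GlobalState, ResponseParams, propagate_state

__all__ = [
    "OMPParams",
    "SegmentState",
    "saturation_ramps",
    "spike_update",
    "evolve_between_spikes",
    "balance_removal_rate",
]

logger = logging.getLogger(__name__)

_MODES = ("full", "instantaneous")


@dataclass(frozen=True)
class OMPParams:
    """Plasticity constants of one segment (rates in 1/ms, delays in ms).

    ``tau_min``/``tau_max``/``tau_nom`` are whole-axon values; use
    :meth:`scaled` to derive the per-segment band for a chain of
    ``n_segments`` (all three divided by the segment count, so the summed
    band over the chain is invariant).
    """

    lambda_M: float = 0.02
    lambda_A: float = 0.1
    lambda_H: float = 0.0
    lambda_R0: float | None = None  # None -> Poisson balance value at init
    tau_min: float = 3.0
    tau_max: float = 100.0
    tau_nom: float = 50.0
    mode: str = "full"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if not (0 < self.tau_min < self.tau_nom < self.tau_max):
            raise ValueError("need 0 < tau_min < tau_nom < tau_max")
        for name in ("lambda_M", "lambda_A", "lambda_H"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.lambda_R0 is not None and self.lambda_R0 < 0:
            raise ValueError("lambda_R0 must be non-negative")

    def scaled(self, n_segments: int) -> "OMPParams":
        """Per-segment parameters for a chain of ``n_segments``."""
        if n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        return replace(
            self,
            tau_min=self.tau_min / n_segments,
            tau_max=self.tau_max / n_segments,
            tau_nom=self.tau_nom / n_segments,
        )

    @property
    def band(self) -> float:
        return self.tau_max - self.tau_min


@dataclass
class SegmentState:
    """Mutable state of one segment.

    ``g`` is the shared global-signal state, ``M`` and ``tau`` are per-axon
    vectors, ``lambda_R`` the current removal rate.  ``M_integral`` and
    ``tau_integral`` accumulate time integrals (for epoch means) and are
    reset externally at epoch boundaries.
    """

    g: GlobalState
    M: np.ndarray
    tau: np.ndarray
    lambda_R: float
    M_integral: np.ndarray = field(default=None)  # type: ignore[assignment]
    tau_integral: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.M.shape != self.tau.shape:
            raise ValueError("M and tau must have matching shapes")
        if self.M_integral is None:
            self.M_integral = np.zeros_like(self.M)
        if self.tau_integral is None:
            self.tau_integral = np.zeros_like(self.tau)

    @property
    def n_axons(self) -> int:
        return self.tau.size

    def reset_integrals(self) -> None:
        self.M_integral[:] = 0.0
        self.tau_integral[:] = 0.0


def saturation_ramps(tau, tau_min: float, tau_max: float):
    """Normalized addition/removal ramps (F_sA, F_sR), each clipped to [0, 1].

    F_sA(tau) = (tau - tau_min)/(tau_max - tau_min) vanishes at the lower
    bound (no further shortening), F_sR(tau) = (tau_max - tau)/(tau_max -
    tau_min) at the upper (no further removal); they sum to 1 inside the
    band.
    """
    if tau_max <= tau_min:
        raise ValueError("tau_max must exceed tau_min")
    width = tau_max - tau_min
    tau = np.asarray(tau, dtype=float)
    f_sa = np.clip((tau - tau_min) / width, 0.0, 1.0)
    f_sr = np.clip((tau_max - tau) / width, 0.0, 1.0)
    return f_sa, f_sr


def balance_removal_rate(lambda_M: float, n_axons: int, tau_s: float) -> float:
    """Removal rate balancing spike-driven addition for independent Poisson
    input, ignoring saturation: lambda_R = lambda_M * N_A / tau_s**2."""
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    return lambda_M * n_axons / tau_s**2


def spike_update(
    state: SegmentState,
    axon: int,
    params: OMPParams,
    freeze_tau: bool = False,
) -> SegmentState:
    """Apply the plasticity jump for a spike arriving on ``axon`` (in place).

    Must be called with ``state.g.G`` already evaluated at the spike time (G
    is continuous across the spike, so pre/post-impulse values coincide).
    In full mode the factor jumps, ``M_a += lambda_M G``; in instantaneous
    mode the delay jumps, ``tau_a -= lambda_M F_sA(tau_a) G`` (pre-jump
    ramp), clamped to the band.  ``freeze_tau`` disables delay jumps during
    warm-up.
    """
    if not 0 <= axon < state.n_axons:
        raise IndexError("axon index out of range")
    G = state.g.G
    if params.mode == "full":
        state.M[axon] += params.lambda_M * G
    else:
        if not freeze_tau:
            f_sa = min(max((state.tau[axon] - params.tau_min) / params.band, 0.0), 1.0)
            tau_new = state.tau[axon] - params.lambda_M * f_sa * G
            state.tau[axon] = min(max(tau_new, params.tau_min), params.tau_max)
    return state


def _substep_count(
    dt: float, drive: float, band: float, lambda_H: float, homeo_gap: float
) -> int:
    # Ramp variation: |dtau| per step <= 2% of the band; homeostatic
    # exponent per step <= 0.1.  Usually one step per inter-spike gap.
    h = dt
    if drive > 0:
        h = min(h, 0.02 * band / drive)
    if lambda_H > 0 and homeo_gap > 0:
        h = min(h, 0.1 / (lambda_H * homeo_gap))
    return max(1, min(int(math.ceil(dt / h)), 100000))


def evolve_between_spikes(
    state: SegmentState,
    dt: float,
    params: OMPParams,
    kernel: ResponseParams | None = None,
    freeze_tau: bool = False,
) -> SegmentState:
    """Advance the slow variables over a spike-free interval (in place).

    M decays exactly (full mode); tau follows the ramp equation with
    midpoint sub-steps using the exact M integral; lambda_R integrates its
    multiplicative homeostatic law with the sub-step midpoint mean delay.
    If ``kernel`` is given the global signal is propagated too.  Time
    integrals of M and tau are accumulated for epoch means.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0:
        return state
    lam_A, lam_H = params.lambda_A, params.lambda_H
    t_min, t_max, band = params.tau_min, params.tau_max, params.band
    inv_band = 1.0 / band
    tau_nom = params.tau_nom
    full = params.mode == "full"

    M = state.M
    tau = state.tau
    lam_R = state.lambda_R
    n = tau.size
    inv_n = 1.0 / n

    drive = lam_R
    if full and n:
        drive += lam_A * float(M.max())
    homeo_gap = abs(tau_nom - float(tau.sum()) * inv_n) + 0.02 * band
    n_sub = _substep_count(dt, drive, band, lam_H, homeo_gap)
    h = dt / n_sub
    exp = math.exp
    decay = exp(-lam_A * h) if full else 1.0
    half_gain = 1.0 - exp(-lam_A * h / 2.0) if full else 0.0
    full_gain = 1.0 - decay if full else 0.0
    m_weight = (full_gain / lam_A) if (full and lam_A > 0) else h

    for _ in range(n_sub):
        if freeze_tau:
            if full:
                state.M_integral += M * m_weight
                M *= decay
            state.tau_integral += tau * h
            if lam_H > 0:
                lam_R *= exp(lam_H * (tau_nom - float(tau.sum()) * inv_n) * h)
            continue

        if full:
            # Midpoint predictor with exact M decay inside the sub-step.
            # tau stays clamped in [t_min, t_max], so the ramps need no clip.
            f_sa = (tau - t_min) * inv_band
            f_sr = 1.0 - f_sa
            tau_half = tau + (lam_R * (h / 2.0)) * f_sr - (M * half_gain) * f_sa
            np.maximum(tau_half, t_min, out=tau_half)
            np.minimum(tau_half, t_max, out=tau_half)
            gap_mid = tau_nom - float(tau_half.sum()) * inv_n
            lam_mid = lam_R * exp(lam_H * gap_mid * h / 2.0) if lam_H > 0 else lam_R
            f_sa = tau_half
            f_sa -= t_min
            f_sa *= inv_band  # reuse tau_half buffer as the midpoint ramp
            tau_new = tau + (lam_mid * h) * (1.0 - f_sa) - (M * full_gain) * f_sa
            np.maximum(tau_new, t_min, out=tau_new)
            np.minimum(tau_new, t_max, out=tau_new)
            state.M_integral += M * m_weight
            M *= decay
        else:
            # Pure removal: dtau/dt = lam_R (tau_max - tau)/band, exact.
            shrink_half = exp(-lam_R * h * inv_band / 2.0)
            if lam_H > 0:
                tau_half = t_max - (t_max - tau) * shrink_half
                gap_mid = tau_nom - float(tau_half.sum()) * inv_n
                lam_mid = lam_R * exp(lam_H * gap_mid * h / 2.0)
                shrink = exp(-lam_mid * h * inv_band)
            else:
                gap_mid = 0.0
                shrink = shrink_half * shrink_half
            tau_new = t_max - (t_max - tau) * shrink
            np.maximum(tau_new, t_min, out=tau_new)

        state.tau_integral += (0.5 * h) * (tau + tau_new)
        tau[:] = tau_new
        if lam_H > 0:
            lam_R *= exp(lam_H * gap_mid * h)

    if lam_R < 0:  # unreachable with the multiplicative law; kept as a guard
        logger.warning("lambda_R fell below zero; flooring at 0")
        lam_R = 0.0
    state.lambda_R = lam_R
    g = state.g
    if kernel is not None:
        # Inline exact two-exponential propagation of (G, v).
        a, b = kernel.a, kernel.b
        inv = 1.0 / (a - b)
        c_a = (-b * g.G - g.v) * inv
        c_b = (a * g.G + g.v) * inv
        ea = exp(-a * dt)
        eb = exp(-b * dt)
        g.G = c_a * ea + c_b * eb
        g.v = -a * c_a * ea - b * c_b * eb
    g.t += dt
    return state
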