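"""The oligodendrocyte's global transient signal G(t).

Every spike on any myelinated axon triggers the release of a global factor
whose concentration follows the spike-response kernel

    R(t) = Q (tau_r + tau_d) / tau_d^2 * exp(-t/tau_d) * (1 - exp(-t/tau_r))

for t > 0 (zero otherwise), normalized so that its time integral equals the
single-release quantity Q.  With a single characteristic time
tau_r = tau_d = tau_G and Q = 1 this reduces to

    R(t) = (2/tau_G) exp(-t/tau_G) (1 - exp(-t/tau_G)),

peaking at t_max = tau_G ln 2 with R(t_max) = 1/(2 tau_G).

R is the impulse response of a second-order linear system, written here in
first-order form with the auxiliary variable v = dG/dt:

    dv/dt = -a b G - (a + b) v + q_s * sum_k delta(t - t_k),   dG/dt = v,

with a = (tau_r+tau_d)/(tau_r tau_d), b = 1/tau_d and
q_s = Q (tau_r+tau_d)/(tau_r tau_d^2).  The system matrix has eigenvalues
-a and -b, which are distinct for every tau_r > 0 (a - b = 1/tau_r), so the
between-spike propagation has an exact two-exponential closed form: no
numerical integration is needed.  A spike is a jump of q_s in v; G itself is
continuous across spikes because R(0) = 0.

:func:`analytic_G` evaluates the superposition sum over all past spikes
directly and serves as the verification oracle for the event-driven path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ResponseParams",
    "GlobalState",
    "response_kernel",
    "kernel_peak",
    "propagate_state",
    "apply_spike_impulse",
    "simulate_global",
    "analytic_G",
]

# Beyond this many decay times the kernel is < 2e-22 of its peak; the
# superposition oracle truncates there to bound cost.
_KERNEL_CUTOFF = 50.0


@dataclass(frozen=True)
class ResponseParams:
    """Spike-response kernel parameters (rise/decay times in ms, quantity Q).

    Construct with ``ResponseParams(tau_G=10.0)`` for the single-time form
    (tau_r = tau_d = tau_G), or give ``tau_r`` and ``tau_d`` separately.
    """

    tau_r: float = None  # type: ignore[assignment]
    tau_d: float = None  # type: ignore[assignment]
    Q: float = 1.0
    tau_G: float | None = None

    def __post_init__(self) -> None:
        if self.tau_G is not None:
            object.__setattr__(self, "tau_r", float(self.tau_G))
            object.__setattr__(self, "tau_d", float(self.tau_G))
        if self.tau_r is None or self.tau_d is None:
            raise ValueError("give either tau_G or both tau_r and tau_d")
        if self.tau_r <= 0 or self.tau_d <= 0 or self.Q <= 0:
            raise ValueError("tau_r, tau_d and Q must be positive")

    # Derived constants of the first-order system.
    @property
    def a(self) -> float:
        return (self.tau_r + self.tau_d) / (self.tau_r * self.tau_d)

    @property
    def b(self) -> float:
        return 1.0 / self.tau_d

    @property
    def q_s(self) -> float:
        return self.Q * (self.tau_r + self.tau_d) / (self.tau_r * self.tau_d**2)

    @property
    def support(self) -> float:
        """Effective kernel support used by the superposition oracle (ms)."""
        return _KERNEL_CUTOFF * max(self.tau_r, self.tau_d)


@dataclass
class GlobalState:
    """State of one segment's global signal: amplitude G (1/ms), v = dG/dt."""

    G: float = 0.0
    v: float = 0.0
    t: float = 0.0


def response_kernel(t, params: ResponseParams):
    """Evaluate R(t); accepts scalars or arrays, zero for t <= 0."""
    t = np.asarray(t, dtype=float)
    amp = params.Q * (params.tau_r + params.tau_d) / params.tau_d**2
    with np.errstate(over="ignore"):
        out = np.where(
            t > 0,
            amp
            * np.exp(-np.clip(t, 0, None) / params.tau_d)
            * (1.0 - np.exp(-np.clip(t, 0, None) / params.tau_r)),
            0.0,
        )
    return out if out.ndim else float(out)


def kernel_peak(params: ResponseParams) -> tuple[float, float]:
    """Time and amplitude of the kernel maximum.

    t_max = tau_r ln((tau_r+tau_d)/tau_r); for tau_r = tau_d = tau_G this is
    tau_G ln 2 with R(t_max) = 1/(2 tau_G) (Q = 1).
    """
    ratio = (params.tau_r + params.tau_d) / params.tau_r
    t_max = params.tau_r * np.log(ratio)
    r_max = (params.Q / params.tau_d) * ratio ** (-params.tau_r / params.tau_d)
    return float(t_max), float(r_max)


def propagate_state(
    state: GlobalState, dt: float, params: ResponseParams
) -> GlobalState:
    """Exact closed-form propagation of (G, v) over a spike-free interval.

    Decomposes the state onto the e^{-a t}, e^{-b t} eigenmodes; exact to
    floating point for any dt >= 0.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0:
        return GlobalState(G=state.G, v=state.v, t=state.t)
    a, b = params.a, params.b
    # G = c_a e^{-a t} + c_b e^{-b t};  v = -a c_a e^{-a t} - b c_b e^{-b t}
    inv = 1.0 / (a - b)  # = tau_r > 0, never degenerate
    c_a = (-b * state.G - state.v) * inv
    c_b = (a * state.G + state.v) * inv
    ea = np.exp(-a * dt)
    eb = np.exp(-b * dt)
    G = c_a * ea + c_b * eb
    v = -a * c_a * ea - b * c_b * eb
    return GlobalState(G=float(G), v=float(v), t=state.t + dt)


def apply_spike_impulse(
    state: GlobalState, params: ResponseParams, count: int = 1
) -> GlobalState:
    """Register ``count`` simultaneous spikes: v jumps by count*q_s, G is continuous."""
    return GlobalState(G=state.G, v=state.v + count * params.q_s, t=state.t)


def simulate_global(spike_times, params: ResponseParams, sample_times) -> np.ndarray:
    """Event-driven G(t) at the given sample times.

    Propagates the (G, v) state exactly from spike to spike and evaluates
    the closed form inside each gap (vectorized).  This is the simulation
    path the superposition oracle :func:`analytic_G` is checked against.
    """
    spikes = np.sort(np.asarray(spike_times, dtype=float).ravel())
    t_s = np.asarray(sample_times, dtype=float)
    order = np.argsort(t_s)
    out = np.empty_like(t_s)
    a, b = params.a, params.b
    inv = 1.0 / (a - b)
    state = GlobalState()
    idx = 0
    edges = np.concatenate((spikes, [np.inf]))
    for j, t_end in enumerate(edges):
        # samples inside (state.t, t_end]
        sel = []
        while idx < order.size and t_s[order[idx]] <= t_end:
            sel.append(order[idx])
            idx += 1
        if sel:
            sel = np.asarray(sel)
            dts = t_s[sel] - state.t
            c_a = (-b * state.G - state.v) * inv
            c_b = (a * state.G + state.v) * inv
            out[sel] = c_a * np.exp(-a * dts) + c_b * np.exp(-b * dts)
        if not np.isfinite(t_end):
            break
        state = propagate_state(state, t_end - state.t, params)
        state = apply_spike_impulse(state, params)
    return out


def analytic_G(spike_times, t, params: ResponseParams):
    """Superposition oracle: G(t) = sum over past spikes of R(t - t_spike).

    ``spike_times`` is a flat array of all spikes (all axons pooled); ``t``
    may be a scalar or array of query times.  Contributions with lag beyond
    ``params.support`` are dropped (relative error < 1e-20).  Used only for
    verification, never in the simulation loop.
    """
    spikes = np.sort(np.asarray(spike_times, dtype=float).ravel())
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t_arr)
    for i, tq in enumerate(t_arr):
        lags = tq - spikes
        lags = lags[(lags > 0) & (lags < params.support)]
        if lags.size:
            out[i] = float(np.sum(response_kernel(lags, params)))
    return out if np.ndim(t) else float(out[0])
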