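"""Nested curve models for synchronization profiles and their fitting.

Profiles sigma_tau(t) are summarized by a nested family built around a
double-exponential envelope with optional multiplicative and damped
additive cosine modulation:

    C     sigma_inf
    E1    sigma_inf + p3 exp(-t/tau_L)
    E2    sigma_inf + p3 exp(-t/tau_L) - p4 exp(-t/p5)
    E2C   E2 envelope * (1 + p6 cos(2 pi t/p7 + p8))
    E2C2  E2 envelope * (1 + p6 cos(2 pi t/p7 + p8)
                           + p9 exp(-t/p10) cos(2 pi t/p11 + p12))

The two headline quantities are the long-time baseline ``sigma_inf`` and
the synchronization time constant ``tau_L``.  Fits are bounded trust-region
least squares from many random starts; each richer model is additionally
warm-started from the best simpler fit (with the extra terms switched off),
which enforces the RSS nesting hierarchy up to optimizer tolerance.

Parameter boxes (sigma0 = sigma_tau(0), T = profile span):
0 <= sigma_inf <= 2 sigma0; T/1000 < tau_L < 1000 T; 0 < p3, p4 < 2 sigma0;
T/1000 < p5 < 5 T; 0 < p6, p9 < sigma0/2; T/25 < p7, p11 (capped at 100 T —
periods far beyond the record are indistinguishable from none);
0 < p8, p12 < 2 pi; p10 bounded like p5.  Strict bounds are nudged inward
by a relative 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .experiment import SyncProfile

__all__ = [
    "MODEL_ORDER",
    "MODEL_NPARAMS",
    "PARAM_NAMES",
    "FitModelResult",
    "model_predict",
    "model_jacobian",
    "fit_model",
    "fit_all",
    "fits_to_frame",
]

MODEL_ORDER = ("C", "E1", "E2", "E2C", "E2C2")
MODEL_NPARAMS = {"C": 1, "E1": 3, "E2": 5, "E2C": 8, "E2C2": 12}
PARAM_NAMES = {
    "C": ["sigma_inf"],
    "E1": ["sigma_inf", "p3", "tau_L"],
    "E2": ["sigma_inf", "p3", "tau_L", "p4", "p5"],
    "E2C": ["sigma_inf", "p3", "tau_L", "p4", "p5", "p6", "p7", "p8"],
    "E2C2": [
        "sigma_inf", "p3", "tau_L", "p4", "p5", "p6", "p7", "p8",
        "p9", "p10", "p11", "p12",
    ],
}
_LOG_PARAMS = {"tau_L", "p5", "p7", "p10", "p11"}  # sampled log-uniformly


@dataclass
class FitModelResult:
    """One model's best fit to one profile."""

    model_id: str
    x: np.ndarray
    rss: float
    n_pts: int
    converged: bool
    n_restarts: int
    boundary_frac: float
    sigma_tau0: float
    T_span: float

    @property
    def n_params(self) -> int:
        return MODEL_NPARAMS[self.model_id]

    @property
    def mse(self) -> float:
        return self.rss / self.n_pts

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES[self.model_id], self.x))

    @property
    def sigma_inf(self) -> float:
        return float(self.x[0])

    @property
    def tau_L(self) -> float | None:
        return float(self.x[2]) if self.model_id != "C" else None


def model_predict(model_id: str, params: Sequence[float], t) -> np.ndarray:
    """Evaluate a model curve at times ``t`` (ms)."""
    t = np.asarray(t, dtype=float)
    p = np.asarray(params, dtype=float)
    if model_id not in MODEL_ORDER:
        raise ValueError(f"unknown model {model_id!r}")
    if p.size != MODEL_NPARAMS[model_id]:
        raise ValueError(
            f"{model_id} takes {MODEL_NPARAMS[model_id]} parameters, got {p.size}"
        )
    if model_id == "C":
        return np.full_like(t, p[0])
    env = p[1] * np.exp(-t / p[2])
    if model_id == "E1":
        return p[0] + env
    env = env - p[3] * np.exp(-t / p[4])
    if model_id == "E2":
        return p[0] + env
    mod = 1.0 + p[5] * np.cos(2 * np.pi * t / p[6] + p[7])
    if model_id == "E2C":
        return p[0] + env * mod
    mod = mod + p[8] * np.exp(-t / p[9]) * np.cos(2 * np.pi * t / p[10] + p[11])
    return p[0] + env * mod


def model_jacobian(model_id: str, params: Sequence[float], t) -> np.ndarray:
    """Analytic Jacobian of :func:`model_predict` w.r.t. the parameters."""
    t = np.asarray(t, dtype=float)
    p = np.asarray(params, dtype=float)
    n = MODEL_NPARAMS[model_id]
    J = np.zeros((t.size, n))
    J[:, 0] = 1.0
    if model_id == "C":
        return J
    e3 = np.exp(-t / p[2])
    env = p[1] * e3
    d_env = [e3, p[1] * e3 * t / p[2] ** 2]
    if model_id != "E1":
        e5 = np.exp(-t / p[4])
        env = env - p[3] * e5
        d_env += [-e5, -p[3] * e5 * t / p[4] ** 2]
    if model_id in ("E1", "E2"):
        J[:, 1 : n] = np.column_stack(d_env)
        return J
    c1 = 2 * np.pi * t / p[6] + p[7]
    mod = 1.0 + p[5] * np.cos(c1)
    d_mod = [
        np.cos(c1),
        p[5] * np.sin(c1) * 2 * np.pi * t / p[6] ** 2,
        -p[5] * np.sin(c1),
    ]
    if model_id == "E2C2":
        e10 = np.exp(-t / p[9])
        c2 = 2 * np.pi * t / p[10] + p[11]
        mod = mod + p[8] * e10 * np.cos(c2)
        d_mod += [
            e10 * np.cos(c2),
            p[8] * e10 * t / p[9] ** 2 * np.cos(c2),
            p[8] * e10 * np.sin(c2) * 2 * np.pi * t / p[10] ** 2,
            -p[8] * e10 * np.sin(c2),
        ]
    J[:, 1:5] = np.column_stack(d_env) * mod[:, None]
    J[:, 5:n] = env[:, None] * np.column_stack(d_mod)
    return J


def _bounds(model_id: str, sigma0: float, T: float) -> tuple[np.ndarray, np.ndarray]:
    amp = max(2.0 * sigma0, 1e-9)
    box = {
        "sigma_inf": (0.0, amp),
        "p3": (0.0, amp),
        "tau_L": (T / 1000.0, 1000.0 * T),
        "p4": (0.0, amp),
        "p5": (T / 1000.0, 5.0 * T),
        "p6": (0.0, max(sigma0 / 2.0, 1e-9)),
        "p7": (T / 25.0, 100.0 * T),
        "p8": (0.0, 2.0 * np.pi),
        "p9": (0.0, max(sigma0 / 2.0, 1e-9)),
        "p10": (T / 1000.0, 5.0 * T),
        "p11": (T / 25.0, 100.0 * T),
        "p12": (0.0, 2.0 * np.pi),
    }
    # sigma_inf's bounds are closed; the rest are strict, nudged inward.
    lo, hi = [], []
    for name in PARAM_NAMES[model_id]:
        a, b = box[name]
        if name != "sigma_inf":
            span = b - a
            a, b = a + 1e-12 * span, b - 1e-12 * span
        lo.append(a)
        hi.append(b)
    return np.array(lo), np.array(hi)


def _random_start(
    model_id: str, lo: np.ndarray, hi: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    x = np.empty_like(lo)
    for i, name in enumerate(PARAM_NAMES[model_id]):
        if name in _LOG_PARAMS:
            x[i] = np.exp(rng.uniform(np.log(lo[i]), np.log(hi[i])))
        else:
            x[i] = rng.uniform(lo[i], hi[i])
    return x


def _embed(x_simple: np.ndarray, simple: str, rich: str,
           lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Embed a simpler model's optimum into a richer model's parameter box
    with the extra terms (amplitudes) switched off."""
    names_s = PARAM_NAMES[simple]
    x = np.empty(MODEL_NPARAMS[rich])
    for i, name in enumerate(PARAM_NAMES[rich]):
        if name in names_s:
            x[i] = x_simple[names_s.index(name)]
        elif name in ("p4", "p6", "p9"):  # amplitudes: off
            x[i] = lo[i]
        elif name in ("p8", "p12"):
            x[i] = np.pi
        else:  # time constants: geometric middle of the box
            x[i] = np.sqrt(lo[i] * hi[i])
    return np.clip(x, lo, hi)


def fit_model(
    profile: SyncProfile,
    model_id: str,
    n_restarts: int = 50,
    seed: int | np.random.SeedSequence = 0,
    warm_starts: Sequence[np.ndarray] = (),
) -> FitModelResult:
    """Bounded multi-start least-squares fit of one model to one profile."""
    t = np.asarray(profile.times, dtype=float)
    y = np.asarray(profile.sigma_tau, dtype=float)
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    n_pts = t.size
    if n_pts < MODEL_NPARAMS[model_id] + 2:
        raise ValueError("profile too short for this model")
    sigma0 = profile.sigma_tau0
    T = float(t[-1])

    if model_id == "C":
        s = float(np.clip(np.mean(y), 0.0, 2.0 * sigma0))
        rss = float(np.sum((y - s) ** 2))
        return FitModelResult("C", np.array([s]), rss, n_pts, True, 0, 0.0, sigma0, T)

    lo, hi = _bounds(model_id, sigma0, T)

    def resid(x):
        return model_predict(model_id, x, t) - y

    def jac(x):
        return model_jacobian(model_id, x, t)

    rng = np.random.default_rng(seed)
    starts = [np.clip(np.asarray(w, dtype=float), lo, hi) for w in warm_starts]
    starts += [_random_start(model_id, lo, hi, rng) for _ in range(n_restarts)]

    best_x, best_rss, converged = None, np.inf, False
    for x0 in starts:
        try:
            sol = least_squares(
                resid, x0, jac=jac, bounds=(lo, hi), method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=2000,
            )
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if rss < best_rss:
            best_rss, best_x, converged = rss, sol.x, bool(sol.success)
    if best_x is None:  # every start failed: report the first start as-is
        best_x = starts[0]
        best_rss = float(np.sum(resid(best_x) ** 2))
        converged = False

    span = hi - lo
    at_bound = (best_x - lo < 1e-6 * span) | (hi - best_x < 1e-6 * span)
    return FitModelResult(
        model_id, best_x, best_rss, n_pts, converged, len(starts),
        float(np.mean(at_bound)), sigma0, T,
    )


def fit_all(
    profile: SyncProfile,
    n_restarts: int = 50,
    seed: int | np.random.SeedSequence = 0,
) -> dict[str, FitModelResult]:
    """Fit all five nested models, warm-starting each from its predecessors.

    The warm starts make the RSS hierarchy monotone (a richer model can
    always reproduce a simpler one with its extra amplitudes at zero), up to
    the strict-bound nudge of 1e-12.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(MODEL_ORDER))
    results: dict[str, FitModelResult] = {}
    for model_id, child in zip(MODEL_ORDER, children):
        warm = []
        if model_id != "C":
            lo, hi = _bounds(model_id, profile.sigma_tau0, float(profile.times[-1]))
            for simpler, res in results.items():
                warm.append(_embed(res.x, simpler, model_id, lo, hi))
        res = fit_model(profile, model_id, n_restarts, child, warm_starts=warm)
        # Guard the nesting contract: never report a richer model worse than
        # an already-fitted simpler one beyond the embedding error.
        for simpler, prev in results.items():
            if res.rss > prev.rss * (1 + 1e-9) and warm:
                lo, hi = _bounds(model_id, profile.sigma_tau0, float(profile.times[-1]))
                x_emb = _embed(prev.x, simpler, model_id, lo, hi)
                t = profile.times[np.isfinite(profile.sigma_tau)]
                y = profile.sigma_tau[np.isfinite(profile.sigma_tau)]
                rss_emb = float(np.sum((model_predict(model_id, x_emb, t) - y) ** 2))
                if rss_emb < res.rss:
                    res = FitModelResult(
                        model_id, x_emb, rss_emb, res.n_pts, res.converged,
                        res.n_restarts, res.boundary_frac, res.sigma_tau0, res.T_span,
                    )
        results[model_id] = res
    return results


def fits_to_frame(fits_by_profile):
    """Tabulate fit results (one row per profile per model) for text export.

    ``fits_by_profile`` is a sequence of dicts as returned by
    :func:`fit_all`; write the result with ``frame.to_csv(path, sep="\t")``.
    """
    import pandas as pd

    rows = []
    for pid, fits in enumerate(fits_by_profile):
        for model_id, res in fits.items():
            rows.append(
                {
                    "profile_id": pid,
                    "model_id": model_id,
                    "rss": res.rss,
                    "mse": res.mse,
                    "n_pts": res.n_pts,
                    "n_params": res.n_params,
                    "converged": res.converged,
                    "boundary_frac": res.boundary_frac,
                    **{f"param_{k}": v for k, v in res.params.items()},
                }
            )
    return pd.DataFrame(rows)
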