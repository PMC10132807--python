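"""Tolerance-modified F-test selection among the nested profile models.

The classical partial F-test compares a restricted (R) and an unrestricted
(U) model through

    F_num = (RSS_R - RSS_U) / (n_U - n_R),
    F_den = RSS_U / (n_pts - n_U),      F = F_num / F_den,

with F ~ F(n_U - n_R, n_pts - n_U) under the null that the extra terms are
unnecessary.  Simulated synchronization profiles are nearly noise-free, so
even negligible systematic wiggles reject the simple models at absurdly
small alpha.  The modified test therefore floors the denominator with a
tolerance pseudo-noise: with MSE_min = (p_MSE * sigma_tau(0) / 100)^2 and
RSS_min = n_pts * MSE_min,

    F_den_m = (RSS_U + RSS_min) / (n_pts - n_U),    F_m = F_num / F_den_m.

At p_MSE = 0 the classical test is recovered exactly.  Selection starts
from the minimum-MSE fit (usually the full model), tests each more
restricted model against it in increasing complexity order, and keeps the
most restricted one not rejected at the given alpha; afterwards an ad-hoc
guard reverts toward the unrestricted model while the chosen model's MSE
exceeds 500x the unrestricted one's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .profile_fit import FitModelResult, MODEL_ORDER

__all__ = [
    "ALPHA_LEVELS",
    "ComparisonRecord",
    "SelectionResult",
    "modified_f_test",
    "select_model",
    "selection_report",
    "selections_to_frame",
]

ALPHA_LEVELS = (0.01, 1e-5, 1e-10, 1e-15)
DEFAULT_P_MSE = 2.0
MSE_REVERSION_FACTOR = 500.0


@dataclass(frozen=True)
class ComparisonRecord:
    """One restricted-vs-unrestricted test."""

    restricted: str
    unrestricted: str
    f_num: float
    f_den_m: float
    f_m: float
    df: tuple[int, int]
    p_value: float


@dataclass
class SelectionResult:
    """Outcome of model selection for one profile at one (p_MSE, alpha)."""

    chosen: str
    unrestricted: str
    alpha: float
    p_mse: float
    rss_min: float
    mse_min: float
    comparisons: list[ComparisonRecord] = field(default_factory=list)
    reverted: bool = False


def modified_f_test(
    fit_r: FitModelResult,
    fit_u: FitModelResult,
    p_mse: float,
    sigma_tau0: float | None = None,
    n_pts: int | None = None,
) -> ComparisonRecord:
    """Tolerance-modified partial F-test of ``fit_r`` nested in ``fit_u``."""
    if MODEL_ORDER.index(fit_r.model_id) >= MODEL_ORDER.index(fit_u.model_id):
        raise ValueError("fit_r must be strictly nested in fit_u")
    n_pts = fit_u.n_pts if n_pts is None else n_pts
    sigma_tau0 = fit_u.sigma_tau0 if sigma_tau0 is None else sigma_tau0
    n_u, n_r = fit_u.n_params, fit_r.n_params
    if n_pts <= n_u:
        raise ValueError("need n_pts > n_U")
    if fit_r.rss < fit_u.rss * (1 - 1e-6) - 1e-12:
        raise ValueError(
            "restricted RSS below unrestricted RSS: nesting hierarchy broken"
        )
    rss_r = max(fit_r.rss, fit_u.rss)  # clip optimizer-tolerance inversions
    f_num = (rss_r - fit_u.rss) / (n_u - n_r)
    mse_min = (p_mse * sigma_tau0 / 100.0) ** 2
    rss_min = n_pts * mse_min
    f_den_m = (fit_u.rss + rss_min) / (n_pts - n_u)
    if f_den_m == 0.0:
        f_m = 0.0 if f_num == 0.0 else np.inf
    else:
        f_m = f_num / f_den_m
    df = (n_u - n_r, n_pts - n_u)
    p = float(stats.f.sf(f_m, *df)) if np.isfinite(f_m) else 0.0
    return ComparisonRecord(
        fit_r.model_id, fit_u.model_id, f_num, f_den_m, f_m, df, p
    )


def select_model(
    fits: Mapping[str, FitModelResult],
    p_mse: float = DEFAULT_P_MSE,
    alpha: float = 0.01,
    sigma_tau0: float | None = None,
) -> SelectionResult:
    """Choose the most parsimonious model not rejected by the modified test.

    The unrestricted reference is the minimum-MSE fit (ties broken toward
    the simpler model); candidates are the models nested within it, tested
    in increasing complexity; the most restricted with p >= alpha wins.
    The 500x-MSE guard then walks back toward the reference while the
    chosen model fits catastrophically worse.
    """
    missing = set(MODEL_ORDER) - set(fits)
    if missing:
        raise ValueError(f"missing fits for models {sorted(missing)}")
    sigma_tau0 = fits["E2C2"].sigma_tau0 if sigma_tau0 is None else sigma_tau0

    mses = {m: fits[m].mse for m in MODEL_ORDER}
    unrestricted = min(MODEL_ORDER, key=lambda m: (mses[m], MODEL_ORDER.index(m)))
    u_idx = MODEL_ORDER.index(unrestricted)
    fit_u = fits[unrestricted]

    mse_min = (p_mse * sigma_tau0 / 100.0) ** 2
    rss_min = fit_u.n_pts * mse_min

    comparisons: list[ComparisonRecord] = []
    candidates = list(MODEL_ORDER[:u_idx])  # most restricted first
    chosen = unrestricted
    for m in candidates:
        rec = modified_f_test(fits[m], fit_u, p_mse, sigma_tau0)
        comparisons.append(rec)
        if rec.p_value >= alpha:
            chosen = m
            break

    reverted = False
    order = candidates + [unrestricted]
    while chosen != unrestricted and (
        fits[chosen].mse > MSE_REVERSION_FACTOR * fit_u.mse
    ):
        chosen = order[order.index(chosen) + 1]
        reverted = True

    return SelectionResult(
        chosen=chosen,
        unrestricted=unrestricted,
        alpha=alpha,
        p_mse=p_mse,
        rss_min=rss_min,
        mse_min=mse_min,
        comparisons=comparisons,
        reverted=reverted,
    )


def selection_report(
    fits: Mapping[str, FitModelResult],
    p_mse: float = DEFAULT_P_MSE,
    alphas: Sequence[float] = ALPHA_LEVELS,
) -> dict[float, SelectionResult]:
    """Run the selection at every alpha level, as used for the pie charts."""
    return {a: select_model(fits, p_mse, a) for a in alphas}


def selections_to_frame(reports_by_profile):
    """Tabulate selection outcomes (one row per profile per alpha level).

    ``reports_by_profile`` is a sequence of dicts as returned by
    :func:`selection_report`; suitable for building model-selection charts.
    """
    import pandas as pd

    rows = []
    for pid, report in enumerate(reports_by_profile):
        for alpha, sel in report.items():
            rows.append(
                {
                    "profile_id": pid,
                    "alpha": alpha,
                    "p_mse": sel.p_mse,
                    "chosen": sel.chosen,
                    "unrestricted": sel.unrestricted,
                    "reverted": sel.reverted,
                    "f_m": {c.restricted: c.f_m for c in sel.comparisons},
                }
            )
    return pd.DataFrame(rows)
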