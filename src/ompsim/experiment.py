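"""Run orchestration: initialization, warm-up, epochs, synchrony metric, sweeps.

A *trial* draws fixed delays and initial adaptive delays, synthesizes the
spike schedule, optionally runs warm-up epochs with frozen delays (letting
the removal rate approach equilibrium), then records the arrival-time
spread

    sigma_tau = SD_a( D_a + sum_o tau_a(o) )

at every epoch boundary (population SD, instantaneous delays).  The
resulting synchronization profile sigma_tau(t), together with its
pre-learning value sigma_tau(0), is the unit of analysis for the fitting
and model-selection machinery.  Epoch means of M and tau and the removal
rate per segment can be recorded as traces.

A *sweep* runs the Cartesian product of a parameter grid times ``n_r``
trials, each with a deterministic derived seed, and collects profiles into
a pandas DataFrame (exportable as delimited text plus a parameter
manifest).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .global_signal import GlobalState, ResponseParams
from .oligo_chain import ChainConfig, ChainState, run_chain
from .segment_dynamics import OMPParams, SegmentState, balance_removal_rate
from .spike_gen import (
    Correlation,
    SignalSpec,
    FixedDelays,
    SpikeSchedule,
    apply_jitter,
    draw_fixed_delays,
    generate_bundle,
)

__all__ = [
    "ExperimentConfig",
    "RunConfig",
    "SyncProfile",
    "initialize_run",
    "spread_metric",
    "run_trial",
    "sweep",
    "profiles_to_frame",
    "export_profiles",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Trial structure: duration, epoching, warm-up, initial-delay spread.

    ``T_exp`` is the learning duration (ms), split into ``n_e`` recorded
    epochs of length ``T_e = T_exp/n_e``.  ``warmup_epochs=None`` resolves
    to 2 when homeostasis is active and 0 otherwise.  ``sigma_D`` is the
    fixed-delay spread (ms); ``p_tau`` the percent spread of the initial
    per-segment delays about ``tau_nom/N_O``.
    """

    T_exp: float = 6e5
    n_e: int = 50
    n_r: int = 3
    sigma_D: float = 10.0
    p_tau: float = 5.0
    warmup_epochs: int | None = None

    def __post_init__(self) -> None:
        if self.T_exp <= 0:
            raise ValueError("T_exp must be positive")
        if self.n_e < 2:
            raise ValueError("n_e must be >= 2")
        if self.p_tau < 0 or self.sigma_D < 0:
            raise ValueError("p_tau and sigma_D must be non-negative")

    @property
    def T_e(self) -> float:
        return self.T_exp / self.n_e

    def resolved_warmup(self, params: OMPParams) -> int:
        if self.warmup_epochs is not None:
            return self.warmup_epochs
        return 2 if params.lambda_H > 0 else 0


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one simulation: signal, kernel, plasticity,
    chain and experiment sections, YAML round-trippable."""

    signal: tuple[SignalSpec, ...]
    kernel: ResponseParams
    plasticity: OMPParams
    chain: ChainConfig
    experiment: ExperimentConfig
    axon_groups: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        sig = self.signal
        if isinstance(sig, SignalSpec):
            sig = (sig,)
        object.__setattr__(self, "signal", tuple(sig))
        if self.axon_groups is not None:
            object.__setattr__(self, "axon_groups", tuple(self.axon_groups))

    def resolved_groups(self) -> np.ndarray:
        if self.axon_groups is not None:
            g = np.asarray(self.axon_groups, dtype=int)
            if g.size != self.chain.n_axons:
                raise ValueError("axon_groups length must equal n_axons")
            return g
        if len(self.signal) != 1:
            raise ValueError("axon_groups required for multi-group signals")
        return np.full(self.chain.n_axons, self.signal[0].group_id, dtype=int)

    def mean_tau_s(self) -> float:
        return float(np.mean([s.tau_s for s in self.signal]))

    def to_dict(self) -> dict:
        def enc(obj):
            d = {}
            for f in fields(obj):
                v = getattr(obj, f.name)
                if isinstance(v, (np.ndarray,)):
                    v = v.tolist()
                elif hasattr(v, "value") and not isinstance(v, (int, float)):
                    v = v.value
                d[f.name] = v
            return d

        return {
            "signal": [enc(s) for s in self.signal],
            "kernel": enc(self.kernel),
            "plasticity": enc(self.plasticity),
            "chain": {
                "n_segments": self.chain.n_segments,
                "n_axons": self.chain.n_axons,
            },
            "experiment": enc(self.experiment),
            "axon_groups": list(self.axon_groups) if self.axon_groups else None,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        kern = dict(d["kernel"])
        if kern.get("tau_G") is not None:
            kern = {"tau_G": kern["tau_G"], "Q": kern.get("Q", 1.0)}
        return cls(
            signal=tuple(SignalSpec(**s) for s in d["signal"]),
            kernel=ResponseParams(**kern),
            plasticity=OMPParams(**d["plasticity"]),
            chain=ChainConfig(**d["chain"]),
            experiment=ExperimentConfig(**d["experiment"]),
            axon_groups=d.get("axon_groups"),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SyncProfile:
    """Synchronization profile of one trial.

    ``times`` are epoch-end times measured from the start of learning (ms);
    ``sigma_tau`` the spread at each; ``sigma_tau0`` the pre-learning spread
    (after initialization, before epoch 1); ``sigma_D_only`` the fixed-delay
    part of it.  ``group_sigma`` maps group id -> within-group profile.
    ``traces`` optionally holds epoch means (``mean_M``, ``mean_tau`` as
    (n_e, N_O, N_A) arrays) and per-segment ``lambda_R``.
    """

    times: np.ndarray
    sigma_tau: np.ndarray
    sigma_tau0: float
    sigma_D_only: float
    seed: int | None = None
    meta: dict = field(default_factory=dict)
    group_sigma: dict[int, np.ndarray] = field(default_factory=dict)
    group_sigma0: dict[int, float] = field(default_factory=dict)
    traces: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.times)


def spread_metric(fixed: FixedDelays | np.ndarray, tau_totals: np.ndarray) -> float:
    """Population SD of per-axon total arrival delay, SD(D_a + tau_a); zero
    means perfect synchrony."""
    D = fixed.D if isinstance(fixed, FixedDelays) else np.asarray(fixed, dtype=float)
    tau = np.asarray(tau_totals, dtype=float)
    if D.shape != tau.shape:
        raise ValueError("fixed delays and tau_totals must have equal length")
    if D.size < 2:
        raise ValueError("need at least two axons")
    return float(np.std(D + tau))


def initialize_run(
    config: RunConfig,
    seed: int | np.random.SeedSequence,
    fixed_delays: np.ndarray | None = None,
) -> tuple[ChainState, FixedDelays]:
    """Draw fixed delays and build the initial chain state.

    M starts at zero; each local delay is drawn N(tau_0, p_tau*tau_0/100)
    with tau_0 = tau_nom/N_O, clamped into the per-segment band; lambda_R
    starts at the Poisson balance value (or ``lambda_R0`` if given); fixed
    delays are drawn N(0, sigma_D) and normalized to spread exactly sigma_D.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_delays, ss_tau = ss.spawn(2)
    chain_cfg, params, exp = config.chain, config.plasticity, config.experiment
    n_o, n_a = chain_cfg.n_segments, chain_cfg.n_axons

    if fixed_delays is not None:
        D = np.asarray(fixed_delays, dtype=float)
        if D.size != n_a:
            raise ValueError("fixed_delays length must equal n_axons")
        fixed = FixedDelays(D=D, sigma_D=float(np.std(D)))
    else:
        fixed = draw_fixed_delays(n_a, exp.sigma_D, ss_delays)
    seg_params = params.scaled(n_o)
    tau_0 = seg_params.tau_nom
    if not (seg_params.tau_min < tau_0 < seg_params.tau_max):
        raise ValueError("tau_0 = tau_nom/N_O outside the per-segment band")

    rng = np.random.default_rng(ss_tau)
    if exp.p_tau > 0:
        taus = rng.normal(tau_0, exp.p_tau * tau_0 / 100.0, size=(n_o, n_a))
        taus = np.clip(taus, seg_params.tau_min, seg_params.tau_max)
    else:
        taus = np.full((n_o, n_a), tau_0)

    if params.lambda_R0 is not None:
        lam_R = params.lambda_R0
    else:
        lam_R = balance_removal_rate(params.lambda_M, n_a, config.mean_tau_s())

    segments = [
        SegmentState(
            g=GlobalState(), M=np.zeros(n_a), tau=taus[o].copy(), lambda_R=lam_R
        )
        for o in range(n_o)
    ]
    return ChainState(segments=segments), fixed


def _group_spread(
    fixed: FixedDelays, tau_tot: np.ndarray, groups: np.ndarray
) -> dict[int, float]:
    out = {}
    for g in np.unique(groups):
        m = groups == g
        if m.sum() >= 2:
            out[int(g)] = float(np.std(fixed.D[m] + tau_tot[m]))
    return out


def run_trial(
    config: RunConfig,
    seed: int | np.random.SeedSequence,
    record_traces: bool = False,
    fixed_delays: np.ndarray | None = None,
) -> SyncProfile:
    """Run one full trial and return its synchronization profile.

    ``fixed_delays`` overrides the random draw with an explicit per-axon
    vector (used when comparing against closed-form predictions at
    prescribed lags).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_init, ss_bundle, ss_jitter = ss.spawn(3)

    chain_cfg, params, exp = config.chain, config.plasticity, config.experiment
    kernel = config.kernel
    groups = config.resolved_groups()
    specs = {s.group_id: s for s in config.signal}
    if len(specs) != len(config.signal):
        raise ValueError("duplicate group_id in signal specs")

    warmup = exp.resolved_warmup(params)
    T_e = exp.T_e
    t_start = warmup * T_e
    t_total = t_start + exp.T_exp

    chain, fixed = initialize_run(config, ss_init, fixed_delays=fixed_delays)
    seg_params = params.scaled(chain_cfg.n_segments)

    # Spike synthesis over the full (warm-up + learning) window; fixed
    # delays are baked into the trains, then jitter is applied per axon.
    long_specs = {g: replace(s, duration=t_total) for g, s in specs.items()}
    schedule = generate_bundle(long_specs, groups, fixed, ss_bundle)
    sigma_j = np.array([specs[int(g)].sigma_j for g in groups])
    if np.any(sigma_j > 0):
        schedule = apply_jitter(schedule, sigma_j, ss_jitter)

    sigma0 = spread_metric(fixed, chain.total_tau())
    gsigma0 = _group_spread(fixed, chain.total_tau(), groups)

    n_e, n_o, n_a = exp.n_e, chain_cfg.n_segments, chain_cfg.n_axons
    times = np.array([(k + 1) * T_e for k in range(n_e)])
    sig = np.full(n_e, np.nan)
    gsig: dict[int, np.ndarray] = {g: np.full(n_e, np.nan) for g in gsigma0}
    mean_M = np.zeros((n_e, n_o, n_a)) if record_traces else None
    mean_tau = np.zeros((n_e, n_o, n_a)) if record_traces else None
    lam_R_trace = np.zeros((n_e, n_o)) if record_traces else None

    boundaries = [t_start + (k + 1) * T_e for k in range(n_e)]
    if warmup > 0:
        boundaries = [t_start] + boundaries  # sync point at freeze release

    def record(tb: float, ch: ChainState) -> None:
        if tb < t_start + 0.5 * T_e:  # warm-up release point: just reset
            for seg in ch.segments:
                seg.reset_integrals()
            return
        k = int(round((tb - t_start) / T_e)) - 1
        tau_tot = ch.total_tau()
        sig[k] = spread_metric(fixed, tau_tot)
        for g, v in _group_spread(fixed, tau_tot, groups).items():
            if g in gsig:
                gsig[g][k] = v
        if record_traces:
            for o, seg in enumerate(ch.segments):
                mean_M[k, o] = seg.M_integral / T_e
                mean_tau[k, o] = seg.tau_integral / T_e
                lam_R_trace[k, o] = seg.lambda_R
        for seg in ch.segments:
            seg.reset_integrals()

    run_chain(
        chain,
        schedule,
        seg_params,
        kernel,
        duration=t_total,
        freeze_tau_until=t_start,
        record_times=boundaries,
        record_fn=record,
    )

    traces = {}
    if record_traces:
        traces = {"mean_M": mean_M, "mean_tau": mean_tau, "lambda_R": lam_R_trace}
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return SyncProfile(
        times=times,
        sigma_tau=sig,
        sigma_tau0=sigma0,
        sigma_D_only=float(np.std(fixed.D)),
        seed=seed_val,
        meta={"config": config, "warmup_epochs": warmup,
              "encountered_spikes": chain.encountered_spikes},
        group_sigma=gsig,
        group_sigma0=gsigma0,
        traces=traces,
    )


def _set_path(config: RunConfig, path: str, value) -> RunConfig:
    """Return a config with dotted ``section.field`` replaced by ``value``.

    The ``signal`` section applies the field to every group spec; ``kernel``
    accepts ``tau_G`` as shorthand for the single-time response.
    """
    section, name = path.split(".", 1)
    if section == "signal":
        return replace(
            config, signal=tuple(replace(s, **{name: value}) for s in config.signal)
        )
    if section == "kernel":
        if name == "tau_G":
            return replace(config, kernel=ResponseParams(tau_G=value, Q=config.kernel.Q))
        return replace(config, kernel=replace(config.kernel, **{name: value}))
    if section == "plasticity":
        return replace(config, plasticity=replace(config.plasticity, **{name: value}))
    if section == "chain":
        return replace(config, chain=replace(config.chain, **{name: value}))
    if section == "experiment":
        return replace(config, experiment=replace(config.experiment, **{name: value}))
    raise KeyError(f"unknown config section {section!r}")


def sweep(
    base: RunConfig,
    grid: Mapping[str, Sequence],
    n_r: int,
    seed: int,
    max_events: float = 5e7,
) -> list[SyncProfile]:
    """Cartesian-product parameter sweep with deterministic derived seeds.

    ``grid`` maps dotted parameter paths (e.g. ``"kernel.tau_G"``) to value
    lists.  Each (setting, trial) pair gets its own child seed of ``seed``,
    so re-running reproduces bit-identical profiles.  A rough event-count
    guard rejects sweeps whose total spike-event count exceeds
    ``max_events``.
    """
    names = list(grid)
    combos = list(itertools.product(*(grid[n] for n in names)))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(combos) * n_r)

    est = 0.0
    cfgs = []
    for combo in combos:
        cfg = base
        for n, v in zip(names, combo):
            cfg = _set_path(cfg, n, v)
        cfgs.append(cfg)
        rate = sum(
            np.sum(cfg.resolved_groups() == s.group_id) / s.tau_s
            for s in cfg.signal
        )
        est += n_r * rate * cfg.experiment.T_exp * cfg.chain.n_segments
    if est > max_events:
        raise RuntimeError(
            f"estimated {est:.2g} spike events exceeds max_events={max_events:.2g}; "
            "raise max_events to override"
        )

    profiles = []
    idx = 0
    for combo, cfg in zip(combos, cfgs):
        for r in range(n_r):
            prof = run_trial(cfg, children[idx])
            prof.meta.update(
                {"params": dict(zip(names, combo)), "trial": r, "sweep_index": idx}
            )
            profiles.append(prof)
            idx += 1
    return profiles


def profiles_to_frame(profiles: Sequence[SyncProfile]) -> pd.DataFrame:
    """Long-format table of profiles: one row per (run, epoch)."""
    rows = []
    for i, p in enumerate(profiles):
        params = p.meta.get("params", {})
        for k in range(p.n_epochs):
            rows.append(
                {
                    "run_id": i,
                    "epoch": k + 1,
                    "time_ms": p.times[k],
                    "sigma_tau_ms": p.sigma_tau[k],
                    "sigma_tau0_ms": p.sigma_tau0,
                    **params,
                }
            )
    return pd.DataFrame(rows)


def export_profiles(
    profiles: Sequence[SyncProfile], path: str | Path, manifest: str | Path | None = None
) -> None:
    """Write profiles as tab-delimited text, plus a parameter manifest."""
    frame = profiles_to_frame(profiles)
    frame.to_csv(path, sep="\t", index=False)
    if manifest is not None:
        rows = [
            {"run_id": i, "seed": p.seed, **p.meta.get("params", {})}
            for i, p in enumerate(profiles)
        ]
        pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
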