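"""Synthesis of per-axon spike trains from renewal processes.

Two inter-spike-interval (ISI) families are supported: a refractory Poisson
process (ISI = t_R + Exponential with mean tau_s - t_R, so the mean ISI is
tau_s regardless of the refractory period) and regular spiking at constant
intervals tau_s.  Axons may carry mutually independent trains or be
time-locked: a time-locked group shares a single base train, and each axon
sees it shifted by its fixed delay.  Gaussian jitter, applied independently
per axon and per spike, degrades the locking.

All randomness flows through :class:`numpy.random.SeedSequence` children
spawned from a master seed, one stream per axon (plus one per group for the
shared base trains), so enlarging a bundle never perturbs existing trains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Family",
    "Correlation",
    "SignalSpec",
    "FixedDelays",
    "SpikeSchedule",
    "generate_base_train",
    "generate_bundle",
    "apply_jitter",
    "normalize_fixed_delays",
    "draw_fixed_delays",
    "export_schedule",
    "import_schedule",
]


class Family(str, Enum):
    """ISI distribution family of a renewal process."""

    poisson_refractory = "poisson_refractory"
    regular = "regular"


class Correlation(str, Enum):
    """Cross-axon temporal structure of a signal group."""

    independent = "independent"
    time_locked = "time_locked"


@dataclass(frozen=True)
class SignalSpec:
    """Parameters of the renewal process driving one group of axons.

    Parameters
    ----------
    family:
        ISI family (refractory Poisson or regular).
    tau_s:
        Mean inter-spike interval, ms (the firing rate is ``1/tau_s``).
    t_R:
        Absolute refractory period for the refractory Poisson family, ms.
    sigma_j:
        SD of the Gaussian spike-time jitter, ms.
    sigma_s:
        Percent firing-rate variability across axons (each axon's tau_s is
        drawn once per run from ``N(tau_s, sigma_s/100 * tau_s)``).
    correlation:
        Whether axons in the group are independent or time-locked.
    group_id:
        Integer label used in mixed-signal bundles.
    duration:
        Total simulated time, ms; spikes live in ``[0, duration]``.
    """

    family: Family = Family.poisson_refractory
    tau_s: float = 100.0
    t_R: float = 0.0
    sigma_j: float = 0.0
    sigma_s: float = 0.0
    correlation: Correlation = Correlation.time_locked
    group_id: int = 0
    duration: float = 1e5

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "correlation", Correlation(self.correlation))
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.t_R < 0:
            raise ValueError("t_R must be non-negative")
        if self.family is Family.poisson_refractory and self.t_R >= self.tau_s:
            raise ValueError(
                "refractory period t_R must be below tau_s for the refractory "
                "Poisson family (mean rate not realizable otherwise)"
            )
        if self.sigma_j < 0 or self.sigma_s < 0:
            raise ValueError("sigma_j and sigma_s must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class FixedDelays:
    """Per-axon non-modifiable source-side delays D_a (ms).

    ``sigma_D`` records the target population spread; after
    :func:`normalize_fixed_delays` the population SD of ``D`` equals it
    exactly.  ``D_mean`` is an arbitrary positivity offset (zero for
    normalized delays; only the spread matters for synchrony).
    """

    D: np.ndarray
    sigma_D: float
    D_mean: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "D", np.asarray(self.D, dtype=float))
        if self.D.ndim != 1:
            raise ValueError("D must be a 1-D vector of per-axon delays")

    @property
    def n_axons(self) -> int:
        return self.D.size


@dataclass
class SpikeSchedule:
    """Per-axon sorted spike times with group provenance.

    ``trains[a]`` is a strictly-increasing array of spike times (ms) on axon
    ``a``; ``groups[a]`` the group label; ``mean_rates[a]`` the realized mean
    firing rate (1/ms) over the schedule duration.
    """

    trains: list[np.ndarray]
    duration: float
    groups: np.ndarray = field(default=None)  # type: ignore[assignment]
    mean_rates: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        if self.groups is None:
            self.groups = np.zeros(len(self.trains), dtype=int)
        self.groups = np.asarray(self.groups, dtype=int)
        if self.mean_rates is None:
            self.mean_rates = np.array(
                [t.size / self.duration for t in self.trains]
            )
        for t in self.trains:
            if t.size and (t[0] < 0 or t[-1] > self.duration):
                raise ValueError("spike times must lie in [0, duration]")
            if np.any(np.diff(t) < 0):
                raise ValueError("spike times must be sorted per axon")

    @property
    def n_axons(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))


def generate_base_train(
    spec: SignalSpec, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Draw one spike train on ``[0, spec.duration]`` from the renewal process.

    For ``regular``, spikes sit on the deterministic grid
    ``tau_s, 2 tau_s, ... <= duration``.  For ``poisson_refractory``, ISIs are
    ``t_R + Exponential(mean = tau_s - t_R)`` so the mean ISI equals tau_s.
    """
    if spec.family is Family.regular:
        n = int(np.floor(spec.duration / spec.tau_s))
        return spec.tau_s * np.arange(1, n + 1)

    rng = np.random.default_rng(seed)
    # Draw ISIs in blocks until the cumulative time exceeds the duration.
    mean_exp = spec.tau_s - spec.t_R
    block = max(16, int(1.25 * spec.duration / spec.tau_s) + 16)
    times: list[np.ndarray] = []
    t_last = 0.0
    while t_last <= spec.duration:
        isis = spec.t_R + rng.exponential(mean_exp, size=block)
        cum = t_last + np.cumsum(isis)
        times.append(cum)
        t_last = cum[-1]
    all_times = np.concatenate(times)
    return all_times[all_times <= spec.duration]


def _axon_streams(
    seed: int | np.random.SeedSequence, n: int
) -> list[np.random.SeedSequence]:
    """First ``n`` child streams of a master seed (stable under growth of n)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ss.spawn(n)


def generate_bundle(
    spec_per_group: Mapping[int, SignalSpec] | Sequence[SignalSpec],
    axon_groups: Sequence[int],
    fixed: FixedDelays,
    seed: int | np.random.SeedSequence,
) -> SpikeSchedule:
    """Synthesize a bundle of ``NA`` spike trains from per-group specs.

    ``axon_groups[a]`` names the group of axon ``a``; every group must have a
    spec.  Time-locked groups share one base train, shifted per axon by its
    fixed delay; independent groups draw fully independent trains (with the
    fixed delay likewise added, so a downstream observer sees the same mean
    latency structure).  Jitter is *not* applied here — see
    :func:`apply_jitter`.
    """
    groups = np.asarray(axon_groups, dtype=int)
    n_axons = groups.size
    if n_axons != fixed.n_axons:
        raise ValueError("axon_groups length must match fixed-delay vector")
    if isinstance(spec_per_group, Mapping):
        specs = dict(spec_per_group)
    else:
        specs = {s.group_id: s for s in spec_per_group}
    missing = set(np.unique(groups)) - set(specs)
    if missing:
        raise ValueError(f"no SignalSpec for groups {sorted(missing)}")
    if len(specs) != len({g for g in specs}):
        raise ValueError("overlapping group assignments in spec_per_group")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    # Stable stream layout: one child per axon, then one per group id drawn
    # from a disjoint tail so adding axons never reuses group entropy.
    axon_ss = ss.spawn(n_axons)
    group_ids = sorted(specs)
    group_ss = {g: s for g, s in zip(group_ids, ss.spawn(n_axons + len(group_ids))[n_axons:])}

    duration = max(s.duration for s in specs.values())
    base_trains = {
        g: generate_base_train(specs[g], group_ss[g])
        for g in group_ids
        if specs[g].correlation is Correlation.time_locked
    }

    trains: list[np.ndarray] = []
    for a in range(n_axons):
        spec = specs[int(groups[a])]
        rng = np.random.default_rng(axon_ss[a])
        if spec.correlation is Correlation.time_locked:
            t = base_trains[int(groups[a])]
            if spec.sigma_s > 0:
                # Per-axon rate heterogeneity: rescale the shared train so the
                # axon's mean ISI is tau_s_a while locking degrades smoothly.
                tau_a = rng.normal(spec.tau_s, spec.sigma_s / 100.0 * spec.tau_s)
                tau_a = max(tau_a, 0.05 * spec.tau_s)
                t = t * (tau_a / spec.tau_s)
            t = t + fixed.D[a]
        else:
            if spec.sigma_s > 0:
                tau_a = rng.normal(spec.tau_s, spec.sigma_s / 100.0 * spec.tau_s)
                tau_a = max(tau_a, max(0.05 * spec.tau_s, spec.t_R * 1.01))
                spec_a = replace(spec, tau_s=tau_a)
            else:
                spec_a = spec
            t = generate_base_train(spec_a, axon_ss[a]) + fixed.D[a]
        t = t[(t >= 0.0) & (t <= duration)]
        trains.append(t)

    return SpikeSchedule(trains=trains, duration=duration, groups=groups)


def apply_jitter(
    schedule: SpikeSchedule,
    sigma_j: float | np.ndarray,
    seed: int | np.random.SeedSequence,
) -> SpikeSchedule:
    """Shift every spike independently by ``N(0, sigma_j)`` (ms).

    ``sigma_j`` may be a scalar or a per-axon vector (mixed bundles whose
    groups carry different jitter levels).  Jitter is independent across
    axons even for time-locked groups.  Output trains are re-sorted; spikes
    jittered outside ``[0, duration]`` are dropped.  ``sigma_j = 0`` is the
    identity.
    """
    sig = np.broadcast_to(
        np.asarray(sigma_j, dtype=float), (schedule.n_axons,)
    )
    if np.any(sig < 0):
        raise ValueError("sigma_j must be non-negative")
    if np.all(sig == 0):
        return SpikeSchedule(
            trains=[t.copy() for t in schedule.trains],
            duration=schedule.duration,
            groups=schedule.groups.copy(),
        )
    streams = _axon_streams(seed, schedule.n_axons)
    trains = []
    for t, s, sj in zip(schedule.trains, streams, sig):
        if sj == 0:
            trains.append(t.copy())
            continue
        rng = np.random.default_rng(s)
        tj = np.sort(t + rng.normal(0.0, sj, size=t.size))
        trains.append(tj[(tj >= 0.0) & (tj <= schedule.duration)])
    return SpikeSchedule(
        trains=trains, duration=schedule.duration, groups=schedule.groups.copy()
    )


def normalize_fixed_delays(D: np.ndarray | Iterable[float], sigma_D: float) -> FixedDelays:
    """Rescale mean-centered delays so their population SD is exactly sigma_D.

    Implements ``D_norm = sigma_D * D / SD(D)`` with the population SD
    (divisor N).  All-equal delays (zero SD) are rejected.
    """
    D = np.asarray(D, dtype=float)
    sd = float(np.std(D))
    if sd == 0.0:
        raise ValueError("cannot normalize all-equal fixed delays (zero SD)")
    return FixedDelays(D=sigma_D * D / sd, sigma_D=sigma_D, D_mean=0.0)


def draw_fixed_delays(
    n_axons: int, sigma_D: float, seed: int | np.random.SeedSequence
) -> FixedDelays:
    """Draw ``N(0, sigma_D)`` delays and normalize their spread to sigma_D."""
    rng = np.random.default_rng(seed)
    D = rng.normal(0.0, sigma_D, size=n_axons)
    D = D - D.mean()
    return normalize_fixed_delays(D, sigma_D)


def export_schedule(schedule: SpikeSchedule, path: str | Path) -> None:
    """Write a schedule as two-column delimited text (axon index, time in ms)."""
    with open(path, "w") as fh:
        fh.write("axon\ttime_ms\n")
        for a, t in enumerate(schedule.trains):
            for x in t:
                fh.write(f"{a}\t{x:.8g}\n")


def import_schedule(path: str | Path, duration: float | None = None) -> SpikeSchedule:
    """Read a schedule written by :func:`export_schedule`."""
    data = np.loadtxt(path, skiprows=1, ndmin=2)
    if data.size == 0:
        raise ValueError("empty schedule file")
    axons = data[:, 0].astype(int)
    times = data[:, 1]
    n_axons = int(axons.max()) + 1
    trains = [np.sort(times[axons == a]) for a in range(n_axons)]
    if duration is None:
        duration = float(times.max())
    return SpikeSchedule(trains=trains, duration=duration)
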