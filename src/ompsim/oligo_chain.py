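"""Event-driven simulation of the oligodendrocyte chain.

A bundle of ``N_A`` axons passes through ``N_O`` effective-oligodendrocyte
segments in series.  A spike entering the bundle at time t reaches segment 1
at t, segment o+1 at its arrival at segment o plus the local delay
``tau_a(o)`` read at that arrival instant (causal, frozen per traversal),
and the target after the last segment's delay.  Every arrival triggers the
segment's global-signal impulse and plasticity update at that instant.

The fixed source-side delays are part of the spike schedule itself
(time-locked trains are shifted copies of one base train), so routing adds
no extra offset; the synchrony metric combines the fixed-delay vector with
the summed adaptive delays separately.

Events are processed from a single priority queue ordered by
(time, segment, axon) — ascending segment then axon breaks wall-time ties
deterministically.  Between events each segment's state is advanced lazily,
only when its next event (or a recording boundary) arrives.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .global_signal import GlobalState, ResponseParams, apply_spike_impulse
from .segment_dynamics import (
    OMPParams,
    SegmentState,
    evolve_between_spikes,
    spike_update,
)
from .spike_gen import SpikeSchedule

__all__ = ["ChainConfig", "ChainState", "route_spike", "run_chain", "export_arrivals"]


@dataclass(frozen=True)
class ChainConfig:
    """Geometry of the chain: segment count, axon count, myelination matrix.

    The myelination matrix (segments x axons, non-negative integers) is
    stored and validated for generality, but the v1 dynamics are defined for
    full connectivity only — an all-ones matrix; anything else is rejected
    rather than silently partially honored.
    """

    n_segments: int
    n_axons: int
    myelination_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.n_axons < 2:
            raise ValueError("n_axons must be >= 2")
        m = self.myelination_matrix
        if m is None:
            m = np.ones((self.n_segments, self.n_axons), dtype=int)
        m = np.asarray(m)
        if m.shape != (self.n_segments, self.n_axons):
            raise ValueError("myelination matrix must be n_segments x n_axons")
        if np.any(m < 0) or not np.issubdtype(m.dtype, np.integer):
            raise ValueError("myelination matrix entries must be non-negative integers")
        object.__setattr__(self, "myelination_matrix", m)
        if not np.all(m == 1):
            raise NotImplementedError(
                "chain dynamics are implemented for the all-ones myelination "
                "matrix only (full connectivity)"
            )


@dataclass
class ChainState:
    """Ordered segment states plus bookkeeping of the last run."""

    segments: list[SegmentState]
    encountered_spikes: int = 0  # total segment arrivals processed
    arrivals: list[tuple[int, float, float]] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def total_tau(self) -> np.ndarray:
        """Per-axon total adaptive delay, sum of local delays over segments."""
        return np.sum([s.tau for s in self.segments], axis=0)


def route_spike(
    chain: ChainState | Sequence[np.ndarray],
    axon: int,
    source_time: float,
    fixed_delay: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Arrival times of one spike at each segment, and at the target.

    Uses the current local delays as a frozen snapshot: arrival at segment 1
    is ``source_time + fixed_delay``; each subsequent arrival adds the
    previous segment's local delay for this axon.  Diagnostic helper — the
    dynamic simulation (:func:`run_chain`) recomputes delays at each
    arrival as plasticity evolves.
    """
    taus = (
        [s.tau for s in chain.segments] if isinstance(chain, ChainState) else chain
    )
    t = source_time + fixed_delay
    if t < 0:
        raise ValueError("negative entry time")
    arrivals = np.empty(len(taus))
    for o, tau_o in enumerate(taus):
        arrivals[o] = t
        t += float(tau_o[axon])
    return arrivals, t


def run_chain(
    chain: ChainState,
    schedule: SpikeSchedule,
    params: OMPParams,
    kernel: ResponseParams,
    duration: float,
    freeze_tau_until: float = 0.0,
    record_times: Sequence[float] = (),
    record_fn: Callable[[float, ChainState], None] | None = None,
) -> ChainState:
    """Drive the chain with a spike schedule over ``[0, duration]`` (in place).

    ``params`` must already be per-segment scaled.  At each recording time
    all segments are synchronized to that instant and ``record_fn(t, chain)``
    is invoked (for synchrony snapshots and epoch means).  Spikes still in
    flight past ``duration`` are dropped.  Target arrivals are appended to
    ``chain.arrivals`` as ``(axon, source_time, target_time)``.
    """
    n_seg = chain.n_segments
    segments = chain.segments
    heap: list[tuple[float, int, int, float]] = []
    for a, train in enumerate(schedule.trains):
        for t in train:
            if t <= duration:
                heap.append((float(t), 0, a, float(t)))
    heapq.heapify(heap)

    boundaries = sorted(float(t) for t in record_times)
    b_idx = 0
    push = heapq.heappush
    pop = heapq.heappop

    def sync_all(to: float) -> None:
        for seg in segments:
            dt = to - seg.g.t
            if dt > 0:
                evolve_between_spikes(
                    seg, dt, params, kernel=kernel,
                    freeze_tau=seg.g.t < freeze_tau_until,
                )

    while heap or b_idx < len(boundaries):
        if heap:
            t_next = heap[0][0]
        else:
            t_next = np.inf
        while b_idx < len(boundaries) and boundaries[b_idx] <= t_next:
            tb = boundaries[b_idx]
            sync_all(tb)
            if record_fn is not None:
                record_fn(tb, chain)
            b_idx += 1
        if not heap:
            break
        t, o, a, t_src = pop(heap)
        if t > duration:
            continue
        seg = segments[o]
        dt = t - seg.g.t
        if dt < -1e-9:
            raise RuntimeError("event-queue time regression")
        frozen = t < freeze_tau_until
        if dt > 0:
            evolve_between_spikes(seg, dt, params, kernel=kernel, freeze_tau=frozen)
        local_tau = float(seg.tau[a])  # frozen for this traversal
        seg.g.v += kernel.q_s  # spike impulse; G continuous (R(0)=0)
        spike_update(seg, a, params, freeze_tau=frozen)
        chain.encountered_spikes += 1
        t_out = t + local_tau
        if o + 1 < n_seg:
            push(heap, (t_out, o + 1, a, t_src))
        else:
            chain.arrivals.append((a, t_src, t_out))
    return chain


def export_arrivals(chain: ChainState, path: str | Path) -> None:
    """Write the target-arrival log as delimited text."""
    with open(path, "w") as fh:
        fh.write("axon\tsource_time_ms\ttarget_time_ms\n")
        for a, t_src, t_tgt in chain.arrivals:
            fh.write(f"{a}\t{t_src:.8g}\t{t_tgt:.8g}\n")
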