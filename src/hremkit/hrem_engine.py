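"""Coupled-replica engine: exchange criterion, adaptive phase, and the three
sampling protocols (single long chain, replicate swarm, HREM) at matched budget.

Replica bookkeeping follows the scaling-factor-exchange convention: an
accepted swap moves the scaling factors between the two walkers, so a walker
(replica) is a trajectory wandering through the ladder of scaled Hamiltonians
while each *node* (fixed scaling factor) always holds exactly one walker.
Internally the state is stored node-indexed, where the same move is a swap of
configurations and walker ids between the two node slots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .ladder import (AcceptanceStats, AdaptiveConfig, InstabilityError,
                     ScalingLadder, adaptive_update, reset_on_instability)
from .model_systems import BasinPartition, ModelSystem, ThermoState, sample_chain


@dataclass(frozen=True)
class ExchangeSchedule:
    """When to attempt exchanges and how long to run.

    ``total_steps`` is the per-replica Metropolis step budget; one exchange
    sweep over alternating even/odd contiguous pairs runs every
    ``attempt_interval`` steps.  ``record_interval`` (in steps, a multiple of
    ``attempt_interval``) sets the stride of the coordinate/occupancy record.
    """

    total_steps: int
    attempt_interval: int = 25
    record_interval: int | None = None

    def __post_init__(self):
        if self.attempt_interval < 1:
            raise ValueError("attempt_interval must be >= 1")
        if self.total_steps < self.attempt_interval:
            raise ValueError("total_steps must cover at least one exchange sweep")
        rec = self.record_interval or self.attempt_interval
        if rec % self.attempt_interval:
            raise ValueError("record_interval must be a multiple of attempt_interval")
        object.__setattr__(self, "record_interval", rec)

    @property
    def n_sweeps(self) -> int:
        return self.total_steps // self.attempt_interval

    @property
    def record_stride(self) -> int:
        """Record stride in sweeps."""
        return self.record_interval // self.attempt_interval


@dataclass
class HREMRun:
    """Joint record of an HREM simulation.

    ``walker_by_node[t, k]`` is the walker id occupying node k at recorded
    sweep t; ``coords_by_node[t, k]`` the coordinate held there.  The exchange
    log is a dict of flat arrays (sweep, pair, delta, accepted, s_k, s_k1).
    """

    system: str
    ladder: ScalingLadder
    ladder_history: list
    schedule: ExchangeSchedule
    thermo: ThermoState
    seed: int
    walker_by_node: np.ndarray
    coords_by_node: np.ndarray
    exchange_log: dict
    adaptive_stats: list
    production_stats: AcceptanceStats
    reset_events: list
    n_adaptive_sweeps: int

    @property
    def n_replicas(self) -> int:
        return self.ladder.n

    def node_of_replica(self) -> np.ndarray:
        """(T, n) array: node index occupied by each walker at each record."""
        return np.argsort(self.walker_by_node, axis=1, kind="stable")

    def target_state_trajectory(self) -> np.ndarray:
        """Coordinate series at the unscaled node s = 1 (Boltzmann at the target)."""
        return self.coords_by_node[:, 0]

    def replica_trajectory(self, walker: int) -> np.ndarray:
        """Coordinate series followed by one walker across the ladder."""
        nodes = self.node_of_replica()[:, walker]
        return self.coords_by_node[np.arange(len(nodes)), nodes]

    @property
    def total_steps(self) -> int:
        """Total sampler steps over all replicas (the CPU-budget currency)."""
        return self.schedule.total_steps * self.n_replicas


@dataclass
class ReplicateSet:
    """m independent single-chain trajectories of identical length."""

    system: str
    seeds: list
    steps_each: int
    record_interval: int
    trajectories: list

    def __post_init__(self):
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("replicate seeds must be pairwise distinct")

    @property
    def m(self) -> int:
        return len(self.trajectories)

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.trajectories)

    @property
    def total_steps(self) -> int:
        return self.m * self.steps_each


def exchange_delta(beta: float, s_k: float, s_k1: float, u_a: float, u_b: float) -> float:
    """Metropolis exponent for the k <-> k+1 scaling swap.

    Delta = beta (s_k - s_k1)(U_b - U_a) with U_a the unscaled energy of the
    configuration at node k and U_b at node k+1; accept with min(1, e^-Delta).
    """
    return beta * (s_k - s_k1) * (u_b - u_a)


def spawn_seeds(master: int, n: int) -> np.ndarray:
    """Derive n independent sub-seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(master)
    return (ss.generate_state(n) % (2**31 - 1)).astype(np.int64)


def run_hrem(system: ModelSystem, ladder: ScalingLadder, schedule: ExchangeSchedule,
             thermo: ThermoState, adaptive: AdaptiveConfig | None = None,
             seed: int = 0) -> HREMRun:
    """Run n coupled chains over the ladder with periodic exchange sweeps.

    Chain k targets exp(-beta s_k U).  With ``adaptive`` set, the first
    ``n_iterations * window_sweeps`` sweeps form the adaptive phase (default:
    the first 10% of the run split into n_iterations windows); after each
    window the ladder is updated from that window's acceptance statistics and
    the ladder is frozen afterwards.  An instability during adaptation resets
    to the geometric ladder with reduced gain and continues (the event is
    recorded).  Fully deterministic given ``seed``.
    """
    n = ladder.n
    pot = system.potential
    kind, a, b, c, lo, hi = pot.kernel_params()
    beta = thermo.beta
    bath_var = system.bath.total_var if system.bath is not None else 0.0
    n_sweeps = schedule.n_sweeps
    stride = schedule.record_stride

    if n == 1:
        # degenerate single-state ladder: plain chain, no exchange machinery
        coords = sample_chain(pot, thermo, s=1.0, n_steps=schedule.total_steps,
                              step_size=system.step_size, seed=seed, x0=system.x0,
                              record_interval=schedule.record_interval)
        T = len(coords)
        return HREMRun(system=system.name, ladder=ladder, ladder_history=[ladder],
                       schedule=schedule, thermo=thermo, seed=seed,
                       walker_by_node=np.zeros((T, 1), dtype=np.int8),
                       coords_by_node=coords[:, None],
                       exchange_log={k: np.empty(0) for k in
                                     ("sweep", "pair", "delta", "accepted", "s_k", "s_k1")},
                       adaptive_stats=[], production_stats=AcceptanceStats(
                           attempts=np.zeros(0, dtype=np.int64),
                           accepts=np.zeros(0, dtype=np.int64)),
                       reset_events=[], n_adaptive_sweeps=0)

    if adaptive is not None:
        window = adaptive.window_sweeps or max(1, n_sweeps // (10 * adaptive.n_iterations))
        n_adaptive = adaptive.n_iterations * window
        if n_adaptive > n_sweeps:
            raise ValueError(f"adaptive phase ({n_adaptive} sweeps) exceeds the run "
                             f"({n_sweeps} sweeps)")
    else:
        window = 0
        n_adaptive = 0

    # node-indexed state
    x = np.full(n, float(system.x0))
    u = np.array([float(pot.energy(xi)) for xi in x])
    walker = np.arange(n, dtype=np.int8)
    current = ladder
    config = adaptive
    history = [current]
    resets = []
    adaptive_stats = []

    walker_rec = np.empty((n_sweeps, n), dtype=np.int8)
    coord_rec = np.empty((n_sweeps, n))
    max_log = (n // 2 + 1) * n_sweeps
    ex_sweep = np.empty(max_log, dtype=np.int64)
    ex_pair = np.empty(max_log, dtype=np.int16)
    ex_delta = np.empty(max_log)
    ex_acc = np.empty(max_log, dtype=np.int8)
    log_s_k = np.empty(max_log)
    log_s_k1 = np.empty(max_log)

    seeds = spawn_seeds(seed, (adaptive.n_iterations if adaptive else 0) + 1)
    done = 0
    m_total = 0

    def run_block(block_sweeps, block_seed):
        nonlocal done, m_total
        s_arr = current.as_array()
        attempts = np.zeros(n - 1, dtype=np.int64)
        accepts = np.zeros(n - 1, dtype=np.int64)
        m = _kernels.run_hrem_block(
            kind, a, b, c, lo, hi, beta, s_arr, x, u, walker,
            bath_var, done, block_sweeps, schedule.attempt_interval,
            system.step_size, int(block_seed),
            walker_rec[done:done + block_sweeps], coord_rec[done:done + block_sweeps],
            ex_sweep[m_total:], ex_pair[m_total:], ex_delta[m_total:], ex_acc[m_total:],
            attempts, accepts)
        pairs = ex_pair[m_total:m_total + m]
        log_s_k[m_total:m_total + m] = s_arr[pairs]
        log_s_k1[m_total:m_total + m] = s_arr[pairs + 1]
        done += block_sweeps
        m_total += m
        return AcceptanceStats(attempts=attempts, accepts=accepts)

    for it in range(adaptive.n_iterations if adaptive else 0):
        stats = run_block(window, seeds[it])
        adaptive_stats.append(stats)
        try:
            current = adaptive_update(current, stats, config.c)
        except InstabilityError:
            current, config = reset_on_instability(current, config)
            resets.append({"sweep": done, "iteration": it, "new_c": config.c})
        history.append(current)
        if config.sigma_threshold and stats.sd < config.sigma_threshold:
            break

    production_stats = run_block(n_sweeps - done, seeds[-1])

    log = {
        "sweep": ex_sweep[:m_total].copy(),
        "pair": ex_pair[:m_total].astype(np.int64),
        "delta": ex_delta[:m_total].copy(),
        "accepted": ex_acc[:m_total].astype(np.int64),
        "s_k": log_s_k[:m_total].copy(),
        "s_k1": log_s_k1[:m_total].copy(),
    }
    return HREMRun(system=system.name, ladder=current, ladder_history=history,
                   schedule=schedule, thermo=thermo, seed=seed,
                   walker_by_node=walker_rec[::stride].copy(),
                   coords_by_node=coord_rec[::stride].copy(),
                   exchange_log=log, adaptive_stats=adaptive_stats,
                   production_stats=production_stats, reset_events=resets,
                   n_adaptive_sweeps=n_adaptive)


def run_replicates(system: ModelSystem, thermo: ThermoState, m: int, steps_each: int,
                   base_seed: int = 0, record_interval: int = 1) -> ReplicateSet:
    """m independent plain chains with distinct derived seeds."""
    if m < 1:
        raise ValueError("need at least one replicate")
    seeds = [int(base_seed) + i + 1 for i in range(m)]
    trajs = [sample_chain(system.potential, thermo, s=1.0, n_steps=steps_each,
                          step_size=system.step_size, seed=sd, x0=system.x0,
                          record_interval=record_interval)
             for sd in seeds]
    return ReplicateSet(system=system.name, seeds=seeds, steps_each=steps_each,
                        record_interval=record_interval, trajectories=trajs)


def count_basin_transitions(traj: np.ndarray, basins: BasinPartition) -> int:
    """Number of basin-label changes after dropping unlabelled (barrier) points."""
    labels = basins.classify(np.asarray(traj))
    labels = labels[labels >= 0]
    if labels.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(labels)))


def run_discrete_pair(energies, beta: float, s_pair, n_sweeps: int, seed: int = 0) -> np.ndarray:
    """Two-replica HREM on a discrete state space; returns joint visit counts.

    A validation workhorse: the stationary joint law of (state at node 0,
    state at node 1) is the exactly enumerable product of the two scaled
    Boltzmann distributions, so detailed balance of the full exchange kernel
    can be tested against closed-form expectations.
    """
    energies = np.asarray(energies, dtype=float)
    s0, s1 = s_pair
    return _kernels.run_discrete_pair(energies, float(beta), float(s0), float(s1),
                                      int(n_sweeps), int(seed) % 2**31)
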