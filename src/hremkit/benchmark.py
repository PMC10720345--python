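"""Equal-budget comparison of the three sampling protocols on a model system.

Protocols: a single long chain, a swarm of m independent short replicates,
and HREM (optionally with the adaptive acceptance-equalization phase).  The
report per protocol: basin-transition counts, per-basin sample counts and
occupancies with block SEs, basin free-energy differences against the
quadrature truth, and the RMS error of the PMF against the quadrature
reference on the same bins.

Budget accounting: with ``budget_mode="total"`` every protocol burns the same
total number of sampler steps (HREM n x S, single n x S, replicates
m x (n S / m)); with ``budget_mode="target"`` the single chain and the
replicate pool are granted only the HREM target-state budget S, the honest
comparison when only target-state samples are analyzed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hrem_engine import (ExchangeSchedule, count_basin_transitions, run_hrem,
                          run_replicates, sample_chain, spawn_seeds)
from .ladder import AdaptiveConfig, geometric_ladder
from .model_systems import ModelSystem, ThermoState, boltzmann_populations, get_system
from .pmf_analysis import basin_populations, pmf_1d


@dataclass(frozen=True)
class BenchmarkConfig:
    system: str
    n_replicas: int = 8
    s_min: float = 0.1
    target_steps: int = 100000       # per-replica sampler steps (target-state budget)
    attempt_interval: int = 10
    m_replicates: int = 8
    adaptive: bool = True
    c: float = 2.0
    n_iterations: int = 10
    budget_mode: str = "total"       # "total" | "target"
    single_steps: int | None = None  # override for the single-chain budget
    bins: int = 72
    seed: int = 0

    def __post_init__(self):
        if self.budget_mode not in ("total", "target"):
            raise ValueError("budget_mode must be 'total' or 'target'")


def _pmf_range(system: ModelSystem):
    if system.potential.periodic:
        return (-math.pi, math.pi)
    return (system.potential.r_min, system.potential.r_max)


def reference_pmf(system: ModelSystem, thermo: ThermoState, bins: int):
    """Quadrature-truth PMF on the same bins: V = -RT ln(p_bin / max p_bin)."""
    lo, hi = _pmf_range(system)
    edges = np.linspace(lo, hi, bins + 1)
    grid = np.linspace(lo, hi, bins * 50 + 1)
    u = system.potential.energy(grid)
    w = np.exp(-thermo.beta * (u - u.min()))
    idx = np.clip(np.searchsorted(edges, grid, side="right") - 1, 0, bins - 1)
    p = np.bincount(idx, weights=w, minlength=bins)
    p /= p.sum()
    v = -thermo.rt * np.log(p / p.max())
    return edges, p, v


def _analyze(tag, samples, system, thermo, bins, truth_pops, v_ref, edges):
    pops, se = basin_populations(samples, system.basins)
    counts = np.bincount(
        system.basins.classify(np.asarray(samples)).clip(min=-1) + 1,
        minlength=len(system.basins.intervals) + 1)[1:]
    pmf = pmf_1d(samples, bins=edges, thermo=thermo)
    ok = ~pmf.mask & np.isfinite(v_ref)
    rms = float(np.sqrt(np.mean((pmf.v[ok] - v_ref[ok]) ** 2))) if ok.any() else math.nan
    # free-energy gap of basin 1 relative to basin 0, sampled vs quadrature
    if pops[0] > 0 and pops[1] > 0:
        df = -thermo.rt * math.log(pops[1] / pops[0])
    else:
        df = math.nan
    df_true = -thermo.rt * math.log(truth_pops[1] / truth_pops[0])
    return {
        "protocol": tag,
        "n_samples": int(np.asarray(samples).size),
        "transitions": count_basin_transitions(samples, system.basins),
        "basin_counts": [int(x) for x in counts],
        "populations": [float(x) for x in pops],
        "population_se": [float(x) for x in se],
        "delta_f": df,
        "delta_f_true": float(df_true),
        "pmf_rms_error": rms,
    }


def run_benchmark(config: BenchmarkConfig, thermo: ThermoState | None = None) -> dict:
    """Run the three protocols and report sampling-quality metrics per protocol."""
    thermo = thermo or ThermoState()
    system = get_system(config.system, thermo)
    n = config.n_replicas
    S = config.target_steps
    total = n * S
    seeds = spawn_seeds(config.seed, 3)

    ladder = geometric_ladder(n, config.s_min)
    schedule = ExchangeSchedule(total_steps=S, attempt_interval=config.attempt_interval)
    adaptive = AdaptiveConfig(c=config.c, n_iterations=config.n_iterations) \
        if config.adaptive else None
    hrem = run_hrem(system, ladder, schedule, thermo, adaptive=adaptive, seed=int(seeds[0]))
    # discard the adaptive transient from target-state analysis
    skip = hrem.n_adaptive_sweeps // max(1, hrem.schedule.record_stride)
    target = hrem.target_state_trajectory()[skip:]

    if config.budget_mode == "total":
        single_steps = config.single_steps or total
        rep_each = total // config.m_replicates
    else:
        single_steps = config.single_steps or S
        rep_each = S // config.m_replicates
    single = sample_chain(system.potential, thermo, s=1.0, n_steps=single_steps,
                          step_size=system.step_size, seed=int(seeds[1]), x0=system.x0)
    reps = run_replicates(system, thermo, m=config.m_replicates, steps_each=rep_each,
                          base_seed=int(seeds[2]))

    truth_pops = boltzmann_populations(system.potential, thermo, system.basins)
    edges, _, v_ref = reference_pmf(system, thermo, config.bins)

    rows = [
        _analyze("single", single, system, thermo, config.bins, truth_pops, v_ref, edges),
        _analyze("replicates", reps.pooled(), system, thermo, config.bins,
                 truth_pops, v_ref, edges),
        _analyze("hrem", target, system, thermo, config.bins, truth_pops, v_ref, edges),
    ]
    rep_transitions = [count_basin_transitions(t, system.basins) for t in reps.trajectories]
    warnings_ = []
    from .diagnostics import round_trip_times
    rtt = round_trip_times(hrem.node_of_replica(), n_nodes=n)
    if rtt.n_round_trips == 0:
        warnings_.append("budget too small for any completed HREM round trip")
    return {
        "config": {k: getattr(config, k) for k in (
            "system", "n_replicas", "s_min", "target_steps", "attempt_interval",
            "m_replicates", "adaptive", "c", "n_iterations", "budget_mode",
            "single_steps", "bins", "seed")},
        "temperature_K": thermo.temperature,
        "total_steps": {"hrem": hrem.total_steps, "single": int(single_steps),
                        "replicates": reps.total_steps},
        "protocols": rows,
        "replicate_transitions": rep_transitions,
        "hrem_round_trips": rtt.n_round_trips,
        "truth_populations": [float(p) for p in truth_pops],
        "warnings": warnings_,
    }
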