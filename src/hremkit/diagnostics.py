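"""Replica-diffusion diagnostics from node-occupancy time series.

All functions consume a ``node_traj`` array of shape (T, m): the node index
(0-based, node 0 = target state, node n-1 = most scaled) occupied by each of
the m replica walkers at each recorded sweep.  Metrics:

* upward/downward flux f_u(k), f_d(k) — direct labelled-visit counting and a
  cheaper Markov first-passage (splitting-probability) estimate;
* the mean absolute deviation of f_u from the endpoint-pinned linear ideal;
* round-trip times (node 0 -> node n-1 -> node 0);
* the residence variance: the variance of per-walker node residence fractions
  relative to the ideal uniform 1/n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels


@dataclass
class FluxProfile:
    """Per-node labelled visit counts and up-flux fractions.

    ``f_u[k]`` is nan where no labelled visit was recorded; those nodes are
    excluded from the ideality deviation.
    """

    z_u: np.ndarray
    z_d: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.z_u)

    @property
    def f_u(self) -> np.ndarray:
        tot = self.z_u + self.z_d
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.z_u / tot, np.nan)

    @property
    def f_d(self) -> np.ndarray:
        return 1.0 - self.f_u


@dataclass
class DiffusionStats:
    """Completed round-trip durations (in recorded-sweep units) per walker."""

    trips: list  # one list of durations per walker

    @property
    def all_trips(self) -> np.ndarray:
        flat = [t for per in self.trips for t in per]
        return np.asarray(flat, dtype=float)

    @property
    def n_round_trips(self) -> int:
        return len(self.all_trips)

    @property
    def mean_rtt(self) -> float:
        """Mean round-trip time; nan when no trip completed (never reported as 0)."""
        t = self.all_trips
        return float(t.mean()) if t.size else math.nan


@dataclass
class ResidenceStats:
    """Per-walker node residence fractions tau[i, k] and the scalar variance."""

    tau: np.ndarray  # (m, n)

    @property
    def delta_tau_sq(self) -> float:
        """Mean over walkers and nodes of (n*tau - 1)^2; 0 at ideal uniform residence."""
        n = self.tau.shape[1]
        return float(np.mean((n * self.tau - 1.0) ** 2))


def _check_node_traj(node_traj):
    node_traj = np.asarray(node_traj)
    if node_traj.ndim == 1:
        node_traj = node_traj[:, None]
    if node_traj.ndim != 2 or node_traj.shape[0] < 1:
        raise ValueError("node_traj must be a (T, m) array with T >= 1")
    return node_traj.astype(np.int64, copy=False)


def replica_flux_counts(node_traj, n_nodes: int | None = None) -> FluxProfile:
    """Direct labelled-visit flux: z_u counts visits by walkers whose last
    extreme contact was the target node 0, z_d by those coming from node n-1.

    A walker is relabelled on arrival at an extreme before its visit is
    counted, so f_u(0) = 1 and f_u(n-1) = 0 identically; visits before the
    first extreme contact are unlabelled and counted for neither flux.
    """
    traj = _check_node_traj(node_traj)
    n = int(n_nodes or traj.max() + 1)
    T, m = traj.shape
    z_u = np.zeros(n, dtype=np.int64)
    z_d = np.zeros(n, dtype=np.int64)
    t_idx = np.arange(T)
    for i in range(m):
        col = traj[:, i]
        at0 = col == 0
        atn = col == n - 1
        last0 = np.maximum.accumulate(np.where(at0, t_idx, -1))
        lastn = np.maximum.accumulate(np.where(atn, t_idx, -1))
        up = last0 > lastn
        down = lastn > last0
        z_u += np.bincount(col[up], minlength=n)
        z_d += np.bincount(col[down], minlength=n)
    return FluxProfile(z_u=z_u, z_d=z_d)


def flux_deviation(profile: FluxProfile) -> float:
    """Mean absolute deviation of f_u(k) from the endpoint-pinned linear ideal.

    The ideal labelled-process profile of an unbiased walk is
    f_u(k) = (n-1-k)/(n-1) for 0-based k (pinned to 1 at the target node and
    0 at the most-scaled node); nodes with no labelled visit are excluded.
    """
    n = profile.n_nodes
    if n < 2:
        raise ValueError("flux deviation needs at least 2 nodes")
    f = profile.f_u
    ideal = (n - 1 - np.arange(n)) / (n - 1)
    ok = ~np.isnan(f)
    if ok.sum() < 2:
        raise ValueError("need at least 2 nodes with labelled visits")
    return float(np.mean(np.abs(f[ok] - ideal[ok])))


def _transition_counts(node_traj, n):
    traj = _check_node_traj(node_traj)
    up = np.zeros(n - 1, dtype=np.int64)      # k -> k+1
    down = np.zeros(n - 1, dtype=np.int64)    # k+1 -> k
    for i in range(traj.shape[1]):
        col = traj[:, i]
        frm, to = col[:-1], col[1:]
        step_up = to == frm + 1
        step_down = to == frm - 1
        up += np.bincount(frm[step_up], minlength=n - 1)[: n - 1]
        down += np.bincount(to[step_down], minlength=n - 1)[: n - 1]
    return up, down


def replica_flux_mfpt(node_traj, n_nodes: int | None = None) -> FluxProfile:
    """First-passage flux estimate from the node-occupancy chain.

    Estimates the nearest-neighbour (birth-death) transition probabilities of
    the occupancy chain from observed transition counts, then takes f_u(k) as
    the splitting probability of reaching node 0 before node n-1 from node k
    under the estimated chain (exact tridiagonal linear solve).  For a
    reversible occupancy chain this equals the stationary labelled fraction.
    The returned profile carries effective counts z_u = f_u * N_k, z_d =
    (1 - f_u) * N_k with N_k the number of visits to node k.
    """
    traj = _check_node_traj(node_traj)
    n = int(n_nodes or traj.max() + 1)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    up, down = _transition_counts(traj, n)
    bad = np.nonzero((up == 0) | (down == 0))[0]
    if bad.size:
        raise ValueError(f"no observed transitions on edge(s) {bad.tolist()} "
                         f"(k <-> k+1); a longer trajectory is needed")
    visits = np.bincount(traj.ravel(), minlength=n).astype(float)
    # departure probabilities from each interior node
    out_k = visits.copy()
    p_up = np.zeros(n)
    p_dn = np.zeros(n)
    p_up[:-1] = up / out_k[:-1]
    p_dn[1:] = down / out_k[1:]
    # splitting probability h(k) = P(hit 0 before n-1 | k): tridiagonal solve
    h = np.zeros(n)
    h[0] = 1.0
    if n > 2:
        A = np.zeros((n - 2, n - 2))
        rhs = np.zeros(n - 2)
        for j, k in enumerate(range(1, n - 1)):
            stay = 1.0 - p_up[k] - p_dn[k]
            A[j, j] = 1.0 - stay
            if k - 1 >= 1:
                A[j, j - 1] = -p_dn[k]
            else:
                rhs[j] += p_dn[k] * 1.0
            if k + 1 <= n - 2:
                A[j, j + 1] = -p_up[k]
        h[1:-1] = np.linalg.solve(A, rhs)
    h[-1] = 0.0
    return FluxProfile(z_u=h * visits, z_d=(1.0 - h) * visits)


def round_trip_times(node_traj, n_nodes: int | None = None) -> DiffusionStats:
    """Round trips node 0 -> node n-1 -> node 0 per walker.

    A trip starts at a visit to node 0, requires touching node n-1, and
    completes on the next return to node 0; the next trip starts there.
    Partial trips at the end of the record are discarded.
    """
    traj = _check_node_traj(node_traj)
    n = int(n_nodes or traj.max() + 1)
    trips = []
    for i in range(traj.shape[1]):
        col = traj[:, i]
        ev_t = np.nonzero((col == 0) | (col == n - 1))[0]
        per = []
        start = None
        armed = False  # True once node n-1 was touched after the trip start
        for t in ev_t:
            if col[t] == 0:
                if armed and start is not None:
                    per.append(float(t - start))
                    start = t
                    armed = False
                elif start is None:
                    start = t
            else:  # node n-1
                if start is not None:
                    armed = True
        trips.append(per)
    return DiffusionStats(trips=trips)


def residence_variance(node_traj, n_nodes: int | None = None) -> ResidenceStats:
    """Per-walker residence fractions and their variance relative to 1/n."""
    traj = _check_node_traj(node_traj)
    n = int(n_nodes or traj.max() + 1)
    T, m = traj.shape
    tau = np.empty((m, n))
    for i in range(m):
        tau[i] = np.bincount(traj[:, i], minlength=n) / T
    return ResidenceStats(tau=tau)


def synthetic_birth_death_walk(n_nodes: int, bias: float = 0.0, n_steps: int = 100000,
                               seed: int = 0, laziness: float = 0.2,
                               x0: int = 0) -> np.ndarray:
    """Synthetic lazy nearest-neighbour walk with reflecting ends (test fixture).

    ``bias`` in (-1, 1) tilts the move distribution: p_up - p_down =
    bias * (1 - laziness).  Returns a (T, 1) node trajectory.
    """
    if not -1.0 < bias < 1.0:
        raise ValueError("bias must lie in (-1, 1)")
    move = 1.0 - laziness
    p_up = move * (1.0 + bias) / 2.0
    p_dn = move * (1.0 - bias) / 2.0
    out = _kernels.birth_death_walk(int(n_nodes), p_up, p_dn, int(n_steps),
                                    int(x0), int(seed) % 2**31)
    return out[:, None]


def cyclic_occupancy_fixture(n_nodes: int, n_cycles: int = 10) -> np.ndarray:
    """Deterministic ideal-residence fixture: walker i occupies node (i+t) mod n.

    Every row is a permutation of the nodes and every walker spends exactly
    1/n of the time on each node, so the residence variance is exactly 0.
    """
    t = np.arange(n_nodes * n_cycles)[:, None]
    i = np.arange(n_nodes)[None, :]
    return (i + t) % n_nodes


def frozen_occupancy_fixture(n_nodes: int, n_sweeps: int = 100) -> np.ndarray:
    """Pathological fixture: every walker frozen on its starting node."""
    return np.tile(np.arange(n_nodes), (n_sweeps, 1))
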