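"""Scaling-ladder construction, acceptance statistics, and the adaptive update.

A Hamiltonian replica-exchange run couples n states with scaled potentials
s_1 U, ..., s_n U where s_1 = 1 > s_2 > ... > s_n = s_min.  The classic
protocol is the geometric progression s_k = s_min^((k-1)/(n-1)), which
maximises the energy-distribution overlap of contiguous states for a harmonic
ensemble.  Anharmonic systems then show strongly unbalanced per-pair
acceptances P_acc(k); the adaptive scheme implemented here iteratively
rebalances them at constant replica number:

    g_k  =  ds_k * [1 + c * sigma * (P_acc(k) - <P_acc>)]
    ds'  =  g * (1 - s_min) / sum(g)          (exact sum conservation)

Pairs accepting above the mean get a wider gap (which lowers their future
acceptance) and vice versa; corrections vanish as the spread sigma does, so a
perfectly balanced ladder is a fixed point.  If the gain c is too large a raw
gap can go non-positive; that raises :class:`InstabilityError` and the policy
is to restart from the geometric ladder with a reduced gain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np


class InstabilityError(RuntimeError):
    """The adaptive update produced a non-positive scaling gap (gain too large)."""


@dataclass(frozen=True)
class ScalingLadder:
    """Ordered scaling factors s_1 = 1 >= ... >= s_n = s_min."""

    s: tuple

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        if s.ndim != 1 or s.size < 1:
            raise ValueError("ladder needs at least one scaling factor")
        if s[0] != 1.0:
            raise ValueError(f"s[1] must be exactly 1, got {s[0]}")
        if np.any(np.diff(s) >= 0):
            raise ValueError("scaling factors must be strictly decreasing")
        if s[-1] <= 0:
            raise ValueError("s_min must be positive")

    @property
    def n(self) -> int:
        return len(self.s)

    @property
    def s_min(self) -> float:
        return self.s[-1]

    @property
    def gaps(self) -> np.ndarray:
        """The n-1 positive differences ds_k = s_k - s_{k+1}."""
        return -np.diff(np.asarray(self.s))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.s, dtype=float)


@dataclass(frozen=True)
class AdaptiveConfig:
    """Parameters of the on-the-fly acceptance-equalization scheme.

    ``c`` is the dimensionless gain; ``n_iterations`` update cycles are applied,
    one per measurement window of ``window_sweeps`` exchange sweeps (the reset
    frequency omega in attempt units is 1/window_sweeps).  ``c_backoff``
    multiplies c after an instability reset; ``sigma_threshold`` lets the
    iteration stop early once the measured spread falls below it.
    """

    c: float = 2.0
    n_iterations: int = 10
    window_sweeps: int | None = None
    sigma_threshold: float = 0.0
    c_backoff: float = 0.5

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("gain c must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.window_sweeps is not None and self.window_sweeps < 1:
            raise ValueError("window_sweeps must be >= 1")
        if not 0.0 < self.c_backoff < 1.0:
            raise ValueError("c_backoff must lie in (0, 1)")
        if self.sigma_threshold < 0:
            raise ValueError("sigma_threshold must be >= 0")


@dataclass(frozen=True)
class AcceptanceStats:
    """Per-pair exchange acceptance fractions and their mean/spread.

    Pairs with zero attempts carry P_acc = nan and are excluded from the mean
    and the (population) standard deviation; ``incomplete`` flags that case.
    """

    attempts: np.ndarray
    accepts: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.attempts, dtype=np.int64)
        k = np.asarray(self.accepts, dtype=np.int64)
        if a.shape != k.shape or a.ndim != 1:
            raise ValueError("attempts/accepts must be 1-d arrays of equal length")
        if np.any(k > a) or np.any(a < 0) or np.any(k < 0):
            raise ValueError("accepts must satisfy 0 <= accepts <= attempts")
        object.__setattr__(self, "attempts", a)
        object.__setattr__(self, "accepts", k)

    @property
    def n_pairs(self) -> int:
        return len(self.attempts)

    @property
    def p_acc(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.attempts > 0, self.accepts / self.attempts, np.nan)

    @property
    def incomplete(self) -> bool:
        return bool(np.any(self.attempts == 0))

    @property
    def mean(self) -> float:
        p = self.p_acc
        return float(np.nanmean(p)) if np.any(~np.isnan(p)) else math.nan

    @property
    def sd(self) -> float:
        """Population standard deviation of P_acc over the defined pairs."""
        p = self.p_acc[~np.isnan(self.p_acc)]
        return float(np.std(p)) if p.size else math.nan


def geometric_ladder(n: int, s_min: float) -> ScalingLadder:
    """Geometric scaling protocol s_k = s_min^((k-1)/(n-1))."""
    if n < 2:
        raise ValueError(f"a ladder needs at least 2 states, got n={n}")
    if not 0.0 < s_min < 1.0:
        raise ValueError(f"s_min must lie in (0, 1), got {s_min}")
    k = np.arange(n, dtype=float)
    s = s_min ** (k / (n - 1))
    s[0] = 1.0
    s[-1] = s_min
    return ScalingLadder(s=tuple(s))


def effective_temperature(temperature: float, s: float) -> float:
    """Effective temperature T/s of a state with scaling factor s."""
    if s <= 0:
        raise ValueError(f"scaling factor must be positive, got {s}")
    return temperature / s


def adaptive_update(ladder: ScalingLadder, stats: AcceptanceStats, c: float) -> ScalingLadder:
    """One acceptance-equalization iteration on the scaling gaps.

    Raises :class:`InstabilityError` if any corrected gap is non-positive
    (the caller should reset to the geometric ladder and lower c), and
    ``ValueError`` if any pair has zero attempts.
    """
    if stats.n_pairs != ladder.n - 1:
        raise ValueError(f"stats cover {stats.n_pairs} pairs but the ladder has {ladder.n - 1}")
    if stats.incomplete:
        raise ValueError("every pair needs at least one exchange attempt; "
                         "use a longer measurement window")
    p = stats.p_acc
    sigma = stats.sd
    mean = stats.mean
    gaps = ladder.gaps
    g = gaps * (1.0 + c * sigma * (p - mean))
    if np.any(g <= 0.0):
        raise InstabilityError(
            f"adaptive correction with c={c} produced non-positive gap(s) at "
            f"pair(s) {np.nonzero(g <= 0.0)[0] + 1}; reset the ladder and lower c")
    s_min = ladder.s_min
    g *= (1.0 - s_min) / g.sum()
    s = np.empty(ladder.n)
    s[0] = 1.0
    s[1:] = 1.0 - np.cumsum(g)
    s[-1] = s_min
    return ScalingLadder(s=tuple(s))


def reset_on_instability(ladder: ScalingLadder, config: AdaptiveConfig
                         ) -> tuple[ScalingLadder, AdaptiveConfig]:
    """Instability policy: back to the geometric ladder with a reduced gain."""
    fresh = geometric_ladder(ladder.n, ladder.s_min)
    return fresh, replace(config, c=config.c * config.c_backoff)


def acceptance_summary(exchange_log, n_pairs: int | None = None) -> AcceptanceStats:
    """Aggregate an exchange log into per-pair acceptance statistics.

    ``exchange_log`` is a mapping/record-array with integer fields ``pair``
    (0-based pair index k for the k <-> k+1 exchange) and ``accepted`` (0/1).
    Pairs without attempts are reported as missing with a warning.
    """
    pair = np.asarray(exchange_log["pair"], dtype=np.int64)
    acc = np.asarray(exchange_log["accepted"], dtype=np.int64)
    if pair.size == 0:
        raise ValueError("empty exchange log")
    if n_pairs is None:
        n_pairs = int(pair.max()) + 1
    attempts = np.bincount(pair, minlength=n_pairs)
    accepts = np.bincount(pair, weights=acc, minlength=n_pairs).astype(np.int64)
    stats = AcceptanceStats(attempts=attempts, accepts=accepts)
    if stats.incomplete:
        warnings.warn("exchange log has pair(s) with zero attempts; "
                      "their P_acc is reported as missing", stacklevel=2)
    return stats
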