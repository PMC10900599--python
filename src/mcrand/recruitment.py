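"""Poisson-gamma patient recruitment for multi-center trials.

Patients arrive at each of ``N`` centers according to a homogeneous Poisson
process whose rate is itself random across centers,
``lambda_i ~ Gamma(alpha, beta)`` (rate parametrization, so
``E[lambda_i] = alpha/beta`` and ``var[lambda_i] = alpha/beta**2``).  Centers
open at staggered activation times ``u_i ~ Uniform(a_lo, a_hi)``; a center
contributes no arrivals before its activation.  Recruitment is *competitive*:
there are no per-center quotas and the trial stops at the ``n``-th pooled
enrollment.

Under simultaneous activation the per-center count by time ``t`` is marginally
negative binomial and the final per-center sample sizes are beta-binomial;
these closed forms are exercised as distributional test oracles.

Center and region indices are 0-based throughout the in-memory API; tabular
exports use 1-based IDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialConfig",
    "RecruitmentPattern",
    "sample_center_rates",
    "sample_activation_times",
    "simulate_recruitment",
    "completion_time",
    "center_size_histogram",
    "pattern_to_frame",
]


@dataclass(frozen=True)
class TrialConfig:
    """Parameters of a multi-center trial with staggered center activation.

    Parameters
    ----------
    n : target sample size (patients).
    N : number of centers.
    G : number of geographic regions; centers are assigned to regions in
        contiguous blocks of ``N // G`` (``N`` must be divisible by ``G``).
    T : target recruitment period in days (descriptive only; the simulation
        runs until the ``n``-th enrollment regardless).
    a_lo, a_hi : bounds of the uniform center-activation window (days).
    alpha, beta : gamma hyperparameters of the center recruitment rates
        (patients/center/day; mean rate ``alpha/beta``).
    redraw_rates_per_replicate : if True (default) the rates ``lambda_i`` are
        redrawn for every simulated replicate, matching the mixed-Poisson
        marginals of the model; if False a single rate vector is drawn once
        and shared by all replicates of an experiment.
    """

    n: int
    N: int
    G: int = 1
    T: float = 365.0
    a_lo: float = 0.0
    a_hi: float = 0.0
    alpha: float = 1.0
    beta: float = 1.0
    redraw_rates_per_replicate: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 1 <= self.G <= self.N:
            raise ValueError("G must satisfy 1 <= G <= N")
        if self.N % self.G != 0:
            raise ValueError(
                "N must be divisible by G (centers are assigned to regions "
                "in equal contiguous blocks)"
            )
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not 0 <= self.a_lo <= self.a_hi:
            raise ValueError("activation window requires 0 <= a_lo <= a_hi")
        if self.T <= 0:
            raise ValueError("T must be positive")

    @property
    def region_of(self) -> np.ndarray:
        """Region index (0-based) of each center, contiguous blocks of N/G."""
        return np.repeat(np.arange(self.G), self.N // self.G)

    @property
    def mean_rate(self) -> float:
        """Mean center recruitment rate alpha/beta (patients/center/day)."""
        return self.alpha / self.beta


@dataclass(frozen=True)
class RecruitmentPattern:
    """The ordered enrollment stream of one simulated replicate.

    ``times`` are calendar days (nondecreasing); ``centers`` and ``regions``
    are 0-based indices; ``rates`` and ``activations`` are the per-center
    draws that generated the stream.
    """

    times: np.ndarray
    centers: np.ndarray
    regions: np.ndarray
    rates: np.ndarray
    activations: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.centers) == len(self.regions) == n):
            raise ValueError("times, centers, regions must have equal length")
        if len(self.rates) != len(self.activations):
            raise ValueError("rates and activations must have equal length")
        if n and np.any(np.diff(self.times) < 0):
            raise ValueError("times must be nondecreasing")
        if n and np.any(self.times < self.activations[self.centers]):
            raise ValueError("enrollment before center activation")

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def n_centers(self) -> int:
        return len(self.rates)

    def center_counts(self) -> np.ndarray:
        """Final number of patients per center, ``n_i`` (sums to n)."""
        return np.bincount(self.centers, minlength=self.n_centers)


def sample_center_rates(
    N: int, alpha: float, beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw N center recruitment rates from Gamma(shape=alpha, rate=beta)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    return rng.gamma(shape=alpha, scale=1.0 / beta, size=N)


def sample_activation_times(
    N: int, a_lo: float, a_hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw N i.i.d. Uniform(a_lo, a_hi) center activation times (days)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= a_lo <= a_hi:
        raise ValueError("requires 0 <= a_lo <= a_hi")
    if a_lo == a_hi:
        return np.full(N, float(a_lo))
    return rng.uniform(a_lo, a_hi, size=N)


def _invert_cumulative_intensity(
    rates: np.ndarray, activations: np.ndarray, target: float
) -> float:
    """Smallest t with expected pooled event count M(t) = sum_i rate_i *
    max(t - u_i, 0) equal to ``target`` (M is piecewise linear increasing)."""
    order = np.argsort(activations)
    u = activations[order]
    lam = rates[order]
    cum_rate = np.cumsum(lam)
    # expected mass accrued by the time each center activates
    mass_at_u = np.concatenate(([0.0], np.cumsum(cum_rate[:-1] * np.diff(u))))
    idx = int(np.searchsorted(mass_at_u, target, side="right")) - 1
    return u[idx] + (target - mass_at_u[idx]) / cum_rate[idx]


def simulate_recruitment(
    config: TrialConfig,
    rates: Sequence[float],
    activations: Sequence[float],
    rng: np.random.Generator,
) -> RecruitmentPattern:
    """Simulate the first ``n`` pooled enrollments across all centers.

    Uses the conditional-uniform property of the Poisson process: per center,
    the number of arrivals on a window is Poisson and, given the count, the
    arrival times are i.i.d. uniform on the window.  The horizon is extended
    adaptively until at least ``n`` pooled events exist, the pooled stream is
    sorted, and the first ``n`` events are retained.  Exact floating-point
    time ties (a null event for continuous times) are broken by ascending
    center index.
    """
    rates = np.asarray(rates, dtype=float)
    activations = np.asarray(activations, dtype=float)
    if rates.shape != (config.N,) or activations.shape != (config.N,):
        raise ValueError("rates and activations must have shape (N,)")
    if np.any(rates <= 0):
        raise ValueError("rates must all be positive")
    if np.any(activations < 0):
        raise ValueError("activations must all be >= 0")

    n, N = config.n, config.N
    # horizon covering the expected n-th event plus a 4-sigma cushion
    target = n + 4.0 * np.sqrt(n) + 10.0
    t_prev = 0.0
    t_hi = _invert_cumulative_intensity(rates, activations, target)

    all_times: list[np.ndarray] = []
    all_centers: list[np.ndarray] = []
    total = 0
    while True:
        window_lo = np.maximum(activations, t_prev)
        dur = np.maximum(t_hi - window_lo, 0.0)
        counts = rng.poisson(rates * dur)
        k = int(counts.sum())
        if k:
            lo = np.repeat(window_lo, counts)
            span = np.repeat(dur, counts)
            all_times.append(lo + rng.random(k) * span)
            all_centers.append(np.repeat(np.arange(N), counts))
            total += k
        if total >= n:
            break
        deficit = n - total
        target += deficit + 4.0 * np.sqrt(deficit) + 10.0
        t_prev = t_hi
        t_hi = _invert_cumulative_intensity(rates, activations, target)

    times = np.concatenate(all_times)
    centers = np.concatenate(all_centers)
    order = np.lexsort((centers, times))[:n]
    centers = centers[order].astype(np.int32)
    return RecruitmentPattern(
        times=times[order],
        centers=centers,
        regions=config.region_of[centers].astype(np.int32),
        rates=rates,
        activations=activations,
    )


def completion_time(pattern: RecruitmentPattern) -> float:
    """Calendar time (days) at which the n-th patient was enrolled."""
    return float(pattern.times[-1])


def center_size_histogram(patterns: Iterable[RecruitmentPattern]) -> np.ndarray:
    """Average number of centers recruiting exactly j patients, j=0,1,...

    Returns an array ``h`` with ``h[j]`` = mean over replicates of the number
    of centers whose final size is exactly ``j``; ``h.sum() == N``.
    """
    patterns = list(patterns)
    if not patterns:
        raise ValueError("need at least one pattern")
    counts = [p.center_counts() for p in patterns]
    jmax = max(int(c.max()) for c in counts)
    hist = np.zeros(jmax + 1)
    for c in counts:
        hist += np.bincount(c, minlength=jmax + 1)
    return hist / len(patterns)


def pattern_to_frame(pattern: RecruitmentPattern) -> pd.DataFrame:
    """Tabular export of an enrollment stream (1-based IDs)."""
    return pd.DataFrame(
        {
            "patient_id": np.arange(1, pattern.n + 1),
            "time_days": pattern.times,
            "center_id": pattern.centers + 1,
            "region_id": pattern.regions + 1,
        }
    )
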