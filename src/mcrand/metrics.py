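"""Balance and randomness measures for randomization sequences.

Balance is quantified through the loss — the patients-equivalent information
sacrificed to treatment imbalance under a fixed-effects normal linear model —
at trial level ``L1 = D(n)^2 / n``, region level
``L2 = sum_g D_g(n)^2 / n_g`` and center level ``L3 = sum_i D_i(n)^2 / n_i``,
with relative efficiency ``RE = 1 - L/n``; through the standard deviation of
the absolute final imbalance; through survival curves
``Pr(|imbalance| >= d)``; and through ``P_skewed``, the expected fraction of
centers (with at least 2 patients) whose allocation is more extreme than 2:1.

Randomness (a selection-bias proxy) is quantified by the expected proportion
of correct guesses of a center-level investigator under the convergence
strategy (guess the locally underrepresented arm) and under the deterministic
strategy (guess only when the next local assignment is certain), and by the
expected proportion of deterministic assignments PD (fraction of conditional
probabilities exactly 0 or 1, without regard to center).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .allocation import DesignSpec
from .recruitment import RecruitmentPattern

__all__ = [
    "DETERMINISTIC_TOL",
    "is_deterministic",
    "loss_trial",
    "loss_by_stratum",
    "relative_efficiency",
    "sd_abs_imbalance",
    "skew_fractions",
    "p_skewed",
    "pcg_convergence",
    "pcg_deterministic",
    "prop_deterministic",
    "tail_probability",
    "ReplicateMetrics",
    "MetricsSummary",
    "summarize_allocations",
]

#: Conditional probabilities are exact rationals, so boundary values are exact
#: in floating point; the tolerance only guards against degenerate rounding.
DETERMINISTIC_TOL = 1e-12

_PCGD_FAMILIES = ("center_stratified", "dbr")


def is_deterministic(phi) -> np.ndarray:
    """Elementwise indicator of a forced assignment (phi equal to 0 or 1)."""
    phi = np.asarray(phi)
    return (phi <= DETERMINISTIC_TOL) | (phi >= 1.0 - DETERMINISTIC_TOL)


def loss_trial(D_n, n: int):
    """Trial-level loss D(n)^2 / n."""
    if n <= 0:
        raise ValueError("n must be positive")
    return np.asarray(D_n, dtype=float) ** 2 / n


def loss_by_stratum(imbalances, sizes):
    """Stratum-level loss sum_s D_s^2 / n_s over strata with n_s >= 1.

    Accepts 1-D (strata,) or 2-D (replicates, strata) arrays; empty strata
    must have zero imbalance and contribute nothing.
    """
    D = np.asarray(imbalances, dtype=float)
    sz = np.asarray(sizes, dtype=float)
    if D.shape != sz.shape:
        raise ValueError("imbalances and sizes must have the same shape")
    if np.any((sz == 0) & (D != 0)):
        raise ValueError("nonzero imbalance in an empty stratum")
    contrib = np.where(sz > 0, D**2 / np.maximum(sz, 1.0), 0.0)
    return contrib.sum(axis=-1)


def relative_efficiency(L, n: int):
    """Estimation efficiency 1 - L/n relative to the perfectly balanced design."""
    if n <= 0:
        raise ValueError("n must be positive")
    L = np.asarray(L, dtype=float)
    if np.any(L < 0) or np.any(L > n):
        raise ValueError("loss must lie in [0, n]")
    return 1.0 - L / n


def sd_abs_imbalance(abs_D_values) -> float:
    """Sample standard deviation of |D(n)| across replicates."""
    v = np.asarray(abs_D_values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicates")
    return float(np.std(v, ddof=1))


def skew_fractions(center_imbalances, center_sizes) -> np.ndarray:
    """Per-replicate fraction of eligible centers with a skewed allocation.

    A center with ``n_i >= 2`` patients is *skewed* when ``|D_i|/n_i > 1/3``
    (strictly — a 2:1 split is not skewed).  Replicates without any eligible
    center yield NaN with a warning.
    """
    D = np.atleast_2d(np.asarray(center_imbalances, dtype=float))
    sz = np.atleast_2d(np.asarray(center_sizes, dtype=float))
    eligible = sz >= 2
    n_eligible = eligible.sum(axis=1)
    skewed = eligible & (np.abs(D) > sz / 3.0)
    with np.errstate(invalid="ignore"):
        frac = skewed.sum(axis=1) / n_eligible
    if np.any(n_eligible == 0):
        warnings.warn(
            "replicate(s) without any center of >= 2 patients excluded from "
            "P_skewed",
            stacklevel=2,
        )
    return frac


def p_skewed(center_imbalances, center_sizes) -> float:
    """Mean across replicates of the skewed-center fraction."""
    frac = skew_fractions(center_imbalances, center_sizes)
    return float(np.nanmean(frac))


def _center_replay(
    centers: np.ndarray, delta: np.ndarray, N: int, b1: Optional[int] = None
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Replay the per-center imbalance along each sequence.

    Returns the per-replicate convergence-strategy score (the guesser at each
    patient's own center guesses the locally underrepresented arm, random
    guess on a local tie, scoring 1 / 0.5 / 0 against the realized
    assignment) and, when ``b1`` is given, the per-replicate fraction of
    steps at which the patient's center imbalance sat at the threshold
    ``|D_i(m)| = b1`` — the steps a center-local observer knows to be forced
    under dynamic balancing.
    """
    centers = np.atleast_2d(centers)
    delta = np.atleast_2d(delta)
    R, n = centers.shape
    rows = np.arange(R)
    Dc = np.zeros((R, N), dtype=np.int64)
    score = np.zeros(R)
    forced = np.zeros(R) if b1 is not None else None
    for m in range(n):
        ci = centers[:, m]
        d = Dc[rows, ci]
        dm = delta[:, m].astype(bool)
        score += np.where(d == 0, 0.5, ((d < 0) & dm) | ((d > 0) & ~dm))
        if forced is not None:
            forced += np.abs(d) == b1
        Dc[rows, ci] = d + np.where(dm, 1, -1)
    return score / n, (forced / n if forced is not None else None)


def _pcg_convergence_batch(centers: np.ndarray, delta: np.ndarray, N: int) -> np.ndarray:
    return _center_replay(centers, delta, N)[0]


def pcg_convergence(delta: np.ndarray, pattern: RecruitmentPattern) -> float:
    """Realized correct-guess proportion of one sequence (convergence strategy)."""
    if len(delta) != pattern.n:
        raise ValueError("delta and pattern are misaligned")
    return float(
        _pcg_convergence_batch(pattern.centers[None, :], np.asarray(delta)[None, :],
                               pattern.n_centers)[0]
    )


def pcg_deterministic(
    phi,
    design_family: str,
    *,
    centers: Optional[np.ndarray] = None,
    delta: Optional[np.ndarray] = None,
    n_centers: Optional[int] = None,
    b1: Optional[int] = None,
):
    """Correct-guess proportion under the deterministic strategy.

    The guesser is an investigator at the patient's center who guesses only
    when the next assignment *in that center* is known with certainty (score
    1) and guesses at random otherwise (score 0.5).  For center-stratified
    procedures every forced assignment is recognizable from the center's own
    history, so the score is 1 exactly when phi is 0 or 1.  For dynamic
    balancing only the center-level forcings ``|D_i(m)| = b1`` are
    recognizable locally (region- and trial-triggered forcings are not), so
    only those score 1; ``centers``, ``delta``, ``n_centers`` and ``b1`` must
    then be supplied.  For unstratified, region-stratified and CRD designs the
    strategy degenerates to random guessing and the value is 0.5 by
    convention.
    """
    phi = np.asarray(phi, dtype=float)
    if design_family == "dbr":
        if centers is None or delta is None or n_centers is None or b1 is None:
            raise ValueError(
                "DBR PCG_d needs centers, delta, n_centers and b1 to replay "
                "center imbalances"
            )
        _, forced = _center_replay(centers, delta, n_centers, b1=b1)
        out = 0.5 + 0.5 * forced
        return out if phi.ndim > 1 else float(out[0])
    if design_family not in _PCGD_FAMILIES:
        if phi.ndim <= 1:
            return 0.5
        return np.full(phi.shape[0], 0.5)
    return np.where(is_deterministic(phi), 1.0, 0.5).mean(axis=-1)


def prop_deterministic(phi):
    """Fraction of assignments with conditional probability exactly 0 or 1."""
    return is_deterministic(phi).mean(axis=-1)


def tail_probability(imbalance_values, d_max: Optional[int] = None) -> np.ndarray:
    """Empirical survival curve Pr(|imbalance| >= d) for d = 0..d_max.

    ``imbalance_values`` are per-replicate nonnegative integers (|D(n)|, or a
    max over centers/regions).  The curve is nonincreasing and equals 1 at
    d = 0.
    """
    v = np.asarray(imbalance_values)
    if v.size == 0:
        raise ValueError("need at least one replicate")
    if np.any(v < 0):
        raise ValueError("imbalance values must be nonnegative")
    vmax = int(v.max())
    if d_max is None:
        d_max = vmax
    pmf = np.bincount(v.astype(np.int64), minlength=max(d_max, vmax) + 1) / v.size
    surv = 1.0 - np.concatenate(([0.0], np.cumsum(pmf)))
    surv = np.clip(surv, 0.0, 1.0)
    return surv[: d_max + 1]


# ---------------------------------------------------------------------------
# Replicate-level and aggregated containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicateMetrics:
    """All balance/randomness measures of a single allocated replicate."""

    L1: float
    L2: float
    L3: float
    RE1: float
    RE2: float
    RE3: float
    abs_D: int
    max_center_imb: int
    max_region_imb: int
    skew_fraction: float
    pcg_c: float
    pcg_d: float
    prop_det: float


@dataclass
class MetricsSummary:
    """Aggregated operating characteristics of one design over all replicates.

    ``per_replicate`` holds the full per-replicate vectors (for boxplots and
    quantiles); scalar fields are the headline aggregates; ``tail_*`` are the
    survival curves Pr(|imbalance| >= d) at the three levels.
    """

    design: str
    n_reps: int
    per_replicate: pd.DataFrame
    sd_abs_imbalance: float
    p_skewed: float
    pcg_c: float
    pcg_d: float
    prop_det: float
    tail_trial: np.ndarray
    tail_region: np.ndarray
    tail_center: np.ndarray

    def scalars(self) -> dict:
        d = {
            "SD_abs_imbalance": self.sd_abs_imbalance,
            "P_skewed": self.p_skewed,
            "PCG_c": self.pcg_c,
            "PCG_d": self.pcg_d,
            "PD": self.prop_det,
        }
        for col in ("L1", "L2", "L3", "RE1", "RE2", "RE3"):
            d[f"{col}_mean"] = float(self.per_replicate[col].mean())
            d[f"{col}_median"] = float(self.per_replicate[col].median())
        return d

    def tail_frame(self) -> pd.DataFrame:
        frames = []
        for level, curve in (
            ("trial", self.tail_trial),
            ("region", self.tail_region),
            ("center", self.tail_center),
        ):
            frames.append(
                pd.DataFrame(
                    {
                        "design": self.design,
                        "level": level,
                        "d": np.arange(len(curve)),
                        "probability": curve,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _stratum_sums(labels: np.ndarray, t: np.ndarray, S: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate signed sums and counts by stratum via a flat bincount."""
    R, n = labels.shape
    flat = (np.arange(R)[:, None] * S + labels).ravel()
    signed = np.bincount(flat, weights=t.ravel(), minlength=R * S).reshape(R, S)
    counts = np.bincount(flat, minlength=R * S).reshape(R, S)
    return signed, counts


def summarize_allocations(
    design: DesignSpec,
    delta: np.ndarray,
    phi: np.ndarray,
    centers: np.ndarray,
    regions: np.ndarray,
    N: int,
    G: int,
) -> MetricsSummary:
    """Compute every per-replicate measure and aggregate across replicates."""
    delta = np.atleast_2d(delta)
    phi = np.atleast_2d(phi)
    centers = np.atleast_2d(centers)
    regions = np.atleast_2d(regions)
    R, n = delta.shape
    t = (2 * delta.astype(np.int64) - 1).astype(float)

    Dn = t.sum(axis=1)
    Dc, nc = _stratum_sums(centers, t, N)
    Dg, ng = _stratum_sums(regions, t, G)

    L1 = loss_trial(Dn, n)
    L2 = loss_by_stratum(Dg, ng)
    L3 = loss_by_stratum(Dc, nc)

    abs_D = np.abs(Dn).astype(np.int64)
    max_c = np.abs(Dc).max(axis=1).astype(np.int64)
    max_g = np.abs(Dg).max(axis=1).astype(np.int64)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # replicate exclusion handled via nanmean
        skew = skew_fractions(Dc, nc)
    pdet = np.asarray(prop_deterministic(phi), dtype=float)
    b1 = design.b1 if design.family == "dbr" else None
    pcgc, forced = _center_replay(centers, delta, N, b1=b1)
    if design.family == "dbr":
        pcgd = 0.5 + 0.5 * forced
    else:
        pcgd = np.broadcast_to(
            np.asarray(pcg_deterministic(phi, design.family), dtype=float), (R,)
        )

    per_rep = pd.DataFrame(
        {
            "L1": L1,
            "L2": L2,
            "L3": L3,
            "RE1": relative_efficiency(L1, n),
            "RE2": relative_efficiency(L2, n),
            "RE3": relative_efficiency(L3, n),
            "abs_D": abs_D,
            "max_center_imb": max_c,
            "max_region_imb": max_g,
            "skew_fraction": skew,
            "pcg_c": pcgc,
            "pcg_d": pcgd,
            "prop_det": pdet,
        }
    )

    return MetricsSummary(
        design=design.label,
        n_reps=R,
        per_replicate=per_rep,
        sd_abs_imbalance=sd_abs_imbalance(abs_D) if R >= 2 else 0.0,
        p_skewed=float(np.nanmean(skew)),
        pcg_c=float(pcgc.mean()),
        pcg_d=float(pcgd.mean()),
        prop_det=float(pdet.mean()),
        tail_trial=tail_probability(abs_D),
        tail_region=tail_probability(max_g),
        tail_center=tail_probability(max_c),
    )
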