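"""Exact reference computations for the unstratified procedures and CRD.

Each unstratified MTI procedure is a Markov chain on the imbalance
``D in {-b..b}`` (time-inhomogeneous for the permuted block design, whose
transition kernel depends on the within-block position ``m mod 2b``).
Propagating the exact kernel gives the distribution of ``D(n)`` and the exact
expected proportion of deterministic assignments, which the test suite uses
as independent oracles for the simulation path.  Complete randomization
admits closed binomial forms.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .allocation import PROCEDURES, _F
from .metrics import DETERMINISTIC_TOL

__all__ = ["exact_imbalance_pmf", "exact_pd", "crd_sd_abs_imbalance"]


def _propagate(procedure: str, b: int, n: int):
    """Yield (states, pmf_before_step, phi_at_step) for m = 0..n-1, then final pmf."""
    states = np.arange(-b, b + 1)
    pmf = np.zeros(2 * b + 1)
    pmf[b] = 1.0
    for m in range(n):
        phi = np.asarray(_F(procedure, states, m, b), dtype=float)
        # Inadmissible states carry zero mass; clip phi to [0,1] there so the
        # kernel stays stochastic (PBD's formula can leave [0,1] off-support).
        phi = np.clip(phi, 0.0, 1.0)
        yield states, pmf.copy(), phi
        up = pmf * phi
        down = pmf * (1.0 - phi)
        new = np.zeros_like(pmf)
        new[1:] += up[:-1]
        new[:-1] += down[1:]
        pmf = new
    yield states, pmf, None


def exact_imbalance_pmf(procedure: str, b: int, n: int) -> dict[int, float]:
    """Exact distribution of the final imbalance D(n) under one procedure."""
    if procedure not in PROCEDURES:
        raise ValueError(f"procedure must be one of {PROCEDURES}")
    if b < 1 or n < 1:
        raise ValueError("require b >= 1 and n >= 1")
    for states, pmf, phi in _propagate(procedure, b, n):
        pass
    return {int(s): float(p) for s, p in zip(states, pmf)}


def exact_pd(procedure: str, b: int, n: int) -> float:
    """Exact expected proportion of deterministic assignments over n patients."""
    if procedure not in PROCEDURES:
        raise ValueError(f"procedure must be one of {PROCEDURES}")
    if b < 1 or n < 1:
        raise ValueError("require b >= 1 and n >= 1")
    acc = 0.0
    for states, pmf, phi in _propagate(procedure, b, n):
        if phi is None:
            break
        det = (phi <= DETERMINISTIC_TOL) | (phi >= 1.0 - DETERMINISTIC_TOL)
        acc += float(pmf[det].sum())
    return acc / n


def crd_sd_abs_imbalance(n: int) -> float:
    """Exact SD of |D(n)| under complete randomization, D = 2*Bin(n,1/2) - n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, 0.5)
    abs_d = np.abs(2 * k - n)
    e1 = float(np.sum(pmf * abs_d))
    e2 = float(np.sum(pmf * abs_d**2))
    return float(np.sqrt(e2 - e1**2))
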