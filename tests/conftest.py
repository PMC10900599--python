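import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mcrand as mc

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Replicates for the stochastic checks; tolerances scale as 3 standard
#: errors of the corresponding Monte Carlo estimator at this size.
N_REPS = 2000
MASTER_SEED = 20260928


@pytest.fixture(scope="session")
def s1_run() -> mc.ExperimentResult:
    """A shared Scenario 1 experiment over the designs exercised by the
    headline operating-characteristic checks."""
    cfg, _ = mc.scenario_presets("scenario1")
    designs = tuple(
        mc.DesignSpec.from_label(lbl)
        for lbl in (
            "CRD",
            "U-PBD(2)",
            "U-BUD(2)",
            "U-EUD(2)",
            "U-BSD(2)",
            "C-PBD(2)",
            "DBR(2,2,2)",
        )
    )
    spec = mc.ExperimentSpec(cfg, designs, n_reps=N_REPS, seed=MASTER_SEED)
    return mc.run_experiment(spec)


@pytest.fixture(scope="session")
def s3_completion_times() -> np.ndarray:
    """Completion times of the enlarged-center-count scenario."""
    cfg, _ = mc.scenario_presets("scenario3")
    rng = np.random.default_rng(MASTER_SEED + 1)
    return mc.simulate_patterns(cfg, N_REPS, rng).completion_times


def bootstrap_se(values: np.ndarray, stat, n_boot: int = 200, seed: int = 0) -> float:
    """Bootstrap standard error of a statistic over replicate values."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values)
    reps = [
        stat(values[rng.integers(0, len(values), len(values))]) for _ in range(n_boot)
    ]
    return float(np.std(reps, ddof=1))


def mc_se(per_replicate_values: np.ndarray) -> float:
    """Standard error of a mean over replicates."""
    v = np.asarray(per_replicate_values, dtype=float)
    return float(np.std(v, ddof=1) / np.sqrt(len(v)))
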