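"""Monte Carlo experiment orchestration: scenarios, replication, reporting.

One experiment draws ``n_reps`` recruitment patterns from the Poisson-gamma
model and allocates *the same* patterns with every requested design (each
design on an independent seeded substream), so that design comparisons are
paired.  The four study scenarios vary the rate dispersion, the number of
centers, and the MTI thresholds:

* scenario1 — base case: n=500, N=80, G=5, activation Uniform(0, 122) days,
  alpha=120, beta=5800 (nearly constant rates, mean 500 enrollments in ~365 d)
* scenario2 — realistic rate dispersion: alpha=1.2, beta=58
* scenario3 — doubled center count: N=160, rates as scenario2
* scenario4 — rates as scenario2, all MTI thresholds doubled (b=4; DBR
  triples (4,4,4), (4,8,8), (4,8,16))
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .allocation import DesignSpec, allocate_batch
from .metrics import MetricsSummary, summarize_allocations
from .recruitment import (
    TrialConfig,
    sample_activation_times,
    sample_center_rates,
    simulate_recruitment,
)

__all__ = [
    "ExperimentSpec",
    "ExperimentResult",
    "scenario_presets",
    "design_grid",
    "run_experiment",
    "simulate_patterns",
    "load_config",
    "write_report",
]

SCENARIOS = ("scenario1", "scenario2", "scenario3", "scenario4")


def design_grid(b: int, dbr_triples: Sequence[tuple[int, int, int]]) -> list[DesignSpec]:
    """The 16-design comparison grid: 4 procedures x 3 stratifications,
    the DBR threshold triples, and complete randomization."""
    designs: list[DesignSpec] = []
    for family in ("unstratified", "region_stratified", "center_stratified"):
        for proc in ("PBD", "BUD", "EUD", "BSD"):
            designs.append(DesignSpec(family, procedure=proc, b=b))
    for b1, b2, b3 in dbr_triples:
        designs.append(DesignSpec("dbr", b1=b1, b2=b2, b3=b3))
    designs.append(DesignSpec("crd"))
    return designs


def scenario_presets(name: str) -> tuple[TrialConfig, list[DesignSpec]]:
    """Exact parameter sets of the four study scenarios."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    base = dict(n=500, N=80, G=5, T=365.0, a_lo=0.0, a_hi=122.0)
    if name == "scenario1":
        config = TrialConfig(alpha=120.0, beta=5800.0, **base)
    elif name == "scenario2":
        config = TrialConfig(alpha=1.2, beta=58.0, **base)
    elif name == "scenario3":
        base["N"] = 160
        config = TrialConfig(alpha=1.2, beta=58.0, **base)
    else:  # scenario4
        config = TrialConfig(alpha=1.2, beta=58.0, **base)
        return config, design_grid(4, [(4, 4, 4), (4, 8, 8), (4, 8, 16)])
    return config, design_grid(2, [(2, 2, 2), (2, 4, 4), (2, 4, 8)])


@dataclass(frozen=True)
class ExperimentSpec:
    """A full Monte Carlo experiment: one trial configuration, a list of
    designs to run on shared recruitment patterns, and a master seed."""

    config: TrialConfig
    designs: tuple[DesignSpec, ...]
    n_reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        labels = [d.label for d in self.designs]
        if len(set(labels)) != len(labels):
            raise ValueError("design labels must be unique")


@dataclass
class PatternBatch:
    """n_reps recruitment patterns in matrix form (replicates x patients)."""

    config: TrialConfig
    centers: np.ndarray  # (R, n) int32
    regions: np.ndarray  # (R, n) int32
    completion_times: np.ndarray  # (R,)
    center_counts: np.ndarray  # (R, N)

    @property
    def checksum(self) -> int:
        """CRC of the enrollment streams; designs allocated on this batch
        share it, guaranteeing the paired-comparison contract."""
        return zlib.crc32(np.ascontiguousarray(self.centers).tobytes())

    def size_histogram(self) -> np.ndarray:
        """Mean number of centers with exactly j patients, j = 0, 1, ..."""
        return np.bincount(self.center_counts.ravel()) / len(self.center_counts)


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    patterns: PatternBatch
    summaries: dict[str, MetricsSummary]
    pattern_checksum: int

    def recruitment_summary(self) -> dict:
        ct = self.patterns.completion_times
        hist = self.patterns.size_histogram()
        q1, med, q3 = np.percentile(ct, [25, 50, 75])
        return {
            "completion_mean": float(ct.mean()),
            "completion_median": float(med),
            "completion_iqr": [float(q1), float(q3)],
            "completion_range": [float(ct.min()), float(ct.max())],
            "mean_zero_recruitment_centers": float(hist[0]),
            "center_size_histogram": hist.tolist(),
        }

    def scalar_table(self) -> pd.DataFrame:
        rows = []
        for label, s in self.summaries.items():
            for metric, value in s.scalars().items():
                rows.append({"design": label, "metric": metric, "value": value})
        return pd.DataFrame(rows)


def simulate_patterns(
    config: TrialConfig, n_reps: int, rng: np.random.Generator
) -> PatternBatch:
    """Draw n_reps recruitment patterns (rates/activations redrawn per
    replicate unless the configuration pins a single rate draw)."""
    R, n, N = n_reps, config.n, config.N
    centers = np.empty((R, n), dtype=np.int32)
    completion = np.empty(R)
    shared_rates = None
    if not config.redraw_rates_per_replicate:
        shared_rates = sample_center_rates(N, config.alpha, config.beta, rng)
    for r in range(R):
        rates = (
            shared_rates
            if shared_rates is not None
            else sample_center_rates(N, config.alpha, config.beta, rng)
        )
        acts = sample_activation_times(N, config.a_lo, config.a_hi, rng)
        pat = simulate_recruitment(config, rates, acts, rng)
        centers[r] = pat.centers
        completion[r] = pat.times[-1]
    regions = config.region_of.astype(np.int32)[centers]
    flat = (np.arange(R)[:, None] * N + centers).ravel()
    counts = np.bincount(flat, minlength=R * N).reshape(R, N)
    return PatternBatch(
        config=config,
        centers=centers,
        regions=regions,
        completion_times=completion,
        center_counts=counts,
    )


def run_experiment(spec: ExperimentSpec) -> ExperimentResult:
    """Run the full paired Monte Carlo comparison.

    The master seed spawns one substream for recruitment and one per design,
    so every design sees the identical pattern batch and reruns with the same
    seed are byte-identical.
    """
    ss = np.random.SeedSequence(spec.seed)
    rec_seed, *design_seeds = ss.spawn(1 + len(spec.designs))
    patterns = simulate_patterns(
        spec.config, spec.n_reps, np.random.default_rng(rec_seed)
    )
    checksum = patterns.checksum
    summaries: dict[str, MetricsSummary] = {}
    for design, dseed in zip(spec.designs, design_seeds):
        drng = np.random.default_rng(dseed)
        delta, phi = allocate_batch(
            patterns.centers,
            patterns.regions,
            spec.config.N,
            spec.config.G,
            design,
            drng,
        )
        summaries[design.label] = summarize_allocations(
            design, delta, phi, patterns.centers, patterns.regions,
            spec.config.N, spec.config.G,
        )
    return ExperimentResult(
        spec=spec, patterns=patterns, summaries=summaries, pattern_checksum=checksum
    )


def load_config(path: str | Path) -> ExperimentSpec:
    """Build an ExperimentSpec from a YAML scenario file.

    Recognized keys: n, N, G, T_days, activation_window [a_lo, a_hi], alpha,
    beta, seed, n_reps, redraw_rates_per_replicate, designs (list of labels
    such as 'U-PBD(2)' or 'DBR(2,4,8)'; default: the 16-design grid at b=2).
    """
    raw = yaml.safe_load(Path(path).read_text())
    window = raw.get("activation_window", [0.0, 0.0])
    config = TrialConfig(
        n=int(raw["n"]),
        N=int(raw["N"]),
        G=int(raw.get("G", 1)),
        T=float(raw.get("T_days", 365.0)),
        a_lo=float(window[0]),
        a_hi=float(window[1]),
        alpha=float(raw["alpha"]),
        beta=float(raw["beta"]),
        redraw_rates_per_replicate=bool(raw.get("redraw_rates_per_replicate", True)),
    )
    if "designs" in raw:
        designs = [DesignSpec.from_label(lbl) for lbl in raw["designs"]]
    else:
        designs = design_grid(2, [(2, 2, 2), (2, 4, 4), (2, 4, 8)])
    return ExperimentSpec(
        config=config,
        designs=tuple(designs),
        n_reps=int(raw.get("n_reps", 10_000)),
        seed=int(raw.get("seed", 0)),
    )


def write_report(result: ExperimentResult, outdir: str | Path, figures: bool = False) -> None:
    """Write tidy CSV + JSON summaries (and optionally overview figures)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.scalar_table().to_csv(outdir / "metrics_summary.csv", index=False)
    tails = pd.concat(
        [s.tail_frame() for s in result.summaries.values()], ignore_index=True
    )
    tails.to_csv(outdir / "tail_probabilities.csv", index=False)
    rec = result.recruitment_summary()
    payload = {
        "seed": result.spec.seed,
        "n_reps": result.spec.n_reps,
        "pattern_checksum": result.pattern_checksum,
        "recruitment": rec,
        "designs": {lbl: s.scalars() for lbl, s in result.summaries.items()},
    }
    (outdir / "summary.json").write_text(json.dumps(payload, indent=2))
    if figures:
        _write_figures(result, outdir)


def _write_figures(result: ExperimentResult, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(result.summaries)
    fig, axes = plt.subplots(3, 1, figsize=(12, 12), sharex=True)
    for ax, col, title in zip(
        axes, ("L1", "L2", "L3"), ("Trial-level loss", "Region-level loss", "Center-level loss")
    ):
        ax.boxplot(
            [result.summaries[lbl].per_replicate[col] for lbl in labels],
            tick_labels=labels,
            showfliers=False,
        )
        ax.set_ylabel(title)
    axes[-1].tick_params(axis="x", rotation=75)
    fig.tight_layout()
    fig.savefig(outdir / "loss_boxplots.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(3, 1, figsize=(12, 10), sharex=True)
    for ax, (metric, attr) in zip(
        axes, (("PD", "prop_det"), ("PCG_c", "pcg_c"), ("PCG_d", "pcg_d"))
    ):
        ax.bar(labels, [getattr(result.summaries[lbl], attr) for lbl in labels])
        ax.set_ylabel(metric)
    axes[-1].tick_params(axis="x", rotation=75)
    fig.tight_layout()
    fig.savefig(outdir / "randomness_measures.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 3, figsize=(15, 4), sharey=True)
    for ax, level in zip(axes, ("trial", "region", "center")):
        for lbl in labels:
            curve = getattr(result.summaries[lbl], f"tail_{level}")
            ax.plot(np.arange(len(curve)), curve, label=lbl, lw=1)
        ax.set_title(f"{level} level")
        ax.set_xlabel("d")
    axes[0].set_ylabel("Pr(|imbalance| >= d)")
    axes[-1].legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(outdir / "tail_curves.png", dpi=120)
    plt.close(fig)
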