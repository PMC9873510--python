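"""Monte-Carlo operating characteristics of the deviation analysis.

The deviation test is treated as a studied statistical object: cohorts are
drawn from the generative model, the full pipeline (simulate -> aggregate ->
eligibility -> baseline fit -> residual test) runs on each, and rejection
rates are tallied — type-I error on null cohorts (event effect 0), power
along a grid of proportional-loss effect sizes, and recovery of the effect
size itself from the mean proportional deviation of post-event scans.

Comparisons across the effect grid use common random numbers: replicate k
reuses the same cohort seed at every effect size, so power differences along
the grid are not washed out by simulation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .baseline import GLOBAL_REGION_LABEL
from .errors import (
    ConfigurationError,
    DegenerateDesignError,
    DegenerateStandardizationError,
    EligibilityViolationError,
)
from .pipeline import deviation_analysis
from .simulate import RegionParams, SimConfig, default_protocols, simulate_cohort

_SEED_BOUND = 2**31


def default_eval_sim() -> SimConfig:
    """Evaluation cohort: one affected candidate region plus the global measure.

    Mirrors the regional-vs-global contrast the method is built around while
    keeping replicates cheap.
    """
    return SimConfig(
        regions=(
            RegionParams("parahippocampal", 2100.0, 250.0, -8.0, 4.0, 30.0, bilateral=True),
            RegionParams("CortexVol", 520000.0, 45000.0, -2600.0, 900.0, 3500.0, bilateral=False),
        ),
        protocols=default_protocols(),
        affected_regions=("parahippocampal",),
    )


@dataclass
class EvalConfig:
    """Specification of one Monte-Carlo study."""

    sim: SimConfig = field(default_factory=default_eval_sim)
    effect_grid: tuple[float, ...] = (0.0, 0.01, 0.02, 0.05)
    n_replicates: int = 200
    alpha: float = 0.05
    pooling: str = "per_subject_mean"
    variant: str = "welch"
    min_pre: int = 3
    max_degenerate_frac: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if not (0 < self.alpha <= 1):
            raise ConfigurationError("alpha must be in (0, 1]")
        if not self.effect_grid:
            raise ConfigurationError("effect_grid must be nonempty")
        self.sim.validate()


@dataclass
class PowerResult:
    """Per (effect size, region) rejection rates and effect-recovery summaries.

    ``table`` columns: delta, region_label, n_effective, n_degenerate,
    n_rejections, rejection_rate, ci_low/ci_high (exact binomial 95%),
    mean_mean_post_z, sd_mean_post_z, mean_delta_hat, sd_delta_hat.
    """

    table: pd.DataFrame
    config: EvalConfig

    def row(self, delta: float, region_label: str) -> pd.Series:
        match = self.table[
            (self.table["delta"] == delta) & (self.table["region_label"] == region_label)
        ]
        if match.empty:
            raise KeyError((delta, region_label))
        return match.iloc[0]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False, float_format="%.6g")
        return path


def _replicate_metrics(
    sim_config: SimConfig,
    pooling: str,
    variant: str,
    min_pre: int,
    alpha: float,
) -> dict[str, dict[str, float]]:
    """One full pipeline run; per-region p value, mean post z, delta-hat."""
    sim = simulate_cohort(sim_config)
    out = deviation_analysis(
        sim.cohort,
        sim.subjects,
        min_pre=min_pre,
        pooling=pooling,
        variant=variant,
        require_stable=True,
        subgroup="all",
    )
    residuals = out.residuals
    post = residuals[residuals["phase"] == "post"]
    delta_hat = (-post["raw_residual"] / post["predicted"]).groupby(post["region_label"]).mean()
    metrics: dict[str, dict[str, float]] = {}
    for result in out.analysis.results:
        if result.no_data:
            continue
        metrics[result.region_label] = {
            "p": result.p_value,
            "reject": float(result.p_value <= alpha),
            "mean_post_z": result.mean_post_z,
            "delta_hat": float(delta_hat.get(result.region_label, np.nan)),
        }
    return metrics


def _run_grid(config: EvalConfig, grid: Sequence[float]) -> PowerResult:
    config.validate()
    master = np.random.default_rng(config.seed)
    replicate_seeds = master.integers(0, _SEED_BOUND, size=config.n_replicates)

    rows: list[dict] = []
    for delta in grid:
        per_region: dict[str, dict[str, list[float]]] = {}
        n_degenerate = 0
        for seed in replicate_seeds:
            sim_config = replace(config.sim, event_effect=float(delta), seed=int(seed))
            try:
                metrics = _replicate_metrics(
                    sim_config, config.pooling, config.variant, config.min_pre, config.alpha
                )
            except (
                DegenerateDesignError,
                DegenerateStandardizationError,
                EligibilityViolationError,
            ):
                n_degenerate += 1
                continue
            for region, vals in metrics.items():
                bucket = per_region.setdefault(
                    region, {"reject": [], "mean_post_z": [], "delta_hat": []}
                )
                bucket["reject"].append(vals["reject"])
                bucket["mean_post_z"].append(vals["mean_post_z"])
                bucket["delta_hat"].append(vals["delta_hat"])
        if n_degenerate > config.max_degenerate_frac * config.n_replicates:
            raise ConfigurationError(
                f"{n_degenerate}/{config.n_replicates} replicates degenerate at delta={delta}; "
                "the generative configuration is unusable"
            )
        for region, bucket in sorted(per_region.items()):
            rejects = np.asarray(bucket["reject"])
            n_eff = len(rejects)
            k = int(rejects.sum())
            ci = stats.binomtest(k, n_eff).proportion_ci(confidence_level=0.95, method="exact")
            mean_post = np.asarray(bucket["mean_post_z"])
            dhat = np.asarray(bucket["delta_hat"])
            rows.append(
                {
                    "delta": float(delta),
                    "region_label": region,
                    "n_effective": n_eff,
                    "n_degenerate": n_degenerate,
                    "n_rejections": k,
                    "rejection_rate": k / n_eff,
                    "ci_low": float(ci.low),
                    "ci_high": float(ci.high),
                    "mean_mean_post_z": float(mean_post.mean()),
                    "sd_mean_post_z": float(mean_post.std(ddof=1)) if n_eff > 1 else float("nan"),
                    "mean_delta_hat": float(dhat.mean()),
                    "sd_delta_hat": float(dhat.std(ddof=1)) if n_eff > 1 else float("nan"),
                }
            )
    return PowerResult(table=pd.DataFrame(rows), config=config)


def run_calibration(config: EvalConfig) -> PowerResult:
    """Type-I error of the full pipeline on null cohorts (effect size 0).

    Requires 0 in the effect grid; only the null point is run. Degenerate
    replicates are skipped and counted, never silently absorbed.
    """
    if 0.0 not in config.effect_grid:
        raise ConfigurationError("run_calibration requires 0 in the effect grid")
    return _run_grid(config, [0.0])


def run_power(config: EvalConfig) -> PowerResult:
    """Rejection rate along the whole effect grid with paired cohort seeds."""
    return _run_grid(config, list(config.effect_grid))


def plot_power(result: PowerResult, path: str | Path) -> Path:
    """Power curve per region (rejection rate vs effect size, 95% binomial CI)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for region, sub in result.table.groupby("region_label"):
        sub = sub.sort_values("delta")
        ax.errorbar(
            sub["delta"],
            sub["rejection_rate"],
            yerr=[sub["rejection_rate"] - sub["ci_low"], sub["ci_high"] - sub["rejection_rate"]],
            marker="o",
            capsize=3,
            label=region,
        )
    ax.axhline(result.config.alpha, color="0.6", lw=0.8, ls="--")
    ax.set_xlabel("proportional post-event volume loss")
    ax.set_ylabel(f"rejection rate at alpha = {result.config.alpha:g}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
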