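"""Replicated simulation study comparing the three treatment-effect estimators.

For each scenario the harness repeatedly generates a full study (k trials
plus a treated cohort), computes up to three estimators of the population
effect ARE —

    trials_only  : inverse-variance pooled trial estimate (biased by the
                   generalizability gap zeta when the eligible stratum
                   differs from the population),
    cohort_only  : posterior mean of theta_alpha from the cohort trajectory
                   model (biased by the projection bias phi_alpha),
    combined     : posterior mean of the mixture effect ARE from the
                   eligibility-stratified model with the pooled-trial prior,

— and summarizes each as absolute bias, empirical SE and MSE against the
known truth. Replicate seeds derive deterministically from the master seed,
so a design reruns bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import meta_prior
from .cohort_model import MCMCConfig, RandomEffectsSpec, fit_cohort_model
from .combined_model import fit_combined_model
from .simulator import ScenarioConfig, simulate_study

logger = logging.getLogger(__name__)

ESTIMATORS = ("trials_only", "cohort_only", "combined")

REPORT_COLUMNS = [
    "scenario", "estimator", "n_reps", "n_converged", "mean_estimate",
    "absolute_bias", "empirical_se", "mse", "truth_ARE", "phi_alpha", "zeta",
]


@dataclass(frozen=True)
class StudyDesign:
    """A list of scenarios to replicate and the estimators to compare."""

    scenarios: Sequence[ScenarioConfig]
    n_reps: int = 500
    estimators: tuple[str, ...] = ESTIMATORS
    master_seed: int = 0
    mcmc_config: MCMCConfig = field(default_factory=MCMCConfig)
    re_spec: RandomEffectsSpec = field(
        default_factory=lambda: RandomEffectsSpec(("b0", "b1"))
    )
    pooling_method: str = "dersimonian_laird"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        unknown = set(self.estimators) - set(ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimators {sorted(unknown)}")
        if not self.scenarios:
            raise ValueError("at least one scenario is required")


def replicate_seed(master_seed: int, scenario_index: int, rep: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    ss = np.random.SeedSequence([master_seed, scenario_index, rep])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_replicate(
    scenario: ScenarioConfig,
    seed: int,
    estimators: Iterable[str] = ESTIMATORS,
    mcmc_config: MCMCConfig | None = None,
    re_spec: RandomEffectsSpec | tuple = ("b0", "b1"),
    pooling_method: str = "dersimonian_laird",
) -> dict[str, dict]:
    """Generate one study replicate and compute the requested estimators.

    Returns ``{estimator: {"estimate", "se", "converged"}}``. Requesting only
    ``trials_only`` skips cohort generation cost's MCMC entirely.
    """
    estimators = tuple(estimators)
    mcmc_config = mcmc_config or MCMCConfig()
    mcmc_config = replace(mcmc_config, seed=seed)
    data = simulate_study(scenario, seed=seed)
    out: dict[str, dict] = {}

    pooled = None
    if "trials_only" in estimators or "combined" in estimators:
        pooled = meta_prior.pool(data.trials, method=pooling_method)
    if "trials_only" in estimators:
        out["trials_only"] = {
            "estimate": pooled.pooled_estimate,
            "se": pooled.pooled_se,
            "converged": True,
        }
    if "cohort_only" in estimators:
        res = fit_cohort_model(
            data.cohort, scenario.alpha, re_spec=re_spec, mcmc_config=mcmc_config
        )
        out["cohort_only"] = {
            "estimate": res.theta_alpha,
            "se": res.theta_alpha_se,
            "converged": res.converged,
        }
    if "combined" in estimators:
        prior = meta_prior.to_prior(pooled)
        res = fit_combined_model(
            data.cohort, scenario.alpha, prior,
            re_spec=re_spec, mcmc_config=mcmc_config,
        )
        out["combined"] = {
            "estimate": res.are,
            "se": res.are_se,
            "converged": res.converged,
        }
    return out


def summarize(estimates: Sequence[float], truth: float) -> dict:
    """Absolute bias, empirical SE and MSE of a set of replicate estimates."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("need >= 2 converged replicates to summarize")
    return {
        "n_converged": int(est.size),
        "mean_estimate": float(est.mean()),
        "absolute_bias": float(abs(est.mean() - truth)),
        "empirical_se": float(est.std(ddof=1)),
        "mse": float(np.mean((est - truth) ** 2)),
    }


def run_study(design: StudyDesign) -> pd.DataFrame:
    """Execute every scenario x replicate and return the comparison report.

    Non-converged MCMC replicates are excluded from the summaries and
    counted. Columns are fixed (:data:`REPORT_COLUMNS`).
    """
    for sc in design.scenarios:  # fail fast on any invalid scenario
        _ = sc.ARE2, sc.omega_sq
    rows = []
    for s_idx, scenario in enumerate(design.scenarios):
        per_est: dict[str, list[float]] = {e: [] for e in design.estimators}
        for rep in range(design.n_reps):
            seed = replicate_seed(design.master_seed, s_idx, rep)
            result = run_replicate(
                scenario, seed,
                estimators=design.estimators,
                mcmc_config=design.mcmc_config,
                re_spec=design.re_spec,
                pooling_method=design.pooling_method,
            )
            for est_name, res in result.items():
                if res["converged"]:
                    per_est[est_name].append(res["estimate"])
                else:
                    logger.warning(
                        "scenario %d rep %d: %s flagged non-converged, excluded",
                        s_idx, rep, est_name,
                    )
        for est_name in design.estimators:
            stats = summarize(per_est[est_name], scenario.ARE)
            rows.append(
                {
                    "scenario": s_idx,
                    "estimator": est_name,
                    "n_reps": design.n_reps,
                    **stats,
                    "truth_ARE": scenario.ARE,
                    "phi_alpha": scenario.phi_alpha,
                    "zeta": scenario.zeta,
                }
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, index=False)


def plot_comparison(report: pd.DataFrame, path: str | Path | None = None):
    """Minimal bias/MSE figure: one panel per metric, estimators grouped by
    scenario."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for ax, metric in zip(axes, ("absolute_bias", "mse")):
        pivot = report.pivot(index="scenario", columns="estimator", values=metric)
        pivot.plot.bar(ax=ax, rot=0)
        ax.set_ylabel(metric.replace("_", " "))
        ax.set_xlabel("scenario")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
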