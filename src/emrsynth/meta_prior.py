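"""Meta-analytic pooling of trial change-score effects into a normal prior.

Each randomized trial contributes a treated-minus-control difference in mean
change score from treatment offer (t = 0) to the effect time alpha, with its
standard error. Trials are pooled by inverse-variance weighting, either under
a common-effect (fixed-effect) model or with DerSimonian-Laird random effects
(the default: the simulated trial programme injects between-trial variation).
The pooled estimate and its standard error become the mean and standard
deviation of a normal informative prior for the trial-eligible treatment
effect ARE1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

PoolingMethod = Literal["fixed_effect", "dersimonian_laird"]


@dataclass(frozen=True)
class TrialResult:
    """Aggregated result of one randomized trial."""

    trial_id: str
    estimate: float       # treated-minus-control difference in mean change
    se: float             # standard error of the estimate
    n_treated: int = 0
    n_control: int = 0

    def __post_init__(self) -> None:
        if not self.se >= 0:
            raise ValueError(f"se must be non-negative, got {self.se}")


@dataclass(frozen=True)
class MetaAnalysisResult:
    pooled_estimate: float
    pooled_se: float
    tau_sq: float                 # between-trial variance (0 under fixed effect)
    k: int
    method: PoolingMethod

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("meta-analysis needs k >= 1 trials")
        if self.method == "fixed_effect" and self.tau_sq != 0:
            raise ValueError("fixed-effect pooling implies tau_sq = 0")


@dataclass(frozen=True)
class InformativePrior:
    """Normal prior; for ARE1 the mean/sd come from the pooled meta-analysis."""

    mean: float
    sd: float
    family: str = "normal"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sd) and self.sd > 0):
            raise ValueError(f"prior sd must be finite and positive, got {self.sd}")


def summarize_trial(
    treated_changes: Sequence[float],
    control_changes: Sequence[float],
    trial_id: str = "trial",
) -> TrialResult:
    """Aggregate per-participant change scores (value at alpha minus value at
    offer) into a difference-in-means estimate with its standard error.

    se = sqrt(s_t^2/n_t + s_c^2/n_c) with unbiased sample variances. Arms of
    size < 2 leave the variance undefined and raise.
    """
    t = np.asarray(treated_changes, dtype=float)
    c = np.asarray(control_changes, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("each arm needs >= 2 observations for a variance")
    estimate = t.mean() - c.mean()
    se = float(np.sqrt(t.var(ddof=1) / t.size + c.var(ddof=1) / c.size))
    return TrialResult(
        trial_id=trial_id,
        estimate=float(estimate),
        se=se,
        n_treated=int(t.size),
        n_control=int(c.size),
    )


def pool(
    trials: Sequence[TrialResult],
    method: PoolingMethod = "dersimonian_laird",
) -> MetaAnalysisResult:
    """Inverse-variance pooling of trial results.

    Under ``dersimonian_laird`` the between-trial variance tau^2 is the DL
    moment estimator truncated at zero, added to each trial's variance before
    re-weighting; with a single trial or homogeneous estimates it reduces to
    the fixed-effect answer.
    """
    if len(trials) == 0:
        raise ValueError("cannot pool zero trials")
    y = np.array([t.estimate for t in trials], dtype=float)
    v = np.array([t.se**2 for t in trials], dtype=float)
    if np.any(v <= 0):
        raise ValueError("all trial SEs must be positive for pooling")
    w = 1.0 / v
    tau_sq = 0.0
    if method == "dersimonian_laird" and len(trials) > 1:
        ybar_fe = np.sum(w * y) / np.sum(w)
        q = np.sum(w * (y - ybar_fe) ** 2)
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau_sq = max(0.0, (q - (len(trials) - 1)) / denom)
        w = 1.0 / (v + tau_sq)
    elif method not in ("fixed_effect", "dersimonian_laird"):
        raise ValueError(f"unknown pooling method {method!r}")
    pooled = float(np.sum(w * y) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    return MetaAnalysisResult(
        pooled_estimate=pooled,
        pooled_se=pooled_se,
        tau_sq=float(tau_sq) if method == "dersimonian_laird" else 0.0,
        k=len(trials),
        method=method,
    )


def to_prior(meta: MetaAnalysisResult) -> InformativePrior:
    """Normal prior with mean = pooled estimate and sd = pooled SE."""
    return InformativePrior(mean=meta.pooled_estimate, sd=meta.pooled_se)


# --- CSV interface --------------------------------------------------------

def read_trials_csv(path: str | Path) -> list[TrialResult]:
    """Read trial results from CSV.

    Accepts either aggregated rows (``trial_id, estimate, se``) or per-arm
    summaries (``trial_id, n_t, mean_change_t, sd_t, n_c, mean_change_c,
    sd_c``), which are converted to difference-in-means form.
    """
    df = pd.read_csv(path)
    if {"estimate", "se"}.issubset(df.columns):
        return [
            TrialResult(
                trial_id=str(r.trial_id),
                estimate=float(r.estimate),
                se=float(r.se),
                n_treated=int(getattr(r, "n_treated", 0) or 0),
                n_control=int(getattr(r, "n_control", 0) or 0),
            )
            for r in df.itertuples()
        ]
    per_arm = {"trial_id", "n_t", "mean_change_t", "sd_t", "n_c", "mean_change_c", "sd_c"}
    if per_arm.issubset(df.columns):
        out = []
        for r in df.itertuples():
            se = float(np.sqrt(r.sd_t**2 / r.n_t + r.sd_c**2 / r.n_c))
            out.append(
                TrialResult(
                    trial_id=str(r.trial_id),
                    estimate=float(r.mean_change_t - r.mean_change_c),
                    se=se,
                    n_treated=int(r.n_t),
                    n_control=int(r.n_c),
                )
            )
        return out
    raise ValueError(
        f"{path}: expected columns (trial_id, estimate, se) or per-arm summaries"
    )


def write_trials_csv(trials: Sequence[TrialResult], path: str | Path) -> None:
    pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "estimate": [t.estimate for t in trials],
            "se": [t.se for t in trials],
            "n_treated": [t.n_treated for t in trials],
            "n_control": [t.n_control for t in trials],
        }
    ).to_csv(path, index=False)
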