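"""Cohort-only Bayesian piecewise-linear trajectory model.

Outcome trajectories in a treated cohort are modelled as piecewise linear
with change points at the treatment offer (t = 0) and at a later, unknown
time delta in (0, 3): slope beta1 before the offer, an initial post-offer
slope, and slope beta3 after delta. Under the assumption that, absent
treatment, patients would have continued on their pre-offer line
(mu0(t) = beta0 + beta1 t), the treatment effect at a fixed time alpha is

    theta_alpha = mu1(alpha) - mu0(alpha)
                = (beta2 - beta1) alpha                      if alpha < delta
                = (beta2 - beta3) delta + (beta3 - beta1) alpha  otherwise,

and the model is reparametrized so that theta_alpha itself is a coefficient
(the initial post-offer slope beta2 is implied). theta_alpha estimates the
average effect of the treatment offer up to projection bias.

Random effects on any subset of {intercept, pre-slope, treatment effect,
late slope} capture between-patient variation. Fitting is fully Bayesian:
vague normal priors on coefficients, U(0, 100) on the residual SD, U(0, 3)
on delta, and the standard vague hierarchy on the random-effect covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._lmm import MarginalLMM, run_ensemble
from .cohort_data import CohortDataset
from .results import PosteriorSummary, check_convergence

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryParams",
    "RandomEffectsSpec",
    "MCMCConfig",
    "trajectory_basis",
    "mean_trajectory",
    "theta_from_betas",
    "beta2_from_theta",
    "CohortTrajectoryModel",
    "CohortTrajectoryResults",
    "fit_cohort_model",
    "check_convergence",
]


@dataclass(frozen=True)
class TrajectoryParams:
    """Fixed-effect parameters of the reparametrized piecewise trajectory."""

    beta0: float          # outcome at the treatment offer
    beta1: float          # pre-offer slope (score/yr)
    theta_alpha: float    # treatment effect at t = alpha (score units)
    beta3: float          # slope after the second change point
    delta: float          # second change point (yr), in (0, 3)
    sigma: float = 1.0    # residual SD

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if not self.sigma >= 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Which coefficients get subject random effects, and the covariance prior.

    ``covariance_prior`` is "direct" (SDs U(0, bound) with correlation
    U(-1, 1); up to two effects, the standard two-effect recipe) or "angles"
    (separation strategy with hyperspherical-angle Cholesky, required for
    three or more effects, usable for two as a sensitivity check).
    """

    which: tuple[str, ...] = ("b0", "b1")
    covariance_prior: str = "auto"
    sd_bound: float = 100.0

    _ORDER = ("b0", "b1", "b2", "b3")

    def __post_init__(self) -> None:
        unknown = set(self.which) - set(self._ORDER)
        if unknown:
            raise ValueError(f"unknown random effects {sorted(unknown)}")
        if not self.which:
            raise ValueError("at least one random effect is required")
        ordered = tuple(w for w in self._ORDER if w in self.which)
        object.__setattr__(self, "which", ordered)

    @property
    def q(self) -> int:
        return len(self.which)

    def corr_param(self) -> str:
        if self.covariance_prior == "auto":
            return "direct" if self.q <= 2 else "angles"
        return self.covariance_prior


@dataclass(frozen=True)
class MCMCConfig:
    """Ensemble-sampler settings. ``draws`` counts total steps per walker;
    the first ``warmup`` (default half) are discarded, the rest thinned."""

    draws: int = 1200
    warmup: int | None = None
    walkers: int | None = None
    thin: int = 2
    seed: int = 0
    rhat_max: float = 1.05


# --- trajectory algebra ---------------------------------------------------

def trajectory_basis(
    t: np.ndarray, alpha: float, delta: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indicator-basis columns of the reparametrized piecewise mean.

    Returns (pre-slope basis, treatment-effect basis, late-slope basis); the
    mean trajectory is ``beta0 + beta1*b1 + theta_alpha*btheta + beta3*b3``.
    The basis depends on whether alpha falls before or after delta, so it is
    recomputed per posterior draw inside the sampler.
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if not delta > 0:
        raise ValueError(f"delta must be positive, got {delta}")
    t = np.asarray(t, dtype=float)
    post = np.minimum(t, delta) * (t >= 0)
    pre = t * (t < 0)
    late = (t - delta) * (t >= delta)
    if alpha < delta:
        c1, ctheta, c3 = 1.0, 1.0 / alpha, 0.0
    else:
        c1, ctheta, c3 = alpha / delta, 1.0 / delta, 1.0 - alpha / delta
    return pre + c1 * post, ctheta * post, c3 * post + late


def mean_trajectory(t, params: TrajectoryParams, alpha: float):
    """Expected trajectory under treatment offer at time(s) ``t``.

    Piecewise linear and continuous; equals beta0 at t = 0 and reduces to
    the untreated line beta0 + beta1*t when theta_alpha = 0 and beta3 =
    beta1.
    """
    b1, btheta, b3 = trajectory_basis(t, alpha, params.delta)
    out = (
        params.beta0
        + params.beta1 * b1
        + params.theta_alpha * btheta
        + params.beta3 * b3
    )
    return float(out) if np.isscalar(t) else out


def theta_from_betas(
    beta1: float, beta2: float, beta3: float, delta: float, alpha: float
) -> float:
    """Treatment effect at alpha from the segment slopes.

    theta = (beta2 - beta1) alpha when the effect time precedes the second
    change point, else (beta2 - beta3) delta + (beta3 - beta1) alpha.
    """
    if alpha < delta:
        return (beta2 - beta1) * alpha
    return (beta2 - beta3) * delta + (beta3 - beta1) * alpha


def beta2_from_theta(
    theta_alpha: float, beta1: float, beta3: float, delta: float, alpha: float
) -> float:
    """Initial post-offer slope implied by the reparametrization (inverse of
    :func:`theta_from_betas` in beta2)."""
    if alpha < delta:
        return theta_alpha / alpha + beta1
    return (theta_alpha - (beta3 - beta1) * alpha) / delta + beta3


# --- model ----------------------------------------------------------------

_RE_LABELS = {"b0": "intercept", "b1": "pre_slope", "b2": "effect", "b3": "late_slope"}


class CohortTrajectoryModel:
    """Bayesian piecewise trajectory model for a treated-only cohort.

    Parameters
    ----------
    dataset : CohortDataset (or use :meth:`from_dataframe`).
    alpha : effect time in years, in (0, 3].
    re_spec : which coefficients vary by subject.
    coef_prior_sd : SD of the vague normal priors on coefficients.
    """

    param_names = ("beta0", "beta1", "theta_alpha", "beta3")

    def __init__(
        self,
        dataset: CohortDataset,
        alpha: float,
        re_spec: RandomEffectsSpec | Sequence[str] = ("b0", "b1"),
        coef_prior_sd: float = 100.0,
        sigma_bound: float = 100.0,
        delta_bounds: tuple[float, float] = (0.0, 3.0),
    ) -> None:
        if not isinstance(re_spec, RandomEffectsSpec):
            re_spec = RandomEffectsSpec(tuple(re_spec))
        if not 0.0 < alpha <= 3.0:
            raise ValueError(f"alpha must lie in (0, 3], got {alpha}")
        self.alpha = float(alpha)
        self.re_spec = re_spec
        self.coef_prior_sd = float(coef_prior_sd)
        self.sigma_bound = float(sigma_bound)
        self.delta_bounds = delta_bounds

        rec = dataset.records.sort_values(
            ["subject_id", "time_years"], kind="mergesort"
        )
        self.t = rec.time_years.to_numpy(dtype=float)
        self.y = rec.adjusted_score.to_numpy(dtype=float)
        codes, _ = pd.factorize(rec.subject_id, sort=False)
        self.subject = codes
        self.starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
        self.n_subjects = len(self.starts)
        self._validate_identifiability()
        self._lmm = self._build_lmm()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        alpha: float,
        score_col: str = "adjusted_score",
        time_col: str = "time_years",
        subject_col: str = "subject_id",
        **kwargs,
    ) -> "CohortTrajectoryModel":
        """Build directly from a long-format DataFrame of scores."""
        records = df.rename(
            columns={score_col: "adjusted_score", time_col: "time_years",
                     subject_col: "subject_id"}
        ).copy()
        for col, val in (("numerator", np.nan), ("denominator", 30)):
            if col not in records.columns:
                records[col] = val
        baselines = pd.DataFrame({"subject_id": records.subject_id.unique()})
        return cls(CohortDataset(records, baselines), alpha, **kwargs)

    def _validate_identifiability(self) -> None:
        if not np.any(self.t > 0):
            raise ValueError(
                "no post-offer observations: theta_alpha is unidentifiable"
            )
        has_pre = np.zeros(self.n_subjects, bool)
        has_post = np.zeros(self.n_subjects, bool)
        np.logical_or.at(has_pre, self.subject, self.t < 0)
        np.logical_or.at(has_post, self.subject, self.t > 0)
        if not np.any(has_pre & has_post):
            logger.warning(
                "no subject has both pre- and post-offer observations; "
                "the pre-offer slope is identified only across subjects"
            )

    # fixed-effect / random-effect design for a given change point
    def design(self, delta: float) -> tuple[np.ndarray, np.ndarray]:
        b1, btheta, b3 = trajectory_basis(self.t, self.alpha, delta)
        ones = np.ones_like(self.t)
        cols = {"b0": ones, "b1": b1, "b2": btheta, "b3": b3}
        X = np.column_stack([ones, b1, btheta, b3])
        Z = np.column_stack([cols[w] for w in self.re_spec.which])
        return X, Z

    def _build_lmm(self) -> MarginalLMM:
        p = 4
        return MarginalLMM(
            y=self.y,
            starts=self.starts,
            design=self.design,
            prior_mean=np.zeros(p),
            prior_sd=np.full(p, self.coef_prior_sd),
            q=self.re_spec.q,
            delta_bounds=self.delta_bounds,
            sigma_bound=self.sigma_bound,
            re_sd_bound=self.re_spec.sd_bound,
            corr_param=self.re_spec.corr_param(),
        )

    def _init_center(self) -> np.ndarray:
        # crude data-driven start: delta mid-range; sigma from within-subject
        # spread; intercept-RE sd from between-subject spread
        subj_mean = np.add.reduceat(self.y, self.starts) / np.diff(
            np.r_[self.starts, len(self.y)]
        )
        resid = self.y - subj_mean[self.subject]
        sigma0 = max(float(resid.std()), 0.25)
        sd0 = max(float(subj_mean.std()), 0.5)
        lo, hi = self.delta_bounds
        center = [0.5 * (lo + hi) * 0.5 + 0.25, sigma0]
        for w in self.re_spec.which:
            center.append(sd0 if w == "b0" else 0.5)
        if self._lmm.corr_param == "direct":
            center += [0.0] * self._lmm.n_corr
        else:
            center += [np.pi / 2] * self._lmm.n_corr
        return np.asarray(center)

    def fit(self, mcmc_config: MCMCConfig | None = None) -> "CohortTrajectoryResults":
        """Sample the posterior; returns a results object with draws,
        summaries and convergence diagnostics."""
        cfg = mcmc_config or MCMCConfig()
        run = run_ensemble(
            self._lmm,
            init_center=self._init_center(),
            seed=cfg.seed,
            n_steps=cfg.draws,
            n_warmup=cfg.warmup,
            n_walkers=cfg.walkers,
            thin=cfg.thin,
        )
        draws: dict[str, np.ndarray] = {}
        for j, name in enumerate(self.param_names):
            draws[name] = run.beta[:, :, j]
        draws["delta"] = run.psi[:, :, 0]
        draws["sigma"] = run.psi[:, :, 1]
        for j, w in enumerate(self.re_spec.which):
            draws[f"sd_{_RE_LABELS[w]}"] = run.psi[:, :, 2 + j]
        q = self.re_spec.q
        for j in range(self._lmm.n_corr):
            label = "rho" if self._lmm.corr_param == "direct" else f"angle_{j}"
            draws[label] = run.psi[:, :, 2 + q + j]
        res = CohortTrajectoryResults(
            draws=draws, acceptance=run.acceptance, extra={"alpha": self.alpha}
        )
        res.model = self
        res.converged = check_convergence(res, rhat_max=cfg.rhat_max)
        if not res.converged:
            logger.warning("convergence flagged: max R-hat %.3f", max(res.rhat.values()))
        return res


class CohortTrajectoryResults(PosteriorSummary):
    """Posterior for the cohort-only model; point estimate of the treatment
    effect is the posterior mean of theta_alpha, its SE the posterior SD."""

    model: CohortTrajectoryModel | None = None
    converged: bool = True

    @property
    def theta_alpha(self) -> float:
        return self.mean("theta_alpha")

    @property
    def theta_alpha_se(self) -> float:
        return self.sd("theta_alpha")


def fit_cohort_model(
    dataset: CohortDataset,
    alpha: float,
    re_spec: RandomEffectsSpec | Sequence[str] = ("b0", "b1"),
    mcmc_config: MCMCConfig | None = None,
    **model_kwargs,
) -> CohortTrajectoryResults:
    """One-call interface: build the model from a dataset and sample it."""
    model = CohortTrajectoryModel(dataset, alpha, re_spec=re_spec, **model_kwargs)
    return model.fit(mcmc_config)
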