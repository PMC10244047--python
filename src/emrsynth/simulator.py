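"""Generative model for trial and treated-cohort datasets.

The target population P splits into a trial-eligible stratum P1 (proportion
pi, itself partitioned across k trial-specific subsets) and a non-eligible
stratum P2. Each individual carries a treatment effect Delta_i at the effect
time alpha and an outcome-at-offer level gamma0_i, drawn hierarchically:

    Delta_i | eligible, trial j ~ N(ARE1_j, omega^2),  ARE1_j ~ N(ARE1, tau1^2)
    Delta_i | non-eligible      ~ N(ARE2, nu^2)
    gamma0_i | eligible, trial j ~ N(Gamma01_j, omega0^2), Gamma01_j ~ N(Gamma01, tau0^2)
    gamma0_i | non-eligible      ~ N(Gamma02, sigma0^2)

Untreated trajectories are two-slope piecewise lines (slope gamma1 before
the offer, gamma2 after); treated trajectories add a piecewise-linear
offset that is 0 at the offer, equals Delta_i exactly at t = alpha, and has
a single kink at the second change point delta with slope offset
(gamma3 - gamma2). Two biases are controlled directly:

    projection bias      phi_alpha = (gamma2 - gamma1) * alpha
    generalizability bias zeta     = ARE1 - ARE

Trial datasets randomize arms 50:50 and aggregate per-participant change
scores from offer to alpha; the cohort offers treatment to everyone and
records scores at irregular times in [-1, 3].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort_data import CohortDataset
from .meta_prior import TrialResult, summarize_trial

__all__ = [
    "ScenarioConfig",
    "SimulatedIndividual",
    "SimulatedStudyData",
    "control_trajectory",
    "treated_trajectory",
    "treatment_offset",
    "simulate_trials",
    "simulate_cohort",
    "simulate_study",
    "biases",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """All inputs of the generative model, with the study's stock values as
    defaults (middle value wherever a grid of settings exists).

    Derived quantities (``ARE2``, ``omega_sq``, ``zeta``, ``phi_alpha``) are
    computed, not set: ``zeta`` is controlled through ARE1 and ``phi_alpha``
    through gamma2, so the population effect ARE stays fixed while either
    bias is switched on.
    """

    n1: int = 1000            # combined size of all trials
    k: int = 4                # number of trials
    n2: int = 1500            # cohort size
    ARE: float = 1.0          # average effect of treatment offer in P
    ARE1: float = 1.0         # average effect in the trial-eligible stratum
    alpha: float = 0.25       # effect time (yr)
    pi: float = 0.7           # trial-eligible proportion
    Gamma0: float = 20.0      # mean outcome at offer in P
    Gamma02: float = 20.0     # mean outcome at offer in P2
    gamma1: float = -2.0      # pre-offer slope (score/yr)
    gamma2: float = -2.0      # untreated post-offer slope
    gamma3: float = -1.9      # treated slope after the change point
    delta: float = 0.3        # second change point (yr)
    sigma: float = 2.0        # residual SD
    sigma0: float = 4.0       # SD of outcome-at-offer
    nu_sq: float = 1.0        # total variance of Delta_i within each stratum
    tau1_sq: float = 0.25     # between-trial variance of ARE1_j
    Gamma01: float = 20.0     # mean outcome at offer in P1
    tau0_sq: float = 0.25     # between-trial variance of Gamma01_j
    obs_per_subject: tuple[int, int] = (1, 8)   # discrete-uniform bounds
    obs_window: tuple[float, float] = (-1.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError(f"pi must lie in (0, 1), got {self.pi}")
        if self.omega_sq < 0:
            raise ValueError(
                f"tau1_sq {self.tau1_sq} exceeds total variance nu_sq {self.nu_sq}"
            )
        if self.omega0_sq < 0:
            raise ValueError(
                f"tau0_sq {self.tau0_sq} exceeds sigma0^2 {self.sigma0**2}"
            )
        if self.delta <= 0 or self.alpha <= 0:
            raise ValueError("alpha and delta must be positive")
        if self.n1 // self.k < 4:
            raise ValueError("fewer than 4 participants per trial")

    # --- derived quantities ---
    @property
    def ARE2(self) -> float:
        """Non-eligible effect implied by ARE = pi*ARE1 + (1-pi)*ARE2."""
        return (self.ARE - self.pi * self.ARE1) / (1.0 - self.pi)

    @property
    def omega_sq(self) -> float:
        """Within-trial-subset variance of Delta_i (total minus between-trial)."""
        return self.nu_sq - self.tau1_sq

    @property
    def omega0_sq(self) -> float:
        return self.sigma0**2 - self.tau0_sq

    @property
    def zeta(self) -> float:
        return self.ARE1 - self.ARE

    @property
    def phi_alpha(self) -> float:
        return (self.gamma2 - self.gamma1) * self.alpha

    def with_(self, **changes) -> "ScenarioConfig":
        return replace(self, **changes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("obs_per_subject", "obs_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def biases(scenario: ScenarioConfig) -> tuple[float, float]:
    """(projection bias phi_alpha, generalizability bias zeta)."""
    return scenario.phi_alpha, scenario.zeta


@dataclass(frozen=True)
class SimulatedIndividual:
    """One member of the target population with latent generative values."""

    id: str
    Z: int                    # trial eligibility indicator
    Delta: float              # individual treatment effect at alpha
    gamma0_i: float           # outcome at the offer
    R: int = 1                # randomized arm (trials only; cohort all 1)
    trial: int = -1           # trial-subset index when Z = 1


def control_mean(individual: SimulatedIndividual, t, scenario: ScenarioConfig):
    """Noise-free untreated trajectory: two-slope line through gamma0_i."""
    t = np.asarray(t, dtype=float)
    return individual.gamma0_i + np.where(
        t < 0, scenario.gamma1 * t, scenario.gamma2 * t
    )


def treatment_offset(individual: SimulatedIndividual, t, scenario: ScenarioConfig):
    """Treated-minus-untreated difference: zero for t <= 0, equals Delta_i at
    t = alpha, piecewise linear with its only kink at delta where the slope
    changes by (gamma3 - gamma2)."""
    t = np.asarray(t, dtype=float)
    a, d = scenario.alpha, scenario.delta
    g32 = scenario.gamma3 - scenario.gamma2
    D = individual.Delta
    if a < d:
        early = (D / a) * t
        late = (D / a) * d + g32 * (t - d)
    else:
        early = t * (D / d + g32 * (1.0 - a / d))
        late = D + g32 * (t - a)
    out = np.where(t < d, early, late)
    return np.where(t <= 0, 0.0, out)


def _residual(rng: np.random.Generator | None, scenario: ScenarioConfig, size):
    if rng is None or scenario.sigma == 0:
        return np.zeros(size)
    return rng.normal(0.0, scenario.sigma, size)


def control_trajectory(
    individual: SimulatedIndividual,
    t,
    scenario: ScenarioConfig,
    rng: np.random.Generator | None = None,
):
    """Untreated outcome(s) at time(s) t, one residual per observation."""
    t = np.asarray(t, dtype=float)
    return control_mean(individual, t, scenario) + _residual(rng, scenario, t.shape)


def treated_trajectory(
    individual: SimulatedIndividual,
    t,
    scenario: ScenarioConfig,
    rng: np.random.Generator | None = None,
):
    """Outcome(s) under treatment offer; reverts to the untreated line for
    t < 0 (treatment cannot act before the offer)."""
    t = np.asarray(t, dtype=float)
    base = control_mean(individual, t, scenario)
    return base + treatment_offset(individual, t, scenario) + _residual(
        rng, scenario, t.shape
    )


# --- study generation -----------------------------------------------------

def _trial_sizes(n1: int, k: int) -> list[int]:
    base, rem = divmod(n1, k)
    return [base + (1 if j < rem else 0) for j in range(k)]


def simulate_trials(
    scenario: ScenarioConfig, rng: np.random.Generator
) -> list[TrialResult]:
    """Generate k randomized trials and aggregate each to an estimate + SE.

    Trial j draws its own effect level ARE1_j ~ N(ARE1, tau1^2) and intercept
    level Gamma01_j ~ N(Gamma01, tau0^2); participants split 50:50 by
    randomization; the per-participant change score is the outcome at alpha
    minus the outcome at the offer, each carrying its own residual.
    """
    out: list[TrialResult] = []
    omega = np.sqrt(scenario.omega_sq)
    omega0 = np.sqrt(scenario.omega0_sq)
    for j, n_j in enumerate(_trial_sizes(scenario.n1, scenario.k)):
        are1_j = rng.normal(scenario.ARE1, np.sqrt(scenario.tau1_sq))
        g01_j = rng.normal(scenario.Gamma01, np.sqrt(scenario.tau0_sq))
        deltas = rng.normal(are1_j, omega, n_j)
        g0 = rng.normal(g01_j, omega0, n_j)
        arms = rng.binomial(1, 0.5, n_j)
        changes_t, changes_c = [], []
        for i in range(n_j):
            ind = SimulatedIndividual(
                id=f"T{j}_{i}", Z=1, Delta=deltas[i], gamma0_i=g0[i],
                R=int(arms[i]), trial=j,
            )
            y0 = control_trajectory(ind, 0.0, scenario, rng)
            if arms[i] == 1:
                ya = treated_trajectory(ind, scenario.alpha, scenario, rng)
                changes_t.append(float(ya - y0))
            else:
                ya = control_trajectory(ind, scenario.alpha, scenario, rng)
                changes_c.append(float(ya - y0))
        out.append(summarize_trial(changes_t, changes_c, trial_id=f"trial_{j}"))
    return out


def simulate_cohort(
    scenario: ScenarioConfig, rng: np.random.Generator
) -> CohortDataset:
    """Generate a treated cohort of n2 individuals from the target population.

    Eligibility Z ~ Bernoulli(pi); latent effects and intercepts use the
    marginal stratum distributions (trial-subset levels integrated out, the
    cohort being sampled independently of any particular trial replicate).
    Each subject gets a DiscreteUniform(1, 8) number of observations at
    times U(-1, 3), sorted; everyone is offered treatment so all outcomes
    follow the treated trajectory. Eligibility flags are set to Z.
    """
    n2 = scenario.n2
    z = rng.binomial(1, scenario.pi, n2)
    nu = np.sqrt(scenario.nu_sq)
    deltas = np.where(
        z == 1,
        rng.normal(scenario.ARE1, nu, n2),
        rng.normal(scenario.ARE2, nu, n2),
    )
    g0 = np.where(
        z == 1,
        rng.normal(scenario.Gamma01, scenario.sigma0, n2),
        rng.normal(scenario.Gamma02, scenario.sigma0, n2),
    )
    lo_n, hi_n = scenario.obs_per_subject
    t_lo, t_hi = scenario.obs_window
    rows = []
    for i in range(n2):
        ind = SimulatedIndividual(
            id=f"C{i:05d}", Z=int(z[i]), Delta=float(deltas[i]),
            gamma0_i=float(g0[i]),
        )
        n_obs = int(rng.integers(lo_n, hi_n + 1))
        times = np.sort(rng.uniform(t_lo, t_hi, n_obs))
        ys = treated_trajectory(ind, times, scenario, rng)
        for t_ij, y_ij in zip(times, ys):
            rows.append((ind.id, float(t_ij), float(y_ij)))
    records = pd.DataFrame(rows, columns=["subject_id", "time_years", "adjusted_score"])
    # continuous simulated scores: keep the standardization identity by
    # recording them over the full 30-item denominator
    records["denominator"] = 30
    records["numerator"] = records.adjusted_score
    baselines = pd.DataFrame(
        {
            "subject_id": [f"C{i:05d}" for i in range(n2)],
            "eligible": z.astype(bool),
        }
    )
    eligible = {f"C{i:05d}": bool(z[i]) for i in range(n2)}
    return CohortDataset(records=records, baselines=baselines, eligible=eligible)


@dataclass
class SimulatedStudyData:
    """One replicate of the full study: k trials plus a treated cohort,
    with the generating scenario kept as ground truth."""

    trials: list[TrialResult]
    cohort: CohortDataset
    truth: ScenarioConfig = field(repr=False)


def simulate_study(scenario: ScenarioConfig, seed: int | None = None) -> SimulatedStudyData:
    """Generate trials and cohort from one seeded stream (bit-reproducible:
    same scenario and seed give identical datasets)."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    trials = simulate_trials(scenario, rng)
    cohort = simulate_cohort(scenario, rng)
    return SimulatedStudyData(trials=trials, cohort=cohort, truth=scenario)
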