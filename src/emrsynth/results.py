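"""Posterior results containers shared by the trajectory models."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PosteriorSummary:
    """Posterior draws with per-parameter summaries and sampler diagnostics.

    ``draws`` maps parameter name -> array of shape (chains, draws); ensemble
    walkers play the role of chains for the split-R-hat and effective sample
    size computations. ``divergences`` is always 0 for the ensemble sampler
    (the concept belongs to Hamiltonian samplers) and is kept for interface
    stability.
    """

    draws: dict[str, np.ndarray]
    acceptance: float = np.nan
    divergences: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.draws.values()}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent draw shapes {shapes}")
        (self.shape,) = shapes
        idata = az.from_dict({k: v for k, v in self.draws.items()})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        self.rhat = {k: float(rhat[k].values) for k in self.draws}
        self.ess = {k: float(ess[k].values) for k in self.draws}

    @property
    def n_chains(self) -> int:
        return self.shape[0]

    @property
    def n_draws(self) -> int:
        return int(np.prod(self.shape))

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.flat(name).mean())

    def sd(self, name: str) -> float:
        return float(self.flat(name).std(ddof=1))

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        q = np.quantile(self.flat(name), [lo, 1.0 - lo])
        return float(q[0]), float(q[1])

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior mean, SD, central credible interval and diagnostics."""
        rows = []
        for name in self.draws:
            lo, hi = self.ci(name, level)
            rows.append(
                {
                    "parameter": name,
                    "mean": self.mean(name),
                    "sd": self.sd(name),
                    f"ci_{level:.0%}_low": lo,
                    f"ci_{level:.0%}_high": hi,
                    "rhat": self.rhat[name],
                    "ess": self.ess[name],
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def to_csv(self, path) -> None:
        self.summary().to_csv(path)


def check_convergence(
    summary: PosteriorSummary,
    rhat_max: float = 1.05,
    max_divergences: int = 0,
) -> bool:
    """True iff every split-R-hat is <= ``rhat_max`` (closed bound) and the
    divergence count does not exceed ``max_divergences``. Requires >= 2
    chains, since R-hat is undefined for a single chain."""
    if summary.n_chains < 2:
        raise ConvergenceError("R-hat needs at least 2 chains")
    worst = max(summary.rhat.values())
    return worst <= rhat_max and summary.divergences <= max_divergences
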