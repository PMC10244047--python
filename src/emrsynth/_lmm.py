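"""Marginalized Bayesian linear mixed model sampled with an ensemble MCMC.

The trajectory models in this package are linear-Gaussian given the change
point ``delta`` and the variance components: outcomes stack as

    y = X(delta) beta + Z(delta) b + eps,   b_i ~ N(0, Sigma_b),  eps ~ N(0, sigma^2 I)

with independent normal priors on the fixed coefficients ``beta``. Both the
subject random effects ``b_i`` and ``beta`` can therefore be integrated out
in closed form (Woodbury / matrix-determinant-lemma identities on the
low-rank structure), leaving a marginal posterior over the small
non-conjugate block

    psi = (delta, sigma, RE standard deviations, RE correlation terms).

That block is explored with the affine-invariant ensemble sampler (emcee);
``beta`` is then re-drawn exactly from its conditional normal for each
retained ensemble draw, so coefficient posteriors carry no extra
Monte-Carlo approximation beyond the psi draws themselves.

Random-effect covariance priors follow the usual vague recipes: a single
effect gets sd ~ U(0, bound); two effects get independent sd ~ U(0, bound)
plus correlation ~ U(-1, 1); three or more use the separation strategy
(sd ~ U(0, bound) scales around a correlation matrix parametrized by the
hyperspherical angles of its Cholesky factor, angles uniform on (0, pi)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import emcee
import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

_LOG2PI = float(np.log(2.0 * np.pi))


def corr_cholesky_from_angles(angles: np.ndarray, q: int) -> np.ndarray:
    """Lower-triangular Cholesky factor of a correlation matrix from its
    q(q-1)/2 hyperspherical angles in (0, pi), row-major below the diagonal."""
    L = np.zeros((q, q))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, q):
        sin_prod = 1.0
        for j in range(i):
            theta = angles[idx]
            idx += 1
            L[i, j] = np.cos(theta) * sin_prod
            sin_prod *= np.sin(theta)
        L[i, i] = sin_prod
    return L


@dataclass
class MarginalLMM:
    """Marginal log-posterior for one trajectory model.

    Parameters
    ----------
    y : outcome vector, rows sorted by subject.
    starts : first row index of each subject (for segment reductions).
    design : callable ``delta -> (X, Z)`` with X (N, p) fixed-effect columns
        and Z (N, q) random-effect columns, both recomputed per draw because
        the piecewise basis depends on the change point.
    prior_mean, prior_sd : independent normal prior on beta (length p).
    delta_bounds : support of the uniform change-point prior.
    sigma_bound, re_sd_bound : upper bounds of the U(0, b) scale priors.
    corr_param : "direct" (rho ~ U(-1,1); only valid for q <= 2) or
        "angles" (hyperspherical Cholesky, any q >= 2).
    """

    y: np.ndarray
    starts: np.ndarray
    design: Callable[[float], tuple[np.ndarray, np.ndarray]]
    prior_mean: np.ndarray
    prior_sd: np.ndarray
    q: int
    delta_bounds: tuple[float, float] = (0.0, 3.0)
    sigma_bound: float = 100.0
    re_sd_bound: float = 100.0
    corr_param: str = "direct"

    def __post_init__(self) -> None:
        if self.corr_param == "direct" and self.q > 2:
            raise ValueError("direct correlation parametrization needs q <= 2")
        self.n_corr = 0 if self.q < 2 else self.q * (self.q - 1) // 2
        self.ndim = 2 + self.q + self.n_corr
        self.n_obs = len(self.y)
        self.n_subjects = len(self.starts)

    # --- parameter vector layout: [delta, sigma, sds (q), corr (n_corr)] ---

    def unpack(self, psi: np.ndarray):
        delta = psi[0]
        sigma = psi[1]
        sds = psi[2 : 2 + self.q]
        corr = psi[2 + self.q :]
        return delta, sigma, sds, corr

    def _within_support(self, psi: np.ndarray) -> bool:
        delta, sigma, sds, corr = self.unpack(psi)
        lo, hi = self.delta_bounds
        if not (lo + 1e-6 < delta < hi - 1e-6):
            return False
        if not (1e-6 < sigma < self.sigma_bound):
            return False
        if np.any(sds <= 1e-6) or np.any(sds >= self.re_sd_bound):
            return False
        if self.corr_param == "direct":
            if corr.size and not (-1.0 + 1e-6 < corr[0] < 1.0 - 1e-6):
                return False
        else:
            if corr.size and (np.any(corr <= 1e-4) or np.any(corr >= np.pi - 1e-4)):
                return False
        return True

    def re_cholesky(self, sds: np.ndarray, corr: np.ndarray) -> np.ndarray:
        """Cholesky factor of the random-effect covariance Sigma_b."""
        if self.q == 1:
            return np.array([[sds[0]]])
        if self.corr_param == "direct":
            rho = corr[0]
            Lc = np.array([[1.0, 0.0], [rho, np.sqrt(1.0 - rho * rho)]])
        else:
            Lc = corr_cholesky_from_angles(corr, self.q)
        return sds[:, None] * Lc

    # --- marginal likelihood ----------------------------------------------

    def _segment_moments(self, delta: float):
        """Per-subject Z'Z, Z'X, Z'y and global X'X, X'y, y'y for this delta."""
        X, Z = self.design(delta)
        r = self.y - X @ self.prior_mean
        ZtZ = np.add.reduceat(Z[:, :, None] * Z[:, None, :], self.starts, axis=0)
        ZtX = np.add.reduceat(Z[:, :, None] * X[:, None, :], self.starts, axis=0)
        Ztr = np.add.reduceat(Z * r[:, None], self.starts, axis=0)
        XtX = X.T @ X
        Xtr = X.T @ r
        rtr = float(r @ r)
        return X, Z, r, ZtZ, ZtX, Ztr, XtX, Xtr, rtr

    def _collapse(self, psi: np.ndarray):
        """Return (loglik, B_cho, XtVir) after integrating b and beta.

        B = Sigma_beta^{-1} + X' V^{-1} X is the conditional precision of
        beta; its Cholesky factorization is reused for exact beta draws.
        """
        delta, sigma, sds, corr = self.unpack(psi)
        Lb = self.re_cholesky(sds, corr)
        # Sigma_b^{-1} and log|Sigma_b| via the Cholesky factor
        Lb_inv = np.linalg.inv(Lb)
        Sb_inv = Lb_inv.T @ Lb_inv
        logdet_Sb = 2.0 * float(np.sum(np.log(np.diag(Lb))))

        X, Z, r, ZtZ, ZtX, Ztr, XtX, Xtr, rtr = self._segment_moments(delta)
        s2 = sigma * sigma
        # A_i = Sigma_b^{-1} + Z_i'Z_i / sigma^2  (q x q per subject)
        A = Sb_inv[None, :, :] + ZtZ / s2
        sign, logdet_A = np.linalg.slogdet(A)
        if np.any(sign <= 0):
            return -np.inf, None, None
        AinvZtX = np.linalg.solve(A, ZtX)           # (m, q, p)
        AinvZtr = np.linalg.solve(A, Ztr[:, :, None])[:, :, 0]  # (m, q)

        XtViX = (XtX - np.einsum("mqp,mqr->pr", ZtX, AinvZtX) / s2) / s2
        XtVir = (Xtr - np.einsum("mq,mqp->p", Ztr, AinvZtX) / s2) / s2
        rtVir = (rtr - float(np.einsum("mq,mq->", Ztr, AinvZtr)) / s2) / s2
        logdet_V = (
            self.n_obs * np.log(s2)
            + float(np.sum(logdet_A))
            + self.n_subjects * logdet_Sb
        )

        prior_prec = 1.0 / self.prior_sd**2
        B = XtViX + np.diag(prior_prec)
        try:
            B_cho = cho_factor(B, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf, None, None
        logdet_B = 2.0 * float(np.sum(np.log(np.diag(B_cho[0]))))
        logdet_Sbeta = float(np.sum(np.log(self.prior_sd**2)))
        Binv_XtVir = cho_solve(B_cho, XtVir)
        quad = rtVir - float(XtVir @ Binv_XtVir)
        loglik = -0.5 * (
            logdet_V + logdet_Sbeta + logdet_B + quad + self.n_obs * _LOG2PI
        )
        return loglik, B_cho, Binv_XtVir

    def log_prob(self, psi: np.ndarray) -> float:
        """Log posterior density of psi (flat priors within the support)."""
        if not self._within_support(psi):
            return -np.inf
        loglik, _, _ = self._collapse(psi)
        if not np.isfinite(loglik):
            return -np.inf
        return loglik

    def draw_beta(self, psi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Exact draw from beta | psi, y (conditional multivariate normal)."""
        loglik, B_cho, Binv_XtVir = self._collapse(psi)
        if not np.isfinite(loglik):
            raise ValueError("psi outside the posterior support")
        mean = self.prior_mean + Binv_XtVir
        z = rng.standard_normal(len(mean))
        # B = L L' => cov = B^{-1}, sample = mean + L'^{-1} z
        Lfac = np.tril(B_cho[0])
        return mean + solve_triangular(Lfac.T, z, lower=False)


@dataclass
class EnsembleRun:
    """Raw output of one ensemble run: psi chain plus exact beta draws."""

    psi: np.ndarray        # (walkers, kept_steps, ndim)
    beta: np.ndarray       # (walkers, kept_steps, p)
    acceptance: float
    n_walkers: int
    n_steps: int
    n_warmup: int


def run_ensemble(
    lmm: MarginalLMM,
    init_center: np.ndarray,
    seed: int,
    n_steps: int = 1200,
    n_warmup: int | None = None,
    n_walkers: int | None = None,
    thin: int = 2,
) -> EnsembleRun:
    """Run the affine-invariant ensemble over psi and append exact beta draws.

    Walkers start in a small ball around ``init_center`` (clipped into the
    prior support); the first ``n_warmup`` steps (default half) are
    discarded and the remainder thinned.
    """
    ndim = lmm.ndim
    if n_walkers is None:
        n_walkers = max(2 * ndim + 2, 12)
    if n_warmup is None:
        n_warmup = n_steps // 2
    rng = np.random.default_rng(seed)

    p0 = np.empty((n_walkers, ndim))
    for w in range(n_walkers):
        for attempt in range(200):
            cand = init_center * (1.0 + 0.05 * rng.standard_normal(ndim))
            cand += 0.01 * rng.standard_normal(ndim)
            if np.isfinite(lmm.log_prob(cand)):
                p0[w] = cand
                break
        else:
            raise RuntimeError("could not initialize walkers in the support")

    # differential-evolution moves traverse the correlated (delta, sigma,
    # RE-scale) posterior far more efficiently than the default stretch move
    sampler = emcee.EnsembleSampler(
        n_walkers,
        ndim,
        lmm.log_prob,
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    state = sampler.run_mcmc(
        p0, n_steps, progress=False, skip_initial_state_check=True
    )
    del state
    chain = sampler.get_chain(discard=n_warmup, thin=thin)  # (steps, walkers, ndim)
    psi = np.swapaxes(chain, 0, 1)                          # (walkers, steps, ndim)

    n_w, n_kept, _ = psi.shape
    p = len(lmm.prior_mean)
    beta = np.empty((n_w, n_kept, p))
    for w in range(n_w):
        for s in range(n_kept):
            beta[w, s] = lmm.draw_beta(psi[w, s], rng)
    return EnsembleRun(
        psi=psi,
        beta=beta,
        acceptance=float(np.mean(sampler.acceptance_fraction)),
        n_walkers=n_walkers,
        n_steps=n_steps,
        n_warmup=n_warmup,
    )
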