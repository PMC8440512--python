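"""Blocked Gibbs sampler for the Gaussian linear mixed model.

Model:  y = X beta + sum_g z_g * u_g[group_g] + eps,
        eps ~ N(0, sigma^2),  u_g[j] ~ N(0, tau_g^2) iid,
        beta ~ N(0, prior_sd^2 I),
        tau_g^2, sigma^2 ~ Inverse-Gamma.

Every conditional is conjugate, so the sampler alternates exact draws:
the fixed-effect block from its multivariate normal conditional, each
random-effect vector group-wise (scalar normals, vectorized over groups),
and the variances from inverse-gamma conditionals.  There are no
accept/reject steps and hence no divergent transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RandomTerm", "GibbsResult", "gibbs_lmm"]


@dataclass(frozen=True)
class RandomTerm:
    """One variance component: ``z * u[group]`` with iid normal levels."""

    name: str
    group_codes: np.ndarray  # (n,) int codes in [0, n_levels)
    z: np.ndarray  # (n,) covariate (ones for a random intercept)
    n_levels: int


@dataclass
class GibbsResult:
    beta: np.ndarray  # (chains, draws, p)
    sigma2: np.ndarray  # (chains, draws)
    tau2: dict[str, np.ndarray]  # name -> (chains, draws)


def _run_chain(
    y: np.ndarray,
    X: np.ndarray,
    terms: list[RandomTerm],
    prior_sd: float,
    iterations: int,
    warmup: int,
    rng: np.random.Generator,
    ig_a: float,
    ig_b: float,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    n, p = X.shape
    XtX = X.T @ X
    prior_prec = np.eye(p) / prior_sd**2
    # per-term sufficient statistics
    z2_sums = [
        np.bincount(t.group_codes, weights=t.z**2, minlength=t.n_levels)
        for t in terms
    ]
    beta = np.zeros(p)
    us = [np.zeros(t.n_levels) for t in terms]
    tau2 = np.ones(len(terms))
    sigma2 = float(np.var(y)) or 1.0

    keep = iterations - warmup
    beta_draws = np.empty((keep, p))
    sigma2_draws = np.empty(keep)
    tau2_draws = np.empty((keep, len(terms)))

    ranef_total = np.zeros(n)
    for it in range(iterations):
        # beta | rest
        r = y - ranef_total
        prec = XtX / sigma2 + prior_prec
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, X.T @ r / sigma2)
        beta = mean + np.linalg.solve(chol.T, rng.standard_normal(p))
        fixed = X @ beta

        # each random term | rest
        for k, t in enumerate(terms):
            ranef_total -= t.z * us[k][t.group_codes]
            resid = y - fixed - ranef_total
            zr = np.bincount(t.group_codes, weights=t.z * resid, minlength=t.n_levels)
            post_prec = z2_sums[k] / sigma2 + 1.0 / tau2[k]
            post_mean = (zr / sigma2) / post_prec
            us[k] = post_mean + rng.standard_normal(t.n_levels) / np.sqrt(post_prec)
            ranef_total += t.z * us[k][t.group_codes]
            # tau2 | u
            tau2[k] = 1.0 / rng.gamma(
                ig_a + t.n_levels / 2.0, 1.0 / (ig_b + 0.5 * us[k] @ us[k])
            )

        # sigma2 | rest
        resid = y - fixed - ranef_total
        sigma2 = 1.0 / rng.gamma(
            ig_a + n / 2.0, 1.0 / (ig_b + 0.5 * resid @ resid)
        )

        if it >= warmup:
            j = it - warmup
            beta_draws[j] = beta
            sigma2_draws[j] = sigma2
            tau2_draws[j] = tau2
    return beta_draws, sigma2_draws, tau2_draws


def gibbs_lmm(
    y,
    X,
    terms: list[RandomTerm],
    prior_sd: float = 10.0,
    chains: int = 4,
    iterations: int = 5000,
    warmup: int = 1000,
    seed: int | None = None,
    ig_a: float = 0.5,
    ig_b: float = 0.5,
) -> GibbsResult:
    """Sample the posterior of a Gaussian LMM; returns per-chain draws."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if chains < 2:
        raise ValueError("at least 2 chains are required for diagnostics")
    if warmup >= iterations:
        raise ValueError("warmup must be smaller than iterations")
    keep = iterations - warmup
    p = X.shape[1]
    beta = np.empty((chains, keep, p))
    sigma2 = np.empty((chains, keep))
    tau2 = {t.name: np.empty((chains, keep)) for t in terms}
    seeds = np.random.SeedSequence(seed).spawn(chains)
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        b, s2, t2 = _run_chain(
            y, X, terms, prior_sd, iterations, warmup, rng, ig_a, ig_b
        )
        beta[c] = b
        sigma2[c] = s2
        for k, t in enumerate(terms):
            tau2[t.name][c] = t2[:, k]
    return GibbsResult(beta=beta, sigma2=sigma2, tau2=tau2)
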