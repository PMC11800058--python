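"""Stage 1: per-environment mixed-model analysis of plot data.

For each environment and trait the model is

    y_ijk = mu + L_i + R_j + B_k(R_j) + e_ijk

with genotype L_i ~ N(0, sigma_L^2) and block-within-replicate
B_k(R_j) ~ N(0, sigma_BR^2) random, replicate R_j fixed, and plot error
e_ijk ~ N(0, sigma_e^2).  Variance components are estimated by REML —
direct maximization of the restricted log-likelihood over the two
variance ratios (genotype/error, block/error) with the error variance
profiled out — and genotype BLUPs come from the mixed-model equations
at the estimates.  Negative components are handled by the box
constraint gamma >= 0 (boundary REML).

Broad-sense heritability on an entry-mean basis is
H^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / r) with r replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "Stage1Fit",
    "fit_stage1",
    "heritability",
    "adjusted_phenotypes",
    "stage1_summary",
]

_LOG2PI = np.log(2 * np.pi)


@dataclass
class Stage1Fit:
    """REML fit of the stage-1 model for one (environment, trait)."""

    environment: str
    trait: str
    mu: float
    rep_effects: dict[str, float]
    sigma_g2: float
    sigma_br2: float
    sigma_e2: float
    blups: pd.Series          # genotype -> predicted deviation from mu
    loglik: float             # restricted log-likelihood at the optimum
    n_obs: int
    n_iter: int

    @property
    def adjusted(self) -> pd.Series:
        """Adjusted phenotypes: mu-hat + genotype BLUP."""
        return self.mu + self.blups

    @property
    def h2(self) -> float:
        r = max(len(self.rep_effects), 1)
        return heritability(self.sigma_g2, self.sigma_e2, r)


def _design(sub: pd.DataFrame, trait: str):
    """Fixed and random design matrices for one environment's plots."""
    y = sub[trait].to_numpy(float)
    reps = sorted(sub["rep"].unique())
    genos = sorted(sub["genotype"].unique())
    blocks = sorted({(r, b) for r, b in zip(sub["rep"], sub["block"])})
    n = len(sub)
    x = np.ones((n, len(reps)))
    for j, r in enumerate(reps[1:], start=1):
        x[:, j] = (sub["rep"] == r).to_numpy(float)
    zg = np.zeros((n, len(genos)))
    zg[np.arange(n), pd.Categorical(sub["genotype"], categories=genos).codes] = 1.0
    zb = np.zeros((n, len(blocks)))
    bidx = {rb: k for k, rb in enumerate(blocks)}
    for i, rb in enumerate(zip(sub["rep"], sub["block"])):
        zb[i, bidx[rb]] = 1.0
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("singular fixed-effects design (replicate structure)")
    return y, x, zg, zb, reps, genos


def _reml_neg_loglik(gam: np.ndarray, y, x, zg, zb) -> float:
    """Negative restricted log-likelihood profiled over the error variance.

    H = I + gamma_g Zg Zg' + gamma_b Zb Zb'; the restricted likelihood is
    -1/2 [ log|H| + log|X'H^-1 X| + (n-p)(1 + log(2 pi sigma_e^2-hat)) ]
    with sigma_e^2-hat = y'Py / (n-p).
    """
    n, p = x.shape
    h = np.eye(n) + gam[0] * (zg @ zg.T) + gam[1] * (zb @ zb.T)
    try:
        ch = np.linalg.cholesky(h)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_h = 2.0 * np.log(np.diag(ch)).sum()
    hi_x = np.linalg.solve(h, x)
    hi_y = np.linalg.solve(h, y)
    xhx = x.T @ hi_x
    sign, logdet_xhx = np.linalg.slogdet(xhx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xhx, x.T @ hi_y)
    ypy = y @ hi_y - (x.T @ hi_y) @ beta
    if ypy <= 0:
        return np.inf
    s2 = ypy / (n - p)
    return 0.5 * (logdet_h + logdet_xhx + (n - p) * (1.0 + _LOG2PI + np.log(s2)))


def fit_stage1(plots: pd.DataFrame, environment: str, trait: str) -> Stage1Fit:
    """REML fit of the stage-1 model for one environment and trait.

    ``plots`` is a long table with columns env, genotype, rep, block and
    one column per trait.  Raises on a singular replicate design or if
    the optimizer fails from every start.
    """
    sub = plots[plots["env"] == environment]
    if sub.empty:
        raise ValueError(f"no plots for environment {environment!r}")
    if sub["genotype"].nunique() < 2:
        raise ValueError("need at least two genotypes")
    y, x, zg, zb, reps, genos = _design(sub, trait)

    # optimize over log variance ratios: well-scaled finite differences at
    # any magnitude, with the lower bound exp(-30) standing in for gamma = 0
    def objective(theta: np.ndarray) -> float:
        return _reml_neg_loglik(np.exp(theta), y, x, zg, zb)

    starts = [(-0.7, -0.7), (0.7, -2.3), (-3.0, -3.0), (1.6, 0.0)]
    best = None
    n_iter = 0
    for s in starts:
        res = optimize.minimize(
            objective,
            x0=np.array(s),
            args=(),
            method="L-BFGS-B",
            # upper bound exp(18.4) ~ 1e8 keeps H well enough conditioned
            # for the dense solves while making shrinkage negligible
            bounds=[(-30.0, 18.4)] * 2,
        )
        n_iter += res.nit
        # a degenerate (noise-free) response drives gamma to the box bound
        # and trips the line search; any finite optimum is still usable
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            f"REML did not converge for {environment}/{trait} "
            f"after {n_iter} iterations over {len(starts)} starts"
        )
    gam = np.exp(best.x)
    gam = np.where(gam < 1e-9, 0.0, gam)

    # error variance and effects from the mixed-model equations at gamma-hat
    n, p = x.shape
    h = np.eye(n) + gam[0] * (zg @ zg.T) + gam[1] * (zb @ zb.T)
    hi_x = np.linalg.solve(h, x)
    hi_y = np.linalg.solve(h, y)
    xhx = x.T @ hi_x
    beta = np.linalg.solve(xhx, x.T @ hi_y)
    ypy = y @ hi_y - (x.T @ hi_y) @ beta
    s2e = float(ypy / (n - p))
    resid_proj = hi_y - hi_x @ beta          # H^-1 (y - X beta) = P y
    u_g = gam[0] * (zg.T @ resid_proj)       # BLUP: gamma Z' P y
    u_b = gam[1] * (zb.T @ resid_proj)
    del u_b  # block BLUPs are nuisance; only their variance is reported

    mu = float(beta[0] + np.mean([0.0, *beta[1:]]))  # average over replicates
    blups = pd.Series(u_g, index=genos, name=trait)
    return Stage1Fit(
        environment=environment,
        trait=trait,
        mu=mu,
        rep_effects={str(r): (0.0 if j == 0 else float(beta[j]))
                     for j, r in enumerate(reps)},
        sigma_g2=float(gam[0] * s2e),
        sigma_br2=float(gam[1] * s2e),
        sigma_e2=s2e,
        blups=blups,
        loglik=-float(best.fun),
        n_obs=n,
        n_iter=n_iter,
    )


def heritability(sigma_g2: float, sigma_e2: float, r: int) -> float:
    """Entry-mean broad-sense heritability sigma_g^2/(sigma_g^2 + sigma_e^2/r)."""
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be >= 0")
    if r < 1:
        raise ValueError("replicate count must be >= 1")
    if sigma_g2 == 0 and sigma_e2 == 0:
        raise ValueError("heritability undefined when both variances are zero")
    return sigma_g2 / (sigma_g2 + sigma_e2 / r)


def adjusted_phenotypes(
    plots: pd.DataFrame, traits: list[str] | None = None
) -> pd.DataFrame:
    """Stage-1 adjusted phenotypes for every (environment, genotype, trait).

    Long table with columns env, genotype, trait, value where
    value = mu-hat + genotype BLUP from the per-environment fit.  These
    are the responses the stage-2 prediction models consume.
    """
    if traits is None:
        traits = [c for c in plots.columns if c not in ("env", "genotype", "rep", "block")]
    rows = []
    for env in sorted(plots["env"].unique()):
        for trait in traits:
            fit = fit_stage1(plots, env, trait)
            adj = fit.adjusted
            rows.append(
                pd.DataFrame(
                    {"env": env, "genotype": adj.index, "trait": trait, "value": adj.values}
                )
            )
    return pd.concat(rows, ignore_index=True)


def stage1_summary(plots: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Per-environment summary: mean, SD of adjusted values, components, H^2."""
    if traits is None:
        traits = [c for c in plots.columns if c not in ("env", "genotype", "rep", "block")]
    rows = []
    for env in sorted(plots["env"].unique()):
        for trait in traits:
            fit = fit_stage1(plots, env, trait)
            rows.append(
                {
                    "env": env,
                    "trait": trait,
                    "mean": fit.mu,
                    "sd": float(fit.adjusted.std(ddof=1)),
                    "sigma_g2": fit.sigma_g2,
                    "sigma_br2": fit.sigma_br2,
                    "sigma_e2": fit.sigma_e2,
                    "h2": fit.h2,
                }
            )
    return pd.DataFrame(rows)
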