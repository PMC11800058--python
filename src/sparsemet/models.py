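"""Stage 2: kernel-based genomic prediction models M1, M2, M3.

The response is the vector of stage-1 adjusted phenotypes over
(genotype, environment) cells.  Each model is a Bayesian linear mixed
model with an intercept, one Gaussian random effect per covariance
kernel, and i.i.d. Gaussian error:

* M1 (E + L):          environment block kernel Z_E Z_E', iid line
  kernel Z_g Z_g'
* M2 (E + L + G):      M1 plus the genomic kernel Z_g G Z_g'
* M3 (E + L + G + GxE): M2 plus the reaction-norm interaction kernel
  (Z_g G Z_g') o (Z_E Z_E') — the Hadamard product that zeroes genomic
  covariance between cells in different environments.

Fitting uses a Gibbs sampler parameterized on each kernel's eigenbasis
restricted to the observed cells (the spectral decomposition is done
once per kernel, after which the coordinate effects have a diagonal
joint conditional), with scaled-inverse-chi-square priors on all
variance components.  Masked cells are predicted at each retained sweep
through the Gaussian conditional mean K[masked, observed] K[obs, obs]^+ u,
and posterior means over sweeps are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import GRM

__all__ = [
    "CellFrame",
    "Kernel",
    "SamplerConfig",
    "FitResult",
    "build_kernels",
    "fit_model",
    "MODELS",
]

MODELS = ("M1", "M2", "M3")

#: eigenvalues below this fraction of the largest are treated as null space
_EIG_TOL = 1e-10


@dataclass
class CellFrame:
    """Ordered (genotype, environment) cells with responses and masking.

    ``y`` holds the adjusted phenotype per cell; masked cells (observed
    = False) carry no response and are the prediction targets.
    """

    genotypes: np.ndarray
    environments: np.ndarray
    y: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=object)
        self.environments = np.asarray(self.environments, dtype=object)
        self.y = np.asarray(self.y, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        n = len(self.genotypes)
        if not (len(self.environments) == len(self.y) == len(self.observed) == n):
            raise ValueError("cell arrays must have equal length")
        cells = list(zip(self.genotypes, self.environments))
        if len(set(cells)) != n:
            raise ValueError("duplicate (genotype, environment) cells")
        if not self.observed.any():
            raise ValueError("need at least one observed cell")

    def __len__(self) -> int:
        return len(self.genotypes)

    @classmethod
    def from_blups(
        cls, blups: pd.DataFrame, trait: str, observed_cells: set[tuple[str, str]]
    ) -> "CellFrame":
        """Build cells for one trait from a long adjusted-phenotype table.

        ``observed_cells`` is the set of (genotype, env) pairs that count
        as phenotyped; everything else is masked for prediction.
        """
        sub = blups[blups["trait"] == trait]
        obs = np.array(
            [(g, e) in observed_cells for g, e in zip(sub["genotype"], sub["env"])]
        )
        return cls(
            genotypes=sub["genotype"].to_numpy(object),
            environments=sub["env"].to_numpy(object),
            y=sub["value"].to_numpy(float),
            observed=obs,
        )


@dataclass
class Kernel:
    """A cells x cells covariance kernel with a structural label."""

    label: str  # env | line | genomic | gxe
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kernel must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError(f"kernel {self.label!r} is not symmetric")
        self.values = (v + v.T) / 2.0


def build_kernels(cells: CellFrame, grm: GRM | None, model: str) -> list[Kernel]:
    """Covariance kernels over the cells for one of the models M1/M2/M3.

    The interaction kernel is the elementwise (Hadamard) product of the
    genomic kernel and the same-environment indicator, hence zero for
    every pair of cells in different environments.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    same_env = (
        cells.environments[:, None] == cells.environments[None, :]
    ).astype(float)
    same_line = (cells.genotypes[:, None] == cells.genotypes[None, :]).astype(float)
    kernels = [Kernel("env", same_env), Kernel("line", same_line)]
    if model in ("M2", "M3"):
        if grm is None:
            raise ValueError(f"model {model} requires a GRM")
        missing = sorted(set(cells.genotypes) - set(grm.genotype_ids))
        if missing:
            raise ValueError(f"genotypes absent from the GRM: {missing}")
        idx = {g: i for i, g in enumerate(grm.genotype_ids)}
        rows = np.array([idx[g] for g in cells.genotypes])
        genomic = grm.values[np.ix_(rows, rows)]
        kernels.append(Kernel("genomic", genomic))
        if model == "M3":
            kernels.append(Kernel("gxe", genomic * same_env))
    return kernels


@dataclass
class SamplerConfig:
    """Gibbs sampler settings and priors.

    Scaled-inverse-chi-square priors with ``df0`` degrees of freedom;
    prior modes split ``r2`` of the response variance equally across the
    kernel terms, the remainder going to the error.  ``fixed_components``
    pins variance components (label -> value, error under "error") so
    predictions can be checked against the closed-form mixed-model
    solution.
    """

    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 5
    df0: float = 5.0
    r2: float = 0.5
    seed: int | None = None
    fixed_components: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("chain length must exceed the burn-in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class FitResult:
    """Posterior summaries of one model fit."""

    components: dict[str, float]          # posterior-mean variance per kernel
    sigma_e2: float
    predictions: np.ndarray               # posterior-mean prediction per cell
    n_samples: int
    chains: dict[str, np.ndarray] = field(repr=False)
    ess: dict[str, float] = field(default_factory=dict)


def _ess(chain: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    n = len(chain)
    if n < 4 or np.ptp(chain) == 0:
        return float(n)
    c = chain - chain.mean()
    if c.var() == 0:  # constant up to rounding
        return float(n)
    acf = np.correlate(c, c, mode="full")[n - 1:] / (np.arange(n, 0, -1) * c.var())
    s = 0.0
    for k in range(1, n - 1):
        if acf[k] < 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def fit_model(
    cells: CellFrame, kernels: list[Kernel], config: SamplerConfig | None = None
) -> FitResult:
    """Fit a kernel mixed model by Gibbs sampling and predict every cell.

    Each kernel is eigendecomposed on the observed cells; effect
    coordinates on the orthonormal eigenbasis have independent Gaussian
    conditionals, making one sweep a handful of matrix-vector products.
    Masked cells receive the conditional-mean prediction given the
    sampled observed-cell effects, averaged over retained sweeps.
    """
    config = config or SamplerConfig()
    obs = cells.observed
    y_o = cells.y[obs]
    n_o = int(obs.sum())
    n_all = len(cells)
    masked = ~obs

    bases, preds, labels = [], [], []
    for k in kernels:
        koo = k.values[np.ix_(obs, obs)]
        evals, evecs = np.linalg.eigh(koo)
        top = evals.max() if len(evals) else 0.0
        if top <= 0:
            raise ValueError(f"kernel {k.label!r} is null on the observed cells")
        if evals.min() < -1e-8 * top:
            raise ValueError(
                f"kernel {k.label!r} is not PSD on the observed cells "
                f"(min eigenvalue {evals.min():.3e})"
            )
        keep = evals > _EIG_TOL * top
        d, v = evals[keep], evecs[:, keep]
        bases.append((v, d))
        # conditional-mean map for masked cells: K_mo V D^-1
        m = k.values[np.ix_(masked, obs)] @ v / d if masked.any() else None
        preds.append(m)
        labels.append(k.label)

    rng = np.random.default_rng(config.seed)
    var_y = float(np.var(y_o, ddof=1)) if n_o > 1 else 1.0
    df0 = config.df0
    # prior sum-of-squares nu*s0^2 chosen so the prior mode sits at
    # var_y*r2/n_kernels per kernel and var_y*(1-r2) for the error
    mode_k = var_y * config.r2 / max(len(kernels), 1)
    prior_ss_k = mode_k * (df0 + 2.0)
    prior_ss_e = var_y * (1.0 - config.r2) * (df0 + 2.0)

    fixed = config.fixed_components or {}
    sig = {lab: fixed.get(lab, mode_k) for lab in labels}
    sig_e = fixed.get("error", var_y * (1.0 - config.r2))
    mu = float(y_o.mean())
    b = [np.zeros(len(d)) for _, d in bases]
    e = y_o - mu

    n_keep = (config.n_iter - config.burn_in) // config.thin
    pred_sum = np.zeros(n_all)
    chains: dict[str, list[float]] = {lab: [] for lab in labels}
    chains["error"] = []
    kept = 0
    for it in range(config.n_iter):
        # intercept (flat prior)
        e += mu
        mu = float(rng.normal(e.mean(), np.sqrt(sig_e / n_o)))
        e -= mu
        # kernel effects on eigencoordinates: V'V = I so the joint
        # conditional is diagonal and sampled in one vectorized draw
        for j, (v, d) in enumerate(bases):
            e += v @ b[j]
            t = v.T @ e
            prec = 1.0 / sig_e + 1.0 / (sig[labels[j]] * d)
            cvar = 1.0 / prec
            b[j] = cvar * t / sig_e + np.sqrt(cvar) * rng.standard_normal(len(d))
            e -= v @ b[j]
            if labels[j] not in fixed:
                ss = float(np.sum(b[j] ** 2 / d))
                sig[labels[j]] = (prior_ss_k + ss) / rng.chisquare(df0 + len(d))
        if "error" not in fixed:
            sig_e = (prior_ss_e + float(e @ e)) / rng.chisquare(df0 + n_o)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            yhat = np.empty(n_all)
            fitted = mu + sum(v @ bj for (v, _), bj in zip(bases, b))
            yhat[obs] = fitted
            if masked.any():
                yhat[masked] = mu + sum(
                    m @ bj for m, bj in zip(preds, b) if m is not None
                )
            pred_sum += yhat
            for lab in labels:
                chains[lab].append(sig[lab])
            chains["error"].append(sig_e)
            kept += 1

    chain_arr = {lab: np.asarray(c) for lab, c in chains.items()}
    return FitResult(
        components={lab: float(chain_arr[lab].mean()) for lab in labels},
        sigma_e2=float(chain_arr["error"].mean()),
        predictions=pred_sum / kept,
        n_samples=kept,
        chains=chain_arr,
        ess={lab: _ess(c) for lab, c in chain_arr.items()},
    )
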