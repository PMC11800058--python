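"""Synthetic multi-environment-trial data with known genetic architecture.

Generates SNP marker matrices under Hardy-Weinberg proportions, additive
genetic values by marker regression (the implicit GBLUP prior: i.i.d.
Gaussian marker effects), environment-specific genetic deviations whose
covariance is sigma_gxe^2 * G within environment and zero across
environments, and plot-level phenotypes laid out as incomplete blocks
nested within complete replicates — the structure a two-replicate
alpha-lattice trial hands to a per-environment mixed-model analysis.

Ground truth (per-cell genetic values and their component breakdown) is
retained so downstream estimators can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MarkerMatrix

__all__ = [
    "VarianceComponents",
    "SimConfig",
    "TrueSignals",
    "simulate_markers",
    "simulate_effects",
    "simulate_plots",
    "simulate_dataset",
    "error_variance_for_h2",
    "default_config",
]


@dataclass
class VarianceComponents:
    """Variance components (trait units squared) for one trait.

    env is the variance of environment-effect deviations around the
    stated per-environment trait means (zero when the means already
    carry the environmental signal); g is the genotype main effect
    variance, gxe the genotype-by-environment interaction variance,
    block_in_rep the incomplete-block variance, error the plot residual.
    """

    env: float = 0.0
    g: float = 1.0
    gxe: float = 0.0
    block_in_rep: float = 0.0
    error: float = 1.0

    def __post_init__(self) -> None:
        for name in ("env", "g", "gxe", "block_in_rep", "error"):
            if getattr(self, name) < 0:
                raise ValueError(f"variance component {name!r} must be >= 0")


@dataclass
class SimConfig:
    """Configuration of one synthetic multi-environment trial."""

    n_genotypes: int = 435
    n_environments: int = 5
    n_markers: int = 2984
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    n_replicates: int = 2
    n_blocks_per_rep: int = 10
    variance_components: dict[str, VarianceComponents] = field(default_factory=dict)
    trait_means: dict[str, list[float]] = field(default_factory=dict)
    rep_effect_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5] with lo <= hi")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        for n in (self.n_genotypes, self.n_environments, self.n_markers,
                  self.n_replicates, self.n_blocks_per_rep):
            if n < 1:
                raise ValueError("all counts must be positive")
        if not self.variance_components:
            self.variance_components = {"trait1": VarianceComponents()}
        for trait, vc in list(self.variance_components.items()):
            if isinstance(vc, dict):
                self.variance_components[trait] = VarianceComponents(**vc)
        for trait in self.variance_components:
            means = self.trait_means.setdefault(trait, [0.0] * self.n_environments)
            if len(means) != self.n_environments:
                raise ValueError(
                    f"trait_means[{trait!r}] must list one mean per environment"
                )

    @property
    def traits(self) -> list[str]:
        return list(self.variance_components)

    @property
    def environment_ids(self) -> list[str]:
        return [f"E{l + 1}" for l in range(self.n_environments)]

    @property
    def genotype_ids(self) -> list[str]:
        width = len(str(self.n_genotypes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genotypes)]


@dataclass
class TrueSignals:
    """Ground-truth genetic values per (genotype, environment) cell.

    For each trait: ``env_effect[l] + g_main[i] + gxe[i, l]`` is the cell
    value, stored alongside its components so the decomposition identity
    holds exactly.
    """

    genotype_ids: list[str]
    environment_ids: list[str]
    env_effect: dict[str, np.ndarray]          # trait -> (n_env,)
    g_main: dict[str, np.ndarray]              # trait -> (n_geno,)
    gxe: dict[str, np.ndarray]                 # trait -> (n_geno, n_env)

    def cell_values(self, trait: str) -> np.ndarray:
        """(n_genotypes, n_environments) grid of true genetic values."""
        return (
            self.env_effect[trait][None, :]
            + self.g_main[trait][:, None]
            + self.gxe[trait]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for trait in self.env_effect:
            cells = self.cell_values(trait)
            for li, env in enumerate(self.environment_ids):
                for gi, geno in enumerate(self.genotype_ids):
                    rows.append(
                        {
                            "trait": trait,
                            "env": env,
                            "genotype": geno,
                            "env_effect": self.env_effect[trait][li],
                            "g_main": self.g_main[trait][gi],
                            "gxe": self.gxe[trait][gi, li],
                            "value": cells[gi, li],
                        }
                    )
        return pd.DataFrame(rows)


def error_variance_for_h2(genetic_variance: float, h2: float, r: int) -> float:
    """Plot error variance implied by an entry-mean heritability target.

    Inverts H^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / r).  The genetic
    variance should be the within-environment genotypic variance (main
    plus interaction) since a per-environment analysis cannot separate
    the two.
    """
    if not (0 < h2 < 1):
        raise ValueError("h2 must be in (0, 1)")
    return r * genetic_variance * (1.0 - h2) / h2


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Study-scale defaults: 435 genotypes, 5 environments, 2984 SNPs.

    Two traits on the cassava scale: dm (dry matter, g) with
    per-environment means 29.84-37.31 and entry-mean H^2 near 0.83, and
    fyld (fresh root yield, kg) with means 17.21-30.44 and H^2 near
    0.70.  Error variances are derived from those heritability targets
    at r = 2 replicates; block variance is a modest fraction of the
    plot error.
    """
    dm_g, dm_gxe = 4.5, 1.2
    fy_g, fy_gxe = 22.0, 9.0
    cfg = dict(
        n_genotypes=435,
        n_environments=5,
        n_markers=2984,
        maf_range=(0.05, 0.5),
        missing_rate=0.0,
        n_replicates=2,
        n_blocks_per_rep=10,
        variance_components={
            "dm": VarianceComponents(
                g=dm_g,
                gxe=dm_gxe,
                block_in_rep=0.5,
                error=error_variance_for_h2(dm_g + dm_gxe, 0.83, 2),
            ),
            "fyld": VarianceComponents(
                g=fy_g,
                gxe=fy_gxe,
                block_in_rep=2.5,
                error=error_variance_for_h2(fy_g + fy_gxe, 0.70, 2),
            ),
        },
        trait_means={
            "dm": [37.31, 34.04, 30.52, 33.60, 29.84],
            "fyld": [30.44, 21.41, 23.49, 25.74, 17.21],
        },
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def simulate_markers(config: SimConfig) -> MarkerMatrix:
    """Draw a genotypes x markers matrix under Hardy-Weinberg proportions.

    Each marker's minor allele frequency is sampled uniformly from
    ``config.maf_range``; genotype classes {0, 1, 2} then follow HWE
    proportions (f^2, 2f(1-f), (1-f)^2) with 0 the minor homozygote.
    Missing entries (NaN) are placed i.i.d. at ``config.missing_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n, p = config.n_genotypes, config.n_markers
    maf = rng.uniform(*config.maf_range, size=p)
    u = rng.random((n, p))
    p0 = maf**2
    p01 = p0 + 2 * maf * (1 - maf)
    values = np.where(u < p0, 0.0, np.where(u < p01, 1.0, 2.0))
    if config.missing_rate > 0:
        values[rng.random((n, p)) < config.missing_rate] = np.nan
    return MarkerMatrix(config.genotype_ids, [f"M{m + 1}" for m in range(p)], values)


def simulate_effects(markers: MarkerMatrix, config: SimConfig) -> TrueSignals:
    """Generate per-trait genetic values from the marker matrix.

    Genotype main effects are marker regressions g = X b with i.i.d.
    Gaussian effects b ~ N(0, sigma_g^2 / p) on the column-standardized
    matrix, so the main values have variance sigma_g^2 (G has unit mean
    diagonal).  Interaction deviations are drawn per environment from
    N(0, sigma_gxe^2 * G), independently across environments, so the
    genomic-kernel reaction-norm model is correctly specified for this
    generator.  Environment effects are the configured per-environment
    means plus optional N(0, sigma_env^2) deviations.
    """
    values = markers.values
    if np.isnan(values).any():
        raise ValueError("markers contain missing entries; impute before simulating")
    sd = values.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance marker columns cannot be standardized")
    x = (values - values.mean(axis=0)) / sd
    n, p = x.shape
    n_env = config.n_environments
    root = None
    if any(vc.gxe > 0 for vc in config.variance_components.values()):
        # one eigendecomposition of G serves every trait's interaction draw
        g_mat = x @ x.T / p
        evals, evecs = np.linalg.eigh((g_mat + g_mat.T) / 2)
        root = evecs * np.sqrt(np.clip(evals, 0.0, None))

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    env_effect, g_main, gxe = {}, {}, {}
    for trait, vc in config.variance_components.items():
        b = rng.normal(0.0, np.sqrt(vc.g / p), size=p)
        g_main[trait] = x @ b
        dev = np.zeros(n_env) if vc.env == 0 else rng.normal(0, np.sqrt(vc.env), n_env)
        env_effect[trait] = np.asarray(config.trait_means[trait]) + dev
        if vc.gxe > 0:
            z = rng.normal(size=(n, n_env))
            gxe[trait] = np.sqrt(vc.gxe) * (root @ z)
        else:
            gxe[trait] = np.zeros((n, n_env))
    return TrueSignals(
        list(markers.genotype_ids), config.environment_ids, env_effect, g_main, gxe
    )


def simulate_plots(signals: TrueSignals, config: SimConfig) -> pd.DataFrame:
    """Expand cell-level genetic values into plot-level records.

    Every (genotype, environment) cell yields ``n_replicates`` records:
    cell value + replicate effect (fixed within environment, drawn once
    from N(0, rep_effect_sd^2)) + incomplete-block effect (blocks
    randomized within replicate, variance sigma_BR^2) + plot error
    (variance sigma_e^2).  Columns: env, genotype, rep, block, then one
    column per trait.
    """
    if config.n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    n = len(signals.genotype_ids)
    n_blocks = config.n_blocks_per_rep
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 37]))
    traits = config.traits
    frames = []
    for li, env in enumerate(signals.environment_ids):
        # replicate effects are fixed effects: one draw per (env, rep)
        rep_eff = rng.normal(0.0, config.rep_effect_sd, size=config.n_replicates)
        rep_eff -= rep_eff.mean()  # identifiable against the intercept
        for rj in range(config.n_replicates):
            block_of = rng.permuted(np.arange(n) % n_blocks)  # balanced random blocks
            rec = {
                "env": env,
                "genotype": signals.genotype_ids,
                "rep": rj + 1,
                "block": block_of + 1,
            }
            for trait in traits:
                vc = config.variance_components[trait]
                cell = signals.cell_values(trait)[:, li]
                blk = rng.normal(0.0, np.sqrt(vc.block_in_rep), size=n_blocks)
                err = rng.normal(0.0, np.sqrt(vc.error), size=n)
                rec[trait] = cell + rep_eff[rj] + blk[block_of] + err
            frames.append(pd.DataFrame(rec))
    plots = pd.concat(frames, ignore_index=True)
    return plots


def simulate_dataset(config: SimConfig) -> tuple[MarkerMatrix, TrueSignals, pd.DataFrame]:
    """Convenience wrapper: markers -> QC -> effects -> plots.

    Markers are QC-filtered (dropping e.g. markers monomorphic in the
    sample, which cannot be standardized) and mean-imputed before the
    genetic values are generated; the returned marker matrix is the
    post-QC one so it matches the genetic architecture exactly.
    """
    from .markers import impute_mean, qc_filter

    raw = simulate_markers(config)
    work, _ = qc_filter(raw)
    if config.missing_rate > 0:
        work = impute_mean(work)
    signals = simulate_effects(work, config)
    plots = simulate_plots(signals, config)
    return work, signals, plots
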