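"""Sparse-testing allocation designs: non-overlapping / overlapping splits.

A design assigns each environment a training set (TRS) of genotypes to
phenotype, composed of NOL genotypes (tested in exactly one environment)
and OL genotypes (one common set tested in every environment).  The
construction starts from a random equal partition of all genotypes into
one base set per environment; a design with TRS size t and n_ol common
genotypes drops n_ol genotypes from each environment's base subset and
re-observes one common set of n_ol drawn from the dropped pool.  Testing
sets are each environment's complement of its base partition set, minus
any OL genotypes observed there, so predicted cells are never phenotyped
cells.

At the study scale — 435 genotypes over 5 environments, base sets of 87
— the 77/10 design observes 435 plots, 395 distinct genotypes, and
leaves 40 genotypes unobserved; all-NOL testing sets hold exactly 348
genotypes per environment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AllocationDesign",
    "DesignCounts",
    "partition_nol",
    "build_design",
    "design_counts",
    "enumerate_design_grid",
    "classify_cv",
    "design_to_json",
    "design_from_json",
]


@dataclass
class AllocationDesign:
    """One NOL/OL allocation of genotypes to environments."""

    trs_size: int
    n_nol: int
    n_ol: int
    ol_set: frozenset[str]
    nol_sets: dict[str, frozenset[str]]      # environment -> NOL genotypes
    testing_sets: dict[str, frozenset[str]]  # environment -> prediction genotypes
    seed: int | None = None
    label: str = field(init=False)

    def __post_init__(self) -> None:
        self.label = f"{self.n_nol}/{self.n_ol}"
        if self.n_nol + self.n_ol != self.trs_size:
            raise ValueError("n_nol + n_ol must equal trs_size")
        if len(self.ol_set) != self.n_ol:
            raise ValueError("ol_set size does not match n_ol")
        envs = list(self.nol_sets)
        for env in envs:
            if len(self.nol_sets[env]) != self.n_nol:
                raise ValueError(f"NOL set for {env} has the wrong size")
            if self.nol_sets[env] & self.ol_set:
                raise ValueError(f"NOL set for {env} intersects the OL set")
            if self.observed_set(env) & self.testing_sets[env]:
                raise ValueError(f"testing set for {env} overlaps its observed set")
        for i, a in enumerate(envs):
            for b in envs[i + 1:]:
                if self.nol_sets[a] & self.nol_sets[b]:
                    raise ValueError(f"NOL sets for {a} and {b} are not disjoint")

    @property
    def environments(self) -> list[str]:
        return list(self.nol_sets)

    def observed_set(self, env: str) -> frozenset[str]:
        """Genotypes phenotyped in ``env``: its NOL set plus the common OL set."""
        return self.nol_sets[env] | self.ol_set


@dataclass
class DesignCounts:
    """Exact observation bookkeeping for one design."""

    observed_plots: int     # number of observed (genotype, environment) cells
    unique_observed: int    # genotypes observed in >= 1 environment
    unobserved: int         # genotypes never observed
    per_env_trs: dict[str, int]


def partition_nol(
    genotype_ids: list[str], n_env: int, seed: int | None = None
) -> list[frozenset[str]]:
    """Randomly partition the genotypes into n_env equal disjoint base sets.

    Requires len(genotype_ids) divisible by n_env (e.g. 435 genotypes over
    5 environments give five sets of 87).
    """
    n = len(genotype_ids)
    if n % n_env:
        raise ValueError(
            f"{n} genotypes are not divisible by {n_env} environments "
            f"(remainder {n % n_env})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    size = n // n_env
    ids = np.asarray(genotype_ids, dtype=object)
    return [
        frozenset(ids[order[k * size:(k + 1) * size]].tolist()) for k in range(n_env)
    ]


def build_design(
    base_partition: list[frozenset[str]],
    trs_size: int,
    n_ol: int,
    seed: int | None = None,
    environment_ids: list[str] | None = None,
) -> AllocationDesign:
    """Construct one NOL/OL design from a base partition.

    From each environment's base set a random subset of ``trs_size``
    genotypes is taken (TRS sizes below the base size drop genotypes
    entirely), then ``n_ol`` of those are dropped per environment to
    leave ``trs_size - n_ol`` NOL genotypes; one OL set of size ``n_ol``
    is drawn uniformly from the pooled dropped genotypes and marked
    observed in every environment.  Testing sets are each environment's
    complement of its *base* partition set minus the OL genotypes, so a
    testing cell is never phenotyped in its own environment; at the
    435-genotype study scale all-NOL compositions give exactly 348
    testing genotypes per environment, and OL compositions slightly
    fewer (the OL genotypes originating in other base sets are removed
    from evaluation where they are observed).
    """
    n_env = len(base_partition)
    base_size = len(base_partition[0])
    if not 0 <= n_ol <= trs_size <= base_size:
        raise ValueError("need 0 <= n_ol <= trs_size <= base set size")
    if environment_ids is None:
        environment_ids = [f"E{k + 1}" for k in range(n_env)]
    all_ids = frozenset().union(*base_partition)
    rng = np.random.default_rng(seed)
    n_nol = trs_size - n_ol
    nol_sets: dict[str, frozenset[str]] = {}
    dropped: list[str] = []
    for env, base in zip(environment_ids, base_partition):
        chosen = rng.choice(sorted(base), size=trs_size, replace=False)
        keep = rng.choice(trs_size, size=n_nol, replace=False) if n_nol else []
        keep_mask = np.zeros(trs_size, dtype=bool)
        keep_mask[list(keep)] = True
        nol_sets[env] = frozenset(chosen[keep_mask].tolist())
        dropped.extend(chosen[~keep_mask].tolist())
    if n_ol > len(dropped):
        raise ValueError(
            f"cannot draw {n_ol} OL genotypes from a dropped pool of {len(dropped)}"
        )
    ol = frozenset(rng.choice(sorted(dropped), size=n_ol, replace=False).tolist())
    testing = {
        env: all_ids - base - ol
        for env, base in zip(environment_ids, base_partition)
    }
    return AllocationDesign(
        trs_size=trs_size,
        n_nol=n_nol,
        n_ol=n_ol,
        ol_set=ol,
        nol_sets=nol_sets,
        testing_sets=testing,
        seed=seed,
    )


def design_counts(design: AllocationDesign, all_ids) -> DesignCounts:
    """Exact observation counts for a design over the full genotype list."""
    observed_union: set[str] = set()
    per_env = {}
    plots = 0
    for env in design.environments:
        obs = design.observed_set(env)
        per_env[env] = len(obs)
        plots += len(obs)
        observed_union |= obs
    total = len(set(all_ids))
    return DesignCounts(
        observed_plots=plots,
        unique_observed=len(observed_union),
        unobserved=total - len(observed_union),
        per_env_trs=per_env,
    )


def enumerate_design_grid(
    trs_sizes: list[int] = (87, 77, 67, 57, 47), step: int = 10
) -> list[tuple[int, int, int]]:
    """Enumerate the study's allocation grid: (trs_size, n_nol, n_ol) triples.

    For each TRS size the NOL count descends from trs_size in steps of
    ``step`` down to its last positive value, then 0 — e.g. TRS 87 with
    step 10 yields NOL 87, 77, ..., 7, 0 (ten designs), TRS 47 yields
    47, 37, ..., 7, 0 (six).  The default arguments reproduce the full
    study grid of 40 designs.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    grid = []
    for trs in trs_sizes:
        nols = list(range(trs, 0, -step)) + [0]
        grid.extend((trs, n_nol, trs - n_nol) for n_nol in nols)
    return grid


def classify_cv(design: AllocationDesign) -> str:
    """CV scheme of a design: CV1 when every training genotype is common
    to all environments (n_nol = 0, so testing genotypes are unseen
    everywhere), otherwise CV2."""
    return "CV1" if design.n_nol == 0 else "CV2"


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def design_to_json(design: AllocationDesign, path=None) -> str:
    payload = {
        "trs_size": design.trs_size,
        "n_nol": design.n_nol,
        "n_ol": design.n_ol,
        "seed": design.seed,
        "ol_set": sorted(design.ol_set),
        "nol_sets": {e: sorted(s) for e, s in design.nol_sets.items()},
        "testing_sets": {e: sorted(s) for e, s in design.testing_sets.items()},
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def design_from_json(source) -> AllocationDesign:
    if isinstance(source, str) and source.lstrip().startswith("{"):
        payload = json.loads(source)
    else:
        with open(source) as fh:
            payload = json.load(fh)
    return AllocationDesign(
        trs_size=payload["trs_size"],
        n_nol=payload["n_nol"],
        n_ol=payload["n_ol"],
        ol_set=frozenset(payload["ol_set"]),
        nol_sets={e: frozenset(s) for e, s in payload["nol_sets"].items()},
        testing_sets={e: frozenset(s) for e, s in payload["testing_sets"].items()},
        seed=payload.get("seed"),
    )
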