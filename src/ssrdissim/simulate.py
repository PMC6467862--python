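"""Random-walk stepwise-mutation simulator for haploid SSR populations.

An ancestral allele (default 200 repeats) evolves for a fixed number of
generations; in each generation a locus mutates with probability *p* and,
if it does, gains or loses exactly one repeat unit with equal probability.
*p* is drawn from a moment-matched Beta distribution (default mean 0.25,
variance 0.02) truncated at a hard cap (default 0.5):

* ``rate_mode="constant"`` — a single *p* is redrawn every generation and
  shared by all loci, so loci differ only through the random placement of
  mutation events;
* ``rate_mode="variable"`` — each locus draws its own *p* once and keeps
  it, making the mutation rate an intrinsic, locus-specific property.

Individuals are samples of the trajectory state at known generation
("age"), so every simulated population carries exact ground truth: the
pairwise difference in age and the exact number of mutation events
separating the two sampled states.  Three sampling designs are provided:
clonal (one linked multi-locus trajectory, one age per individual), sexual
(independent single-locus trajectories, independent ages per locus), and
clonal age groups (blocks of near-coeval individuals whose group centres
are a fixed number of generations apart).
"""

from __future__ import annotations

import dataclasses
import functools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .io import Dataset, SSRError, build_dataset, write_dataset

logger = logging.getLogger("ssrdissim")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    ``mut_mean``/``mut_var`` are the moments of the per-generation mutation
    probability distribution; ``mut_cap`` is the hard upper bound enforced
    by rejection.  ``max_generations`` is the trajectory length; individual
    sampling ages are uniform on [0, max_generations].
    """

    n_loci: int = 8
    ancestral_repeats: int = 200
    mut_mean: float = 0.25
    mut_var: float = 0.02
    mut_cap: float = 0.5
    rate_mode: str = "constant"  # constant | variable
    lineage_mode: str = "clonal"  # clonal | sexual
    n_individuals: int = 100
    max_generations: int = 1362
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.mut_mean < self.mut_cap <= 0.5):
            raise SSRError("need 0 < mut_mean < mut_cap <= 0.5")
        if self.mut_var < 0:
            raise SSRError("mut_var must be >= 0")
        if self.mut_var >= self.mut_mean * (1.0 - self.mut_mean):
            raise SSRError(
                "mut_var too large for a Beta distribution with this mean"
            )
        if self.rate_mode not in ("constant", "variable"):
            raise SSRError(f"unknown rate_mode {self.rate_mode!r}")
        if self.lineage_mode not in ("clonal", "sexual"):
            raise SSRError(f"unknown lineage_mode {self.lineage_mode!r}")


def beta_shape_parameters(mean: float, var: float) -> tuple[float, float]:
    """Shape parameters (a, b) of the Beta distribution with the given
    moments (a ~ 2.094, b ~ 6.281 for mean 0.25, variance 0.02)."""
    a = mean * (mean * (1.0 - mean) / var - 1.0)
    return a, a * (1.0 - mean) / mean


@functools.lru_cache(maxsize=8)
def _truncated_beta_parameters(mean: float, var: float,
                               cap: float) -> tuple[float, float]:
    """Shape parameters (a, b) such that a Beta(a, b) *truncated at cap*
    has the requested mean and variance.

    Rejecting draws above the cap shifts the moments of a naively
    moment-matched Beta (for mean 0.25 / var 0.02 / cap 0.5 the realised
    mean would drop to ~0.23 and the variance to ~0.014), so the shape
    parameters are calibrated against the truncated moments, which are
    available in closed form: E[X^k | X <= c] follows from the identity
    int_0^c x f_{a,b}(x) dx = (a / (a+b)) F_{a+1,b}(c).
    """
    from scipy import optimize, stats

    def truncated_moments(a: float, b: float) -> tuple[float, float]:
        z = stats.beta.cdf(cap, a, b)
        m1 = (a / (a + b)) * stats.beta.cdf(cap, a + 1, b) / z
        m2 = (a * (a + 1) / ((a + b) * (a + b + 1))
              * stats.beta.cdf(cap, a + 2, b) / z)
        return m1, m2 - m1 ** 2

    def residual(log_ab):
        a, b = np.exp(log_ab)
        m, v = truncated_moments(a, b)
        return [m - mean, v - var]

    guess = np.log(beta_shape_parameters(mean, var))
    sol = optimize.root(residual, guess, method="hybr")
    if not sol.success:  # pragma: no cover
        raise SSRError(
            f"no truncated Beta matches mean={mean}, var={var}, cap={cap}"
        )
    a, b = np.exp(sol.x)
    return float(a), float(b)


def draw_mutation_prob(rng: np.random.Generator, config: SimConfig,
                       size: int | None = None) -> float | np.ndarray:
    """Draw per-generation mutation probabilities.

    Beta(a, b) truncated at ``mut_cap`` by rejection, with (a, b)
    calibrated so the *realised* draws match ``(mut_mean, mut_var)``.
    ``mut_var = 0`` degenerates to a point mass at the mean.
    """
    n = 1 if size is None else int(size)
    if config.mut_var == 0.0:
        out = np.full(n, config.mut_mean)
    else:
        a, b = _truncated_beta_parameters(config.mut_mean, config.mut_var,
                                          config.mut_cap)
        out = rng.beta(a, b, size=n)
        bad = out > config.mut_cap
        while bad.any():
            out[bad] = rng.beta(a, b, size=int(bad.sum()))
            bad = out > config.mut_cap
    return float(out[0]) if size is None else out


@dataclass(frozen=True)
class Trajectory:
    """One locus's random walk: repeat count and cumulative mutation count
    at every generation (index 0 = ancestor)."""

    repeats: np.ndarray
    mutations: np.ndarray


def evolve_locus(start_repeats: int, n_generations: int,
                 p_source, rng: np.random.Generator) -> Trajectory:
    """Evolve one locus for ``n_generations`` one-step mutations.

    ``p_source`` is a scalar probability, an array of per-generation
    probabilities, or a callable ``(rng, n) -> array``.  A repeat count
    falling below 1 aborts the simulation: with a 200-repeat ancestor this
    signals a misconfiguration, not a plausible trajectory.
    """
    G = int(n_generations)
    if G < 0:
        raise SSRError("n_generations must be >= 0")
    if callable(p_source):
        p = np.asarray(p_source(rng, G), dtype=float)
    else:
        p = np.broadcast_to(np.asarray(p_source, dtype=float), (G,))
    mutated = rng.random(G) < p
    directions = rng.integers(0, 2, size=G) * 2 - 1
    steps = np.where(mutated, directions, 0)
    repeats = np.concatenate(([start_repeats], start_repeats + np.cumsum(steps)))
    if repeats.min(initial=start_repeats) < 1:
        raise SSRError(
            "repeat count fell below 1 during simulation; "
            "check ancestral_repeats / max_generations"
        )
    mutations = np.concatenate(([0], np.cumsum(mutated)))
    return Trajectory(repeats=repeats, mutations=mutations)


@dataclass
class SimPopulation:
    """Simulated genotypes plus exact ground truth.

    ``ages[i, j]`` is the generation at which individual *i*'s allele at
    locus *j* was sampled; ``true_generation_diff`` is the pairwise
    difference of (mean) ages and ``true_mutation_diff`` the exact number
    of mutation events between the two sampled states, summed over loci.
    """

    genotypes: np.ndarray  # (N, n_loci) repeat counts
    ages: np.ndarray  # (N, n_loci) generations from ancestor
    true_generation_diff: np.ndarray  # (N, N)
    true_mutation_diff: np.ndarray  # (N, N)
    config: SimConfig
    ids: list[str] = field(default_factory=list)
    group_labels: np.ndarray | None = None
    group_age_step: int | None = None

    def __post_init__(self) -> None:
        if not self.ids:
            self.ids = [f"ind{i + 1}" for i in range(self.genotypes.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def individual_ages(self) -> np.ndarray:
        """Age of each genotype: mean of its per-locus ages."""
        return self.ages.mean(axis=1)

    def to_dataset(self, ltr: int = 2, size_offset: float = 0.0) -> Dataset:
        """Express the simulated repeat counts as a haploid size-call
        dataset (size = repeats * ltr + offset)."""
        sizes = self.genotypes * ltr + size_offset
        calls = [[(float(sizes[i, j]),) for j in range(sizes.shape[1])]
                 for i in range(sizes.shape[0])]
        locus_ids = [f"L{j + 1}" for j in range(sizes.shape[1])]
        return build_dataset(locus_ids, [ltr] * len(locus_ids), self.ids,
                             calls, ploidy=1)

    def write(self, outdir: str | Path, ltr: int = 2) -> None:
        """Write genotype/locus tables, ground-truth matrices and the
        configuration (seed included) to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_dataset(self.to_dataset(ltr=ltr),
                      outdir / "genotypes.csv", outdir / "loci.csv")
        np.savetxt(outdir / "true_generation_diff.csv",
                   self.true_generation_diff, delimiter=",", fmt="%.6f")
        np.savetxt(outdir / "true_mutation_diff.csv",
                   self.true_mutation_diff, delimiter=",", fmt="%.6f")
        payload = dataclasses.asdict(self.config)
        if self.group_labels is not None:
            payload["group_labels"] = self.group_labels.tolist()
            payload["group_age_step"] = self.group_age_step
        (outdir / "sim_config.json").write_text(json.dumps(payload, indent=2))


def _locus_p_sources(config: SimConfig, rng: np.random.Generator,
                     G: int, shared_constant: bool) -> list[np.ndarray]:
    """Per-locus arrays of per-generation mutation probabilities.

    constant rate: p redrawn each generation; shared across loci when the
    loci form one linked clonal set.  variable rate: one p per locus, held
    fixed over all generations.
    """
    if config.rate_mode == "constant":
        if shared_constant:
            p = draw_mutation_prob(rng, config, size=G)
            return [p] * config.n_loci
        return [draw_mutation_prob(rng, config, size=G)
                for _ in range(config.n_loci)]
    return [np.full(G, draw_mutation_prob(rng, config))
            for _ in range(config.n_loci)]


def _evolve_all(config: SimConfig, rng: np.random.Generator, G: int,
                shared_constant: bool) -> list[Trajectory]:
    sources = _locus_p_sources(config, rng, G, shared_constant)
    return [evolve_locus(config.ancestral_repeats, G, p, rng)
            for p in sources]


def _truth_from_trajectories(trajs: Sequence[Trajectory],
                             ages: np.ndarray) -> np.ndarray:
    """Exact pairwise mutation-count differences: for each locus, the
    number of mutation events with generation index between the two
    sampling ages, summed over loci."""
    mut = np.column_stack([t.mutations[ages[:, j]]
                           for j, t in enumerate(trajs)])
    diff = np.abs(mut[:, None, :] - mut[None, :, :]).sum(axis=2)
    return diff.astype(float)


def simulate_clonal(config: SimConfig,
                    rng: np.random.Generator | None = None) -> SimPopulation:
    """Sample a clonal population from one linked multi-locus trajectory.

    All loci of an individual share one sampling age, drawn uniformly on
    [0, max_generations]; the pairwise generation difference is the exact
    difference of ages.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    G = config.max_generations
    trajs = _evolve_all(config, rng, G, shared_constant=True)
    age = rng.integers(0, G + 1, size=config.n_individuals)
    ages = np.tile(age[:, None], (1, config.n_loci))
    genotypes = np.column_stack([t.repeats[age] for t in trajs])
    gen_diff = np.abs(age[:, None] - age[None, :]).astype(float)
    return SimPopulation(
        genotypes=genotypes, ages=ages,
        true_generation_diff=gen_diff,
        true_mutation_diff=_truth_from_trajectories(trajs, ages),
        config=config,
    )


def simulate_sexual(config: SimConfig,
                    rng: np.random.Generator | None = None) -> SimPopulation:
    """Assemble sexual haploid genotypes from independent single-locus
    lineages.

    Each locus has its own trajectory and each individual draws an
    independent sampling age per locus; the age of a genotype is the mean
    of its per-locus ages.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    G = config.max_generations
    trajs = _evolve_all(config, rng, G, shared_constant=False)
    ages = rng.integers(0, G + 1,
                        size=(config.n_individuals, config.n_loci))
    genotypes = np.column_stack([t.repeats[ages[:, j]]
                                 for j, t in enumerate(trajs)])
    mean_age = ages.mean(axis=1)
    gen_diff = np.abs(mean_age[:, None] - mean_age[None, :])
    return SimPopulation(
        genotypes=genotypes, ages=ages,
        true_generation_diff=gen_diff,
        true_mutation_diff=_truth_from_trajectories(trajs, ages),
        config=config,
    )


def simulate_age_groups(config: SimConfig, n_groups: int = 100,
                        group_size: int = 20, age_step: int = 15,
                        within_group_age_spread: int = 9,
                        rng: np.random.Generator | None = None) -> SimPopulation:
    """Clonal population structured into near-coeval age groups.

    Group *g* (g = 0 .. n_groups-1) is sampled at ages
    ``g * age_step + U{0..spread}``, so the age difference between group
    centres is a multiple of ``age_step`` and members of one group differ
    by at most ``within_group_age_spread`` generations.  The trajectory is
    evolved exactly long enough to cover the oldest group.
    """
    if within_group_age_spread < 0 or within_group_age_spread >= age_step:
        raise SSRError("need 0 <= within_group_age_spread < age_step")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    G = (n_groups - 1) * age_step + within_group_age_spread
    trajs = _evolve_all(config, rng, G, shared_constant=True)

    labels = np.repeat(np.arange(n_groups), group_size)
    offsets = rng.integers(0, within_group_age_spread + 1, size=labels.size)
    age = labels * age_step + offsets
    ages = np.tile(age[:, None], (1, config.n_loci))
    genotypes = np.column_stack([t.repeats[age] for t in trajs])
    gen_diff = np.abs(age[:, None] - age[None, :]).astype(float)
    return SimPopulation(
        genotypes=genotypes, ages=ages,
        true_generation_diff=gen_diff,
        true_mutation_diff=_truth_from_trajectories(trajs, ages),
        config=dataclasses.replace(config, max_generations=G,
                                   n_individuals=labels.size,
                                   lineage_mode="clonal"),
        group_labels=labels,
        group_age_step=age_step,
    )
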