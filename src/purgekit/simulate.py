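"""Forward Wright-Fisher simulator of recessive deleterious mutations.

Emulates the validation design for the inbreeding-purging estimators: a
large monoecious base population brought to mutation-selection-drift
balance (completely recessive deleterious mutations of homozygous effect
s occurring at a fixed rate per gamete per generation at fresh unlinked
loci, multiplicative fitness), from which small replicate lines are
founded and maintained for many generations either with
fitness-proportional parent sampling (purging operates) or with uniform
parent sampling (selection relaxed, no purging).  Every line's full
pedigree and individual fitness are recorded for analysis, together with
ground truth: the base-population inbreeding load delta = sum 2 d q(1-q)
and the purging coefficient d = s(1/2 - h).

Genome representation is infinite-sites: each new mutation is a fresh
unlinked locus, stored as boolean haplotype matrices; loci are pruned
when lost and folded into a constant fitness factor when fixed.  Free
recombination means each locus is transmitted independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .pedigree import IndividualRecord, Pedigree

__all__ = [
    "SimulationConfig",
    "Population",
    "SimulationOutput",
    "burn_in_base",
    "run_lines",
    "neutral_fitness_generator",
    "random_discrete_pedigree",
]

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study conditions for the validation simulation.

    Defaults are the reference design: base N = 1000 at
    mutation-selection-drift balance, recessive mutations (h = 0) with
    homozygous effect s = 0.3 arising at 0.1 per gamete per generation,
    50 replicate lines of N = 10 kept 50 generations.
    """

    n_base: int = 1000
    mutation_rate: float = 0.1  # new mutations per gamete per generation
    s: float = 0.3
    h: float = 0.0
    n_line: int = 10
    line_generations: int = 50
    n_lines: int = 50
    selection: bool = True  # False = relaxed (uniform parent sampling)
    burn_in_max: int | None = None  # default 10 * n_base
    burn_in_min: int = 500
    convergence_window: int | None = None  # default n_base
    convergence_tol: float = 0.05
    allow_selfing: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0):
            raise ValueError("homozygous effect s must be in [0, 1]")
        if not (0.0 <= self.h <= 0.5):
            raise ValueError("dominance h must be in [0, 0.5]")
        if self.mutation_rate < 0:
            raise ValueError("mutation rate must be >= 0")

    @property
    def true_d(self) -> float:
        """Purging coefficient implied by the mutational model, s(1/2 - h)."""
        return self.s * (0.5 - self.h)


@dataclass
class Population:
    """Diploid population: two boolean haplotype matrices (N x L) over the
    currently segregating deleterious loci, plus the count of fixed loci
    (folded into a constant fitness factor)."""

    hap1: np.ndarray
    hap2: np.ndarray
    n_fixed: int = 0

    @property
    def n(self) -> int:
        return self.hap1.shape[0]

    @property
    def n_loci(self) -> int:
        return self.hap1.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        return (self.hap1.sum(0) + self.hap2.sum(0)) / (2.0 * self.n)

    def fitness(self, s: float, h: float) -> np.ndarray:
        """Multiplicative fitness: (1-s) per homozygous deleterious locus,
        (1-hs) per heterozygous locus, including fixed loci."""
        n_hom = (self.hap1 & self.hap2).sum(1) + self.n_fixed
        w = (1.0 - s) ** n_hom
        if h > 0:
            n_het = (self.hap1 ^ self.hap2).sum(1)
            w = w * (1.0 - h * s) ** n_het
        return w

    def inbreeding_load(self, s: float, h: float) -> float:
        """Eq-1 style load over segregating loci: sum 2 d q (1-q) with the
        per-locus purging coefficient d = s(1/2 - h)."""
        q = self.allele_frequencies()
        d = s * (0.5 - h)
        return float(np.sum(2.0 * d * q * (1.0 - q)))


def _random_bits(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Fair boolean matrix drawn bytewise (cheap for wide matrices)."""
    m, L = shape
    if L == 0:
        return np.zeros(shape, dtype=bool)
    b = rng.integers(0, 256, size=(m, (L + 7) // 8), dtype=np.uint8)
    return np.unpackbits(b, axis=1, count=L).view(np.bool_)


def _gametes(hap1, hap2, parents, rng) -> np.ndarray:
    """One gamete per parent index: homozygous loci always transmitted,
    heterozygous loci with probability 1/2 (free recombination)."""
    h1 = hap1[parents]
    h2 = hap2[parents]
    return (h1 & h2) | ((h1 ^ h2) & _random_bits(rng, h1.shape))


def _sample_parent_pairs(n_off, w, selection, allow_selfing, rng):
    n = len(w)
    prob = None
    if selection:
        tot = w.sum()
        if tot <= 0:
            raise RuntimeError("population fitness collapsed to 0")
        prob = w / tot
    sires = rng.choice(n, size=n_off, p=prob)
    dams = rng.choice(n, size=n_off, p=prob)
    if not allow_selfing and n > 1:
        bad = np.flatnonzero(dams == sires)
        while bad.size:
            dams[bad] = rng.choice(n, size=bad.size, p=prob)
            bad = bad[dams[bad] == sires[bad]]
    return sires, dams


def _next_generation(pop, n_off, config, rng, selection):
    """Advance one generation; returns (new Population, sires, dams,
    parental fitness) with lost loci pruned and fixed loci folded."""
    w = pop.fitness(config.s, config.h)
    sires, dams = _sample_parent_pairs(
        n_off, w, selection, config.allow_selfing, rng
    )
    g1 = _gametes(pop.hap1, pop.hap2, sires, rng)
    g2 = _gametes(pop.hap1, pop.hap2, dams, rng)

    # fresh mutations: each hits a brand-new unlinked locus on one gamete
    nm = rng.poisson(config.mutation_rate, size=2 * n_off)
    m1, m2 = int(nm[:n_off].sum()), int(nm[n_off:].sum())
    if m1 or m2:
        Z1 = np.zeros((n_off, m1 + m2), dtype=bool)
        Z2 = np.zeros((n_off, m1 + m2), dtype=bool)
        rows1 = np.repeat(np.arange(n_off), nm[:n_off])
        Z1[rows1, np.arange(m1)] = True
        rows2 = np.repeat(np.arange(n_off), nm[n_off:])
        Z2[rows2, m1 + np.arange(m2)] = True
        g1 = np.hstack([g1, Z1])
        g2 = np.hstack([g2, Z2])

    counts = g1.sum(0) + g2.sum(0)
    fixed = counts == 2 * n_off
    keep = (counts > 0) & ~fixed
    new = Population(
        hap1=np.ascontiguousarray(g1[:, keep]),
        hap2=np.ascontiguousarray(g2[:, keep]),
        n_fixed=pop.n_fixed + int(fixed.sum()),
    )
    return new, sires, dams, w


def burn_in_base(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[Population, dict]:
    """Evolve the base population to mutation-selection-drift balance.

    Starts mutation-free and runs until the inbreeding load delta
    stabilizes: relative change of the windowed mean delta below
    ``convergence_tol`` between the last two windows of
    ``convergence_window`` generations (default ``n_base``), after at
    least ``burn_in_min`` generations, capped at ``burn_in_max``
    (default 10 * n_base).  Returns the population and an info dict with
    the per-generation delta trajectory.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    N = config.n_base
    pop = Population(
        hap1=np.zeros((N, 0), dtype=bool), hap2=np.zeros((N, 0), dtype=bool)
    )
    max_gen = config.burn_in_max if config.burn_in_max is not None else 10 * N
    window = config.convergence_window if config.convergence_window else N
    deltas = []
    converged_at = None
    for gen in range(1, max_gen + 1):
        pop, _, _, _ = _next_generation(pop, N, config, rng, config.selection)
        deltas.append(pop.inbreeding_load(config.s, config.h))
        if gen >= max(config.burn_in_min, 2 * window) and gen % (window // 4 or 1) == 0:
            recent = np.mean(deltas[-window:])
            previous = np.mean(deltas[-2 * window : -window])
            if previous > 0 and abs(recent - previous) / previous < config.convergence_tol:
                converged_at = gen
                break
    info = {
        "generations": len(deltas),
        "converged_at": converged_at,
        "delta_trajectory": np.asarray(deltas),
        "delta": deltas[-1],
        "n_segregating": pop.n_loci,
        "n_fixed": pop.n_fixed,
    }
    if converged_at is None:
        log.warning("burn-in hit the generation cap without meeting the "
                    "delta convergence criterion")
    return pop, info


@dataclass
class SimulationOutput:
    """Replicate-line simulation results.

    ``pedigrees`` holds one :class:`Pedigree` per line (founders coded as
    unknown-parent records, fitness attached to every individual);
    trajectories are (n_lines, generations + 1) arrays indexed from the
    founder generation.
    """

    pedigrees: list[Pedigree]
    mean_fitness: np.ndarray
    delta_base: float
    true_d: float
    base_frequencies: np.ndarray
    config: SimulationConfig
    selection: bool

    def mean_fitness_trajectory(self) -> np.ndarray:
        """Across-line mean fitness per generation."""
        return self.mean_fitness.mean(axis=0)

    def write(self, outdir) -> None:
        """Write one pedigree TSV per line plus ground-truth JSON and the
        mean-fitness trajectory TSV."""
        from pathlib import Path
        from .pedigree import write_pedigree

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for k, ped in enumerate(self.pedigrees, start=1):
            write_pedigree(ped, out / f"line_{k:03d}.tsv")
        np.savetxt(
            out / "mean_fitness.tsv",
            self.mean_fitness.T,
            delimiter="\t",
            header="\t".join(f"line_{k + 1}" for k in range(len(self.pedigrees))),
            comments="",
        )
        truth = {
            "delta_base": self.delta_base,
            "true_d": self.true_d,
            "selection": self.selection,
            "n_segregating_base": int(len(self.base_frequencies)),
            "config": {
                k: v for k, v in asdict(self.config).items() if v is not None
            },
        }
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))


def run_lines(
    base: Population,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    selection: bool | None = None,
) -> SimulationOutput:
    """Found and maintain replicate lines from a burnt-in base population.

    Each line starts from ``n_line`` distinct base individuals sampled at
    random and runs ``line_generations`` generations of size ``n_line``;
    parents are drawn fitness-proportionally when selection operates and
    uniformly when relaxed.  Mutation continues during maintenance.  The
    recorded fitness of each individual is its multiplicative genotypic
    fitness (environmental noise epsilon = 0).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sel = config.selection if selection is None else selection
    delta_base = base.inbreeding_load(config.s, config.h)
    qbase = base.allele_frequencies()
    nL, T = config.n_line, config.line_generations
    pedigrees = []
    traj = np.zeros((config.n_lines, T + 1))

    for line in range(config.n_lines):
        founders = rng.choice(base.n, size=nL, replace=False)
        h1 = base.hap1[founders]
        h2 = base.hap2[founders]
        counts = h1.sum(0) + h2.sum(0)
        fixed = counts == 2 * nL
        keep = (counts > 0) & ~fixed
        pop = Population(
            hap1=np.ascontiguousarray(h1[:, keep]),
            hap2=np.ascontiguousarray(h2[:, keep]),
            n_fixed=base.n_fixed + int(fixed.sum()),
        )
        records = []
        w = pop.fitness(config.s, config.h)
        traj[line, 0] = w.mean()
        ids = [f"G0_{i + 1}" for i in range(nL)]
        records.extend(
            IndividualRecord(id=ids[i], fitness=float(w[i])) for i in range(nL)
        )
        for t in range(1, T + 1):
            pop, sires, dams, _ = _next_generation(pop, nL, config, rng, sel)
            w = pop.fitness(config.s, config.h)
            traj[line, t] = w.mean()
            new_ids = [f"G{t}_{i + 1}" for i in range(nL)]
            records.extend(
                IndividualRecord(
                    id=new_ids[i],
                    sire=ids[sires[i]],
                    dam=ids[dams[i]],
                    fitness=float(w[i]),
                )
                for i in range(nL)
            )
            ids = new_ids
        pedigrees.append(Pedigree(records))

    return SimulationOutput(
        pedigrees=pedigrees,
        mean_fitness=traj,
        delta_base=delta_base,
        true_d=config.true_d,
        base_frequencies=qbase,
        config=config,
        selection=sel,
    )


def random_discrete_pedigree(
    n: int,
    generations: int,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    allow_selfing: bool = False,
) -> Pedigree:
    """Random-mating bottleneck pedigree with discrete generations.

    ``n`` founders, then ``generations`` generations of ``n`` offspring
    each with parents drawn uniformly from the previous generation
    (distinct unless ``allow_selfing``).  No fitness attached; useful for
    exercising the coefficient recursions on deep, inbred pedigrees.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    records = [IndividualRecord(id=f"G0_{i + 1}") for i in range(n)]
    ids = [r.id for r in records]
    for t in range(1, generations + 1):
        sires = rng.integers(0, n, size=n)
        dams = rng.integers(0, n, size=n)
        if not allow_selfing and n > 1:
            bad = np.flatnonzero(dams == sires)
            while bad.size:
                dams[bad] = rng.integers(0, n, size=bad.size)
                bad = bad[dams[bad] == sires[bad]]
        new_ids = [f"G{t}_{i + 1}" for i in range(n)]
        records.extend(
            IndividualRecord(id=new_ids[i], sire=ids[sires[i]], dam=ids[dams[i]])
            for i in range(n)
        )
        ids = new_ids
    return Pedigree(records)


def neutral_fitness_generator(
    p: Pedigree,
    delta: float,
    d: float,
    lnW0: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    deterministic: bool = False,
) -> np.ndarray:
    """Selection-free fitness draws with known regression behavior.

    Each individual is homozygous by descent at n_i ~ Poisson(F_i
    delta/(2d)) deleterious loci and has fitness W0 (1-2d)^{n_i}, so a
    log-fitness regression on F has expected slope [ln(1-2d)/(2d)] delta.
    At d = 0 the Poisson mean is undefined; pass ``deterministic=True``
    to use the limit W = W0 exp(-delta F) instead.
    """
    from .coefficients import inbreeding_F

    F = inbreeding_F(p)
    W0 = np.exp(lnW0)
    if d == 0.0 or deterministic:
        if d == 0.0 and not deterministic and delta > 0:
            raise ValueError(
                "d = 0 with delta > 0 leaves the Poisson mean undefined; "
                "use deterministic=True for the exp(-delta F) limit"
            )
        return W0 * np.exp(-delta * F)
    if not (0.0 < d <= 0.5):
        raise ValueError("d must lie in (0, 0.5]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = rng.poisson(F * delta / (2.0 * d))
    return W0 * (1.0 - 2.0 * d) ** n
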