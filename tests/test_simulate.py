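"""Forward Wright-Fisher simulator: mutation, selection, drift, lines."""

import numpy as np
import pytest

from purgekit import (
    Population,
    SimulationConfig,
    burn_in_base,
    inbreeding_F,
    lr_fit_given_d,
    neutral_fitness_generator,
    run_lines,
    slope_from_load,
)
from purgekit.simulate import _next_generation, random_discrete_pedigree


def _uniform_base(n, n_loci, q, rng):
    """Synthetic base population at linkage equilibrium with equal per-locus
    frequency q (stand-in for a burnt-in population in cheap tests)."""
    return Population(
        hap1=rng.random((n, n_loci)) < q,
        hap2=rng.random((n, n_loci)) < q,
    )


class TestConfig:
    def test_true_d(self):
        assert SimulationConfig(s=0.3, h=0.0).true_d == pytest.approx(0.15)
        assert SimulationConfig(s=0.4, h=0.25).true_d == pytest.approx(0.1)

    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(s=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(h=0.9)
        with pytest.raises(ValueError):
            SimulationConfig(mutation_rate=-0.1)


class TestDynamics:
    def test_no_mutation_stays_clean(self):
        cfg = SimulationConfig(n_base=30, mutation_rate=0.0, burn_in_max=20,
                               burn_in_min=5, convergence_window=5, seed=0)
        pop, info = burn_in_base(cfg)
        assert pop.n_loci == 0
        assert np.all(pop.fitness(cfg.s, cfg.h) == 1.0)
        assert info["delta"] == 0.0

    def test_neutral_mutations_accumulate(self):
        cfg = SimulationConfig(n_base=50, s=0.0, burn_in_max=40,
                               burn_in_min=40, seed=1)
        pop, _ = burn_in_base(cfg)
        assert pop.n_loci > 0
        assert np.all(pop.fitness(0.0, 0.0) == 1.0)

    def test_drift_martingale(self):
        """Without mutation or selection, mean allele frequency across
        replicates stays at its initial value (drift is directionless)."""
        rng = np.random.default_rng(7)
        cfg = SimulationConfig(n_base=20, mutation_rate=0.0, s=0.3, seed=None)
        q0 = 0.3
        finals = []
        for _ in range(40):
            pop = _uniform_base(20, 25, q0, rng)
            for _ in range(8):
                pop, *_ = _next_generation(pop, 20, cfg, rng, selection=False)
                # keep lost/fixed loci in the average: account via counts
            # after pruning, lost loci contribute 0 and fixed are counted
            q = pop.allele_frequencies()
            finals.append((q.sum() + pop.n_fixed) / 25)
        se = np.std(finals, ddof=1) / np.sqrt(len(finals))
        assert abs(np.mean(finals) - q0) < 3 * se + 1e-12

    def test_relaxed_inbreeding_tracks_neutral_expectation(self):
        """Pedigree mean F per generation follows the exact neutral
        recursion for monoecious random mating without selfing
        (F' = f, f' = (1 + F)/(2N) + (1 - 1/N) f), which approaches the
        ideal 1 - (1 - 1/2N)^t trajectory."""
        rng = np.random.default_rng(3)
        base = _uniform_base(200, 10, 0.05, rng)
        cfg = SimulationConfig(n_base=200, n_line=10, line_generations=20,
                               n_lines=25, mutation_rate=0.0)
        out = run_lines(base, cfg, rng=rng, selection=False)
        T = cfg.line_generations
        meanF = np.zeros((len(out.pedigrees), T + 1))
        for k, ped in enumerate(out.pedigrees):
            F = inbreeding_F(ped)
            for t in range(T + 1):
                meanF[k, t] = F[ped.depth == t].mean()
        N = cfg.n_line
        expect = np.zeros(T + 1)
        Ft, ft = 0.0, 0.0
        for t in range(1, T + 1):
            Ft, ft = ft, (1.0 + Ft) / (2 * N) + (1.0 - 1.0 / N) * ft
            expect[t] = Ft
        obs = meanF.mean(0)
        se = meanF.std(0, ddof=1) / np.sqrt(len(out.pedigrees))
        assert np.all(np.abs(obs - expect) < 3 * se + 0.01)
        # and the ideal closed form is a coarse upper envelope
        ideal = 1.0 - (1.0 - 1.0 / (2 * N)) ** np.arange(T + 1)
        assert np.max(np.abs(obs - ideal)) < 0.06

    def test_purging_raises_final_fitness(self):
        """With d*N = 1.5 > 1 purging is effective: purged lines end with
        higher mean fitness than relaxed lines from the same base."""
        rng = np.random.default_rng(11)
        base = _uniform_base(400, 120, 0.12, rng)  # delta ~ 3.8
        cfg = SimulationConfig(n_base=400, n_line=10, line_generations=30,
                               n_lines=15, mutation_rate=0.0)
        purged = run_lines(base, cfg, rng=np.random.default_rng(1), selection=True)
        relaxed = run_lines(base, cfg, rng=np.random.default_rng(1), selection=False)
        assert (purged.mean_fitness_trajectory()[-1]
                > relaxed.mean_fitness_trajectory()[-1])

    def test_line_pedigree_structure(self):
        rng = np.random.default_rng(5)
        base = _uniform_base(50, 20, 0.1, rng)
        cfg = SimulationConfig(n_base=50, n_line=6, line_generations=4,
                               n_lines=2, mutation_rate=0.05)
        out = run_lines(base, cfg, rng=rng)
        ped = out.pedigrees[0]
        assert ped.n == 6 * 5
        assert len(ped.founders) == 6
        assert np.all(np.isfinite(ped.fitness))
        assert out.mean_fitness.shape == (2, 5)
        assert out.true_d == cfg.true_d


class TestNeutralFitnessGenerator:
    def test_no_inbreeding_gives_w0(self):
        p = random_discrete_pedigree(8, 0, seed=0)  # founders only
        w = neutral_fitness_generator(p, delta=3.0, d=0.2, lnW0=-0.1, seed=1)
        assert np.allclose(w, np.exp(-0.1))

    def test_d_zero_requires_deterministic(self):
        p = random_discrete_pedigree(6, 3, seed=2)
        with pytest.raises(ValueError, match="deterministic"):
            neutral_fitness_generator(p, delta=2.0, d=0.0, seed=1)
        w = neutral_fitness_generator(p, delta=2.0, d=0.0, deterministic=True)
        F = inbreeding_F(p)
        assert np.allclose(w, np.exp(-2.0 * F))

    def test_log_slope_matches_closed_form(self):
        """Regressing log-fitness on F at fixed d recovers the analytic
        slope delta * ln(1-2d)/(2d) within 3 standard errors."""
        delta, d = 2.0, 0.2
        p = random_discrete_pedigree(40, 10, seed=9)
        w = neutral_fitness_generator(p, delta=delta, d=d, lnW0=0.0, seed=33)
        rows = list(zip(p.ids,
                        [p.ids[s] if s >= 0 else 0 for s in p.sire_idx],
                        [p.ids[s] if s >= 0 else 0 for s in p.dam_idx],
                        w.tolist()))
        from conftest import ped_from_rows
        ped = ped_from_rows(rows)
        fit = lr_fit_given_d(ped, 0.0, lnW0=0.0)  # g(0) = F
        expected = slope_from_load(delta, d)
        assert abs(fit.b_g - expected) < 3 * fit.se_b[0]
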