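"""Coancestry, inbreeding, ancestral and purged inbreeding coefficients."""

import numpy as np
import pytest

from purgekit import (
    PedigreeError,
    ancestral_Fa,
    coancestry_matrix,
    compute_coefficients,
    delta_F_reliability,
    inbreeding_F,
    purged_inbreeding,
    purged_inbreeding_grid,
    purged_inbreeding_nonoverlapping,
)
from purgekit.simulate import random_discrete_pedigree

from conftest import ped_from_rows, random_small_pedigree, sib_line
from _oracles import kinship_recursive, purged_coancestry_recursive


class TestCoancestryAndF:
    def test_unrelated_founders(self, trio):
        f = coancestry_matrix(trio)
        i, j = trio.index["1"], trio.index["2"]
        assert f[i, j] == 0.0
        assert f[i, i] == 0.5

    def test_parent_offspring(self, trio):
        f = coancestry_matrix(trio)
        assert f[trio.index["1"], trio.index["3"]] == 0.25

    def test_full_sibs_and_their_offspring(self, fullsib1):
        f = coancestry_matrix(fullsib1)
        assert f[fullsib1.index["C"], fullsib1.index["D"]] == 0.25
        F = inbreeding_F(fullsib1, f)
        assert F[fullsib1.index["X"]] == 0.25

    def test_second_generation_full_sib(self, fullsib2):
        F = inbreeding_F(fullsib2)
        assert F[fullsib2.index["X"]] == 0.375

    def test_offspring_of_selfing(self):
        p = ped_from_rows([("A", 0, 0), ("B", 0, 0), ("C", "A", "B"),
                           ("X", "C", "C")])
        F = inbreeding_F(p)
        assert F[p.index["X"]] == 0.5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_recursive_oracle_on_small_pedigrees(self, seed):
        p = random_small_pedigree(np.random.default_rng(seed))
        assert np.allclose(coancestry_matrix(p), kinship_recursive(p), atol=1e-12)


class TestAncestralFa:
    def test_zero_for_founders_and_first_generation(self, fullsib1):
        Fa = ancestral_Fa(fullsib1)
        for ind in ("A", "B", "C", "D", "X"):
            expected = 0.0 if ind != "X" else 0.0
            assert Fa[fullsib1.index[ind]] == expected
        # X's parents are noninbred with noninbred ancestors
        assert Fa[fullsib1.index["X"]] == 0.0

    def test_one_step_recursion(self):
        # both parents have F = 0.25, Fa = 0 -> offspring Fa = 0.25
        rows = [("A", 0, 0), ("B", 0, 0), ("C", "A", "B"), ("D", "A", "B"),
                ("A2", 0, 0), ("B2", 0, 0), ("C2", "A2", "B2"), ("D2", "A2", "B2"),
                ("P", "C", "D"), ("Q", "C2", "D2"), ("X", "P", "Q")]
        p = ped_from_rows(rows)
        F = inbreeding_F(p)
        Fa = ancestral_Fa(p, F)
        assert F[p.index["P"]] == 0.25 and Fa[p.index["P"]] == 0.0
        assert Fa[p.index["X"]] == pytest.approx(0.25, abs=1e-15)

    def test_monotone_along_sib_line(self):
        p = sib_line(5)
        Fa = ancestral_Fa(p)
        per_gen = [Fa[p.index[f"S{t}a"]] for t in range(6)]
        assert all(b >= a for a, b in zip(per_gen, per_gen[1:]))
        assert np.all((Fa >= 0) & (Fa <= 1))


class TestPurgedInbreeding:
    def test_d0_equals_F_everywhere(self, fullsib2):
        F = inbreeding_F(fullsib2)
        g, _ = purged_inbreeding(fullsib2, 0.0)
        assert np.allclose(g, F, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_d0_equals_F_random_pedigrees(self, seed):
        p = random_small_pedigree(np.random.default_rng(100 + seed))
        g, _ = purged_inbreeding(p, 0.0)
        assert np.allclose(g, inbreeding_F(p), atol=1e-12)

    @pytest.mark.parametrize("d", [0.0, 0.1, 0.25, 0.5])
    def test_first_generation_full_sib_unpurged(self, fullsib1, d):
        g, _ = purged_inbreeding(fullsib1, d)
        assert g[fullsib1.index["X"]] == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("d", [0.0, 0.1, 0.3, 0.5])
    def test_second_generation_full_sib_closed_form(self, fullsib2, d):
        g, _ = purged_inbreeding(fullsib2, d)
        expect = 0.375 * (1.0 - 0.25 * d) ** 2
        assert g[fullsib2.index["X"]] == pytest.approx(expect, abs=1e-12)
        if d == 0.5:
            assert g[fullsib2.index["X"]] == pytest.approx(0.287109375, abs=1e-12)

    def test_d_out_of_range(self, fullsib1):
        for d in (-0.01, 0.51):
            with pytest.raises(ValueError, match="0, 0.5"):
                purged_inbreeding(fullsib1, d)

    @pytest.mark.parametrize("seed", range(6))
    def test_tabular_equals_recursive_oracle(self, seed):
        p = random_small_pedigree(np.random.default_rng(200 + seed))
        F = inbreeding_F(p)
        for d in (0.05, 0.2, 0.5):
            g, state = purged_inbreeding(p, d, F=F)
            g_o, G_o = purged_coancestry_recursive(p, d, F)
            assert np.allclose(g, g_o, atol=1e-12)
            assert np.allclose(state.gamma, G_o, atol=1e-12)

    def test_gamma_symmetric_diag_and_bounds(self, fullsib2):
        F = inbreeding_F(fullsib2)
        g, state = purged_inbreeding(fullsib2, 0.3, F=F)
        G = state.gamma
        assert np.allclose(G, G.T)
        assert np.allclose(np.diag(G), 0.5 * (1 + g) * (1 - 2 * 0.3 * F), atol=1e-15)
        assert np.all(G <= state.f + 1e-12)
        assert np.all(G >= -1e-15)

    def test_g_nonincreasing_and_bounded_by_F(self):
        p = sib_line(6)
        F = inbreeding_F(p)
        grid = np.linspace(0.0, 0.5, 51)
        G = purged_inbreeding_grid(p, grid, F=F)
        assert np.allclose(G[:, 0], F, atol=1e-12)
        assert np.all(np.diff(G, axis=1) <= 1e-12)
        assert np.all(G <= F[:, None] + 1e-12)
        assert np.all(G >= -1e-15)
        # continuity: adjacent grid values close
        assert np.max(np.abs(np.diff(G, axis=1))) < 0.05

    def test_grid_matches_single_d(self, fullsib2):
        grid = np.array([0.0, 0.17, 0.42])
        G = purged_inbreeding_grid(fullsib2, grid)
        for k, d in enumerate(grid):
            g, _ = purged_inbreeding(fullsib2, d)
            assert np.allclose(G[:, k], g, atol=1e-14)


class TestNonoverlapping:
    def test_d0_equals_F(self):
        p = random_discrete_pedigree(6, 5, seed=3)
        g = purged_inbreeding_nonoverlapping(p, 0.0)
        assert np.allclose(g, inbreeding_F(p), atol=1e-12)

    def test_overlapping_formula_overrates(self):
        p = random_discrete_pedigree(8, 8, seed=7)
        for d in (0.1, 0.3, 0.5):
            g18, _ = purged_inbreeding(p, d)
            g22 = purged_inbreeding_nonoverlapping(p, d)
            assert np.all(g22 <= g18 + 1e-12)

    def test_high_correlation_between_variants(self):
        for seed in range(5):
            p = random_discrete_pedigree(10, 10, seed=seed)
            F = inbreeding_F(p)
            for d in np.arange(0.0, 0.51, 0.1):
                _, state = purged_inbreeding(p, d, F=F)
                _, blocks = purged_inbreeding_nonoverlapping(
                    p, d, F=F, return_blocks=True
                )
                a, b = [], []
                for members, G in blocks[1:]:
                    iu = np.triu_indices(len(members))  # all pairs incl. self
                    b.extend(G[iu])
                    a.extend(state.gamma[np.ix_(members, members)][iu])
                r = np.corrcoef(a, b)[0, 1]
                assert r > 0.999

    def test_rejects_overlapping_pedigree(self):
        p = ped_from_rows([("A", 0, 0), ("B", 0, 0), ("C", "A", "B"),
                           ("X", "A", "C")])  # parent-offspring mating
        with pytest.raises(PedigreeError, match="discrete"):
            purged_inbreeding_nonoverlapping(p, 0.2)


class TestDeltaFReliability:
    def test_arithmetic_example(self):
        # mean F 0.2 -> 0.4 gives deltaF = 0.25
        rows = [("A", 0, 0), ("B", 0, 0), ("C", "A", "B"), ("D", "A", "B")]
        p = ped_from_rows(rows)
        rep = delta_F_reliability(
            p, F=np.array([0.2, 0.2, 0.4, 0.4]), d=0.3
        )
        assert rep.delta_F[0] == pytest.approx(0.25)
        assert not rep.reliable[0]  # 0.3 < 2 * 0.25

    def test_no_change_always_reliable(self):
        rows = [("A", 0, 0), ("B", 0, 0), ("C", "A", "B")]
        p = ped_from_rows(rows)
        rep = delta_F_reliability(p, F=np.zeros(3), d=0.01)
        assert rep.delta_F[0] == 0.0
        assert rep.reliable[0]

    def test_single_interval(self, trio):
        rep = delta_F_reliability(trio, F=np.zeros(3), ages=np.zeros(3), d=0.1)
        assert rep.delta_F.size == 0

    def test_ideal_population_rate(self):
        # constant-size ideal population of N=10: deltaF ~ 1/(2N) = 0.05
        p = random_discrete_pedigree(10, 12, seed=11)
        rep = delta_F_reliability(p, d=0.15)
        late = rep.delta_F[3:]
        assert 0.02 < late.mean() < 0.08
        # reliable iff d > 2 deltaF; with d = 0.15 > 0.1 most intervals pass
        assert rep.reliable[3:].mean() > 0.5


def test_compute_coefficients_table(fullsib2):
    table = compute_coefficients(fullsib2, [0.0, 0.25, 0.5])
    assert table.g.shape == (fullsib2.n, 3)
    assert np.allclose(table.g[:, 0], table.F, atol=1e-12)
    assert np.all(table.g[:, 2] <= table.g[:, 1] + 1e-12)
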