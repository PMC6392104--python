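"""Cellular Potts engine: energies, Metropolis kinetics, division geometry."""

import math

import numpy as np
import pytest

from cd8sim.params import (
    ACTIVATED,
    APC,
    EFFECTOR,
    MEDIUM,
    NAIVE,
    PottsConfig,
)
from cd8sim.potts import (
    Tissue,
    attempt_copy,
    boltzmann_acceptance,
    cached_hamiltonian,
    contact_map,
    contact_pairs,
    delta_motility,
    hamiltonian,
    monte_carlo_step,
    split_cell,
)


def brute_force_hamiltonian(tissue):
    """O(S^2)-style oracle: explicit loops over all cells and all
    neighbour node pairs, written independently of the engine."""
    t = tissue
    L = t.L
    cfg = t.config
    energy = 0.0
    for cid in range(1, t.n_cells):
        nodes = [(i, j) for i in range(L) for j in range(L) if t.sigma[i, j] == cid]
        if not nodes:
            continue
        ct = int(t.ctype[cid])
        area = len(nodes)
        edges = 0
        for (i, j) in nodes:
            for (ni, nj) in (((i + 1) % L, j), ((i - 1) % L, j), (i, (j + 1) % L), (i, (j - 1) % L)):
                if t.sigma[ni, nj] != cid:
                    edges += 1
        energy += cfg.lam_area * (area - cfg.target_area[ct]) ** 2
        if cfg.perimeter_constrained[ct]:
            energy += cfg.lam_pm * (4.0 * edges - cfg.target_perimeter_um[ct]) ** 2
    # each unordered neighbour pair once (right and down edges)
    for i in range(L):
        for j in range(L):
            s1 = t.sigma[i, j]
            for (ni, nj) in (((i + 1) % L, j), (i, (j + 1) % L)):
                s2 = t.sigma[ni, nj]
                if s1 != s2:
                    energy += cfg.J[int(t.ctype[s1])][int(t.ctype[s2])]
    return energy


def random_tissue(rng, L=20, n_cells=6):
    t = Tissue(L)
    for _ in range(n_cells):
        for _ in range(50):
            i, j = rng.integers(0, L - 3, 2)
            block = t.sigma[i : i + 3, j : j + 3]
            if np.all(block == MEDIUM):
                t.add_cell(
                    [(i + a, j + b) for a in range(3) for b in range(3)],
                    int(rng.choice([NAIVE, ACTIVATED, EFFECTOR, APC])),
                )
                break
    return t


class TestHamiltonian:
    def test_all_medium_lattice_has_zero_energy(self):
        assert hamiltonian(Tissue(12)) == 0.0

    def test_single_target_shaped_cell(self):
        """A 3x3 CD8 cell at target area (9 nodes) and target perimeter
        (12 edges x 4 um = 48 um) contributes only contact energy with
        the medium: 12 boundary edges x J(cell, medium)."""
        t = Tissue(12)
        t.add_cell([(4 + a, 4 + b) for a in range(3) for b in range(3)], NAIVE)
        j = t.config.J[NAIVE][MEDIUM]
        assert hamiltonian(t) == pytest.approx(12 * j)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(100):
            t = random_tissue(rng)
            # churn the lattice so shapes are irregular
            g = np.random.default_rng(trial)
            monte_carlo_step(t, g, n_attempts=400)
            assert hamiltonian(t) == pytest.approx(brute_force_hamiltonian(t), rel=1e-9)

    def test_incremental_bookkeeping_matches_recomputation(self):
        rng = np.random.default_rng(5)
        t = random_tissue(rng, L=24, n_cells=8)
        t.refresh_theta(rng)
        for _ in range(10):
            monte_carlo_step(t, rng)
            assert cached_hamiltonian(t) == pytest.approx(hamiltonian(t), abs=1e-9)


class TestMetropolis:
    def test_always_accepts_energy_decrease(self):
        assert boltzmann_acceptance(-5.0, 10.0, 0.999999)
        assert boltzmann_acceptance(0.0, 10.0, 0.999999)

    def test_zero_temperature_limit(self):
        """As T -> 0+ energy-increasing copies are essentially never
        accepted."""
        rng = np.random.default_rng(0)
        accepted = sum(
            boltzmann_acceptance(1.0, 1e-6, u) for u in rng.random(100_000)
        )
        assert accepted == 0

    @pytest.mark.parametrize("de,temp", [(2.0, 5.0), (5.0, 5.0), (1.0, 0.5)])
    def test_acceptance_frequency_matches_boltzmann(self, de, temp):
        """Empirical acceptance over 1e5 trials within 3 standard errors
        of exp(-dE/T)."""
        rng = np.random.default_rng(123)
        n = 100_000
        acc = sum(boltzmann_acceptance(de, temp, u) for u in rng.random(n))
        p = math.exp(-de / temp)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(acc / n - p) < 3 * se


class TestMotility:
    def test_zero_weight(self):
        assert delta_motility(0.0, 1.2, (3, 3), (4, 3)) == 0.0

    def test_aligned_direction_maximal(self):
        assert delta_motility(2.0, 0.0, (3, 3), (4, 3)) == pytest.approx(2.0)

    def test_perpendicular_direction_zero(self):
        assert delta_motility(2.0, 0.0, (3, 3), (3, 4)) == pytest.approx(0.0, abs=1e-12)


class TestMonteCarloStep:
    def test_attempt_count_is_three_s(self):
        t = Tissue(20)
        rng = np.random.default_rng(0)
        attempted, _ = monte_carlo_step(t, rng)
        assert attempted == 3 * 20 * 20

    def test_unconstrained_copies_mostly_accepted(self):
        """With all energies and motility off, every heterotypic-boundary
        attempt is free (dE = 0) and accepted."""
        cfg = PottsConfig(
            J=[[0.0] * 7 for _ in range(7)],
            lam_area=0.0,
            lam_pm=0.0,
            motility=[0.0] * 7,
        )
        t = Tissue(16, cfg)
        t.add_cell([(4 + a, 4 + b) for a in range(3) for b in range(3)], NAIVE)
        rng = np.random.default_rng(1)
        attempted, accepted = monte_carlo_step(t, rng)
        # most attempts are interior no-ops; the accepted ones are the
        # boundary copies, and none of those may be rejected
        assert accepted > 0

    def test_node_count_conserved(self):
        rng = np.random.default_rng(2)
        t = random_tissue(rng, L=24, n_cells=8)
        t.refresh_theta(rng)
        S = t.S
        for _ in range(20):
            monte_carlo_step(t, rng)
            counts = np.bincount(t.sigma.ravel(), minlength=t.n_cells)
            assert counts.sum() == S
            np.testing.assert_array_equal(counts[: t.n_cells], t.area[: t.n_cells])

    def test_no_cell_annihilated(self):
        rng = np.random.default_rng(3)
        t = random_tissue(rng, L=20, n_cells=6)
        t.refresh_theta(rng)
        for _ in range(50):
            monte_carlo_step(t, rng)
        assert np.all(t.area[1 : t.n_cells] >= 1)

    def test_seed_reproducibility(self):
        def build(seed):
            rng = np.random.default_rng(seed)
            t = random_tissue(np.random.default_rng(9), L=24, n_cells=6)
            t.refresh_theta(rng)
            for _ in range(30):
                monte_carlo_step(t, rng)
            return t.sigma.copy()

        np.testing.assert_array_equal(build(7), build(7))
        assert not np.array_equal(build(7), build(8))

    def test_area_converges_to_target(self):
        """Strong area constraint and low temperature drive cells to
        their target area."""
        cfg = PottsConfig(lam_area=50.0, temperature=2.0)
        t = Tissue(30, cfg)
        t.add_cell([(5 + a, 5 + b) for a in range(2) for b in range(2)], NAIVE)
        t.add_cell([(15 + a, 15 + b) for a in range(4) for b in range(4)], NAIVE)
        rng = np.random.default_rng(4)
        t.refresh_theta(rng)
        for _ in range(500):
            monte_carlo_step(t, rng)
        areas = t.area[1 : t.n_cells]
        assert np.all(np.abs(areas - 9) <= 1)

    def test_single_attempt_wrapper(self):
        t = Tissue(10)
        t.add_cell([(3 + a, 3 + b) for a in range(3) for b in range(3)], NAIVE)
        rng = np.random.default_rng(5)
        results = [attempt_copy(t, rng) for _ in range(200)]
        assert any(results) and not all(results)


class TestContacts:
    def test_separated_cells_not_in_contact(self):
        t = Tissue(14)
        a = t.add_cell([(1 + i, 1 + j) for i in range(3) for j in range(3)], NAIVE)
        b = t.add_cell([(8 + i, 8 + j) for i in range(3) for j in range(3)], NAIVE)
        cm = contact_map(t)
        assert cm[a] == set() and cm[b] == set()

    def test_abutting_cells_in_contact(self):
        t = Tissue(14)
        a = t.add_cell([(1 + i, 1 + j) for i in range(3) for j in range(3)], NAIVE)
        b = t.add_cell([(1 + i, 4 + j) for i in range(3) for j in range(3)], APC)
        cm = contact_map(t)
        assert cm[a] == {b} and cm[b] == {a}

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            t = random_tissue(rng, L=30, n_cells=10)
            monte_carlo_step(t, rng, n_attempts=2000)
            got = contact_pairs(t.sigma)
            want = set()
            L = t.L
            for i in range(L):
                for j in range(L):
                    s1 = t.sigma[i, j]
                    if s1 == MEDIUM:
                        continue
                    for (ni, nj) in (((i + 1) % L, j), (i, (j + 1) % L)):
                        s2 = t.sigma[ni, nj]
                        if s2 != MEDIUM and s2 != s1:
                            want.add((min(s1, s2), max(s1, s2)))
            assert got == want


class TestSplitCell:
    def test_square_splits_into_connected_halves(self):
        t = Tissue(12)
        cid = t.add_cell([(4 + a, 4 + b) for a in range(3) for b in range(3)], ACTIVATED)
        rng = np.random.default_rng(0)
        mother, daughter = split_cell(t, cid, rng)
        sizes = sorted([int(t.area[mother]), int(t.area[daughter])])
        assert sizes == [4, 5]
        assert t.fragmented_cells() == []

    def test_domino_splits_into_single_nodes(self):
        t = Tissue(8)
        cid = t.add_cell([(2, 2), (2, 3)], ACTIVATED)
        rng = np.random.default_rng(0)
        mother, daughter = split_cell(t, cid, rng)
        assert int(t.area[mother]) == 1 and int(t.area[daughter]) == 1

    def test_single_node_division_deferred(self):
        t = Tissue(8)
        cid = t.add_cell([(2, 2)], ACTIVATED)
        assert split_cell(t, cid, np.random.default_rng(0)) is None

    def test_node_conservation_on_random_shapes(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            t = random_tissue(rng, L=20, n_cells=4)
            monte_carlo_step(t, rng, n_attempts=1500)
            for cid in range(1, t.n_cells):
                if t.area[cid] >= 2:
                    before = int(t.area[cid])
                    res = split_cell(t, cid, rng)
                    if res:
                        m, d = res
                        assert int(t.area[m]) + int(t.area[d]) == before
                    break
            counts = np.bincount(t.sigma.ravel(), minlength=t.n_cells)
            np.testing.assert_array_equal(counts[: t.n_cells], t.area[: t.n_cells])
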