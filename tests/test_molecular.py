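"""Intracellular network: right-hand side, integration, Tbet bistability."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cd8sim.molecular import (
    EnvironmentInputs,
    asymptotic_memory_state,
    check_bistability,
    molecular_rhs,
    step_molecular,
    tbet_fixed_points,
    tbet_rhs,
)
from cd8sim.params import CAS, E, InvalidInputError, MolecularParams, R, TB


def reference_rhs(y, env, p):
    """Independent term-by-term evaluation of the six equations, written
    directly from the model definition (oracle for molecular_rhs)."""
    r, lr, tb, fs, cas, e = y
    f, g, h, il2, tbcm = env.f_APC, env.G, env.H, env.IL2cm, env.Tbcm
    d = np.empty(6)
    d[0] = p.lam_R1 * f + (p.mu_IL2_minus + p.lam_R2) * lr + p.lam_E1 * e \
        - (p.mu_IL2_plus * il2 + p.k_R) * r
    d[1] = p.mu_IL2_plus * il2 * r - p.mu_IL2_minus * lr - p.k_e * lr
    d[2] = p.lam_T1 * f + p.lam_T2 * tb**p.n / (p.lam_T3**p.n + tb**p.n) - p.k_T * tb
    d[3] = h * p.mu_F_plus * tbcm * (p.lam_F / p.k_F - fs) - p.mu_F_minus * fs - p.k_F * fs
    d[4] = g * p.lam_c1 * (1 / (1 + p.lam_c2 * lr)) * (1 / (1 + p.lam_c3 * f)) \
        * (1 / (1 + p.lam_E2 * e)) + p.lam_c4 * fs - p.k_c * cas
    d[5] = (1 / (1 + p.lam_E5 * f)) * (
        p.lam_E3 * lr / (p.lam_E6 + lr) + g * p.lam_E4 / (1 + p.lam_E7 * tb)
    ) - p.k_E * e
    return d


def grid_scan_roots(p, n_grid=20000):
    """Brute-force sign-change scan for the non-negative steady states of
    the antigen-free Tbet equation (oracle for tbet_fixed_points).  Uses a
    linear grid plus a logarithmic one near zero, where roots accumulate
    for shallow Hill exponents."""
    hi = 10.0 * p.lam_T2 / p.k_T
    xs = np.unique(
        np.concatenate(
            [np.logspace(-12, np.log10(hi), 1000), np.linspace(0.0, hi, n_grid)]
        )
    )
    fs = tbet_rhs(xs, p)
    roots = [0.0]
    for i in range(1, len(xs) - 1):
        if fs[i] == 0.0 or fs[i] * fs[i + 1] < 0:
            roots.append(0.5 * (xs[i] + xs[i + 1]))
    return sorted(set(roots))


class TestRHS:
    def test_naive_zero_state_is_fixed_point(self, default_params):
        env = EnvironmentInputs()
        d = molecular_rhs(np.zeros(6), env, default_params)
        assert np.all(d == 0.0)

    def test_stable_tbet_root_has_zero_derivative(self, default_params):
        roots = tbet_fixed_points(default_params)
        tb_s = roots[-1]
        state = np.zeros(6)
        state[TB] = tb_s
        d = molecular_rhs(state, EnvironmentInputs(), default_params)
        assert abs(d[TB]) < 1e-7

    def test_matches_term_by_term_oracle(self, default_params, rng):
        for _ in range(50):
            y = rng.uniform(0, 150, size=6)
            env = EnvironmentInputs(
                f_APC=float(rng.integers(0, 3)),
                G=float(rng.integers(0, 2)),
                H=float(rng.integers(0, 2)),
                IL2cm=float(rng.uniform(0, 30)),
                Tbcm=float(rng.uniform(0, 300)),
            )
            got = molecular_rhs(y, env, default_params)
            want = reference_rhs(y, env, default_params)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_negative_state_rejected(self, default_params):
        y = np.zeros(6)
        y[CAS] = -1.0
        with pytest.raises(InvalidInputError):
            molecular_rhs(y, EnvironmentInputs(), default_params)

    def test_invalid_env_rejected(self, default_params):
        with pytest.raises(InvalidInputError):
            molecular_rhs(np.zeros(6), EnvironmentInputs(G=0.5), default_params)


class TestIntegration:
    def test_zero_state_stays_zero(self, default_params):
        env = EnvironmentInputs()
        y = step_molecular(np.zeros(6), env, default_params, dt=1.0 / 60)
        assert np.all(y == 0.0)

    def test_first_order_consistency(self, default_params):
        """(step(y, dt) - y)/dt converges to the RHS as dt -> 0."""
        y = np.array([10.0, 5.0, 30.0, 1.0, 4.0, 2.0])
        env = EnvironmentInputs(G=1.0, IL2cm=5.0)
        d_true = molecular_rhs(y, env, default_params)
        for dt in (1e-3, 1e-4):
            approx = (step_molecular(y, env, default_params, dt) - y) / dt
            assert np.max(np.abs(approx - d_true)) < 50 * dt

    def test_matches_scipy_reference(self, default_params):
        """One simulated hour agrees with an adaptive RK45 reference."""
        y0 = np.array([20.0, 10.0, 30.0, 0.5, 5.0, 3.0])
        env = EnvironmentInputs(f_APC=1.0, G=1.0, H=1.0, IL2cm=10.0, Tbcm=100.0)
        y = y0
        for _ in range(60):
            y = step_molecular(y, env, default_params, dt=1.0 / 60)
        ref = solve_ivp(
            lambda t, s: molecular_rhs(np.clip(s, 0, None), env, default_params),
            (0.0, 1.0),
            y0,
            rtol=1e-10,
            atol=1e-12,
        ).y[:, -1]
        np.testing.assert_allclose(y, ref, rtol=1e-5, atol=1e-7)

    def test_tbet_converges_to_high_state(self, default_params):
        """Integration of the Tbet equation alone from above the unstable
        point reaches the ~118 mol/L stable state."""
        roots = tbet_fixed_points(default_params)
        tb_u, tb_s = roots[1], roots[2]
        y = np.zeros(6)
        y[TB] = tb_u * 1.2
        env = EnvironmentInputs()
        for _ in range(400):
            y = step_molecular(y, env, default_params, dt=1.0)
        assert abs(y[TB] - tb_s) / tb_s < 0.01
        assert abs(y[TB] - 118.0) / 118.0 < 0.05

    def test_bistability_basins(self, default_params):
        roots = tbet_fixed_points(default_params)
        tb_u, tb_s = roots[1], roots[2]
        env = EnvironmentInputs()
        lo = np.zeros(6)
        lo[TB] = tb_u * 0.8
        hi = np.zeros(6)
        hi[TB] = tb_u * 1.2
        for _ in range(600):
            lo = step_molecular(lo, env, default_params, dt=1.0)
            hi = step_molecular(hi, env, default_params, dt=1.0)
        assert lo[TB] < 0.01 * tb_s
        assert abs(hi[TB] - tb_s) / tb_s < 0.01

    def test_nonnegativity_preserved(self, default_params, rng):
        """Random starts and constant environments never leave the
        non-negative orthant."""
        for _ in range(20):
            y = rng.uniform(0, 200, size=6)
            env = EnvironmentInputs(
                f_APC=float(rng.integers(0, 3)),
                G=float(rng.integers(0, 2)),
                H=float(rng.integers(0, 2)),
                IL2cm=float(rng.uniform(0, 50)),
                Tbcm=float(rng.uniform(0, 300)),
            )
            for _ in range(50):
                y = step_molecular(y, env, default_params, dt=0.25)
                assert np.all(y >= 0.0)

    def test_bad_dt_rejected(self, default_params):
        with pytest.raises(InvalidInputError):
            step_molecular(np.zeros(6), EnvironmentInputs(), default_params, dt=0.0)


class TestTbetAnalysis:
    def test_default_fixed_points(self, default_params):
        roots = tbet_fixed_points(default_params, with_stability=True)
        assert len(roots) == 3
        (r0, s0), (r1, s1), (r2, s2) = roots
        assert r0 == 0.0 and s0 is True
        assert abs(r1 - 21.0) / 21.0 < 0.05 and s1 is False
        assert abs(r2 - 118.0) / 118.0 < 0.05 and s2 is True

    def test_n_equal_one_never_three_roots(self, default_params):
        from dataclasses import replace

        p = replace(default_params, n=1.0)
        assert len(tbet_fixed_points(p)) <= 2
        assert check_bistability(p) is False

    @staticmethod
    def _random_params(rng, n_lo=1.2):
        """Random Tbet parameters away from two degenerate regimes where
        finite-resolution root counting is ill-posed: the saddle-node
        tangency, and Hill exponents so close to 1 that the unstable root
        collapses below floating-point resolution."""
        while True:
            p = MolecularParams(
                lam_T2=float(rng.uniform(5, 100)),
                lam_T3=float(rng.uniform(5, 200)),
                k_T=float(rng.uniform(0.05, 1.0)),
                n=float(rng.uniform(n_lo, 4.0)),
            )
            if 0.95 < p.n < 1.2:
                continue
            lhs = p.lam_T2 * (p.n - 1) ** ((p.n - 1) / p.n) if p.n > 1 else 0.0
            rhs = p.n * p.k_T * p.lam_T3
            if abs(lhs - rhs) > 0.05 * rhs:
                return p

    def test_roots_match_grid_scan(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            p = self._random_params(rng)
            got = tbet_fixed_points(p)
            want = grid_scan_roots(p)
            assert len(got) == len(want)
            spacing = 10.0 * p.lam_T2 / p.k_T / 20000
            for g, w in zip(got, want):
                assert abs(g - w) <= max(spacing, 2e-3 * (1 + w))

    def test_bistability_agrees_with_root_count(self):
        """The closed-form condition is equivalent to the equation having
        three non-negative steady states, over random parameter draws."""
        rng = np.random.default_rng(7)
        agree = 0
        for _ in range(100):
            p = self._random_params(rng, n_lo=0.5)
            bistable = check_bistability(p)
            three = len(tbet_fixed_points(p)) == 3
            agree += bistable == three
        assert agree == 100


class TestMemoryState:
    def test_memory_profile_anchors(self, default_params):
        y = asymptotic_memory_state(default_params)
        assert y[TB] == 0.0
        assert abs(y[E] - 26.0) / 26.0 < 0.10
        assert abs(y[CAS] - 9.0) / 9.0 < 0.15

    def test_memory_profile_is_steady(self, default_params):
        y = asymptotic_memory_state(default_params)
        env = EnvironmentInputs(G=1.0)
        d = molecular_rhs(y, env, default_params)
        assert np.linalg.norm(d) < 1e-4

    def test_memory_receptors_exceed_naive(self, default_params):
        """Eomes sustains IL2 receptors: the memory profile carries more
        receptors than the all-zero naive state."""
        y = asymptotic_memory_state(default_params)
        assert y[R] > 10.0
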