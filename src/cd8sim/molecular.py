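"""Intracellular regulatory network of one CD8 T-cell.

Six coupled ODEs describe the concentrations of non-activated IL2
receptors (R), activated IL2 receptors (LR), Tbet (Tb), activated Fas
(Fs), Caspases (Cas) and Eomes (E).  The network is driven by five
external inputs: the number of bound APCs (f_APC), an activation-history
flag G, a Fas-engagement flag H, the IL2 concentration at the membrane
(IL2cm) and the summed Tbet of contacting effector/memory cells (Tbcm).

The Tbet equation carries an order-n Hill positive feedback; when
n > 1 and lam_T2 (n-1)^((n-1)/n) > n k_T lam_T3 it is bistable with
steady states 0 < Tb_u < Tb_s, 0 and Tb_s stable, Tb_u unstable.  Cell
fate in the population model hinges on which basin a cell's Tbet
concentration falls into.

All functions are vectorised: states may be a single length-6 vector or
an (n_cells, 6) array, with environment inputs broadcast per cell.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .params import (
    CAS,
    E,
    FS,
    LR,
    R,
    TB,
    InvalidInputError,
    MolecularParams,
    NumericalBlowupError,
    STATE_NAMES,
)

__all__ = [
    "EnvironmentInputs",
    "molecular_rhs",
    "step_molecular",
    "tbet_rhs",
    "tbet_fixed_points",
    "check_bistability",
    "asymptotic_memory_state",
]


@dataclass
class EnvironmentInputs:
    """External drivers of the intracellular system for one cell (or,
    as arrays, for a batch of cells)."""

    f_APC: np.ndarray | float = 0.0
    G: np.ndarray | float = 0.0
    H: np.ndarray | float = 0.0
    IL2cm: np.ndarray | float = 0.0
    Tbcm: np.ndarray | float = 0.0

    def validate(self) -> None:
        f, g, h = np.asarray(self.f_APC), np.asarray(self.G), np.asarray(self.H)
        if np.any(f < 0) or np.any(np.asarray(self.IL2cm) < 0) or np.any(np.asarray(self.Tbcm) < 0):
            raise InvalidInputError("f_APC, IL2cm and Tbcm must be non-negative")
        if not (np.isin(g, (0, 1)).all() and np.isin(h, (0, 1)).all()):
            raise InvalidInputError("G and H must be binary flags")


def molecular_rhs(
    state: np.ndarray, env: EnvironmentInputs, params: MolecularParams
) -> np.ndarray:
    """Time derivative of the six concentrations.

    Raises on negative state components or non-positive parameters; the
    zero state with a naive environment (G = 0, everything else 0) is a
    fixed point, so never-activated cells stay quiescent.
    """
    state = np.asarray(state, dtype=float)
    if np.any(state < 0):
        raise InvalidInputError("molecular state components must be non-negative")
    params.validate()
    env.validate()
    return _rhs(state, env, params)


def _rhs(state: np.ndarray, env: EnvironmentInputs, p: MolecularParams) -> np.ndarray:
    """Unchecked right-hand side (hot path)."""
    r, lr, tb, fs, cas, e = (state[..., i] for i in range(6))
    f_apc = np.asarray(env.f_APC, dtype=float)
    g = np.asarray(env.G, dtype=float)
    h = np.asarray(env.H, dtype=float)
    il2 = np.asarray(env.IL2cm, dtype=float)
    tbcm = np.asarray(env.Tbcm, dtype=float)

    out = np.empty_like(state)
    out[..., R] = (
        p.lam_R1 * f_apc
        + (p.mu_IL2_minus + p.lam_R2) * lr
        + p.lam_E1 * e
        - (p.mu_IL2_plus * il2 + p.k_R) * r
    )
    out[..., LR] = p.mu_IL2_plus * il2 * r - p.mu_IL2_minus * lr - p.k_e * lr
    tb_n = tb**p.n
    out[..., TB] = p.lam_T1 * f_apc + p.lam_T2 * tb_n / (p.lam_T3**p.n + tb_n) - p.k_T * tb
    out[..., FS] = (
        h * p.mu_F_plus * tbcm * (p.fas_saturation - fs) - p.mu_F_minus * fs - p.k_F * fs
    )
    out[..., CAS] = (
        g
        * p.lam_c1
        / ((1.0 + p.lam_c2 * lr) * (1.0 + p.lam_c3 * f_apc) * (1.0 + p.lam_E2 * e))
        + p.lam_c4 * fs
        - p.k_c * cas
    )
    out[..., E] = (
        1.0
        / (1.0 + p.lam_E5 * f_apc)
        * (p.lam_E3 * lr / (p.lam_E6 + lr) + g * p.lam_E4 / (1.0 + p.lam_E7 * tb))
        - p.k_E * e
    )
    return out


def _rk4(state, env, p, dt, nsub):
    h = dt / nsub
    y = state
    clipped = 0
    for _ in range(nsub):
        k1 = _rhs(y, env, p)
        k2 = _rhs(np.clip(y + 0.5 * h * k1, 0.0, None), env, p)
        k3 = _rhs(np.clip(y + 0.5 * h * k2, 0.0, None), env, p)
        k4 = _rhs(np.clip(y + h * k3, 0.0, None), env, p)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        clipped += int(np.count_nonzero(y < 0))
        y = np.clip(y, 0.0, None)
    return y, clipped


def step_molecular(
    state: np.ndarray,
    env: EnvironmentInputs,
    params: MolecularParams,
    dt: float,
    *,
    return_clip_count: bool = False,
):
    """Advance the state by ``dt`` hours with fixed-step RK4.

    A single RK4 step is taken; if any variable changes by more than 20%
    of max(|value|, 1) the step is redone with 10 substeps.  Any negative
    intermediate is clipped at zero (the count is returned on request so
    the caller can warn if clipping becomes frequent).
    """
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    state = np.asarray(state, dtype=float)
    y1, clipped = _rk4(state, env, params, dt, 1)
    rel = np.abs(y1 - state) / np.maximum(np.maximum(np.abs(state), np.abs(y1)), 1.0)
    if np.any(rel > 0.2):
        y1, clipped = _rk4(state, env, params, dt, 10)
    if not np.all(np.isfinite(y1)):
        bad = np.where(~np.isfinite(y1))[-1]
        name = STATE_NAMES[int(bad[0]) % 6]
        raise NumericalBlowupError(f"non-finite value in variable {name} after dt={dt}")
    if return_clip_count:
        return y1, clipped
    return y1


# ---------------------------------------------------------------------------
# Analysis of the Tbet sub-equation (f_APC = 0)


def tbet_rhs(x: np.ndarray, params: MolecularParams) -> np.ndarray:
    """dTb/dt of the isolated Tbet equation without antigen drive."""
    x = np.asarray(x, dtype=float)
    xn = x**params.n
    return params.lam_T2 * xn / (params.lam_T3**params.n + xn) - params.k_T * x


def check_bistability(params: MolecularParams) -> bool:
    """True iff the antigen-free Tbet equation has two stable and one
    unstable non-negative steady states (n > 1 and
    lam_T2 (n-1)^((n-1)/n) > n k_T lam_T3)."""
    n = params.n
    if n <= 1:
        return False
    return params.lam_T2 * (n - 1) ** ((n - 1) / n) > n * params.k_T * params.lam_T3


def tbet_fixed_points(
    params: MolecularParams, *, with_stability: bool = False
) -> "list[float] | list[tuple[float, bool]]":
    """All non-negative steady states of the antigen-free Tbet equation,
    ascending.  With ``with_stability`` each root is paired with True if
    locally stable (negative slope of the RHS through the root).

    0 is always a root.  Positive roots solve
    lam_T2 x^(n-1) / (lam_T3^n + x^n) = k_T, found by a sign-change scan
    plus Brent refinement on [0, 10 lam_T2 / k_T].
    """
    from scipy.optimize import brentq

    def g(x):
        # positive roots of the rhs excluding the trivial factor x
        return params.lam_T2 * x ** (params.n - 1.0) / (
            params.lam_T3**params.n + x**params.n
        ) - params.k_T

    hi = 10.0 * params.lam_T2 / params.k_T
    # linear grid for the bulk plus a log-spaced grid so that roots very
    # close to zero (shallow Hill exponents) are not stepped over
    xs = np.unique(
        np.concatenate([np.logspace(-12, np.log10(hi), 500), np.linspace(1e-9, hi, 4000)])
    )
    gs = g(xs)
    roots = [0.0]
    for i in range(len(xs) - 1):
        if gs[i] == 0.0:
            roots.append(float(xs[i]))
        elif gs[i] * gs[i + 1] < 0:
            roots.append(float(brentq(g, xs[i], xs[i + 1], xtol=1e-12)))
    roots = sorted(set(round(r, 10) for r in roots))
    if not with_stability:
        return roots
    eps = max(1e-6, 1e-9 * hi)
    out = []
    for r in roots:
        lo = tbet_rhs(max(r - eps, 0.0), params)
        hi_ = tbet_rhs(r + eps, params)
        if r == 0.0:
            stable = bool(hi_ < 0)
        else:
            stable = bool(lo > 0 and hi_ < 0)
        out.append((r, stable))
    return out


def asymptotic_memory_state(
    params: MolecularParams,
    *,
    start: np.ndarray | None = None,
    dt: float = 0.5,
    tol: float = 1e-9,
    max_hours: float = 5000.0,
    snap_tol: float = 1e-6,
) -> np.ndarray:
    """Resting molecular profile of a memory cell.

    Integrates the network without antigen or contacts (f_APC = 0, H = 0,
    IL2cm = 0, Tbcm = 0) but with activation history G = 1, from a
    low-Tbet post-effector state, until the relative change per step
    drops below ``tol``.  Under the shipped defaults this converges to
    Tb = 0, E ~ 26, Cas ~ 9 mol/L with receptors sustained by Eomes.
    """
    env = EnvironmentInputs(f_APC=0.0, G=1.0, H=0.0, IL2cm=0.0, Tbcm=0.0)
    y = (
        np.array([5.0, 1.0, 1.0, 0.5, 5.0, 5.0])
        if start is None
        else np.asarray(start, dtype=float).copy()
    )
    t = 0.0
    while t < max_hours:
        y_next = step_molecular(y, env, params, dt)
        if np.max(np.abs(y_next - y)) < tol * max(1.0, float(np.max(np.abs(y_next)))):
            # variables that have decayed to numerical zero are reported as 0
            y_next[y_next < snap_tol] = 0.0
            return y_next
        y = y_next
        t += dt
    raise NumericalBlowupError(
        f"memory profile did not converge within {max_hours} h; last state {y}"
    )
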