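"""Extracellular IL2: secretion, diffusion and decay on the lattice.

The cytokine lives on the same periodic L x L grid as the Potts lattice.
Its evolution is the reaction-diffusion law

    d[IL2]/dt = D lap([IL2]) + sources - delta [IL2]

integrated with a forward-time centred-space (FTCS) stencil and a
4-neighbour Laplacian, subcycled so that D dt_sub <= 1/4 (node spacing 1)
for stability.  The stencil conserves mass exactly under periodic
boundaries when delta = 0.

Each secreting cell contributes a per-cell source rate, divided equally
over its nodes.  Cells read the field back as the *membrane
concentration*: the sum of node values over their boundary nodes (nodes
with at least one first-order neighbour outside the cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import FieldParams, InvalidInputError, MEDIUM

__all__ = ["IL2Field", "secretion_rate", "step_field", "il2_at_membrane", "boundary_mask"]


class FieldInstabilityError(RuntimeError):
    pass


@dataclass
class IL2Field:
    """Lattice-aligned IL2 concentration grid plus its physics parameters."""

    grid: np.ndarray
    params: FieldParams = field(default_factory=FieldParams)

    @classmethod
    def zeros(cls, L: int, params: FieldParams | None = None) -> "IL2Field":
        return cls(np.zeros((L, L)), params or FieldParams())

    @property
    def total_mass(self) -> float:
        return float(self.grid.sum())


def secretion_rate(
    state: np.ndarray, f_apc: np.ndarray | float, params: FieldParams
) -> np.ndarray:
    """Per-cell IL2 secretion rate (mol/L/h).

    (lam_R3 LR / (lam_R4 + LR) + lam_1 f_APC) / (1 + lam_T4 Tb):
    autocrine drive saturating in activated receptors plus a TCR-driven
    term, both damped by Tbet.  The caller zeroes it for naive cells and
    APCs, which do not secrete.
    """
    state = np.asarray(state, dtype=float)
    lr = state[..., 1]
    tb = state[..., 2]
    return (params.lam_R3 * lr / (params.lam_R4 + lr) + params.lam_1 * np.asarray(f_apc)) / (
        1.0 + params.lam_T4 * tb
    )


def _laplacian(g: np.ndarray) -> np.ndarray:
    return (
        np.roll(g, 1, axis=0)
        + np.roll(g, -1, axis=0)
        + np.roll(g, 1, axis=1)
        + np.roll(g, -1, axis=1)
        - 4.0 * g
    )


def step_field(field_: IL2Field, sources: np.ndarray | None, dt: float) -> IL2Field:
    """Advance the field by ``dt`` hours in place.

    ``sources`` is a per-node secretion-rate grid (mol/L/h) or None.
    Internally subcycles the FTCS update so D dt_sub <= 1/4.
    """
    p = field_.params
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    # strictly inside the FTCS bound D dt_sub <= 1/4 so the decay term
    # cannot tip the centre coefficient negative
    nsub = max(1, int(np.ceil(5.0 * p.D * dt + p.delta * dt)))
    h = dt / nsub
    g = field_.grid
    for _ in range(nsub):
        g = g + h * (p.D * _laplacian(g) - p.delta * g)
        if sources is not None:
            g = g + h * sources
    if not np.all(np.isfinite(g)) or np.any(g < -1e-12):
        raise FieldInstabilityError(
            f"IL2 field unstable for dt={dt}, D={p.D}: check the stability bound"
        )
    np.clip(g, 0.0, None, out=g)
    field_.grid = g
    return field_


def boundary_mask(sigma: np.ndarray) -> np.ndarray:
    """Nodes whose first-order neighbourhood leaves their own cell.

    Medium nodes are never boundary nodes of a cell.
    """
    m = np.zeros(sigma.shape, dtype=bool)
    for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
        m |= np.roll(sigma, sh, axis=ax) != sigma
    m &= sigma != MEDIUM
    return m


def il2_at_membrane(field_: IL2Field, sigma: np.ndarray, cell_id: int) -> float:
    """Membrane IL2 of one cell: sum of the field over its boundary nodes."""
    nodes = sigma == cell_id
    if not nodes.any():
        raise InvalidInputError(f"cell {cell_id} occupies no lattice node")
    mask = boundary_mask(sigma) & nodes
    return float(field_.grid[mask].sum())


def il2_at_membrane_all(field_: IL2Field, sigma: np.ndarray, n_cells: int) -> np.ndarray:
    """Vectorised membrane IL2 for every cell index in [0, n_cells)."""
    mask = boundary_mask(sigma)
    return np.bincount(
        sigma[mask].ravel(), weights=field_.grid[mask].ravel(), minlength=n_cells
    )[:n_cells]


def deposit_sources(
    sigma: np.ndarray,
    rates: np.ndarray,
    areas: np.ndarray,
) -> np.ndarray:
    """Spread each cell's secretion rate equally over its nodes.

    ``rates`` and ``areas`` are indexed by cell id; returns a per-node
    source-rate grid.
    """
    per_node = np.zeros_like(rates, dtype=float)
    occupied = areas > 0
    per_node[occupied] = rates[occupied] / areas[occupied]
    return per_node[sigma]
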