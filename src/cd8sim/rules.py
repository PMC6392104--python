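"""Cell-level rules: differentiation, cycling, division partitioning,
apoptosis and APC lifetime.

The differentiation scheme is linear and irreversible:

    naive -> pre-activated -> activated -> effector -> memory

* a naive cell touching an APC becomes pre-activated and adheres to it;
* a pre-activated cell whose activated-receptor concentration reaches
  IL2R_th becomes activated, detaches and starts cycling;
* at division each daughter is typed by its Tbet concentration
  (activated below Tbet_th, effector at or above);
* a dividing activated/effector cell whose Eomes exceeds Eomes_th
  converts to memory and stops proliferating (by default the mother
  converts instead of dividing);
* apoptosis strikes any non-naive CD8 cell whose Caspases reach
  Caspases_th; APCs die at a lifetime drawn uniformly from [48, 96] h.

In a secondary response, memory cells may re-bind an APC and re-enter
the scheme at the pre-activated stage, keeping their molecular state.

Division halves the cell volume, so partitioning concentrations with
factors k and 2 - k conserves molecule numbers exactly.
"""

from __future__ import annotations

from typing import Dict, Iterable, Set, Tuple

import numpy as np

from .molecular import EnvironmentInputs
from .params import (
    ACTIVATED,
    APC,
    CAS,
    EFFECTOR,
    InvalidInputError,
    LR,
    MEMORY,
    NAIVE,
    PREACTIVATED,
    TB,
    Thresholds,
)

__all__ = [
    "ALLOWED_TRANSITIONS",
    "sample_cycle_length",
    "mean_cycle_length",
    "partition_concentrations",
    "asymmetric_first_division",
    "environment_inputs",
    "daughter_type",
    "transition",
    "check_apoptosis",
    "sample_apc_lifetime",
]


# Directed edges of the differentiation scheme.  memory -> pre-activated
# is the antigen re-engagement edge used by the secondary response.
ALLOWED_TRANSITIONS: Set[Tuple[int, int]] = {
    (NAIVE, PREACTIVATED),
    (PREACTIVATED, ACTIVATED),
    (ACTIVATED, ACTIVATED),
    (ACTIVATED, EFFECTOR),
    (EFFECTOR, EFFECTOR),
    (ACTIVATED, MEMORY),
    (EFFECTOR, MEMORY),
    (MEMORY, PREACTIVATED),
}


class IllegalTransitionError(RuntimeError):
    """A requested type change would violate the irreversible scheme."""


def transition(current: int, new: int) -> int:
    if current != new and (current, new) not in ALLOWED_TRANSITIONS:
        raise IllegalTransitionError(f"illegal differentiation step {current} -> {new}")
    return new


def mean_cycle_length(k: int | np.ndarray) -> np.ndarray:
    """Mean cycle duration c_k = 6 + 28 k^2 / (k^2 + 100) hours: 6 h for
    the first division, saturating towards 34 h at high division counts."""
    k = np.asarray(k, dtype=float)
    return 6.0 + 28.0 * k**2 / (k**2 + 100.0)


def sample_cycle_length(k: int, rng: np.random.Generator) -> float:
    """Cycle length for a cell preparing its k-th division, drawn at
    birth from Uniform[c_k - 4, c_k + 4] hours."""
    if k < 0:
        raise InvalidInputError("division count must be non-negative")
    c = float(mean_cycle_length(k))
    return float(rng.uniform(c - 4.0, c + 4.0))


def partition_concentrations(
    mother: np.ndarray, m: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """m%-uneven partitioning of the six protein concentrations.

    Independently per protein, a factor k ~ Uniform[1 - m/100, 1] is
    drawn; one daughter (a fair coin per protein) inherits k [i], the
    other (2 - k) [i].  The per-protein sum is exactly twice the mother's
    concentration, i.e. molecule numbers are conserved across the two
    half-volume daughters.
    """
    if not 0.0 <= m <= 100.0:
        raise InvalidInputError(f"degree of unevenness m must be in [0, 100], got {m}")
    mother = np.asarray(mother, dtype=float)
    k = rng.uniform(1.0 - m / 100.0, 1.0, size=mother.shape)
    first_gets_low = rng.random(size=mother.shape) < 0.5
    f1 = np.where(first_gets_low, k, 2.0 - k)
    d1 = f1 * mother
    d2 = (2.0 - f1) * mother
    return d1, d2


def asymmetric_first_division(
    mother: np.ndarray, m: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """First post-activation division of a polarised cell.

    Tbet alone follows the asymmetric rule: with K ~ Uniform[0.5, 1] the
    proximal daughter receives (2 - K) [Tb] and the distal one K [Tb],
    so the proximal daughter never gets less Tbet.  The other five
    proteins follow the ordinary m%-uneven rule.

    Returns (proximal, distal).
    """
    d1, d2 = partition_concentrations(mother, m, rng)
    K = rng.uniform(0.5, 1.0)
    tb = float(np.asarray(mother, dtype=float)[TB])
    d1 = d1.copy()
    d2 = d2.copy()
    d1[TB] = (2.0 - K) * tb
    d2[TB] = K * tb
    return d1, d2


def environment_inputs(
    cell_type: int,
    ever_activated: bool,
    contacts: Iterable[int],
    contact_types: Dict[int, int],
    contact_tbet: Dict[int, float],
    il2cm: float,
) -> EnvironmentInputs:
    """Assemble the five external drivers of the molecular network for
    one CD8 T-cell from the current contact map and IL2 field.

    f_APC counts bound APCs for naive and pre-activated cells only
    (activated and later stages have left the APC); G records activation
    history; H flags Fas engagement by a contacting effector or memory
    cell (non-naive cells only); Tbcm sums the Tbet of those cells.
    """
    f_apc = 0
    h = 0
    tbcm = 0.0
    for other in contacts:
        ot = contact_types[other]
        if ot == APC and cell_type in (NAIVE, PREACTIVATED):
            f_apc += 1
        if ot in (EFFECTOR, MEMORY):
            if cell_type != NAIVE:
                h = 1
            tbcm += contact_tbet.get(other, 0.0)
    if cell_type == NAIVE:
        tbcm = 0.0
    g = 1.0 if (ever_activated or cell_type != NAIVE) else 0.0
    return EnvironmentInputs(
        f_APC=float(f_apc), G=g, H=float(h), IL2cm=float(il2cm), Tbcm=float(tbcm)
    )


def daughter_type(tb: float, thresholds: Thresholds) -> int:
    """Fate of a newborn daughter: effector iff its Tbet reached Tbet_th."""
    return EFFECTOR if tb >= thresholds.Tbet_th else ACTIVATED


def should_become_memory(eomes: float, thresholds: Thresholds) -> bool:
    """Memory conversion check applied to a cell completing its cycle
    (strictly greater, per the differentiation scheme)."""
    return eomes > thresholds.Eomes_th


def check_apoptosis(
    cell_type: int, cas: float, thresholds: Thresholds
) -> bool:
    """True when a CD8 T-cell dies: Caspases at or above threshold, naive
    cells exempt (their network is quiescent and they never die here)."""
    if cell_type == NAIVE:
        return False
    return cas >= thresholds.Caspases_th


def sample_apc_lifetime(rng: np.random.Generator) -> float:
    """APC lifespan in hours, Uniform[48, 96], drawn at simulation start."""
    return float(rng.uniform(48.0, 96.0))
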