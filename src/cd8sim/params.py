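"""Parameter containers and shipped default parameter sets.

All rates are expressed per hour; concentrations in mol/L (arbitrary
normalised units, as customary for lumped gene-activity/protein variables);
lattice lengths in nodes, one node = 4 um so one node is 4 x 4 um^2.

The molecular defaults form the package's calibrated set.  They are
constrained so that

* the Tbet sub-equation is bistable with fixed points 0 < Tb_u ~ 21 <
  Tb_s ~ 118 mol/L,
* the post-effector resting (memory) steady state is (Tb, E, Cas) =
  (0, ~26, ~9) mol/L,
* the population-scale response shows clonal expansion to a peak followed
  by contraction and the emergence of a stable memory pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Dict, Optional

import yaml

# Cell types.  Index 0 is reserved for the extracellular medium in the
# Potts lattice; the ordering is fixed because energy tables index by it.
MEDIUM = 0
APC = 1
NAIVE = 2
PREACTIVATED = 3
ACTIVATED = 4
EFFECTOR = 5
MEMORY = 6

TYPE_NAMES = (
    "medium",
    "apc",
    "naive",
    "preactivated",
    "activated",
    "effector",
    "memory",
)
N_TYPES = len(TYPE_NAMES)

CD8_TYPES = (NAIVE, PREACTIVATED, ACTIVATED, EFFECTOR, MEMORY)

# Index layout of the six-variable molecular state vector.
R, LR, TB, FS, CAS, E = range(6)
STATE_NAMES = ("R", "LR", "Tb", "Fs", "Cas", "E")


class InvalidInputError(ValueError):
    """Raised when a state, environment or parameter violates its domain."""


class NumericalBlowupError(RuntimeError):
    """Raised when an integration step produces NaN or infinity."""


@dataclass
class MolecularParams:
    """Rates and affinities of the intracellular regulatory network.

    lam_* are induction/inhibition strengths, mu_* activation/deactivation
    rates of transmembrane receptors, k_* degradation/dilution rates, n the
    Hill exponent of the Tbet positive feedback loop.
    """

    # IL2 receptor production / activation (R, LR equations)
    lam_R1: float = 30.0      # R production per bound APC
    lam_R2: float = 0.3       # receptor recycling from the activated form
    lam_E1: float = 0.5       # Eomes-driven receptor production
    k_R: float = 0.25         # R turnover
    mu_IL2_plus: float = 0.02  # binding of membrane IL2 to R
    mu_IL2_minus: float = 0.1  # dissociation of the IL2-receptor complex
    k_e: float = 0.1          # internalisation of the activated receptor

    # Tbet equation (bistable positive feedback)
    lam_T1: float = 6.8       # TCR-driven Tbet synthesis per bound APC
    lam_T2: float = 56.634    # maximal autocatalytic synthesis rate
    lam_T3: float = 83.766    # half-saturation of the feedback
    n: float = 1.5            # Hill exponent
    k_T: float = 0.3          # Tbet turnover

    # Activated Fas equation
    mu_F_plus: float = 0.001  # Fas engagement per unit contacting Tbet
    mu_F_minus: float = 0.1   # disengagement
    lam_F: float = 2.0        # with k_F sets the saturation level lam_F/k_F
    k_F: float = 0.2          # activated-Fas turnover

    # Caspases equation
    lam_c1: float = 0.396     # basal activation in experienced cells
    lam_c2: float = 0.05      # inhibition by activated IL2 receptors
    lam_c3: float = 1.0       # inhibition by TCR engagement
    lam_c4: float = 0.05      # activation by engaged Fas
    lam_E2: float = 0.0556    # inhibition by Eomes
    k_c: float = 0.018        # Caspases turnover

    # Eomes equation
    lam_E3: float = 0.05      # induction by activated IL2 receptors
    lam_E4: float = 2.34      # antigen-independent induction (experienced cells)
    lam_E5: float = 10.0      # inhibition by TCR engagement
    lam_E6: float = 20.0      # half-saturation of the IL2R-driven term
    lam_E7: float = 1.0       # inhibition by Tbet
    k_E: float = 0.09         # Eomes turnover

    # Ambiguous saturation term of the Fas equation: the default reading is
    # the bounded ratio lam_F/k_F; the alternative multiplies instead.
    fas_product_form: bool = False

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if name == "fas_product_form":
                continue
            if not value > 0:
                raise InvalidInputError(f"parameter {name} must be > 0, got {value}")

    @property
    def fas_saturation(self) -> float:
        return self.lam_F * self.k_F if self.fas_product_form else self.lam_F / self.k_F


@dataclass
class FieldParams:
    """Extracellular IL2 field: diffusion, decay and secretion law."""

    D: float = 60.0           # diffusion coefficient, node^2/h (960 um^2/h)
    delta: float = 2.0        # decay rate /h
    lam_R3: float = 15.0      # maximal autocrine secretion rate
    lam_R4: float = 20.0      # half-saturation on activated receptors
    lam_1: float = 400.0      # TCR-driven secretion per bound APC
    lam_T4: float = 0.02      # inhibition of secretion by Tbet


@dataclass
class Thresholds:
    """Concentration thresholds steering differentiation and death."""

    IL2R_th: float = 24.0     # activated receptors: pre-activated -> activated
    Tbet_th: float = 40.0     # daughter fate at division: activated vs effector
    Eomes_th: float = 16.0    # dividing cell converts to memory above this
    Caspases_th: float = 19.0  # apoptosis trigger

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise InvalidInputError(f"threshold {name} must be > 0, got {value}")


@dataclass
class UnevennessConfig:
    """Degree of unevenness of molecular partitioning at division.

    ``m`` is a percentage: an m% uneven division gives one daughter up to
    (50 + m/2)% of each protein's molecules and the other the rest.
    """

    m: float = 10.0
    # If the dividing mother carries Eomes above threshold, either convert
    # the mother to memory without dividing (default) or divide and convert
    # both daughters.
    memory_divides: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.m <= 100.0:
            raise InvalidInputError(f"degree of unevenness m must be in [0, 100], got {self.m}")


def _default_J() -> "list[list[float]]":
    """Symmetric contact-energy table over the 7 types.

    Chosen so pre-activated cells adhere tightly to APCs (their lowest
    energy contact), activated cells detach from APCs, and T-cells remain
    compact and do not clump irreversibly.
    """
    J = [[0.0] * N_TYPES for _ in range(N_TYPES)]

    def s(a, b, v):
        J[a][b] = v
        J[b][a] = v

    for t in CD8_TYPES:
        s(t, MEDIUM, 8.0)
    s(APC, MEDIUM, 8.0)
    for a in CD8_TYPES:
        for b in CD8_TYPES:
            if J[a][b] == 0.0 and a != MEDIUM and b != MEDIUM:
                s(a, b, 20.0)
    s(APC, APC, 30.0)
    s(NAIVE, APC, 11.0)
    s(PREACTIVATED, APC, 2.0)    # strong adhesion during priming
    s(ACTIVATED, APC, 30.0)      # detachment after activation
    s(EFFECTOR, APC, 25.0)
    s(MEMORY, APC, 11.0)         # memory cells can re-engage APCs
    return J


@dataclass
class PottsConfig:
    """Cellular Potts energies and Monte-Carlo settings."""

    J: "list[list[float]]" = field(default_factory=_default_J)
    lam_area: float = 8.0
    lam_pm: float = 0.2
    temperature: float = 12.0
    # Target geometry per type (medium unconstrained).  T-cells: 9 nodes
    # (144 um^2) and 48 um perimeter; APCs: 140 nodes, no perimeter term.
    target_area: "list[float]" = field(
        default_factory=lambda: [0.0, 140.0, 9.0, 9.0, 9.0, 9.0, 9.0]
    )
    target_perimeter_um: "list[float]" = field(
        default_factory=lambda: [0.0, 0.0, 48.0, 48.0, 48.0, 48.0, 48.0]
    )
    perimeter_constrained: "list[bool]" = field(
        default_factory=lambda: [False, False, True, True, True, True, True]
    )
    # Motility weight per type; pre-activated cells stay put on the APC.
    motility: "list[float]" = field(
        default_factory=lambda: [0.0, 1.0, 40.0, 0.0, 8.0, 8.0, 40.0]
    )
    theta_update_interval: int = 30   # MCS between privileged-angle refreshes
    neighbour_order: int = 1          # 1 -> 4-neighbour, 2 -> 8-neighbour contacts

    def validate(self) -> None:
        if self.temperature <= 0:
            raise InvalidInputError("Potts temperature must be > 0")
        if self.lam_area < 0 or self.lam_pm < 0:
            raise InvalidInputError("constraint weights must be >= 0")
        for i in range(N_TYPES):
            for j in range(N_TYPES):
                if self.J[i][j] != self.J[j][i]:
                    raise InvalidInputError("contact-energy table J must be symmetric")


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one run."""

    L: int = 150                      # lattice side, S = L * L nodes
    total_mcs: int = 30_000
    minutes_per_mcs: float = 1.0
    n_naive: int = 30
    n_apc: int = 3
    n_memory: int = 0                 # used by the secondary-response mode
    start_day: float = 4.0            # simulation starts day 4 post-infection
    seed: int = 0
    snapshot_every: int = 120         # MCS between recorded population rows
    cell_snapshot_every: int = 1440   # MCS between per-cell molecular tables

    molecular: MolecularParams = field(default_factory=MolecularParams)
    field_params: FieldParams = field(default_factory=FieldParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    unevenness: UnevennessConfig = field(default_factory=UnevennessConfig)
    potts: PottsConfig = field(default_factory=PottsConfig)

    @property
    def S(self) -> int:
        return self.L * self.L

    @property
    def dt_hours(self) -> float:
        return self.minutes_per_mcs / 60.0

    def day_of(self, mcs: int) -> float:
        return self.start_day + mcs * self.minutes_per_mcs / 1440.0

    def validate(self) -> None:
        if self.L < 8:
            raise InvalidInputError("lattice side must be at least 8 nodes")
        for name in ("total_mcs", "n_naive", "n_apc", "n_memory"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        self.molecular.validate()
        self.thresholds.validate()
        self.unevenness.validate()
        self.potts.validate()


def full_scale_preset(seed: int = 0) -> SimulationConfig:
    """Full-scale configuration: 150x150 lattice, 30,000 one-minute MCS
    (20 days 20 h of simulated time), 30 naive CD8 T-cells and 3 APCs."""
    return SimulationConfig(seed=seed)


def scaled_preset(seed: int = 0) -> SimulationConfig:
    """Scaled-down configuration for fast end-to-end runs.

    60x60 lattice, 10 naive cells + 1 APC, 4,000 MCS at 7.5 simulated
    minutes per MCS so the run still spans ~20.8 days and contains the
    whole expansion/contraction/memory arc.
    """
    return SimulationConfig(
        L=60,
        total_mcs=4_000,
        minutes_per_mcs=7.5,
        n_naive=10,
        n_apc=1,
        seed=seed,
        snapshot_every=16,
        cell_snapshot_every=192,
    )


def secondary_preset(base: Optional[SimulationConfig] = None) -> SimulationConfig:
    """Secondary (memory) response: 30 memory cells + 3 APCs, or the
    memory-cell analogue of whatever base config is passed."""
    cfg = base if base is not None else full_scale_preset()
    return replace(cfg, n_memory=cfg.n_naive, n_naive=0)


# ---------------------------------------------------------------------------
# Config file round-trip (flat YAML with sections per component)

def to_dict(cfg: SimulationConfig) -> Dict:
    d = asdict(cfg)
    d["molecular"] = asdict(cfg.molecular)
    d["field"] = d.pop("field_params")
    d["rules"] = {**asdict(cfg.thresholds), **asdict(cfg.unevenness)}
    d.pop("thresholds")
    d.pop("unevenness")
    return d


def from_dict(d: Dict) -> SimulationConfig:
    d = dict(d)
    mol = MolecularParams(**d.pop("molecular", {}))
    fld = FieldParams(**d.pop("field", {}))
    rules = d.pop("rules", {})
    thr = Thresholds(**{k: v for k, v in rules.items() if k in Thresholds.__dataclass_fields__})
    unev = UnevennessConfig(
        **{k: v for k, v in rules.items() if k in UnevennessConfig.__dataclass_fields__}
    )
    potts = PottsConfig(**d.pop("potts", {}))
    cfg = SimulationConfig(
        molecular=mol, field_params=fld, thresholds=thr, unevenness=unev, potts=potts, **d
    )
    cfg.validate()
    return cfg


def load_config(path: str) -> SimulationConfig:
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh))


def save_config(cfg: SimulationConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=False)
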