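"""Model-data distance metrics and a simple calibration search.

Two dimensionless distances compare simulated runs with reference
time-series (in vivo subjects, or a synthetic stand-in):

* ``d_cell`` sums absolute differences of cell-type fractions
  (naive/pre-activated, activated/effector, memory) over types and time
  steps, averaged over (simulation, subject) pairs;
* ``d_prot`` does the same for normalised mean molecular levels (IL2
  receptors = R + LR, Tbet, Eomes), each series divided by its own
  maximum over the sampled time steps.

The total distance D = d_cell + d_prot drives a small coordinate-descent
search used to produce the shipped default parameter set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

CELL_GROUPS = ("naive_pre", "act_eff", "memory")
PROTEINS = ("IL2R", "Tb", "E")


@dataclass
class ReferenceSeries:
    """Per-day reference fractions and normalised molecular levels.

    ``fractions``: subject -> DataFrame indexed by day with the three
    cell-group columns; ``proteins``: subject -> DataFrame with the three
    protein columns (normalised so each column's max over days is 1).
    """

    fractions: Dict[str, pd.DataFrame]
    proteins: Dict[str, pd.DataFrame]

    @property
    def n_subjects(self) -> int:
        return len(self.fractions)

    @property
    def days(self) -> np.ndarray:
        first = next(iter(self.fractions.values()))
        return first.index.to_numpy(dtype=float)


@dataclass
class DistanceReport:
    d_cell: float
    d_prot: float

    @property
    def D(self) -> float:
        return self.d_cell + self.d_prot


def _normalise_columns(df: pd.DataFrame, warn_zero: bool = True) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        mx = out[col].max()
        if mx > 0:
            out[col] = out[col] / mx
        elif warn_zero:
            warnings.warn(f"series {col!r} is identically zero; normalisation skipped")
    return out


def simulation_series(
    population: pd.DataFrame,
    cell_snapshots: Dict[int, pd.DataFrame],
    days: Sequence[float],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Resample one run onto the reference day grid.

    Returns (fractions, raw mean protein levels) with the standard
    groupings: naive+pre-activated, activated+effector, memory; IL2
    receptors counted as R + LR.
    """
    days = np.asarray(days, dtype=float)
    pop_days = population["day"].to_numpy()
    total = (
        population[["naive", "preactivated", "activated", "effector", "memory"]]
        .sum(axis=1)
        .to_numpy()
        .astype(float)
    )
    total = np.where(total == 0, np.nan, total)
    frac = pd.DataFrame(
        {
            "naive_pre": (population["naive"] + population["preactivated"]) / total,
            "act_eff": (population["activated"] + population["effector"]) / total,
            "memory": population["memory"] / total,
        }
    )
    fr = pd.DataFrame(
        {
            c: np.interp(days, pop_days, frac[c].fillna(0.0).to_numpy())
            for c in CELL_GROUPS
        },
        index=days,
    )
    snap_days = []
    rows = []
    for mcs in sorted(cell_snapshots):
        df = cell_snapshots[mcs]
        if not len(df):
            continue
        snap_days.append(float(df["day"].iloc[0]))
        rows.append(
            {
                "IL2R": float((df["R"] + df["LR"]).mean()),
                "Tb": float(df["Tb"].mean()),
                "E": float(df["E"].mean()),
            }
        )
    raw = pd.DataFrame(rows, index=snap_days)
    prot = pd.DataFrame(
        {c: np.interp(days, raw.index.to_numpy(), raw[c].to_numpy()) for c in PROTEINS},
        index=days,
    )
    return fr, prot


def d_cell(sim_fractions: List[pd.DataFrame], reference: ReferenceSeries) -> float:
    """Mean over (simulation, subject) pairs of the summed absolute
    fraction differences over cell groups and time steps."""
    if not sim_fractions:
        raise ValueError("need at least one simulated series")
    total = 0.0
    for sim in sim_fractions:
        if list(sim.columns) != list(CELL_GROUPS):
            raise ValueError(f"expected cell groups {CELL_GROUPS}, got {tuple(sim.columns)}")
        for ref in reference.fractions.values():
            total += float(np.abs(sim.to_numpy() - ref.to_numpy()).sum())
    return total / (len(sim_fractions) * reference.n_subjects)


def d_prot(sim_proteins: List[pd.DataFrame], reference: ReferenceSeries) -> float:
    """As ``d_cell`` for the three molecular series, each normalised by
    its own maximum over the sampled time steps before differencing."""
    if not sim_proteins:
        raise ValueError("need at least one simulated series")
    total = 0.0
    for sim in sim_proteins:
        if list(sim.columns) != list(PROTEINS):
            raise ValueError(f"expected proteins {PROTEINS}, got {tuple(sim.columns)}")
        norm = _normalise_columns(sim)
        for ref in reference.proteins.values():
            ref_n = _normalise_columns(ref, warn_zero=False)
            total += float(np.abs(norm.to_numpy() - ref_n.to_numpy()).sum())
    return total / (len(sim_proteins) * reference.n_subjects)


def distance(
    sim_fractions: List[pd.DataFrame],
    sim_proteins: List[pd.DataFrame],
    reference: ReferenceSeries,
) -> DistanceReport:
    return DistanceReport(
        d_cell=d_cell(sim_fractions, reference), d_prot=d_prot(sim_proteins, reference)
    )


def make_reference_fixture(seed: int = 0, n_subjects: int = 5) -> ReferenceSeries:
    """Synthetic reference series standing in for in vivo data.

    Produces smooth per-subject curves with the canonical response
    shape: naive cells vanish by day 6, activated/effector cells exceed
    94% of the population at the day-8 peak, memory cells dominate by
    day 22; IL2 receptor levels peak day 5, Tbet plateaus over days 6-8
    then declines, Eomes rises monotonically to day 8 and beyond.
    """
    rng = np.random.default_rng(seed)
    days = np.arange(4.0, 23.0, 1.0)
    fractions = {}
    proteins = {}
    for s in range(n_subjects):
        jitter = 1.0 + 0.03 * rng.standard_normal(len(days))
        naive = np.clip(np.exp(-(days - 4.0) / 0.7), 0.0, 1.0)
        naive[days > 6.0] *= 0.02
        memory = 1.0 / (1.0 + np.exp(-(days - 15.0) / 2.0))
        act = np.clip(1.0 - naive - memory, 0.0, 1.0)
        tot = naive + act + memory
        fr = pd.DataFrame(
            {
                "naive_pre": naive / tot,
                "act_eff": act / tot * np.clip(jitter, 0.9, 1.1),
                "memory": memory / tot,
            },
            index=days,
        )
        # jitter must not push the per-day sum above 1
        sums = fr.sum(axis=1)
        fr = fr.div(np.maximum(sums, 1.0), axis=0)
        il2r = np.exp(-((days - 5.0) ** 2) / 6.0) + 0.35 / (
            1.0 + np.exp(-(days - 12.0) / 2.0)
        )
        tbet = np.where(
            days <= 6.0,
            (days - 4.0) / 2.0,
            np.where(days <= 8.0, 1.0, np.exp(-(days - 8.0) / 5.0)),
        )
        eomes = 1.0 / (1.0 + np.exp(-(days - 10.0) / 3.0))
        pr = pd.DataFrame({"IL2R": il2r, "Tb": tbet, "E": eomes}, index=days)
        pr = pr * (1.0 + 0.02 * rng.standard_normal(pr.shape))
        pr = pr.clip(lower=0.0)
        pr = _normalise_columns(pr, warn_zero=False)
        fractions[f"subject_{s}"] = fr
        proteins[f"subject_{s}"] = pr
    return ReferenceSeries(fractions=fractions, proteins=proteins)


def reference_to_csv(ref: ReferenceSeries, path: str) -> None:
    """Write a reference series in the flat CSV layout
    (day, type_or_protein, value, subject_id)."""
    rows = []
    for sid, df in ref.fractions.items():
        for day, row in df.iterrows():
            for col, val in row.items():
                rows.append((day, col, val, sid))
    for sid, df in ref.proteins.items():
        for day, row in df.iterrows():
            for col, val in row.items():
                rows.append((day, col, val, sid))
    pd.DataFrame(rows, columns=["day", "type_or_protein", "value", "subject_id"]).to_csv(
        path, index=False
    )


def reference_from_csv(path: str) -> ReferenceSeries:
    df = pd.read_csv(path)
    fractions = {}
    proteins = {}
    for sid, sub in df.groupby("subject_id"):
        piv = sub.pivot_table(index="day", columns="type_or_protein", values="value")
        fr_cols = [c for c in CELL_GROUPS if c in piv.columns]
        pr_cols = [c for c in PROTEINS if c in piv.columns]
        if fr_cols:
            fractions[str(sid)] = piv[list(CELL_GROUPS)]
        if pr_cols:
            proteins[str(sid)] = piv[list(PROTEINS)]
    return ReferenceSeries(fractions=fractions, proteins=proteins)


def local_search(
    initial: Dict[str, float],
    objective: Callable[[Dict[str, float]], float],
    budget: int,
    step_fraction: float = 0.25,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[str, float], List[float]]:
    """Coordinate-descent over a named parameter subset.

    Each move perturbs one coordinate by +-step_fraction (multiplicative)
    and keeps the best value seen.  Returns (best parameters, trace of
    best objective values — non-increasing by construction).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = rng or np.random.default_rng(0)
    best = dict(initial)
    best_val = objective(best)
    trace = [best_val]
    names = sorted(best)
    evals = 1
    i = 0
    while evals < budget:
        name = names[i % len(names)]
        i += 1
        direction = 1.0 if rng.random() < 0.5 else -1.0
        cand = dict(best)
        cand[name] = best[name] * (1.0 + direction * step_fraction)
        val = objective(cand)
        evals += 1
        if val < best_val:
            best, best_val = cand, val
        trace.append(best_val)
    return best, trace
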