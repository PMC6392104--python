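"""A scaled-down primary CD8 T-cell response, end to end.

Runs the 60x60 preset (10 naive cells + 1 APC, ~20.8 simulated days)
and prints the population arc: clonal expansion to a peak, contraction
by apoptosis, and the memory pool that survives.
"""

from cd8sim import run_primary, scaled_preset, tbet_profile
from cd8sim.params import MolecularParams

out = run_primary(scaled_preset(seed=1))
pop = out.population

print("day   naive  pre  activated  effector  memory")
for _, row in pop.iloc[:: max(1, len(pop) // 12)].iterrows():
    print(
        f"{row['day']:5.1f} {int(row['naive']):6d} {int(row['preactivated']):4d}"
        f" {int(row['activated']):9d} {int(row['effector']):9d} {int(row['memory']):7d}"
    )

s = out.summary()
print(f"\npeak: {s.peak_size} cells on day {s.peak_day:.1f} "
      f"({100 * s.activated_effector_fraction_at_peak:.0f}% activated/effector)")
print(f"contraction: {100 * s.contraction_death_fraction:.0f}% of the peak dies")
print(f"memory pool at day {s.final_day:.1f}: {s.memory_final} cells "
      f"({100 * s.efficiency_ratio:.0f}% of the peak)")

# molecular heterogeneity at the end of the run
last = max(out.cell_snapshots)
prof = tbet_profile(out.cell_snapshots[last], MolecularParams())
if "above_unstable" in prof.columns:
    print(
        f"final snapshot: {prof.attrs['n_below']} cells below the unstable Tbet "
        f"point, {prof.attrs['n_above']} above (the two antagonistic fates)"
    )
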