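"""One-at-a-time sensitivity of the biodynamic peaks.

Perturbs each model parameter by ±10% (re-projecting the constraint set
each time) and prints the five parameters whose perturbation moves the
seat-to-head transmissibility peak the most.
"""

from vibrobody import (
    default_grid,
    female_10dof_topology,
    female_reference_parameters,
    oat_sensitivity,
)

topology = female_10dof_topology()
params = female_reference_parameters()
table = oat_sensitivity(topology, params, [-0.1, 0.1], default_grid(0.5, 20, 0.05))

ranked = (
    table.assign(abs_stht=table["d_peak_stht_pct"].abs())
    .sort_values("abs_stht", ascending=False)
    .head(5)
)
print("Most influential parameters for the STHT peak (±10% perturbation):")
for _, row in ranked.iterrows():
    print(f"  {row['parameter']:>4} {row['fraction']:+.0%}: "
          f"peak magnitude {row['d_peak_stht_pct']:+.2f}%, "
          f"peak frequency shift {row['d_freq_stht_hz']:+.2f} Hz")

# Trunk-chain stiffnesses (k1-k4) and the heavy trunk masses dominate the
# head resonance; hand/forearm parameters barely move it.
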