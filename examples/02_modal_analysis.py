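"""Undamped modal analysis of the seated-female model.

Solves Kφ = ω²Mφ for the assembled 10-DOF system and prints the
natural frequencies with the head/thorax/pelvis entries of the first
two mode shapes.
"""

from vibrobody import assemble_system, female_10dof_topology, undamped_modes

topology = female_10dof_topology()
system = assemble_system(topology, topology.default_parameters())
modes = undamped_modes(system)

print("Natural frequencies (Hz):")
for i, f in enumerate(modes.natural_frequencies_hz, start=1):
    print(f"  mode {i:2d}: {f:7.2f}")

print("\nFirst two mode shapes (unit-max-abs normalized):")
for j in range(2):
    phi = modes.mode_shapes[:, j]
    print(f"  mode {j + 1}: head {phi[0]:+.3f}, thorax {phi[1]:+.3f}, "
          f"pelvis {phi[3]:+.3f}")

# The lowest mode is the whole body bouncing on the seat coupling; higher
# modes localize in the lighter arm segments.
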