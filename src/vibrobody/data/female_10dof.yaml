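# Seated-female 10-DOF lumped-parameter model (synthetic reference fixture).
#
# Masses are the published iteration-1 segment masses (printed sum 54.01 kg;
# project the parameter set through the constraint projection to enforce the
# 54 kg total exactly).  Stiffness and damping are the arithmetic midpoints
# of the constraint bounds (100-300000 N/m, 500-4000 N.s/m) -- a synthetic
# "female-like" ground truth for simulation and calibration exercises, not a
# calibrated model of any measured subject.
#
# Chain: head(1)-thorax(2)-abdomen(3)-pelvis(4)-seat; arm branches hang from
# the thorax.  Coupling 4 ("to: base") is the seat attachment.
name: female-10dof
total_mass: 54.0
segments:
  - {index: 1, name: head, mass: 6.91}
  - {index: 2, name: thorax, mass: 16.19}
  - {index: 3, name: abdomen, mass: 10.80}
  - {index: 4, name: pelvis, mass: 10.25}
  - {index: 5, name: left_upper_arm, mass: 2.87}
  - {index: 6, name: left_forearm, mass: 1.44}
  - {index: 7, name: left_hand, mass: 0.62}
  - {index: 8, name: right_upper_arm, mass: 2.87}
  - {index: 9, name: right_forearm, mass: 1.44}
  - {index: 10, name: right_hand, mass: 0.62}
couplings:
  - {id: 1, from: 1, to: 2, k: 150050.0, c: 2250.0}
  - {id: 2, from: 2, to: 3, k: 150050.0, c: 2250.0}
  - {id: 3, from: 3, to: 4, k: 150050.0, c: 2250.0}
  - {id: 4, from: 4, to: base, k: 150050.0, c: 2250.0}
  - {id: 5, from: 2, to: 5, k: 150050.0, c: 2250.0}
  - {id: 6, from: 5, to: 6, k: 150050.0, c: 2250.0}
  - {id: 7, from: 6, to: 7, k: 150050.0, c: 2250.0}
  - {id: 8, from: 2, to: 8, k: 150050.0, c: 2250.0}
  - {id: 9, from: 8, to: 9, k: 150050.0, c: 2250.0}
  - {id: 10, from: 9, to: 10, k: 150050.0, c: 2250.0}
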