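"""Published reference values for the seated-female 10-DOF model.

The mass table below reproduces published segment-mass values for a
seated adult female.  The first row sums to the stated 54 kg total body
mass; the sixth row — the one reported as best-fitting — sums to about
67.5 kg and therefore violates the 54 kg mass-sum constraint, so it is
kept here only as a labelled reference.

The stiffness and damping rows of the same tables were typeset as
undelimited digit runs; the values stored here are a best-effort parse,
cross-checked against the left/right-arm symmetry constraint and the
linear row-to-row trend.  The parsed k₄ (820 kN/m) exceeds the stated
300 kN/m stiffness bound, one more reason these rows are treated as
illustrative rather than as a usable calibrated model.

The bundled "female-like" fixture therefore combines the row-1 masses
(the row consistent with Σm = 54 kg) with mid-range stiffness and
damping — the arithmetic midpoints of the constraint bounds — and is
labelled synthetic ground truth, not a calibrated model of real data.
"""

from __future__ import annotations

import numpy as np

from .model import (
    DAMPING_BOUNDS,
    STIFFNESS_BOUNDS,
    ParameterSet,
)

__all__ = [
    "TABLE_MASSES_ITER1_KG",
    "TABLE_MASSES_ITER6_KG",
    "TABLE_STIFFNESS_ITER1_N_PER_M",
    "TABLE_DAMPING_ITER1_NS_PER_M",
    "female_reference_parameters",
]

#: Row-1 segment masses, kg: head, thorax, abdomen, pelvis, L upper arm,
#: L forearm, L hand, R upper arm, R forearm, R hand.  Sum 54.01 kg.
TABLE_MASSES_ITER1_KG = np.array(
    [6.91, 16.19, 10.80, 10.25, 2.87, 1.44, 0.62, 2.87, 1.44, 0.62]
)

#: Row-6 segment masses, kg (reported as best-fitting; sum ≈ 67.5 kg,
#: inconsistent with the 54 kg constraint — reference only).
TABLE_MASSES_ITER6_KG = np.array(
    [8.64, 20.24, 13.50, 12.81, 3.59, 1.80, 0.77, 3.59, 1.80, 0.77]
)

#: Row-1 stiffnesses, N/m — best-effort parse of an undelimited table;
#: k₄ exceeds the 300 kN/m bound.  Illustrative only.
TABLE_STIFFNESS_ITER1_N_PER_M = 1e3 * np.array(
    [210.30, 160.50, 250.00, 820.00, 260.00, 170.00, 280.00, 260.00, 170.00, 280.00]
)

#: Row-1 dampings, N·s/m — best-effort parse; c₆ = c₉ sit on the 4000 bound.
TABLE_DAMPING_ITER1_NS_PER_M = 1e2 * np.array(
    [32.10, 23.00, 26.50, 14.30, 22.00, 40.00, 25.00, 22.00, 40.00, 25.00]
)


def female_reference_parameters(constrained: bool = True) -> ParameterSet:
    """Synthetic female-like ground truth: row-1 masses, mid-bound k and c.

    This is the parameter set used as the bundled fixture and as the
    default ground truth of the synthetic-target generator.  With
    ``constrained=True`` (default) the masses are rescaled from their
    printed sum of 54.01 kg to exactly 54 kg through the constraint
    projection, so the set satisfies every constraint exactly.
    """
    from .model import encode_parameters, project_constraints

    k_mid = 0.5 * (STIFFNESS_BOUNDS[0] + STIFFNESS_BOUNDS[1])
    c_mid = 0.5 * (DAMPING_BOUNDS[0] + DAMPING_BOUNDS[1])
    params = ParameterSet(
        masses=TABLE_MASSES_ITER1_KG.copy(),
        stiffnesses=np.full(10, k_mid),
        dampings=np.full(10, c_mid),
    )
    if constrained:
        params = project_constraints(encode_parameters(params))
    return params
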