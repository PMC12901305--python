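"""Lumped-parameter seated-occupant model: topology, parameters, system matrices.

The body is idealised as rigid segment masses connected by linear
spring–damper couplings, vibrating vertically.  One coupling attaches a
single segment (the pelvis in the seated female model) to the vibrating
seat; the harmonic seat displacement enters the equations of motion only
through that coupling.

Indices follow the biomechanics convention: segments and couplings are
numbered from 1.  Assembled matrices are plain 0-based NumPy arrays; the
``base_row`` attribute of :class:`SystemMatrices` is the 0-based row of
the forced equation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SegmentSpec",
    "Coupling",
    "ModelTopology",
    "ParameterSet",
    "ParameterConstraints",
    "SystemMatrices",
    "FEMALE_TOTAL_MASS_KG",
    "female_10dof_topology",
    "female_constraints",
    "assemble_system",
    "encode_parameters",
    "decode_parameters",
    "project_constraints",
]

#: Total body mass (kg) of the seated-female model; the mass-sum constraint.
FEMALE_TOTAL_MASS_KG = 54.0

#: Stiffness bounds, N/m, applied to every coupling of a constrained set.
STIFFNESS_BOUNDS = (100.0, 300000.0)
#: Damping bounds, N·s/m.
DAMPING_BOUNDS = (500.0, 4000.0)
#: Lower clip for any single segment mass, kg.
MASS_FLOOR = 0.1


@dataclass(frozen=True)
class SegmentSpec:
    """One rigid body segment with a single vertical coordinate."""

    index: int
    name: str
    mass: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"segment {self.index} ({self.name}): mass must be > 0")


@dataclass(frozen=True)
class Coupling:
    """Spring–damper element between two segments, or a segment and the seat.

    ``to_segment is None`` marks the seat (base) attachment.
    """

    id: int
    from_segment: int
    to_segment: int | None
    stiffness: float
    damping: float

    def __post_init__(self) -> None:
        if self.to_segment is not None and self.from_segment == self.to_segment:
            raise ValueError(f"coupling {self.id}: from and to segments coincide")
        if self.stiffness <= 0:
            raise ValueError(f"coupling {self.id}: stiffness must be > 0")
        if self.damping < 0:
            raise ValueError(f"coupling {self.id}: damping must be >= 0")

    @property
    def is_base(self) -> bool:
        return self.to_segment is None


@dataclass(frozen=True)
class ModelTopology:
    """Structural blueprint of an n-DOF chain/branch model.

    Segment indices must be contiguous 1..n; exactly one coupling attaches
    a segment to the seat, and the coupling graph (including that seat
    attachment) must leave no segment free-floating.
    """

    name: str
    segments: tuple[SegmentSpec, ...]
    couplings: tuple[Coupling, ...]
    total_mass: float = FEMALE_TOTAL_MASS_KG

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "couplings", tuple(self.couplings))
        self._validate()

    def _validate(self) -> None:
        n = len(self.segments)
        indices = sorted(s.index for s in self.segments)
        if indices != list(range(1, n + 1)):
            raise ValueError(f"segment indices must be contiguous 1..{n}, got {indices}")
        base = [c for c in self.couplings if c.is_base]
        if len(base) != 1:
            ids = [c.id for c in base]
            raise ValueError(
                f"exactly one seat (base) coupling required, found {len(base)} (ids {ids})"
            )
        valid = set(indices)
        for c in self.couplings:
            for s in (c.from_segment, c.to_segment):
                if s is not None and s not in valid:
                    raise ValueError(f"coupling {c.id} references undefined segment {s}")
        # connectivity: every segment must reach the base-attached segment
        adj: dict[int, set[int]] = {i: set() for i in valid}
        for c in self.couplings:
            if not c.is_base:
                adj[c.from_segment].add(c.to_segment)
                adj[c.to_segment].add(c.from_segment)
        seen = {self.base_segment}
        stack = [self.base_segment]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if seen != valid:
            raise ValueError(f"segments {sorted(valid - seen)} are not connected to the base")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_couplings(self) -> int:
        return len(self.couplings)

    @property
    def base_segment(self) -> int:
        """Index (1-based) of the segment attached to the seat."""
        return next(c.from_segment for c in self.couplings if c.is_base)

    def segment(self, index: int) -> SegmentSpec:
        return next(s for s in self.segments if s.index == index)

    def default_parameters(self) -> "ParameterSet":
        """Masses/stiffnesses/dampings as declared on the topology itself."""
        m = np.array([self.segment(i).mass for i in range(1, self.n_segments + 1)])
        order = sorted(self.couplings, key=lambda c: c.id)
        k = np.array([c.stiffness for c in order])
        c_ = np.array([c.damping for c in order])
        return ParameterSet(m, k, c_)


@dataclass
class ParameterSet:
    """Numeric parameter vectors, ordered by segment index / coupling id."""

    masses: np.ndarray
    stiffnesses: np.ndarray
    dampings: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.stiffnesses = np.asarray(self.stiffnesses, dtype=float)
        self.dampings = np.asarray(self.dampings, dtype=float)

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.masses.copy(), self.stiffnesses.copy(), self.dampings.copy())

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())


@dataclass
class SystemMatrices:
    """Assembled M, C, K plus the seat-coupling coefficients.

    ``base_row`` is the 0-based row of the forced equation; the forcing
    vector is (base_k + jω·base_c)·Z₀ at that row.
    """

    M: np.ndarray
    C: np.ndarray
    K: np.ndarray
    base_k: float
    base_c: float
    base_row: int

    @property
    def n(self) -> int:
        return self.M.shape[0]

    @property
    def total_mass(self) -> float:
        return float(np.trace(self.M))


def female_10dof_topology(params: ParameterSet | None = None) -> ModelTopology:
    """The fixed 10-segment seated-female topology.

    Vertical chain head(1)–thorax(2)–abdomen(3)–pelvis(4)–seat through
    couplings 1–4; left arm branch thorax(2)–upper arm(5)–forearm(6)–hand(7)
    through couplings 5–7; right arm branch thorax(2)–upper arm(8)–
    forearm(9)–hand(10) through couplings 8–10.  The pelvis carries the
    seat attachment (k₄, c₄).

    By default the topology is populated with the bundled reference
    parameters (mass sum 54 kg, mid-range stiffness/damping); pass
    ``params`` to declare different values.
    """
    from . import reference

    if params is None:
        params = reference.female_reference_parameters()
    names = [
        "head", "thorax", "abdomen", "pelvis",
        "left_upper_arm", "left_forearm", "left_hand",
        "right_upper_arm", "right_forearm", "right_hand",
    ]
    segments = tuple(
        SegmentSpec(i + 1, names[i], float(params.masses[i])) for i in range(10)
    )
    links: list[tuple[int, int | None]] = [
        (1, 2), (2, 3), (3, 4), (4, None),          # trunk chain + seat
        (2, 5), (5, 6), (6, 7),                     # left arm
        (2, 8), (8, 9), (9, 10),                    # right arm
    ]
    couplings = tuple(
        Coupling(i + 1, a, b, float(params.stiffnesses[i]), float(params.dampings[i]))
        for i, (a, b) in enumerate(links)
    )
    return ModelTopology("female-10dof", segments, couplings, FEMALE_TOTAL_MASS_KG)


def assemble_system(topology: ModelTopology, params: ParameterSet) -> SystemMatrices:
    """Assemble M = diag(m), symmetric K and C from the coupling list.

    Each segment–segment coupling (i, j, k, c) contributes the standard
    2×2 stencil +k on both diagonals and −k off-diagonal (same for c).
    The seat coupling adds base_k/base_c only to the diagonal of the
    attached segment's row; the seat motion enters through the forcing
    vector, not the matrices.
    """
    n = topology.n_segments
    if len(params.masses) != n or len(params.stiffnesses) != topology.n_couplings \
            or len(params.dampings) != topology.n_couplings:
        raise ValueError(
            f"parameter lengths ({len(params.masses)} masses, "
            f"{len(params.stiffnesses)} stiffnesses, {len(params.dampings)} dampings) "
            f"do not match topology ({n} segments, {topology.n_couplings} couplings)"
        )
    if np.any(params.masses <= 0):
        raise ValueError("all masses must be strictly positive")

    M = np.diag(params.masses)
    K = np.zeros((n, n))
    C = np.zeros((n, n))
    base_k = base_c = 0.0
    base_row = -1
    order = sorted(topology.couplings, key=lambda c: c.id)
    for idx, coup in enumerate(order):
        k = params.stiffnesses[idx]
        c = params.dampings[idx]
        i = coup.from_segment - 1
        if coup.is_base:
            K[i, i] += k
            C[i, i] += c
            base_k, base_c, base_row = k, c, i
        else:
            j = coup.to_segment - 1
            K[i, i] += k
            K[j, j] += k
            K[i, j] -= k
            K[j, i] -= k
            C[i, i] += c
            C[j, j] += c
            C[i, j] -= c
            C[j, i] -= c
    return SystemMatrices(M=M, C=C, K=K, base_k=base_k, base_c=base_c, base_row=base_row)


# ---------------------------------------------------------------------------
# Parameter vector encoding and constraint projection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterConstraints:
    """Equality/sum/bound constraints attached to a parameter set.

    ``mass_pairs`` / ``coupling_pairs`` hold 1-based (left, right) index
    pairs forced equal by sagittal symmetry.  Bounds are applied to every
    coupling; single masses are clipped to [mass_floor, total_mass] before
    the multiplicative rescale that enforces the mass sum.
    """

    total_mass: float = FEMALE_TOTAL_MASS_KG
    mass_pairs: tuple[tuple[int, int], ...] = ((5, 8), (6, 9), (7, 10))
    coupling_pairs: tuple[tuple[int, int], ...] = ((5, 8), (6, 9), (7, 10))
    k_bounds: tuple[float, float] = STIFFNESS_BOUNDS
    c_bounds: tuple[float, float] = DAMPING_BOUNDS
    mass_floor: float = MASS_FLOOR

    def satisfied_by(self, p: ParameterSet, rtol: float = 1e-9) -> bool:
        ok = abs(p.masses.sum() - self.total_mass) <= rtol * self.total_mass
        for a, b in self.mass_pairs:
            ok &= p.masses[a - 1] == p.masses[b - 1]
        for a, b in self.coupling_pairs:
            ok &= p.stiffnesses[a - 1] == p.stiffnesses[b - 1]
            ok &= p.dampings[a - 1] == p.dampings[b - 1]
        ok &= bool(np.all(p.stiffnesses >= self.k_bounds[0]) and np.all(p.stiffnesses <= self.k_bounds[1]))
        ok &= bool(np.all(p.dampings >= self.c_bounds[0]) and np.all(p.dampings <= self.c_bounds[1]))
        return bool(ok)


def female_constraints() -> ParameterConstraints:
    """Constraint set of the seated-female model: Σm = 54 kg, left/right
    arm symmetry in m, k, c, and the stiffness/damping bounds."""
    return ParameterConstraints()


def encode_parameters(params: ParameterSet) -> np.ndarray:
    """Flatten to the optimisation vector (m₁..mₙ, k₁..k_nc, c₁..c_nc)."""
    return np.concatenate([params.masses, params.stiffnesses, params.dampings])


def decode_parameters(vector: np.ndarray, n_segments: int, n_couplings: int) -> ParameterSet:
    """Inverse of :func:`encode_parameters`."""
    vector = np.asarray(vector, dtype=float)
    expected = n_segments + 2 * n_couplings
    if vector.shape != (expected,):
        raise ValueError(f"expected vector of length {expected}, got shape {vector.shape}")
    return ParameterSet(
        vector[:n_segments],
        vector[n_segments:n_segments + n_couplings],
        vector[n_segments + n_couplings:],
    )


def project_constraints(
    vector: np.ndarray,
    total_mass: float | None = None,
    constraints: ParameterConstraints | None = None,
    n_segments: int = 10,
    n_couplings: int = 10,
) -> ParameterSet:
    """Project a flat parameter vector onto the feasible set.

    Order: (a) replace each symmetric left/right pair by its mean,
    (b) clip stiffness/damping/mass to bounds, (c) rescale masses
    multiplicatively so their sum is exact.  Steps (b)–(c) iterate to a
    fixed point so the result is idempotent even when rescaling pushes a
    clipped mass back out of bounds; the rescale always runs last, so the
    mass-sum constraint holds exactly on output.
    """
    vector = np.asarray(vector, dtype=float)
    if not np.all(np.isfinite(vector)):
        raise ValueError("parameter vector contains non-finite entries")
    if constraints is None:
        constraints = ParameterConstraints()
    if total_mass is not None:
        constraints = replace(constraints, total_mass=total_mass)
    p = decode_parameters(vector, n_segments, n_couplings)

    for a, b in constraints.mass_pairs:
        mean = 0.5 * (p.masses[a - 1] + p.masses[b - 1])
        p.masses[a - 1] = p.masses[b - 1] = mean
    for a, b in constraints.coupling_pairs:
        km = 0.5 * (p.stiffnesses[a - 1] + p.stiffnesses[b - 1])
        p.stiffnesses[a - 1] = p.stiffnesses[b - 1] = km
        cm = 0.5 * (p.dampings[a - 1] + p.dampings[b - 1])
        p.dampings[a - 1] = p.dampings[b - 1] = cm

    np.clip(p.stiffnesses, *constraints.k_bounds, out=p.stiffnesses)
    np.clip(p.dampings, *constraints.c_bounds, out=p.dampings)

    tm = constraints.total_mass
    m = np.clip(p.masses, constraints.mass_floor, tm)
    for _ in range(100):
        m = m * (tm / m.sum())
        if m.min() >= constraints.mass_floor:
            break
        m = np.clip(m, constraints.mass_floor, tm)
    p.masses = m * (tm / m.sum())
    return p
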