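"""Constrained firefly-algorithm calibration of model parameters.

The calibration minimizes the weighted sum of squared magnitude errors
between target and model biodynamic curves over the frequency grid,

    F = Σ_f [ λ₁(|STHT_e|−|STHT_p|)² + λ₂(|DPMI_e|−|DPMI_p|)²
              + λ₃(|AM_e|−|AM_p|)² ],

subject to the mass-sum, left/right-symmetry and bound constraints,
which are enforced by projection after every move so that every
candidate ever evaluated is feasible.

The optimizer is the canonical firefly algorithm: candidate vectors live
in the unit hypercube spanned by the parameter bounds; a dimmer firefly
i moves toward every brighter j as

    x_i ← x_i + β₀ e^{−γ r²} (x_j − x_i) + α u,   u ~ U(−0.5, 0.5)^d,

with r the Euclidean distance in scaled space; the current best performs
a pure α random walk.  The best-so-far vector is tracked separately, so
the reported objective history is non-increasing.

Because DPMI magnitudes (hundreds to thousands N·s/m) dwarf STHT (order
one), the literal objective effectively prioritizes DPMI.  Setting
``normalize=True`` on :class:`ObjectiveSpec` divides each residual by the
mean of its target curve, balancing the three responses; the default is
the literal unnormalized form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gof import EQUAL_WEIGHTS, GofReport, gof_report
from .model import (
    ModelTopology,
    ParameterConstraints,
    ParameterSet,
    assemble_system,
    encode_parameters,
    project_constraints,
)
from .response import BiodynamicCurves, FrequencyGrid, biodynamic_curves

__all__ = [
    "TargetCurves",
    "ObjectiveSpec",
    "FAConfig",
    "CalibrationResult",
    "objective_value",
    "firefly_move",
    "calibrate",
]


@dataclass(frozen=True)
class TargetCurves:
    """Magnitude target curves on a frequency grid (the quantity fitted)."""

    grid: FrequencyGrid
    stht_mag: np.ndarray
    dpmi_mag: np.ndarray
    am_mag: np.ndarray

    def __post_init__(self) -> None:
        for name in ("stht_mag", "dpmi_mag", "am_mag"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (len(self.grid),):
                raise ValueError(f"{name} length does not match the grid")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_curves(cls, curves: BiodynamicCurves) -> "TargetCurves":
        return cls(curves.grid, curves.stht_mag, curves.dpmi_mag, curves.am_mag)


@dataclass(frozen=True)
class ObjectiveSpec:
    """Weighted squared-error objective against a set of target curves."""

    targets: TargetCurves
    weights: tuple[float, float, float] = EQUAL_WEIGHTS
    normalize: bool = False
    driving_point: str = "seat"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0):
            raise ValueError("weights must be three non-negative values")
        object.__setattr__(self, "weights", tuple(w / w.sum()))


@dataclass(frozen=True)
class FAConfig:
    """Firefly-algorithm settings (defaults are the standard configuration
    used for this model class: swarm 100, 50 iterations, γ=0.8, α=0.2)."""

    swarm_size: int = 100
    iterations: int = 50
    tolerance: float = 1e-4
    patience: int = 5        # consecutive sub-tolerance iterations before stopping
    alpha: float = 0.2       # randomization ("mutation") coefficient
    gamma: float = 0.8       # light absorption coefficient
    beta0: float = 1.0       # attractiveness at zero distance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass
class CalibrationResult:
    """Reproducibility record of one calibration run."""

    best_params: ParameterSet
    best_objective: float
    history: np.ndarray          # per-iteration best-so-far objective
    evaluations: int
    seed: int
    gof_report: GofReport

    def as_dict(self) -> dict:
        return {
            "best_objective": self.best_objective,
            "history": self.history.tolist(),
            "evaluations": self.evaluations,
            "seed": self.seed,
            "gof": self.gof_report.as_dict(),
            "best_params": {
                "masses": self.best_params.masses.tolist(),
                "stiffnesses": self.best_params.stiffnesses.tolist(),
                "dampings": self.best_params.dampings.tolist(),
            },
        }


def model_curves(
    params: ParameterSet,
    topology: ModelTopology,
    grid: FrequencyGrid,
    driving_point: str = "seat",
) -> BiodynamicCurves:
    """Forward model: parameters → biodynamic curves on a grid."""
    return biodynamic_curves(
        assemble_system(topology, params), grid, driving_point=driving_point
    )


def objective_value(
    params: ParameterSet, spec: ObjectiveSpec, topology: ModelTopology
) -> float:
    """Weighted sum of squared magnitude errors over the target grid."""
    curves = model_curves(params, topology, spec.targets.grid, spec.driving_point)
    l1, l2, l3 = spec.weights
    t = spec.targets
    r1 = t.stht_mag - curves.stht_mag
    r2 = t.dpmi_mag - curves.dpmi_mag
    r3 = t.am_mag - curves.am_mag
    if spec.normalize:
        r1 = r1 / np.mean(t.stht_mag)
        r2 = r2 / np.mean(t.dpmi_mag)
        r3 = r3 / np.mean(t.am_mag)
    return float(l1 * np.sum(r1**2) + l2 * np.sum(r2**2) + l3 * np.sum(r3**2))


# ---------------------------------------------------------------------------
# Firefly algorithm
# ---------------------------------------------------------------------------

def _bounds(topology: ModelTopology, constraints: ParameterConstraints):
    n, nc = topology.n_segments, topology.n_couplings
    lb = np.concatenate([
        np.full(n, constraints.mass_floor),
        np.full(nc, constraints.k_bounds[0]),
        np.full(nc, constraints.c_bounds[0]),
    ])
    ub = np.concatenate([
        np.full(n, constraints.total_mass),
        np.full(nc, constraints.k_bounds[1]),
        np.full(nc, constraints.c_bounds[1]),
    ])
    return lb, ub


def firefly_move(
    position_i: np.ndarray,
    position_j: np.ndarray,
    brightness_i: float,
    brightness_j: float,
    config: FAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One firefly update in unit-scaled space.

    ``brightness`` is the objective value (lower = brighter).  If j is
    brighter than i, i is attracted toward j with strength
    β₀e^{−γr²} plus the α random walk; otherwise i only random-walks
    (the rule applied to the current best).
    """
    xi = np.asarray(position_i, dtype=float)
    xj = np.asarray(position_j, dtype=float)
    step = config.alpha * rng.uniform(-0.5, 0.5, size=xi.shape)
    if brightness_j < brightness_i:
        r2 = float(np.sum((xj - xi) ** 2))
        beta = config.beta0 * np.exp(-config.gamma * r2)
        return xi + beta * (xj - xi) + step
    return xi + step


def calibrate(
    spec: ObjectiveSpec,
    topology: ModelTopology,
    config: FAConfig,
    constraints: ParameterConstraints | None = None,
    log=None,
) -> CalibrationResult:
    """Run the constrained firefly algorithm against target curves.

    The swarm initializes uniformly over the bound box (seeded), every
    candidate is projected through the constraint set before evaluation,
    and iteration stops at the iteration budget or once the best
    objective has improved by less than ``tolerance`` for ``patience``
    consecutive full sweeps.  A single stagnant sweep is routine for a
    best-so-far stochastic search, so the tolerance alone is not treated
    as convergence.  ``log``, if given, is called once per iteration
    with (iteration, best_objective, improvement).
    """
    if constraints is None:
        constraints = ParameterConstraints(total_mass=topology.total_mass)
    lb, ub = _bounds(topology, constraints)
    if np.any(ub <= lb):
        raise ValueError("infeasible bounds: empty box")
    span = ub - lb
    n, nc = topology.n_segments, topology.n_couplings
    rng = np.random.default_rng(config.seed)

    def project_unit(x: np.ndarray) -> tuple[np.ndarray, ParameterSet]:
        """Clip to the unit box, project constraints, return both spaces."""
        x = np.clip(x, 0.0, 1.0)
        p = project_constraints(lb + span * x, constraints.total_mass, constraints, n, nc)
        return (encode_parameters(p) - lb) / span, p

    X = rng.uniform(0.0, 1.0, size=(config.swarm_size, lb.size))
    P: list[ParameterSet] = []
    F = np.empty(config.swarm_size)
    for i in range(config.swarm_size):
        X[i], p = project_unit(X[i])
        P.append(p)
        F[i] = objective_value(p, spec, topology)
    evaluations = config.swarm_size

    best = int(np.argmin(F))
    best_f = float(F[best])
    best_p = P[best].copy()
    history = []
    stagnant = 0

    for it in range(config.iterations):
        prev_best = best_f
        for i in range(config.swarm_size):
            xi = X[i]
            moved = False
            for j in range(config.swarm_size):
                if F[j] < F[i]:
                    xi = firefly_move(xi, X[j], F[i], F[j], config, rng)
                    moved = True
            if not moved:  # current best random-walks
                xi = firefly_move(xi, xi, 0.0, 1.0, config, rng)
            X[i], P[i] = project_unit(xi)
            F[i] = objective_value(P[i], spec, topology)
            evaluations += 1
            if F[i] < best_f:
                best_f = float(F[i])
                best_p = P[i].copy()
        history.append(best_f)
        improvement = prev_best - best_f
        if log is not None:
            log(it + 1, best_f, improvement)
        stagnant = stagnant + 1 if improvement < config.tolerance else 0
        if stagnant >= config.patience:
            break

    curves = model_curves(best_p, topology, spec.targets.grid, spec.driving_point)
    report = gof_report(curves, spec.targets, spec.weights)
    return CalibrationResult(
        best_params=best_p,
        best_objective=best_f,
        history=np.asarray(history),
        evaluations=evaluations,
        seed=config.seed,
        gof_report=report,
    )
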