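"""Goodness-of-fit statistics for biodynamic magnitude curves.

The fit statistic for one response curve is

    ε = 1 − √( Σ(τe − τp)² / (N − 2) ) / ( Στe / N ),

i.e. one minus the ratio of a (N−2)-denominator RMS residual to the mean
of the target curve.  ε = 1 for identical curves and can go negative for
very poor fits; it is deliberately not clipped.  Per-response values are
combined by a convex weighting ε̄ = λ₁ε_STHT + λ₂ε_DPMI + λ₃ε_AM, equal
weights by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EQUAL_WEIGHTS",
    "GofReport",
    "goodness_of_fit",
    "weighted_gof",
    "weighted_gof_max",
    "gof_report",
]

EQUAL_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)


def goodness_of_fit(tau_e: np.ndarray, tau_p: np.ndarray) -> float:
    """ε for one pair of magnitude curves (target ``tau_e``, model ``tau_p``)."""
    tau_e = np.asarray(tau_e, dtype=float)
    tau_p = np.asarray(tau_p, dtype=float)
    if tau_e.shape != tau_p.shape:
        raise ValueError(f"curve length mismatch: {tau_e.shape} vs {tau_p.shape}")
    n = tau_e.size
    if n <= 2:
        raise ValueError("goodness of fit needs more than 2 points (N-2 denominator)")
    mean = tau_e.sum() / n
    if mean <= 0:
        raise ValueError("target curve mean must be positive")
    rms = np.sqrt(np.sum(np.square(tau_e - tau_p)) / (n - 2))
    return float(1.0 - rms / mean)


def _check_weights(weights: Sequence[float]) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be three non-negative values summing to 1")
    return w


def weighted_gof(eps: Sequence[float], weights: Sequence[float] = EQUAL_WEIGHTS) -> float:
    """Convex combination ε̄ of the (ε_STHT, ε_DPMI, ε_AM) triplet."""
    w = _check_weights(weights)
    eps = np.asarray(eps, dtype=float)
    if eps.shape != (3,):
        raise ValueError("expected a triplet of per-response fit values")
    return float(w @ eps)


def weighted_gof_max(
    eps_collection: Iterable[Sequence[float]],
    weights: Sequence[float] = EQUAL_WEIGHTS,
) -> float:
    """Best weighted fit over a collection of ε triplets (e.g. candidate models)."""
    values = [weighted_gof(e, weights) for e in eps_collection]
    if not values:
        raise ValueError("empty collection")
    return max(values)


@dataclass(frozen=True)
class GofReport:
    """Per-response and combined fit of one model against one target set.

    Values are stored on the 0–1 scale; multiply by 100 for display as
    percentages.  ``variance`` is the sample variance (N−1 denominator)
    of the three per-response ε values.
    """

    eps_stht: float
    eps_dpmi: float
    eps_am: float
    eps_weighted: float
    variance: float
    n_points: int

    def as_dict(self) -> dict[str, float]:
        return {
            "eps_stht": self.eps_stht,
            "eps_dpmi": self.eps_dpmi,
            "eps_am": self.eps_am,
            "eps_weighted": self.eps_weighted,
            "variance": self.variance,
            "n_points": self.n_points,
        }


def gof_report(model_curves, targets, weights: Sequence[float] = EQUAL_WEIGHTS) -> GofReport:
    """Score model :class:`~vibrobody.response.BiodynamicCurves` against targets.

    ``targets`` needs ``grid``, ``stht_mag``, ``dpmi_mag`` and ``am_mag``
    attributes (see :class:`~vibrobody.calibration.TargetCurves`); grids
    must match exactly.
    """
    if not np.array_equal(
        model_curves.grid.frequencies_hz, targets.grid.frequencies_hz
    ):
        raise ValueError("model and target frequency grids differ")
    eps = np.array(
        [
            goodness_of_fit(targets.stht_mag, model_curves.stht_mag),
            goodness_of_fit(targets.dpmi_mag, model_curves.dpmi_mag),
            goodness_of_fit(targets.am_mag, model_curves.am_mag),
        ]
    )
    return GofReport(
        eps_stht=float(eps[0]),
        eps_dpmi=float(eps[1]),
        eps_am=float(eps[2]),
        eps_weighted=weighted_gof(eps, weights),
        variance=float(np.var(eps, ddof=1)),
        n_points=len(targets.grid),
    )
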