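"""Harmonic base-excitation response and biodynamic transfer functions.

The seat imposes a harmonic displacement z₀(t) = Z₀e^{jωt}; in the
frequency domain the steady state solves

    (−ω²M + jωC + K) Z = b,   b[base_row] = (base_k + jω·base_c) Z₀,

with Z₀ = 1 throughout (transfer functions are invariant to Z₀).
Three standard biodynamic responses are derived from Z:

* STHT — seat-to-head transmissibility, Z₁/Z₀ (dimensionless);
* AM — apparent mass, transmitted seat force per unit seat
  acceleration (kg), with phase convention AM(f→0) → +Σm;
* DPMI — driving-point mechanical impedance, jω·AM (N·s/m), so the
  identity |DPMI| = 2πf·|AM| holds exactly at every frequency.

The driving-point denominator defaults to the seat motion Z₀, which
yields the textbook static limit AM(0) = supported mass.  Passing
``driving_point="pelvis"`` divides by the pelvis motion instead — an
alternative literal reading of "velocity/acceleration at the driving
location" found in parts of the literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SystemMatrices

__all__ = [
    "FrequencyGrid",
    "BiodynamicCurves",
    "PeakSummary",
    "default_grid",
    "steady_state_response",
    "frequency_sweep",
    "biodynamic_curves",
    "peak_summary",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing positive frequencies, Hz."""

    frequencies_hz: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        object.__setattr__(self, "frequencies_hz", f)
        if f.ndim != 1 or f.size < 3:
            raise ValueError("frequency grid needs at least 3 points")
        if np.any(f <= 0):
            raise ValueError("all frequencies must be > 0")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies, rad/s."""
        return TWO_PI * self.frequencies_hz

    def __len__(self) -> int:
        return self.frequencies_hz.size


def default_grid(fmin: float = 0.5, fmax: float = 20.0, df: float = 0.1) -> FrequencyGrid:
    """Uniform grid over the whole-body-vibration band 0.5–20 Hz (196 points)."""
    n = int(round((fmax - fmin) / df)) + 1
    return FrequencyGrid(fmin + df * np.arange(n))


@dataclass(frozen=True)
class BiodynamicCurves:
    """Complex STHT, DPMI and AM sampled on a frequency grid."""

    grid: FrequencyGrid
    stht: np.ndarray   # dimensionless
    dpmi: np.ndarray   # N·s/m
    am: np.ndarray     # kg

    @property
    def stht_mag(self) -> np.ndarray:
        return np.abs(self.stht)

    @property
    def dpmi_mag(self) -> np.ndarray:
        return np.abs(self.dpmi)

    @property
    def am_mag(self) -> np.ndarray:
        return np.abs(self.am)

    def magnitudes(self) -> dict[str, np.ndarray]:
        return {"stht": self.stht_mag, "dpmi": self.dpmi_mag, "am": self.am_mag}


def _system_matrix(sys: SystemMatrices, omega: np.ndarray) -> np.ndarray:
    """Stack A(ω) = −ω²M + jωC + K for each ω, shape (n_ω, n, n)."""
    w = np.atleast_1d(np.asarray(omega, dtype=float))
    return (
        -np.square(w)[:, None, None] * sys.M
        + 1j * w[:, None, None] * sys.C
        + sys.K
    )


def steady_state_response(sys: SystemMatrices, omega: float) -> np.ndarray:
    """Complex displacement vector Z (per unit seat displacement) at one ω."""
    return frequency_sweep(sys, np.array([float(omega)]))[0]


def frequency_sweep(sys: SystemMatrices, omega: np.ndarray) -> np.ndarray:
    """Solve the harmonic steady state for a vector of angular frequencies.

    Returns shape (n_ω, n).  Raises on a singular system matrix, which for a
    physical model occurs only at ω = 0 with no seat stiffness.
    """
    w = np.atleast_1d(np.asarray(omega, dtype=float))
    A = _system_matrix(sys, w)
    b = np.zeros((w.size, sys.n), dtype=complex)
    b[:, sys.base_row] = sys.base_k + 1j * w * sys.base_c
    try:
        return np.linalg.solve(A, b[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular system matrix in frequency sweep: {exc}"
        ) from exc


def biodynamic_curves(
    sys: SystemMatrices,
    grid: FrequencyGrid,
    head_segment: int = 1,
    driving_point: str = "seat",
) -> BiodynamicCurves:
    """Compute STHT, DPMI and AM over a frequency grid.

    The transmitted seat force is F = (base_k + jω·base_c)(Z₀ − Z_b) with
    Z₀ = 1 and Z_b the motion of the seat-attached segment.  AM is F per
    unit driving-point acceleration −ω²D and DPMI = jω·AM, where the
    denominator motion D is Z₀ (default) or the pelvis motion Z_b
    (``driving_point="pelvis"``).
    """
    if driving_point not in ("seat", "pelvis"):
        raise ValueError(f"driving_point must be 'seat' or 'pelvis', got {driving_point!r}")
    w = grid.omega
    Z = frequency_sweep(sys, w)
    stht = Z[:, head_segment - 1]
    zb = Z[:, sys.base_row]
    force = (sys.base_k + 1j * w * sys.base_c) * (1.0 - zb)
    denom = np.ones_like(zb) if driving_point == "seat" else zb
    # seat acceleration is −ω²·D, so AM = F/(−ω²D); then DPMI = jω·AM
    # coincides with the textbook F/(jωD) and AM(f→0) → +Σm.
    am = -force / (np.square(w) * denom)
    dpmi = 1j * w * am
    return BiodynamicCurves(grid=grid, stht=stht, dpmi=dpmi, am=am)


@dataclass(frozen=True)
class PeakSummary:
    """Peak magnitude and its frequency for each biodynamic response."""

    stht_peak: float
    stht_peak_hz: float
    dpmi_peak: float
    dpmi_peak_hz: float
    am_peak: float
    am_peak_hz: float

    def as_dict(self) -> dict[str, float]:
        return {
            "stht_peak": self.stht_peak,
            "stht_peak_hz": self.stht_peak_hz,
            "dpmi_peak": self.dpmi_peak,
            "dpmi_peak_hz": self.dpmi_peak_hz,
            "am_peak": self.am_peak,
            "am_peak_hz": self.am_peak_hz,
        }


def peak_summary(curves: BiodynamicCurves) -> PeakSummary:
    """Argmax of each magnitude curve; ties resolve to the lower frequency."""
    f = curves.grid.frequencies_hz
    out = {}
    for name, mag in curves.magnitudes().items():
        i = int(np.argmax(mag))  # argmax returns the first (lowest-f) maximum
        out[f"{name}_peak"] = float(mag[i])
        out[f"{name}_peak_hz"] = float(f[i])
    return PeakSummary(**out)
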