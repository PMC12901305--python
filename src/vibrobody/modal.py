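"""Undamped modal analysis of an assembled system.

Solves the generalized symmetric eigenproblem Kφ = ω²Mφ and reports
natural frequencies f = ω/2π in Hz with mass-orthogonal mode shapes.
Each mode-shape column is normalized to unit maximum absolute entry with
positive sign at its largest-magnitude component, so shapes are
comparable across runs up to that fixed scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .model import SystemMatrices
from .response import TWO_PI

__all__ = ["ModalResult", "undamped_modes"]


@dataclass(frozen=True)
class ModalResult:
    """Natural frequencies (Hz, ascending) and mode-shape columns."""

    natural_frequencies_hz: np.ndarray
    mode_shapes: np.ndarray  # column j = eigenvector of mode j

    @property
    def n_modes(self) -> int:
        return self.natural_frequencies_hz.size


def undamped_modes(sys: SystemMatrices, zero_tol: float = 1e-9) -> ModalResult:
    """Natural frequencies and mode shapes of the undamped system.

    An ungrounded model (no seat stiffness) has one rigid-body mode;
    eigenvalues within ``zero_tol`` of zero (relative to the largest)
    are reported as exactly 0 Hz.
    """
    if not np.array_equal(sys.K, sys.K.T) or not np.array_equal(sys.M, sys.M.T):
        raise ValueError("modal analysis requires symmetric K and M")
    lam, phi = scipy.linalg.eigh(sys.K, sys.M)
    lam[np.abs(lam) <= zero_tol * np.max(np.abs(lam))] = 0.0
    if np.any(lam < 0):
        raise ValueError("stiffness matrix is indefinite: negative eigenvalue found")
    freqs = np.sqrt(lam) / TWO_PI
    # unit-max-abs normalization, positive sign at the dominant component
    for j in range(phi.shape[1]):
        i = int(np.argmax(np.abs(phi[:, j])))
        phi[:, j] /= phi[i, j]
    return ModalResult(natural_frequencies_hz=freqs, mode_shapes=phi)
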