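"""Convergence and quality diagnostics for phase-retrieval runs.

The convergence indicator is the root mean squared error between an
iteration's phase estimate and the phase of the final iteration,

    RMSE_k = sqrt( mean( (y_k - y_final)^2 ) ),

reported alongside its base-10 logarithm.  A second, ground-truth mode
compares an estimate against a known phantom phase.  Localisation of
strongly phase-shifting objects uses a phase-energy surface: the magnitude
of the phase plotted as a height field over the image plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ShapeError, UndefinedCorrelationError

__all__ = [
    "IterationTrace",
    "rmse",
    "trace_rmse",
    "log_rmse",
    "phase_energy_map",
    "phase_energy_peak",
    "correlation_coefficient",
    "phase_rmse_to_truth",
]


@dataclass
class IterationTrace:
    """Per-iteration diagnostics of a GS run.

    Iteration indices are 1-based and implicit in the array order.  ``rmse``
    is the self-referential convergence measure (phase of iteration ``k``
    against the final phase, so the last entry is 0); ``fourier_rmse`` the
    imaging-plane amplitude mismatch; ``correlation`` the round-trip field
    correlation watched by the early-stopping rule.  ``phase_convention``
    records the scale the phase differences were taken in ("unit" for mapped
    [0, 1] runs, "principal" for raw radians).
    """

    rmse: np.ndarray
    log10_rmse: np.ndarray
    correlation: Optional[np.ndarray] = None
    fourier_rmse: Optional[np.ndarray] = None
    phase_convention: str = "principal"
    rmse_truth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.rmse = np.asarray(self.rmse, dtype=float)
        self.log10_rmse = np.asarray(self.log10_rmse, dtype=float)
        if self.rmse.ndim != 1 or self.rmse.shape != self.log10_rmse.shape:
            raise ShapeError("rmse and log10_rmse must be equal-length 1-D arrays")
        if (self.rmse < 0).any():
            raise InvalidInputError("rmse entries must be non-negative")

    def __len__(self) -> int:
        return self.rmse.size

    @property
    def iteration(self) -> np.ndarray:
        return np.arange(1, len(self) + 1)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with columns (iteration, rmse, log10_rmse, correlation, ...)."""
        data = {
            "iteration": self.iteration,
            "rmse": self.rmse,
            "log10_rmse": self.log10_rmse,
        }
        if self.correlation is not None:
            data["correlation"] = np.asarray(self.correlation, dtype=float)
        if self.fourier_rmse is not None:
            data["fourier_rmse"] = np.asarray(self.fourier_rmse, dtype=float)
        if self.rmse_truth is not None:
            data["rmse_truth"] = np.asarray(self.rmse_truth, dtype=float)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def rmse(values: np.ndarray, reference: np.ndarray) -> float:
    """Root mean squared error between two same-shape arrays."""
    values = np.asarray(values, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if values.shape != reference.shape:
        raise ShapeError(f"shape mismatch: {values.shape} vs {reference.shape}")
    if values.size == 0:
        raise InvalidInputError("rmse of empty arrays is undefined")
    diff = values.ravel() - reference.ravel()
    return float(np.sqrt(np.mean(diff * diff)))


def trace_rmse(snapshots: Sequence[np.ndarray]) -> np.ndarray:
    """RMSE of each phase snapshot against the final snapshot.

    The last entry is exactly 0 by construction (self-comparison).
    """
    if len(snapshots) == 0:
        raise InvalidInputError("trace must contain at least one snapshot")
    final = np.asarray(snapshots[-1], dtype=float)
    out = np.array([rmse(s, final) for s in snapshots])
    out[-1] = 0.0
    return out


def log_rmse(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Base-10 logarithm of RMSE values; 0 maps to the -inf sentinel.

    Negative inputs are invalid (an RMSE is non-negative by definition).
    """
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise InvalidInputError("RMSE values must be non-negative")
    with np.errstate(divide="ignore"):
        return np.log10(values)


def phase_energy_map(phase: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Surface-ready (col index, row index, height) grids for a phase array.

    Height at each pixel is the phase magnitude ``|phase|``; the surface peak
    therefore sits at the arg-max pixel of ``|phase|``.  The returned grids
    plug straight into ``Axes3D.plot_surface(x, y, z)``.
    """
    phase = np.asarray(phase, dtype=float)
    if phase.ndim != 2:
        raise ShapeError(f"phase must be 2-D, got shape {phase.shape}")
    ny, nx = phase.shape
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny))
    return xx, yy, np.abs(phase)


def phase_energy_peak(phase: np.ndarray) -> tuple[int, int]:
    """(row, col) of the phase-energy surface peak (arg-max of ``|phase|``)."""
    _, _, zz = phase_energy_map(phase)
    return tuple(int(i) for i in np.unravel_index(np.argmax(zz), zz.shape))


def correlation_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Modulus of the normalised correlation |<a, b>| / (||a|| * ||b||).

    Works for real or complex arrays; invariant to a global complex scale of
    either argument; lies in [0, 1] by Cauchy-Schwarz.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ShapeError(f"shape mismatch: {a.shape} vs {b.shape}")
    ea = float(np.vdot(a, a).real)
    eb = float(np.vdot(b, b).real)
    if ea == 0.0 or eb == 0.0:
        raise UndefinedCorrelationError("correlation against a zero-energy field is undefined")
    # ratio-of-energies form so self-correlation is exactly 1.0 in floating point
    return float(np.sqrt(min(1.0, abs(np.vdot(a, b)) ** 2 / (ea * eb))))


def phase_rmse_to_truth(
    estimate: np.ndarray,
    truth_radians: np.ndarray,
    estimate_convention: str = "principal",
) -> float:
    """RMSE between a phase estimate and a ground-truth phase, on the unit scale.

    Both arrays are compared in the mapped [0, 1] convention so estimates
    from mapped and unmapped runs are on one common scale: principal-value
    radians are wrapped to [-pi, pi) and affinely mapped to [0, 1] first.
    """
    from .phase_retrieval import map_phase, wrap_phase

    estimate = np.asarray(estimate, dtype=float)
    if estimate_convention == "principal":
        estimate = map_phase(wrap_phase(estimate), (-np.pi, np.pi), (0.0, 1.0))
    elif estimate_convention != "unit":
        raise InvalidInputError(f"unknown convention {estimate_convention!r}")
    truth = map_phase(wrap_phase(np.asarray(truth_radians, dtype=float)), (-np.pi, np.pi), (0.0, 1.0))
    return rmse(estimate, truth)
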