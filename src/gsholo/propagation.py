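"""Angular-spectrum propagation of sampled complex optical fields.

A monochromatic scalar field ``U(x, y, 0)`` sampled on a regular grid is
propagated to a parallel plane at distance ``z`` by filtering its spatial
spectrum with the free-space transfer function derived from the Helmholtz
equation,

    H(f_x, f_y) = exp( j 2*pi (z/lambda) sqrt(1 - (lambda f_x)^2 - (lambda f_y)^2) ),

so that ``U(x, y, z) = IFFT{ H * FFT{U(x, y, 0)} }``.  Spectral components
with ``(lambda f)^2 > 1`` are evanescent: they decay exponentially and carry
no far-field energy.  This implementation zeroes them (hard cutoff), which
keeps back-propagation (negative ``z``) bounded and makes the kernel exactly
unitary on the propagating support.

Transforms use the unitary (``norm="ortho"``) convention throughout so that
Parseval's theorem holds without extra bookkeeping.  Frequencies follow the
standard DFT layout of :func:`numpy.fft.fftfreq`, which is exactly the
ordering produced by :func:`numpy.fft.fft2`; axis 0 is the row (y) axis and
axis 1 the column (x) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidGeometryError

__all__ = [
    "ComplexField",
    "PropagationGeometry",
    "spatial_frequency_grid",
    "transfer_function",
    "propagate",
]


@dataclass
class ComplexField:
    """A sampled 2-D complex optical amplitude with physical metadata.

    Parameters
    ----------
    values
        2-D complex array; modulus is the (dimensionless) amplitude, argument
        the phase in radians.
    pixel_pitch
        Physical sample spacing in metres, identical on both axes.
    wavelength
        Vacuum wavelength in metres.
    """

    values: np.ndarray
    pixel_pitch: float
    wavelength: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise InvalidGeometryError(
                f"field grid must be 2-D with both dims >= 2, got shape {self.values.shape}"
            )
        if not (self.pixel_pitch > 0):
            raise InvalidGeometryError(f"pixel_pitch must be > 0, got {self.pixel_pitch}")
        if not (self.wavelength > 0):
            raise InvalidGeometryError(f"wavelength must be > 0, got {self.wavelength}")
        if not np.all(np.isfinite(self.values.view(float))):
            raise InvalidGeometryError("field values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        """Principal-value phase in [-pi, pi)."""
        from .phase_retrieval import wrap_phase

        return wrap_phase(np.angle(self.values))

    @property
    def energy(self) -> float:
        """Total energy: sum of squared moduli over the grid."""
        return float(np.sum(np.abs(self.values) ** 2))

    def geometry(self, distance: float = 0.0) -> "PropagationGeometry":
        return PropagationGeometry(
            distance=distance,
            wavelength=self.wavelength,
            grid_dims=self.values.shape,
            pixel_pitch=self.pixel_pitch,
        )


@dataclass(frozen=True)
class PropagationGeometry:
    """Geometry of a plane-to-plane propagation step.

    ``distance`` is signed: negative values back-propagate and zero is the
    identity on band-limited fields.
    """

    distance: float
    wavelength: float
    grid_dims: tuple[int, int]
    pixel_pitch: float

    def __post_init__(self) -> None:
        if not (self.wavelength > 0):
            raise InvalidGeometryError(f"wavelength must be > 0, got {self.wavelength}")
        if not (self.pixel_pitch > 0):
            raise InvalidGeometryError(f"pixel_pitch must be > 0, got {self.pixel_pitch}")
        dims = tuple(int(d) for d in self.grid_dims)
        if len(dims) != 2 or min(dims) < 2:
            raise InvalidGeometryError(f"grid_dims must be 2 axes each >= 2, got {self.grid_dims}")
        object.__setattr__(self, "grid_dims", dims)
        if not np.isfinite(self.distance):
            raise InvalidGeometryError("distance must be finite")


def spatial_frequency_grid(geometry: PropagationGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Spatial-frequency grids (f_x, f_y) in cycles per metre, DFT ordering.

    Returns two arrays shaped like the field grid: ``f_x`` varies along axis 1
    (columns) and ``f_y`` along axis 0 (rows).  The frequency step per axis is
    ``1 / (dims * pitch)``, matching :func:`numpy.fft.fftfreq`.
    """
    ny, nx = geometry.grid_dims
    fy = np.fft.fftfreq(ny, d=geometry.pixel_pitch)
    fx = np.fft.fftfreq(nx, d=geometry.pixel_pitch)
    fxx, fyy = np.meshgrid(fx, fy)
    return fxx, fyy


def transfer_function(geometry: PropagationGeometry) -> np.ndarray:
    """Angular-spectrum transfer function on the DFT frequency grid.

    Unit modulus on the propagating support ``(lambda f_x)^2 + (lambda f_y)^2
    <= 1``; exactly zero beyond it (evanescent hard cutoff).  At ``z = 0`` the
    propagating support is identically 1.
    """
    fxx, fyy = spatial_frequency_grid(geometry)
    lam = geometry.wavelength
    arg = 1.0 - (lam * fxx) ** 2 - (lam * fyy) ** 2
    propagating = arg >= 0.0
    kernel = np.zeros(geometry.grid_dims, dtype=complex)
    phase = 2.0 * np.pi * (geometry.distance / lam) * np.sqrt(np.where(propagating, arg, 0.0))
    kernel[propagating] = np.exp(1j * phase[propagating])
    return kernel


def propagate(fld: ComplexField, distance: float) -> ComplexField:
    """Propagate a field by a signed distance via the angular spectrum.

    Implements ``IFFT{ H(z) * FFT{u} }`` with unitary transforms, so energy on
    the propagating support is conserved and ``propagate(u, z)`` followed by
    ``propagate(., -z)`` recovers any band-limited input.
    """
    geom = fld.geometry(distance)
    kernel = transfer_function(geom)
    spectrum = np.fft.fft2(fld.values, norm="ortho")
    out = np.fft.ifft2(kernel * spectrum, norm="ortho")
    return replace(fld, values=out)

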