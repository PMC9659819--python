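"""Synthetic urine-sediment scene generator with ground-truth amplitude and phase.

The phantom stands in for a microscope photograph of urine sediment: a
cluttered background with a few large, faint epithelial cells, one or more
disk-shaped red blood cells (one of which may carry a protruding membrane
bleb), and small speckle debris.  Cells are rendered as phase objects: they
transmit most of the light (amplitude near 1) but imprint a smooth phase
dome whose peak encodes their optical thickness.  Every scene ships with
per-object boolean masks and exact phase ground truth, so retrieval
experiments can be scored without any external data.

Geometry and appearance are deterministic per seed (NumPy PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidConfigError, PlacementError
from .propagation import ComplexField

__all__ = ["PhantomSpec", "PhantomScene", "generate_scene", "scene_to_object_field"]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic scene.

    Defaults describe the demo scene: a 256x256 canvas, three large faint
    epithelial cells, one abnormal red blood cell carrying a membrane bleb,
    light speckle clutter, and a peak red-cell phase shift of 1.5 rad
    (a typical optical thickness for an erythrocyte at visible wavelengths).
    """

    canvas_dims: tuple[int, int] = (256, 256)
    n_epithelial: int = 3
    n_rbc: int = 1
    bleb: bool = True
    bleb_relative_radius: float = 0.45
    phase_amplitude_rbc: float = 1.5
    epithelial_phase_fraction: float = 0.2
    clutter_density: float = 0.01
    seed: int = 0
    rbc_radius: Optional[float] = None  # default: ~4.5% of the canvas side
    epithelial_radius: Optional[float] = None  # default: ~13% of the canvas side
    max_retries: int = 500

    def __post_init__(self) -> None:
        self.canvas_dims = tuple(int(d) for d in self.canvas_dims)
        if len(self.canvas_dims) != 2 or min(self.canvas_dims) < 32:
            raise InvalidConfigError(f"canvas must be >= 32 x 32, got {self.canvas_dims}")
        if self.n_epithelial < 0 or self.n_rbc < 0:
            raise InvalidConfigError("object counts must be >= 0")
        if not (0.0 < self.phase_amplitude_rbc <= np.pi):
            raise InvalidConfigError(
                f"phase_amplitude_rbc must lie in (0, pi], got {self.phase_amplitude_rbc}"
            )
        if not (0.0 <= self.clutter_density < 1.0):
            raise InvalidConfigError(f"clutter_density must lie in [0, 1), got {self.clutter_density}")
        if not (0.0 < self.bleb_relative_radius < 1.0):
            raise InvalidConfigError("bleb_relative_radius must lie in (0, 1)")
        side = min(self.canvas_dims)
        if self.rbc_radius is None:
            self.rbc_radius = 0.045 * side
        if self.epithelial_radius is None:
            self.epithelial_radius = 0.13 * side

    def to_dict(self) -> dict:
        return {
            "canvas_dims": list(self.canvas_dims),
            "n_epithelial": self.n_epithelial,
            "n_rbc": self.n_rbc,
            "bleb": self.bleb,
            "bleb_relative_radius": self.bleb_relative_radius,
            "phase_amplitude_rbc": self.phase_amplitude_rbc,
            "epithelial_phase_fraction": self.epithelial_phase_fraction,
            "clutter_density": self.clutter_density,
            "seed": self.seed,
            "rbc_radius": self.rbc_radius,
            "epithelial_radius": self.epithelial_radius,
        }


@dataclass
class PhantomScene:
    """A rendered scene: RGB image, ground truth, and labelled masks."""

    rgb_image: np.ndarray  # H x W x 3 uint8
    amplitude: np.ndarray  # H x W float in [0, 1]
    phase: np.ndarray  # H x W float, radians; zero outside object masks
    masks: dict  # {"epithelial", "rbc", "bleb", "clutter"} -> bool H x W
    spec: Optional[PhantomSpec] = None


def _dome(shape: tuple[int, int], center: tuple[int, int], radius: float) -> np.ndarray:
    """Raised-cosine dome of unit peak over a disk; 0 outside the disk."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    d = np.hypot(yy - center[0], xx - center[1])
    return np.where(d <= radius, 0.5 * (1.0 + np.cos(np.pi * d / radius)), 0.0)


def _disk(shape: tuple[int, int], center: tuple[int, int], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return np.hypot(yy - center[0], xx - center[1]) <= radius


def _place(
    rng: np.random.Generator,
    shape: tuple[int, int],
    radius: float,
    occupied: np.ndarray,
    max_retries: int,
) -> tuple[int, int]:
    """Random integer centre whose disk avoids the occupied mask and the border."""
    margin = int(np.ceil(radius)) + 2
    if 2 * margin >= min(shape):
        raise PlacementError(f"object of radius {radius} cannot fit a {shape} canvas")
    for _ in range(max_retries):
        cy = int(rng.integers(margin, shape[0] - margin))
        cx = int(rng.integers(margin, shape[1] - margin))
        if not occupied[_disk(shape, (cy, cx), radius + 2)].any():
            return cy, cx
    raise PlacementError(f"could not place object of radius {radius} after {max_retries} tries")


def generate_scene(spec: PhantomSpec) -> PhantomScene:
    """Render a phantom scene from its spec; bit-identical per seed.

    Epithelial cells are large, faint, yellow-tinted blobs with a weak phase
    dome; red blood cells are smaller red-tinted disks with a strong
    raised-cosine phase dome peaking at ``spec.phase_amplitude_rbc`` (the
    scene phase maximum); the first red cell optionally carries a one-sided
    bleb, rendered as a smaller overlapping disk with its own (lower) dome.
    Clutter is dark amplitude-only speckle confined to the background.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.canvas_dims
    amplitude = np.ones(shape)
    phase = np.zeros(shape)
    rgb = np.empty(shape + (3,))
    rgb[..., :] = (0.82, 0.82, 0.80)  # light grey background

    masks = {name: np.zeros(shape, dtype=bool) for name in ("epithelial", "rbc", "bleb", "clutter")}
    occupied = np.zeros(shape, dtype=bool)

    # red blood cells first: the detection target must always find room
    for i in range(spec.n_rbc):
        r = spec.rbc_radius * (1.0 + rng.uniform(-0.15, 0.15))
        footprint = r * (1.0 + spec.bleb_relative_radius) + 1.0 if (spec.bleb and i == 0) else r
        c = _place(rng, shape, footprint, occupied, spec.max_retries)
        dome = _dome(shape, c, r)
        disk = _disk(shape, c, r)
        masks["rbc"] |= disk
        occupied |= disk
        amplitude -= 0.5 * dome
        phase = np.maximum(phase, spec.phase_amplitude_rbc * dome)
        tint = np.array([0.75, 0.18, 0.20])  # red-ish
        rgb[disk] = rgb[disk] * (1 - dome[disk, None]) + tint * dome[disk, None]

        if spec.bleb and i == 0:
            rb = spec.bleb_relative_radius * r
            angle = rng.uniform(0, 2 * np.pi)
            bc = (int(round(c[0] + r * np.sin(angle))), int(round(c[1] + r * np.cos(angle))))
            bdome = _dome(shape, bc, rb)
            bdisk = _disk(shape, bc, rb) & ~disk
            masks["bleb"] |= bdisk
            occupied |= bdisk
            amplitude -= 0.4 * bdome * (~disk)
            phase = np.maximum(phase, 0.8 * spec.phase_amplitude_rbc * bdome * bdisk)
            rgb[bdisk] = rgb[bdisk] * (1 - bdome[bdisk, None]) + tint * bdome[bdisk, None]

    epithelial_peak = spec.epithelial_phase_fraction * spec.phase_amplitude_rbc
    for _ in range(spec.n_epithelial):
        r = spec.epithelial_radius * (1.0 + rng.uniform(-0.2, 0.2))
        c = _place(rng, shape, r, occupied, spec.max_retries)
        dome = _dome(shape, c, r)
        disk = _disk(shape, c, r)
        masks["epithelial"] |= disk
        occupied |= disk
        amplitude -= 0.15 * dome
        phase = np.maximum(phase, epithelial_peak * dome)
        tint = np.array([0.86, 0.80, 0.55])  # yellow-ish
        rgb[disk] = rgb[disk] * (1 - dome[disk, None]) + tint * dome[disk, None]

    if spec.clutter_density > 0:
        n_speckles = int(round(spec.clutter_density * phase.size / 9.0))
        for _ in range(n_speckles):
            cy = int(rng.integers(1, shape[0] - 1))
            cx = int(rng.integers(1, shape[1] - 1))
            sdisk = _disk(shape, (cy, cx), float(rng.uniform(1.0, 2.0))) & ~occupied
            masks["clutter"] |= sdisk
            amplitude[sdisk] = np.minimum(amplitude[sdisk], rng.uniform(0.25, 0.45))
            rgb[sdisk] = (0.35, 0.30, 0.25)  # dark debris

    amplitude = np.clip(amplitude, 0.0, 1.0)
    rgb_u8 = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    return PhantomScene(rgb_image=rgb_u8, amplitude=amplitude, phase=phase, masks=masks, spec=spec)


def scene_to_object_field(
    scene: PhantomScene, wavelength: float = 632.8e-9, pixel_pitch: float = 4.65e-6
) -> ComplexField:
    """Complex object field of the scene: amplitude * exp(j * phase).

    Cells are treated as phase objects — mostly transparent, their shape
    carried by the phase — so the field amplitude is the scene amplitude in
    [0, 1] and the field phase is the ground-truth phase in radians.
    """
    values = scene.amplitude * np.exp(1j * scene.phase)
    return ComplexField(values=values, pixel_pitch=pixel_pitch, wavelength=wavelength)
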