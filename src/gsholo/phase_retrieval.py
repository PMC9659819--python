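"""Gerchberg-Saxton phase retrieval and its initial-phase-optimised variant.

The GS algorithm recovers the phase of a complex field from two intensity
measurements: the amplitude ``|f(x,y)|`` on the input plane and the amplitude
``|g(u,v)|`` on the imaging (Fourier) plane.  Starting from a random phase it
alternates between the planes, each time keeping the computed phase and
replacing the computed amplitude with the measured one:

    g_k  = FFT{ f_k }                       (input -> imaging)
    g'_k = |g| * exp(j * arg g_k)           (imaging-plane amplitude constraint)
    f'_k = IFFT{ g'_k }                     (imaging -> input)
    f_k+1 = |f| * exp(j * arg f'_k)         (input-plane amplitude constraint)

Four model variants are provided, mirroring a comparative study of phase
constraints:

* **Model 1** — plain GS; the imaging-plane *amplitude* reconstruction is the
  quantity of interest.  Iteration identical to Model 2.
* **Model 2** — plain GS phase retrieval from a raw random initial phase,
  no mapping anywhere.
* **Model 3** — the input amplitude is min-max normalised to [0, 1] grey
  levels, the initial random phase is restricted to [-pi, pi], and the output
  phase is affinely mapped from [-pi, pi] to [0, 1].  Mapping is applied only
  at initialisation and output, not inside the loop.
* **Model 4** — Model 3, but the random initial phase is first min-max
  normalised and then scaled by a factor ``beta``, confining the start to
  [0, beta].  A small, non-negative initial phase starts the iteration close
  to the mostly-flat phase of a weak phase object, which is what makes this
  the "improved" variant.

Both transforms use the unitary convention (``norm="ortho"``).  All
randomness flows through :func:`numpy.random.default_rng` (PCG64), so a seed
fully determines a run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .errors import (
    DegenerateInputWarning,
    InvalidConfigError,
    InvalidRangeError,
    ShapeError,
)
from .metrics import IterationTrace, correlation_coefficient, log_rmse, rmse
from .propagation import ComplexField

__all__ = [
    "PhaseMap",
    "GSConfig",
    "GSResult",
    "wrap_phase",
    "random_initial_phase",
    "normalize_phase",
    "optimize_initial_phase",
    "map_phase",
    "fourier_amplitude",
    "gs_step",
    "run_gs",
    "correlation_stop",
]

_PRINCIPAL = (-np.pi, np.pi)
_UNIT = (0.0, 1.0)


@dataclass
class PhaseMap:
    """A real 2-D phase array with a declared range convention.

    ``range_convention`` is ``"principal"`` (radians in [-pi, pi]) or
    ``"unit"`` ([0, 1] after affine mapping).
    """

    values: np.ndarray
    range_convention: str = "principal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError(f"phase map must be 2-D, got shape {self.values.shape}")
        if self.range_convention not in ("principal", "unit"):
            raise InvalidConfigError(
                f"range_convention must be 'principal' or 'unit', got {self.range_convention!r}"
            )
        lo, hi = _PRINCIPAL if self.range_convention == "principal" else _UNIT
        if self.values.size and (self.values.min() < lo - 1e-12 or self.values.max() > hi + 1e-12):
            raise InvalidRangeError(
                f"values outside the {self.range_convention} range [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GSConfig:
    """All retrieval knobs for a GS run.

    Parameters
    ----------
    model
        Variant 1-4 (see module docstring).
    iterations
        Maximum number of iterations (>= 1).
    beta
        Scale of the optimised initial phase (Model 4); the start lies in
        [0, beta].  Default pi: half the principal range.
    seed
        Seed of the random initial phase.
    correlation_threshold
        When set (in (0, 1]), the run stops early once the modulus of the
        normalised correlation between the field before and after one full
        Fourier round trip reaches the threshold.  Off (None) by default.
    map_output
        Map the output phase from [-pi, pi] to [0, 1].  Defaults to the
        model's convention (True for Models 3-4).
    """

    model: int = 4
    iterations: int = 200
    beta: float = float(np.pi)
    seed: int = 0
    correlation_threshold: Optional[float] = None
    map_output: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.model not in (1, 2, 3, 4):
            raise InvalidConfigError(f"model must be one of 1, 2, 3, 4, got {self.model}")
        if int(self.iterations) < 1:
            raise InvalidConfigError(f"iterations must be >= 1, got {self.iterations}")
        self.iterations = int(self.iterations)
        if self.model == 4 and not (self.beta > 0):
            raise InvalidConfigError(f"beta must be > 0 for model 4, got {self.beta}")
        if self.correlation_threshold is not None and not (
            0.0 < self.correlation_threshold <= 1.0
        ):
            raise InvalidConfigError(
                f"correlation_threshold must lie in (0, 1], got {self.correlation_threshold}"
            )
        if self.map_output is None:
            self.map_output = self.model in (3, 4)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "iterations": self.iterations,
            "beta": self.beta,
            "seed": self.seed,
            "correlation_threshold": self.correlation_threshold,
            "map_output": self.map_output,
        }


@dataclass
class GSResult:
    """Output of a GS run.

    ``phase_estimate`` lives on the input plane; its convention is "unit"
    when the run mapped its output and "principal" otherwise.
    ``amplitude_estimate`` is the reconstructed imaging-plane amplitude
    ``|g_K|`` of the final iteration; ``input_amplitude_estimate`` is the
    reconstructed input-plane amplitude ``|f'_K|`` (the Model 1 quantity of
    interest is the former, the reconstructed cell image the latter).
    """

    phase_estimate: PhaseMap
    amplitude_estimate: np.ndarray
    trace: IterationTrace
    iterations_run: int
    config: GSConfig
    input_amplitude_estimate: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def wrap_phase(values: np.ndarray) -> np.ndarray:
    """Wrap angles to the principal interval [-pi, pi)."""
    values = np.asarray(values, dtype=float)
    return np.mod(values + np.pi, 2.0 * np.pi) - np.pi


def random_initial_phase(dims: tuple[int, int], seed: int) -> PhaseMap:
    """I.i.d. uniform random phase on [-pi, pi), principal convention.

    The generator is NumPy's PCG64; the same seed always reproduces the same
    map bit-for-bit.
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 2 or min(dims) < 2:
        raise ShapeError(f"dims must be 2 axes each >= 2, got {dims}")
    rng = np.random.default_rng(seed)
    values = rng.uniform(-np.pi, np.pi, size=dims)
    return PhaseMap(values, "principal")


def normalize_phase(phase: PhaseMap | np.ndarray) -> np.ndarray:
    """Min-max rescale a phase array to [0, 1].

    A constant input is degenerate: an all-zeros array is returned and a
    :class:`DegenerateInputWarning` is emitted.
    """
    values = phase.values if isinstance(phase, PhaseMap) else np.asarray(phase, dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        warnings.warn("constant phase input; returning all zeros", DegenerateInputWarning)
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def optimize_initial_phase(phase: PhaseMap | np.ndarray, beta: float) -> np.ndarray:
    """Normalise a phase map and scale it by ``beta``; values land in [0, beta]."""
    if not (beta > 0):
        raise InvalidConfigError(f"beta must be > 0, got {beta}")
    return normalize_phase(phase) * beta


def map_phase(
    values: np.ndarray,
    from_range: tuple[float, float],
    to_range: tuple[float, float],
) -> np.ndarray:
    """Affinely map ``from_range`` onto ``to_range``; endpoints map to endpoints.

    Values are expected inside ``from_range`` (wrap with :func:`wrap_phase`
    first when mapping raw angles); a zero-width source range is an error.
    """
    values = np.asarray(values, dtype=float)
    a, b = float(from_range[0]), float(from_range[1])
    c, d = float(to_range[0]), float(to_range[1])
    width = b - a
    if width <= 0:
        raise InvalidRangeError(f"from_range must have positive width, got {from_range}")
    tol = 1e-9 * max(1.0, abs(width))
    if values.size and (values.min() < a - tol or values.max() > b + tol):
        raise InvalidRangeError("values fall outside from_range; wrap to principal values first")
    return (values - a) * ((d - c) / width) + c


def fourier_amplitude(values: np.ndarray) -> np.ndarray:
    """Imaging-plane amplitude |FFT{f}| under the unitary transform convention."""
    return np.abs(np.fft.fft2(np.asarray(values, dtype=complex), norm="ortho"))


def _replace_amplitude(values: np.ndarray, amplitude: np.ndarray) -> np.ndarray:
    """Keep the phase of ``values``, impose ``amplitude``; phase := 0 where |values| = 0."""
    modulus = np.abs(values)
    out = np.where(modulus > 0.0, values / np.where(modulus > 0.0, modulus, 1.0), 1.0)
    return amplitude * out


def gs_step(
    current_input_field: ComplexField,
    input_amplitude: np.ndarray,
    target_amplitude: np.ndarray,
) -> tuple[ComplexField, ComplexField]:
    """One GS double projection.

    Forward-transforms the current input-plane field, imposes the imaging
    plane (target) amplitude while keeping the computed phase, transforms
    back, and imposes the input-plane amplitude.  Returns the next
    input-plane field and the constrained imaging-plane field ``g'``.
    """
    from dataclasses import replace

    input_amplitude = np.asarray(input_amplitude, dtype=float)
    target_amplitude = np.asarray(target_amplitude, dtype=float)
    if not (current_input_field.shape == input_amplitude.shape == target_amplitude.shape):
        raise ShapeError(
            "field, input_amplitude and target_amplitude must share one shape; got "
            f"{current_input_field.shape}, {input_amplitude.shape}, {target_amplitude.shape}"
        )
    g = np.fft.fft2(current_input_field.values, norm="ortho")
    g_constrained = _replace_amplitude(g, target_amplitude)
    f_back = np.fft.ifft2(g_constrained, norm="ortho")
    f_next = _replace_amplitude(f_back, input_amplitude)
    return (
        replace(current_input_field, values=f_next),
        replace(current_input_field, values=g_constrained),
    )


def correlation_stop(
    current_field: ComplexField | np.ndarray,
    reference_field: ComplexField | np.ndarray,
    threshold: float,
) -> bool:
    """Stop when the modulus of the normalised complex correlation reaches ``threshold``.

    The correlation is invariant to a global complex scale (in particular a
    global phase factor) of either field; a zero-energy field makes it
    undefined and raises.
    """
    if not (0.0 < threshold <= 1.0):
        raise InvalidConfigError(f"threshold must lie in (0, 1], got {threshold}")
    a = current_field.values if isinstance(current_field, ComplexField) else np.asarray(current_field)
    b = reference_field.values if isinstance(reference_field, ComplexField) else np.asarray(reference_field)
    return correlation_coefficient(a, b) >= threshold


def _initial_phase(dims: tuple[int, int], config: GSConfig) -> np.ndarray:
    """Model-dependent initial phase in radians."""
    raw = random_initial_phase(dims, config.seed).values  # uniform on [-pi, pi)
    if config.model in (1, 2):
        return raw
    if config.model == 3:
        # already restricted to the principal interval by construction
        return raw
    return optimize_initial_phase(PhaseMap(raw, "principal"), config.beta)


def _iterate(
    input_amplitude: np.ndarray,
    target_amplitude: np.ndarray,
    phi0: np.ndarray,
    max_iterations: int,
) -> Iterator[tuple[int, np.ndarray, np.ndarray, np.ndarray]]:
    """Yield (k, |g_k|, f'_k, f_k) for k = 1..max_iterations.

    ``|g_k|`` is the unconstrained imaging-plane amplitude before replacement
    (its mismatch with the target is the classic non-increasing GS error);
    ``f'_k`` is the field after the inverse transform; ``f_k`` the input-plane
    field the iteration started from.
    """
    f = input_amplitude * np.exp(1j * phi0)
    for k in range(1, max_iterations + 1):
        g = np.fft.fft2(f, norm="ortho")
        g_amp = np.abs(g)
        g_constrained = _replace_amplitude(g, target_amplitude)
        f_back = np.fft.ifft2(g_constrained, norm="ortho")
        yield k, g_amp, f_back, f
        f = _replace_amplitude(f_back, input_amplitude)


def _output_phase(f_back: np.ndarray, config: GSConfig) -> np.ndarray:
    """Final-estimate phase in the run's output convention."""
    phi = wrap_phase(np.angle(f_back))
    phi = np.where(np.abs(f_back) > 0.0, phi, 0.0)
    if config.map_output:
        return map_phase(phi, _PRINCIPAL, _UNIT)
    return phi


def run_gs(
    input_amplitude: np.ndarray,
    target_amplitude: np.ndarray,
    config: GSConfig,
) -> GSResult:
    """Run the GS algorithm under one of the four model variants.

    The per-iteration trace records, for each iteration ``k``:

    * ``rmse`` — RMSE between iteration ``k``'s phase estimate and the FINAL
      iteration's phase estimate (the self-referential convergence measure),
      taken in the run's output convention; the last entry is exactly 0;
    * ``log10_rmse`` — its base-10 logarithm (``-inf`` sentinel at 0);
    * ``correlation`` — modulus of the normalised correlation between the
      input-plane field before and after the Fourier round trip, the quantity
      the optional early-stopping threshold watches;
    * ``fourier_rmse`` — RMSE between ``|g_k|`` and the target amplitude,
      the classic GS error that is non-increasing in ``k``.

    The iteration is deterministic given the seed, so the trace is produced
    by replaying the run once against the stored final phase rather than by
    keeping every snapshot in memory.
    """
    input_amplitude = np.asarray(input_amplitude, dtype=float)
    target_amplitude = np.asarray(target_amplitude, dtype=float)
    if input_amplitude.shape != target_amplitude.shape:
        raise ShapeError(
            f"amplitude shapes differ: {input_amplitude.shape} vs {target_amplitude.shape}"
        )
    if input_amplitude.ndim != 2 or min(input_amplitude.shape) < 2:
        raise ShapeError(f"amplitudes must be 2-D with dims >= 2, got {input_amplitude.shape}")
    if (input_amplitude < 0).any() or (target_amplitude < 0).any():
        raise InvalidRangeError("amplitudes must be non-negative")

    if config.model in (3, 4) and input_amplitude.max() > 1.0:
        # grey levels to [0, 1]; data already on [0, 1] is left untouched
        in_amp = normalize_phase(input_amplitude)
    else:
        in_amp = input_amplitude

    phi0 = _initial_phase(in_amp.shape, config)
    f0 = in_amp * np.exp(1j * phi0)

    # pass 1: run to completion (honouring early stop), keep only the end state
    iterations_run = config.iterations
    final_back = None
    final_g_amp = None
    for k, g_amp, f_back, f_in in _iterate(in_amp, target_amplitude, phi0, config.iterations):
        final_back, final_g_amp = f_back, g_amp
        if config.correlation_threshold is not None and correlation_stop(
            f_back, f_in, config.correlation_threshold
        ):
            iterations_run = k
            break

    final_phase = _output_phase(final_back, config)

    # pass 2: replay the identical deterministic iteration, recording diagnostics
    records_rmse = np.empty(iterations_run)
    records_corr = np.empty(iterations_run)
    records_fourier = np.empty(iterations_run)
    for k, g_amp, f_back, f_in in _iterate(in_amp, target_amplitude, phi0, iterations_run):
        phase_k = _output_phase(f_back, config)
        records_rmse[k - 1] = rmse(phase_k, final_phase)
        records_corr[k - 1] = correlation_coefficient(f_back, f_in)
        records_fourier[k - 1] = rmse(g_amp, target_amplitude)

    trace = IterationTrace(
        rmse=records_rmse,
        log10_rmse=log_rmse(records_rmse),
        correlation=records_corr,
        fourier_rmse=records_fourier,
        phase_convention="unit" if config.map_output else "principal",
    )
    convention = "unit" if config.map_output else "principal"
    return GSResult(
        phase_estimate=PhaseMap(final_phase, convention),
        amplitude_estimate=final_g_amp,
        trace=trace,
        iterations_run=iterations_run,
        config=config,
        input_amplitude_estimate=np.abs(final_back),
    )
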