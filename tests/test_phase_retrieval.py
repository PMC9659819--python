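"""GS phase retrieval: mapping operations, single steps, full runs, stopping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsholo import (
    ComplexField,
    DegenerateInputWarning,
    GSConfig,
    InvalidConfigError,
    InvalidRangeError,
    PhaseMap,
    ShapeError,
    UndefinedCorrelationError,
    correlation_stop,
    fourier_amplitude,
    generate_scene,
    gs_step,
    map_phase,
    normalize_phase,
    optimize_initial_phase,
    random_initial_phase,
    run_gs,
    simulate_hologram,
    wrap_phase,
)
from gsholo.phantom import PhantomSpec


class TestRandomInitialPhase:
    def test_deterministic_per_seed(self):
        a = random_initial_phase((32, 32), seed=5)
        b = random_initial_phase((32, 32), seed=5)
        assert np.array_equal(a.values, b.values)
        c = random_initial_phase((32, 32), seed=6)
        assert not np.array_equal(a.values, c.values)

    def test_principal_range(self):
        phase = random_initial_phase((64, 64), seed=0)
        assert phase.range_convention == "principal"
        assert np.abs(phase.values).max() <= np.pi

    def test_uniform_moments(self):
        values = random_initial_phase((256, 256), seed=11).values
        assert abs(values.mean()) < 0.05
        assert values.var() == pytest.approx(np.pi**2 / 3, rel=0.05)


class TestNormalizeAndOptimize:
    def test_minmax_rescale(self):
        out = normalize_phase(np.array([[-np.pi, 0.0], [np.pi, 0.0]]))
        assert out[0, 0] == 0.0 and out[1, 0] == 1.0 and out[0, 1] == pytest.approx(0.5)

    def test_hand_arithmetic(self):
        out = normalize_phase(np.array([[1.0, 2.0, 4.0]]))
        assert np.allclose(out, [[0.0, 1.0 / 3.0, 1.0]])

    def test_constant_input_degenerate(self):
        with pytest.warns(DegenerateInputWarning):
            out = normalize_phase(np.full((4, 4), 0.7))
        assert np.array_equal(out, np.zeros((4, 4)))

    def test_beta_scaling(self):
        out = optimize_initial_phase(np.array([[-np.pi, np.pi]]), beta=np.pi)
        assert np.allclose(out, [[0.0, np.pi]])
        out = optimize_initial_phase(np.array([[0.0, 2.0, 4.0]]), beta=0.5)
        assert np.allclose(out, [[0.0, 0.25, 0.5]])

    def test_beta_one_is_plain_normalisation(self, rng):
        values = rng.normal(size=(8, 8))
        assert np.array_equal(optimize_initial_phase(values, 1.0), normalize_phase(values))

    @pytest.mark.parametrize("beta", [0.0, -1.0])
    def test_invalid_beta(self, beta):
        with pytest.raises(InvalidConfigError):
            optimize_initial_phase(np.array([[0.0, 1.0]]), beta)


class TestMapPhase:
    def test_principal_to_unit_endpoints(self):
        out = map_phase(np.array([[-np.pi, 0.0, np.pi]]), (-np.pi, np.pi), (0.0, 1.0))
        assert np.allclose(out, [[0.0, 0.5, 1.0]])

    def test_identity_ranges(self, rng):
        values = rng.uniform(-1, 1, (6, 6))
        assert np.allclose(map_phase(values, (-1, 1), (-1, 1)), values)

    def test_zero_width_range_rejected(self):
        with pytest.raises(InvalidRangeError):
            map_phase(np.zeros((2, 2)), (1.0, 1.0), (0.0, 1.0))

    def test_out_of_range_values_rejected(self):
        with pytest.raises(InvalidRangeError):
            map_phase(np.array([[4.0]]), (-np.pi, np.pi), (0.0, 1.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_wrap_phase_lands_in_principal_interval(self, a, b):
        wrapped = wrap_phase(np.array([[a, b]]))
        assert (wrapped >= -np.pi).all() and (wrapped < np.pi).all()
        # wrapping preserves the angle modulo 2*pi
        assert np.allclose(np.exp(1j * wrapped), np.exp(1j * np.array([[a, b]])), atol=1e-9)


class TestGSStep:
    @staticmethod
    def field_from(values):
        return ComplexField(np.asarray(values, dtype=complex), 1e-6, 0.5e-6)

    def test_fixed_point_when_constraints_satisfied(self, rng):
        amp = rng.uniform(0.2, 1.0, (8, 8))
        phase = rng.uniform(-np.pi, np.pi, (8, 8))
        fld = self.field_from(amp * np.exp(1j * phase))
        target = fourier_amplitude(fld.values)
        nxt, _ = gs_step(fld, amp, target)
        assert np.linalg.norm(nxt.values - fld.values) / np.linalg.norm(fld.values) < 1e-10

    def test_zero_target_gives_zero_imaging_field(self, rng):
        amp = rng.uniform(0.2, 1.0, (8, 8))
        fld = self.field_from(amp)
        nxt, imaging = gs_step(fld, amp, np.zeros((8, 8)))
        assert np.array_equal(imaging.values, np.zeros((8, 8), dtype=complex))
        # zero-modulus convention: retained phase is 0, so next field is real
        assert np.allclose(nxt.values, amp)

    def test_matches_brute_force_dft(self, rng):
        # one amplitude-replacement step recomputed with an explicit O(N^4) DFT
        n = 4
        amp_in = rng.uniform(0.2, 1.0, (n, n))
        amp_target = rng.uniform(0.2, 1.0, (n, n))
        f0 = amp_in * np.exp(1j * rng.uniform(-np.pi, np.pi, (n, n)))

        idx = np.arange(n)
        w = np.exp(-2j * np.pi * np.outer(idx, idx) / n) / np.sqrt(n)
        g = w @ f0 @ w  # unitary 2-D DFT by direct matrix product
        g_prime = amp_target * np.exp(1j * np.angle(g))
        f_prime = w.conj().T @ g_prime @ w.conj().T
        expected = amp_in * np.exp(1j * np.angle(f_prime))

        nxt, _ = gs_step(self.field_from(f0), amp_in, amp_target)
        assert np.allclose(nxt.values, expected, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        fld = self.field_from(rng.uniform(size=(8, 8)))
        with pytest.raises(ShapeError):
            gs_step(fld, np.ones((8, 8)), np.ones((4, 4)))


class TestCorrelationStop:
    def test_self_correlation_stops(self, rng):
        fld = ComplexField(rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4)), 1e-6, 0.5e-6)
        assert correlation_stop(fld, fld, threshold=1.0)

    def test_global_phase_invariance(self, rng):
        values = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        a = ComplexField(values, 1e-6, 0.5e-6)
        b = ComplexField(values * np.exp(1j * 0.9), 1e-6, 0.5e-6)
        assert correlation_stop(a, b, threshold=1.0 - 1e-12)

    def test_orthogonal_fields_never_stop(self):
        a = ComplexField(np.array([[1.0, 0.0], [0.0, 0.0]]), 1e-6, 0.5e-6)
        b = ComplexField(np.array([[0.0, 1.0], [0.0, 0.0]]), 1e-6, 0.5e-6)
        assert not correlation_stop(a, b, threshold=1e-6)

    def test_zero_energy_is_undefined(self):
        a = ComplexField(np.ones((2, 2)), 1e-6, 0.5e-6)
        z = ComplexField(np.zeros((2, 2)), 1e-6, 0.5e-6)
        with pytest.raises(UndefinedCorrelationError):
            correlation_stop(a, z, threshold=0.5)


class TestRunGS:
    @staticmethod
    def hologram(spec):
        return simulate_hologram(generate_scene(spec))

    def test_trace_length_matches_iterations(self, small_spec):
        amp, target = self.hologram(small_spec)
        result = run_gs(amp, target, GSConfig(model=2, iterations=1, seed=0))
        assert result.iterations_run == 1 and len(result.trace) == 1

    def test_model3_ranges(self, small_spec):
        amp, target = self.hologram(small_spec)
        result = run_gs(amp, target, GSConfig(model=3, iterations=5, seed=3))
        assert result.phase_estimate.range_convention == "unit"
        assert result.phase_estimate.values.min() >= 0.0
        assert result.phase_estimate.values.max() <= 1.0

    def test_model2_phase_in_radians(self, small_spec):
        amp, target = self.hologram(small_spec)
        result = run_gs(amp, target, GSConfig(model=2, iterations=5, seed=3))
        assert result.phase_estimate.range_convention == "principal"
        assert np.abs(result.phase_estimate.values).max() <= np.pi

    @pytest.mark.parametrize("model", [1, 2, 3])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("size", [32, 48, 64])
    def test_fourier_error_monotone(self, model, seed, size):
        # classic GS property: imaging-plane amplitude mismatch never increases
        spec = PhantomSpec(
            canvas_dims=(size, size), n_epithelial=1, n_rbc=1,
            epithelial_radius=size / 5, rbc_radius=size / 10, seed=seed,
        )
        amp, target = self.hologram(spec)
        result = run_gs(amp, target, GSConfig(model=model, iterations=60, seed=seed))
        assert (np.diff(result.trace.fourier_rmse) <= 1e-12).all()

    def test_deterministic_per_config(self, small_spec):
        amp, target = self.hologram(small_spec)
        cfg = GSConfig(model=4, iterations=30, seed=9)
        a = run_gs(amp, target, cfg)
        b = run_gs(amp, target, GSConfig(model=4, iterations=30, seed=9))
        assert np.array_equal(a.phase_estimate.values, b.phase_estimate.values)
        assert np.array_equal(a.trace.rmse, b.trace.rmse)
        assert np.array_equal(a.amplitude_estimate, b.amplitude_estimate)

    def test_fixed_point_run(self, rng):
        # make the seeded initial phase already satisfy both constraints:
        # every iteration must then leave the estimate unchanged
        amp = rng.uniform(0.2, 1.0, (16, 16))
        phi0 = random_initial_phase((16, 16), seed=42).values
        target = fourier_amplitude(amp * np.exp(1j * phi0))
        result = run_gs(amp, target, GSConfig(model=2, iterations=10, seed=42))
        assert np.allclose(result.phase_estimate.values, wrap_phase(phi0), atol=1e-10)
        assert (result.trace.rmse < 1e-10).all()

    def test_trace_final_rmse_zero(self, small_spec):
        amp, target = self.hologram(small_spec)
        result = run_gs(amp, target, GSConfig(model=4, iterations=20, seed=2))
        assert result.trace.rmse[-1] == 0.0
        assert np.isneginf(result.trace.log10_rmse[-1])

    def test_correlation_threshold_stops_early(self, small_spec):
        amp, target = self.hologram(small_spec)
        result = run_gs(amp, target, GSConfig(model=4, iterations=500, seed=2, correlation_threshold=0.999))
        assert result.iterations_run < 500
        assert len(result.trace) == result.iterations_run
        assert result.trace.correlation[-1] >= 0.999

    def test_unknown_model_rejected(self):
        with pytest.raises(InvalidConfigError):
            GSConfig(model=5)

    def test_mismatched_amplitudes_rejected(self):
        with pytest.raises(ShapeError):
            run_gs(np.ones((8, 8)), np.ones((4, 4)), GSConfig(model=2, iterations=1))


class TestPhaseMapInvariants:
    def test_principal_range_enforced(self):
        with pytest.raises(InvalidRangeError):
            PhaseMap(np.array([[4.0]]), "principal")

    def test_unit_range_enforced(self):
        with pytest.raises(InvalidRangeError):
            PhaseMap(np.array([[1.5]]), "unit")

    def test_operations_return_valid_maps(self, small_spec):
        phase = random_initial_phase((16, 16), seed=0)
        PhaseMap(phase.values, "principal")  # no raise
        PhaseMap(normalize_phase(phase), "unit")  # no raise
        PhaseMap(map_phase(phase.values, (-np.pi, np.pi), (0, 1)), "unit")  # no raise
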