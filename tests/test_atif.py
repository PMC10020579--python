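"""Adaptive-threshold neurons: schedule construction, patterns, gradients."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from spikequant import (
    BreakpointVector,
    InvalidInputError,
    InvalidParameterError,
    ThresholdSchedule,
    UniformNeuronParams,
    atif_forward,
    breakpoint_gradients,
    decode_amplitude,
    run_constant_input,
    surrogate_derivative,
    threshold_gradient,
    threshold_schedule_from_breakpoints,
    validate_breakpoints,
)
from spikequant import atif

from conftest import random_valid_breakpoints

# strictly feasible T=4 vector (all pattern inequalities hold strictly
# except the construction's terminal equalities)
P_STRICT = np.array([0.9, 0.55, 0.35, 0.19])


class TestScheduleConstruction:
    def test_equally_spaced_reduces_to_uniform(self):
        sched = threshold_schedule_from_breakpoints([0.8, 0.6, 0.4, 0.2])
        assert np.allclose(sched.V, 0.8)

    def test_interior_recurrence(self):
        # V_th(3) = T (p_3 - p_4) for T = 4
        sched = threshold_schedule_from_breakpoints(P_STRICT)
        assert sched.V[2] == pytest.approx(4 * (0.35 - 0.19))
        assert sched.V[0] == pytest.approx(P_STRICT[0])
        assert sched.V[-1] == pytest.approx(4 * P_STRICT[-1])

    @pytest.mark.parametrize("c", [0.5, 1.0, 2.0])
    def test_uniform_equivalence_on_dense_grid(self, c):
        T = 8
        p = np.arange(T, 0, -1) * c / T
        sched = threshold_schedule_from_breakpoints(p)
        params = UniformNeuronParams(V_th=c, b=0.0, T=T)
        for i in np.linspace(-0.2 * c, 1.3 * c, 151):
            assert (
                atif_forward(i, sched).values.tolist()
                == run_constant_input(i, params).values.tolist()
            )

    def test_ascending_breakpoints_rejected(self):
        with pytest.raises(InvalidParameterError):
            threshold_schedule_from_breakpoints([0.2, 0.4, 0.6, 0.8])

    def test_nonpositive_tail_rejected(self):
        with pytest.raises(InvalidParameterError):
            BreakpointVector(p=np.array([0.5, 0.3, 0.0]))


class TestValidateBreakpoints:
    def test_equally_spaced_vector_passes_validation(self):
        assert validate_breakpoints([0.8, 0.6, 0.4, 0.2], 4).all_ok

    def test_first_fire_lines(self):
        # the first lines of the pattern system: j * p_j >= V_th(j)
        diag = validate_breakpoints(P_STRICT, 4)
        names = [n for n, ok, _ in diag.conditions if n.startswith("first_fire")]
        assert names and diag.all_ok

    def test_ordering_violation_flagged(self):
        diag = validate_breakpoints([0.2, 0.4, 0.6, 0.8], 4)
        assert not diag.all_ok and "descending" in diag.failures()

    def test_positivity_violation_flagged(self):
        diag = validate_breakpoints([0.6, 0.4, 0.2, 0.0], 4)
        assert "positivity" in diag.failures()

    def test_infeasible_interior_flagged(self):
        # too-small p_T starves the late timesteps
        diag = validate_breakpoints([0.8, 0.6, 0.59, 0.01], 4)
        assert not diag.all_ok


class TestForwardPatterns:
    @pytest.mark.parametrize(
        "j,pattern",
        [(1, [1, 1, 1, 1]), (2, [0, 1, 1, 1]), (3, [0, 0, 1, 1]), (4, [0, 0, 0, 1])],
    )
    def test_canonical_patterns_at_breakpoints(self, j, pattern):
        sched = threshold_schedule_from_breakpoints(P_STRICT)
        assert atif_forward(P_STRICT[j - 1], sched).values.tolist() == pattern

    def test_clipping_above_p1_and_silence_below(self):
        sched = threshold_schedule_from_breakpoints(P_STRICT)
        assert atif_forward(2.0, sched).count == 4
        assert atif_forward(0.01, sched).count == 0

    def test_pattern_oracle_random_valid_vectors(self, rng):
        for _ in range(60):
            T = int(rng.choice([2, 3, 4, 5]))
            p = random_valid_breakpoints(rng, T)
            sched = threshold_schedule_from_breakpoints(p)
            for j in range(1, T + 1):
                got = atif_forward(p[j - 1], sched).values.tolist()
                assert got == [0] * (j - 1) + [1] * (T - j + 1)

    def test_exact_patterns_infeasible_for_large_T(self, rng):
        """For T >= 6 the canonical-pattern inequality system is empty.

        The binding chain (p_2 = 1): first-fire of p_2 at t = 2 forces
        V_2 <= 2, i.e. p_3 >= (T-2)/T; sustained firing of p_2 at t = 3
        forces p_4 >= (T-3)/T; no-premature-fire of p_4 at t = 3 forces
        p_4 < T p_3 / (T+3) -- and the last two contradict once T >= 6.
        No descending vector can therefore pass validation.
        """
        T = 8
        for _ in range(300):
            d = rng.uniform(0.1 / T, 3.0 / T, T)
            p = np.cumsum(d[::-1])[::-1] * rng.uniform(0.2, 2.0)
            assert not validate_breakpoints(p, T).all_ok
        # the contradiction itself, for any p_3 admissible at T = 8
        p2 = 1.0
        p3_max = T / (T + 2) * p2          # no-premature-fire of p_3 at t=2
        assert T * p3_max / (T + 3) < (T - 3) / T * p2

    def test_monotone_count_in_input(self, rng):
        p = random_valid_breakpoints(rng, 5)
        sched = threshold_schedule_from_breakpoints(p)
        counts = [atif_forward(i, sched).count
                  for i in np.linspace(-0.1, 1.5 * p[0], 200)]
        assert (np.diff(counts) >= 0).all()


class TestDecodeAmplitude:
    def test_uniform_count_times_vth_over_T(self):
        sched = ThresholdSchedule.uniform(1.0, 4)
        assert decode_amplitude(np.array([0, 0, 1, 1]), sched) == pytest.approx(0.5)

    def test_equally_spaced_breakpoint_decodes_to_itself(self):
        sched = threshold_schedule_from_breakpoints([0.8, 0.6, 0.4, 0.2])
        train = atif_forward(0.4, sched)
        assert decode_amplitude(train, sched) == pytest.approx(0.4)

    def test_all_zero_decodes_to_zero(self):
        sched = threshold_schedule_from_breakpoints(P_STRICT)
        assert decode_amplitude(np.zeros(4, dtype=int), sched) == 0.0

    def test_rate_times_clipping_point(self):
        sched = threshold_schedule_from_breakpoints(P_STRICT)
        train = atif_forward(P_STRICT[2], sched)  # two spikes
        assert decode_amplitude(train, sched) == pytest.approx(P_STRICT[0] * 2 / 4)

    def test_length_mismatch(self):
        sched = ThresholdSchedule.uniform(1.0, 4)
        with pytest.raises(InvalidInputError):
            decode_amplitude(np.array([0, 1]), sched)


class TestSurrogate:
    def test_unit_sigmoid_values(self):
        assert surrogate_derivative(0.0) == pytest.approx(0.25)
        assert surrogate_derivative(1.0) == pytest.approx(0.19661193, rel=1e-6)
        assert surrogate_derivative(50.0) == pytest.approx(0.0, abs=1e-12)
        assert surrogate_derivative(-50.0) == pytest.approx(0.0, abs=1e-12)

    def test_sharpness_rescales(self):
        # alpha * sigma'(alpha q): peak alpha/4, window ~1/alpha
        assert surrogate_derivative(0.0, alpha=10.0) == pytest.approx(2.5)
        assert surrogate_derivative(1.0, alpha=10.0) < 1e-3

    def test_threshold_gradient_sign_and_magnitude(self):
        assert threshold_gradient(1.0, 0.0) == pytest.approx(-0.25)
        assert threshold_gradient(0.0, 1.3) == 0.0
        q = np.linspace(-3, 3, 25)
        g = threshold_gradient(np.ones_like(q), q)
        assert (g < 0).all()  # dq/dV_th = -1: positive upstream pushes down
        assert (np.abs(g) <= 0.25 + 1e-12).all()


class TestBreakpointGradients:
    def test_zero_upstream_gives_zero(self):
        g = breakpoint_gradients(np.zeros(4), np.zeros(4), P_STRICT)
        assert np.allclose(g, 0.0)

    def test_matches_finite_differences_of_relaxed_forward(self, rng):
        def relaxed_loss(p, i, c, alpha):
            V = threshold_schedule_from_breakpoints(p).V
            z, _ = atif.forward_traces(np.asarray(i), V, relaxed=True, alpha=alpha)
            return float(z @ c)

        for _ in range(100):
            T = int(rng.choice([2, 4, 8]))
            d = rng.uniform(0.05, 0.5, T)
            p = np.cumsum(d[::-1])[::-1]
            i = float(rng.uniform(-0.5, 1.5 * p[0]))
            c = rng.normal(0, 1, T)
            alpha = float(rng.choice([1.0, 4.0]))
            V = threshold_schedule_from_breakpoints(p).V
            z, q = atif.forward_traces(np.asarray(i), V, relaxed=True, alpha=alpha)
            g = breakpoint_gradients(c, q, p, relaxed=True, alpha=alpha)
            eps = 1e-6
            fd = np.empty(T)
            for j in range(T):
                pp, pm = p.copy(), p.copy()
                pp[j] += eps
                pm[j] -= eps
                fd[j] = (relaxed_loss(pp, i, c, alpha)
                         - relaxed_loss(pm, i, c, alpha)) / (2 * eps)
            assert np.allclose(g, fd, rtol=1e-4, atol=1e-7)

    def test_jacobian_structure(self):
        # p_2 enters only V_th(2) (with coefficient T) for T = 4
        J = atif.schedule_jacobian(4)
        assert J[0, 0] == 1.0
        assert (J[:, 1] == np.array([0.0, 4.0, 0.0, 0.0])).all()
        assert J[3, 3] == 4.0


class TestReparameterization:
    @given(st.lists(st.floats(-2, 2), min_size=2, max_size=8))
    def test_unconstrained_map_always_valid_ordering(self, a):
        p = atif.breakpoints_from_unconstrained(np.array(a))
        assert (np.diff(p.p) < 0).all() and p.p[-1] > 0

    def test_roundtrip(self):
        a = atif.unconstrained_from_breakpoints(P_STRICT)
        back = atif.breakpoints_from_unconstrained(a)
        assert np.allclose(back.p, P_STRICT)


class TestSerialization:
    def test_json_roundtrip_bit_exact(self, tmp_path):
        sched = threshold_schedule_from_breakpoints(P_STRICT)
        path = tmp_path / "sched.json"
        atif.save_schedule(sched, path, model_kind="atif-nu")
        back = atif.load_schedule(path)
        assert back.V.tolist() == sched.V.tolist()
        assert back.origin.p.tolist() == sched.origin.p.tolist()
        payload = json.loads(path.read_text())
        assert set(payload) == {"T", "p", "V", "model_kind"}
        assert payload["model_kind"] == "atif-nu"

    def test_uniform_schedule_has_no_origin(self, tmp_path):
        sched = ThresholdSchedule.uniform(0.7, 4)
        path = tmp_path / "u.json"
        atif.save_schedule(sched, path, model_kind="atif-u")
        assert atif.load_schedule(path).origin is None
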