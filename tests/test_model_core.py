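"""Forward model: integrator oracles, invariants, papilla decomposition."""

import numpy as np
import pytest

from renalkin.curves_io import TimeAttenuationCurve
from renalkin.model_core import (
    ModelParams,
    arterial_input,
    decompose_papilla,
    simulate,
    simulate_arrays,
    vascular_response,
)
from renalkin.synthetic_data import SyntheticSpec, aif_waveform

GRID = np.arange(0, 120.0001, 0.5)


def const_curve(value, label="c"):
    return TimeAttenuationCurve(GRID, np.full_like(GRID, value), label)


def zero_curve(label="z"):
    return const_curve(0.0, label)


PARAMS = ModelParams(k_perf=0.15, T_d=0.0, f=0.22, k_GFR=0.0048, k_out=0.005)


class TestArterialInput:
    def test_zero_curve_stays_zero(self):
        assert np.allclose(arterial_input(zero_curve(), 0.45).values, 0.0)

    def test_zero_hematocrit_is_identity(self):
        c = const_curve(110.0)
        assert np.allclose(arterial_input(c, 0.0).values, c.values)

    def test_plasma_correction_value(self):
        assert np.allclose(arterial_input(const_curve(110.0), 0.45).values, 200.0)

    def test_hematocrit_of_one_rejected(self):
        with pytest.raises(ValueError):
            arterial_input(const_curve(1.0), 1.0)


class TestSimulate:
    def test_zero_input_gives_zero_everywhere(self):
        cv, ct, ctot = simulate(PARAMS, zero_curve(), zero_curve())
        for c in (cv, ct, ctot):
            assert np.allclose(c.values, 0.0)

    def test_constant_input_matches_closed_form(self):
        """Exponential-update integrator vs the analytic constant-input solution."""
        c = 100.0
        cv, ct, _ = simulate(PARAMS, const_curve(c), zero_curve())
        t = GRID
        k = PARAMS.k_perf
        cv_exact = c * (1 - np.exp(-k * t))
        ct_exact = PARAMS.k_GFR * c * (t - (1 - np.exp(-k * t)) / k)
        assert np.max(np.abs(cv.values[1:] - cv_exact[1:]) / cv_exact[1:]) < 1e-4
        assert np.max(np.abs(ct.values[2:] - ct_exact[2:]) / ct_exact[2:]) < 1e-4

    def test_delay_shifts_solution_of_compact_input(self):
        """With an input that starts at zero, T_d=5 equals the T_d=0 solution shifted 5 s."""
        spec = SyntheticSpec()
        cp = aif_waveform(spec, GRID)  # zero until bolus arrival at 5 s
        zero = np.zeros_like(GRID)
        p0 = ModelParams(0.15, 0.0, 0.22, 0.0048, 0.005)
        p5 = ModelParams(0.15, 5.0, 0.22, 0.0048, 0.005)
        cv0, ct0, _ = simulate_arrays(p0, cp, zero, GRID)
        cv5, ct5, _ = simulate_arrays(p5, cp, zero, GRID)
        shift = int(5.0 / 0.5)
        assert np.allclose(cv5[shift:], cv0[:-shift], atol=1e-9)
        assert np.allclose(ct5[shift:], ct0[:-shift], atol=1e-9)

    def test_linearity_in_the_inputs(self):
        spec = SyntheticSpec()
        cp = aif_waveform(spec, GRID)
        co = np.maximum(GRID - 60.0, 0.0)
        a = 2.5
        cv1, ct1, _ = simulate_arrays(PARAMS, cp, co, GRID)
        cv2, ct2, _ = simulate_arrays(PARAMS, a * cp, a * co, GRID)
        assert np.allclose(cv2, a * cv1)
        assert np.allclose(ct2, a * ct1)

    def test_tubular_signal_nondecreasing_without_outflow(self):
        spec = SyntheticSpec()
        cp = aif_waveform(spec, GRID)
        p = ModelParams(0.15, 0.5, 0.22, 0.0048, 0.0)
        cv, ct, _ = simulate_arrays(p, cp, np.zeros_like(GRID), GRID)
        assert (cv >= -1e-12).all()
        assert (np.diff(ct) >= -1e-12).all()

    def test_integrator_order_richardson(self):
        """Halving the step shrinks the error at second order for smooth input."""
        spec = SyntheticSpec()
        k = 0.15

        def solve(dt):
            t = np.arange(0, 60.0001, dt)
            return t, vascular_response(k, aif_waveform(spec, t) / 0.55, dt)

        t_ref, ref = solve(0.0125)
        errs = []
        for dt in (0.5, 0.25):
            t, cv = solve(dt)
            idx = np.searchsorted(t_ref, t)
            errs.append(np.max(np.abs(cv - ref[idx])))
        assert errs[0] / errs[1] > 2.5  # ~4 for a second-order scheme

    def test_nonuniform_grid_rejected(self):
        bad = np.array([0.0, 0.5, 1.5, 2.0, 3.0])
        with pytest.raises(ValueError):
            simulate_arrays(PARAMS, np.ones(5), np.zeros(5), bad)


@pytest.fixture(scope="module")
def cp():
    spec = SyntheticSpec()
    return TimeAttenuationCurve(GRID, aif_waveform(spec, GRID) / 0.55, "cp")


class TestDecomposePapilla:

    def test_pure_perfusion_papilla_recovers_rate(self, cp):
        rate = 0.05
        papilla = TimeAttenuationCurve(
            GRID, vascular_response(rate, cp.values, 0.5), "papilla"
        )
        d = decompose_papilla(papilla, cp)
        assert d.papilla_rate == pytest.approx(rate, rel=1e-3)
        assert np.max(np.abs(d.filtration_component.values)) < 1e-6 * papilla.values.max()

    def test_late_inflow_separated_from_perfusion(self, cp):
        rate = 0.05
        perf = vascular_response(rate, cp.values, 0.5)
        sigmoid = 150.0 / (1.0 + np.exp(-(GRID - 75.0) / 5.0))  # inflow from ~60 s
        papilla = TimeAttenuationCurve(GRID, perf + sigmoid, "papilla")
        d = decompose_papilla(papilla, cp)
        early = GRID < 55.0
        late = GRID > 80.0
        assert np.max(d.filtration_component.values[early]) < 0.05 * sigmoid.max()
        assert np.allclose(
            d.filtration_component.values[late], sigmoid[late], rtol=0.05
        )
        assert 55.0 < d.arrival_time < 80.0

    def test_zero_papilla_degenerate(self, cp):
        d = decompose_papilla(zero_curve("papilla"), cp)
        assert d.papilla_rate == 0.0
        assert np.allclose(d.perfusion_component.values, 0.0)
        assert np.allclose(d.filtration_component.values, 0.0)

    def test_components_sum_to_input_where_unclipped(self, cp):
        rate = 0.05
        perf = vascular_response(rate, cp.values, 0.5)
        inflow = np.maximum(GRID - 70.0, 0.0) * 2.0
        papilla = TimeAttenuationCurve(GRID, perf + inflow, "papilla")
        d = decompose_papilla(papilla, cp)
        total = d.perfusion_component.values + d.filtration_component.values
        unclipped = papilla.values - d.perfusion_component.values >= 0
        assert np.allclose(total[unclipped], papilla.values[unclipped], atol=1e-9)

    def test_window_outside_data_rejected(self, cp):
        papilla = const_curve(10.0, "papilla")
        with pytest.raises(ValueError):
            decompose_papilla(papilla, cp, window=(0.0, 500.0))


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(k_perf=-0.1), dict(T_d=-1.0), dict(f=1.5), dict(k_GFR=-1e-4)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(k_perf=0.15, T_d=0.5, f=0.22, k_GFR=0.0048, k_out=0.005)
        base.update(kwargs)
        with pytest.raises(ValueError):
            ModelParams(**base)
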