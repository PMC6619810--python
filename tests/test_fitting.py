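"""Parameter estimation, goodness of fit and physiological conversions."""

import numpy as np
import pytest

from renalkin import (
    FitOptions,
    ModelParams,
    apportion_reference_gfr,
    derive_physiology,
    fit_kidney,
    goodness_of_fit,
    preprocess,
)
from renalkin.model_core import arterial_input, decompose_papilla, simulate_arrays
from renalkin.synthetic_data import SyntheticSpec, make_kidney


class TestGoodnessOfFit:
    def test_perfect_fit_is_one(self):
        y = np.array([0.0, 1, 2, 3])
        assert goodness_of_fit(y, y) == pytest.approx(1.0)

    def test_mean_fit_is_zero(self):
        y = np.array([0.0, 1, 2, 3])
        assert goodness_of_fit(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_against_hand_computed_value(self):
        # SS_res = 1, SS_tot = 5  ->  sqrt(1 - 1/5)
        got = goodness_of_fit(np.array([0.0, 1, 2, 3]), np.array([0.0, 1, 2, 2]))
        assert got == pytest.approx(np.sqrt(0.8))

    def test_zero_variance_observed_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit(np.full(4, 2.0), np.arange(4.0))


class TestDerivePhysiology:
    PARAMS = ModelParams(k_perf=0.15, T_d=0.68, f=0.22, k_GFR=0.0048, k_out=0.005)

    def test_gfr_formula(self):
        gfr, _, _ = derive_physiology(self.PARAMS, volume=148.0)
        assert gfr == pytest.approx(0.0048 * 148 * 60)  # 42.6 mL/min

    def test_perfusion_formula(self):
        _, perfusion, _ = derive_physiology(self.PARAMS, volume=148.0)
        assert perfusion == pytest.approx(0.15 * 0.22 * 60 * 100 / 0.55 * 0.9)  # 324

    def test_rbf_is_perfusion_times_volume(self):
        _, perfusion, rbf = derive_physiology(self.PARAMS, volume=148.0)
        assert rbf == pytest.approx(perfusion / 100.0 * 148.0)

    def test_zero_filtration_gives_zero_gfr(self):
        p = ModelParams(0.15, 0.68, 0.22, 0.0, 0.005)
        assert derive_physiology(p, 148.0)[0] == 0.0

    def test_homogeneity(self):
        g1, p1, r1 = derive_physiology(self.PARAMS, 148.0)
        double_kgfr = ModelParams(0.15, 0.68, 0.22, 2 * 0.0048, 0.005)
        assert derive_physiology(double_kgfr, 148.0)[0] == pytest.approx(2 * g1)
        g2, p2, r2 = derive_physiology(self.PARAMS, 2 * 148.0)
        assert g2 == pytest.approx(2 * g1)
        assert r2 == pytest.approx(2 * r1)
        assert p2 == pytest.approx(p1)  # perfusion is per unit mass

    def test_sigma_mode_switch(self):
        _, mult, _ = derive_physiology(self.PARAMS, 148.0, sigma_mode="multiply")
        _, div, _ = derive_physiology(self.PARAMS, 148.0, sigma_mode="divide")
        assert mult == pytest.approx(div * 0.9 * 0.9)


class TestApportionmentProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        total=st.floats(0.0, 200.0),
        left=st.floats(1.0, 1000.0),
        right=st.floats(1.0, 1000.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_split_preserves_total_and_ordering(self, total, left, right):
        gl, gr = apportion_reference_gfr(total, left, right)
        assert gl + gr == pytest.approx(total, abs=1e-9)
        assert gl >= 0 and gr >= 0
        if left > right:
            assert gl >= gr


class TestApportionment:
    @pytest.mark.parametrize(
        "total,left,right,expected",
        [(100.0, 300.0, 300.0, (50.0, 50.0)),
         (60.0, 400.0, 200.0, (40.0, 20.0)),
         (0.0, 300.0, 300.0, (0.0, 0.0))],
    )
    def test_proportional_split(self, total, left, right, expected):
        got = apportion_reference_gfr(total, left, right)
        assert got == pytest.approx(expected)
        assert sum(got) == pytest.approx(total)

    def test_zero_rbf_rejected(self):
        with pytest.raises(ValueError):
            apportion_reference_gfr(50.0, 0.0, 0.0)


class TestFitKidney:
    def test_noiseless_self_consistency(self, fit_noiseless):
        """Noise-free synthetic data refit: near-perfect fit, truth recovered."""
        result, truth = fit_noiseless
        assert result.converged
        assert result.r_multiple > 0.999
        # residual dominated by two-phase-sampling interpolation, ~HU scale
        rms = result.residual_norm / np.sqrt(len(result.fitted_ctot))
        assert rms < 0.02 * result.fitted_ctot.values.max()
        assert result.params.k_perf == pytest.approx(truth.k_perf, rel=0.07)
        assert result.params.f == pytest.approx(truth.f, rel=0.07)
        assert result.params.k_GFR == pytest.approx(truth.k_GFR, rel=0.07)
        assert result.params.T_d == pytest.approx(truth.T_d, abs=0.3)
        assert result.params.k_out == pytest.approx(truth.k_out, rel=0.25)

    def test_noisy_recovery_within_ten_percent(self, noisy_kidney):
        kidney, truth = noisy_kidney
        prepped = preprocess(kidney, dt=0.5, t_max=120.0)
        result = fit_kidney(prepped, FitOptions(seed=2))
        assert result.params.k_perf == pytest.approx(truth.k_perf, rel=0.10)
        assert result.params.f == pytest.approx(truth.f, rel=0.10)
        assert result.params.k_GFR == pytest.approx(truth.k_GFR, rel=0.10)
        assert result.params.k_out == pytest.approx(truth.k_out, rel=0.25)

    def test_objective_no_worse_than_truth(self, prepped_noiseless):
        """Returned minimum beats (or ties) the generating parameters."""
        prepped, truth = prepped_noiseless
        result = fit_kidney(prepped, FitOptions(seed=1))
        cp = arterial_input(prepped.aorta, prepped.hematocrit)
        decomp = decompose_papilla(prepped.papilla, cp, window=(0.0, 35.0))
        times = prepped.parenchyma.times
        _, _, ctot_truth = simulate_arrays(
            truth, cp.values, decomp.filtration_component.values, times
        )
        sse_truth = float(np.sum((ctot_truth - prepped.parenchyma.values) ** 2))
        assert result.residual_norm**2 <= sse_truth * (1 + 1e-6)

    def test_fixed_td_reduces_perfusion_and_gfr(self, prepped_noiseless):
        """Pinning the transit delay at zero biases perfusion and GFR downward."""
        prepped, truth = prepped_noiseless
        assert truth.T_d > 0.3
        free = fit_kidney(prepped, FitOptions(seed=1))
        fixed = fit_kidney(prepped, FitOptions(seed=1, fixed_Td=0.0))
        assert fixed.params.T_d == 0.0
        assert fixed.perfusion < free.perfusion
        assert fixed.gfr < free.gfr

    def test_fit_is_deterministic_for_a_seed(self, prepped_noiseless):
        prepped, _ = prepped_noiseless
        a = fit_kidney(prepped, FitOptions(seed=9))
        b = fit_kidney(prepped, FitOptions(seed=9))
        assert a.params == b.params

    def test_gfr_invariant_holds_exactly(self, fit_noiseless):
        result, _ = fit_noiseless
        kidney, _ = make_kidney(SyntheticSpec(noise_sd=0.0))
        assert result.gfr == result.params.k_GFR * kidney.volume * 60.0

    def test_mismatched_grids_rejected(self, noiseless_kidney):
        kidney, _ = noiseless_kidney
        with pytest.raises(ValueError):
            fit_kidney(kidney)  # raw two-phase grids, not preprocessed
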