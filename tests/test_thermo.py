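import numpy as np
import pandas as pd
import pytest

from coldsense.synth import ChannelModelParams, simulate_current_trace
from coldsense.thermo import (
    KELVIN_OFFSET,
    CurrentTrace,
    arrhenius_transform,
    compute_fold_activation,
    compute_inhibition,
    compute_q10,
    extract_current_at_voltage,
    fit_threshold,
    fold_from_ramp_pair,
    q10_to_slope,
)


def _arrhenius_trace(slope, n=200, t_lo=10.0, t_hi=37.0, intercept=0.0):
    """Current exactly following one Arrhenius line."""
    temp = np.linspace(t_hi, t_lo, n)
    x = 1.0 / (temp + KELVIN_OFFSET)
    current = np.exp(intercept + slope * x)
    return CurrentTrace(times=np.arange(n, dtype=float), current=current, temperature=temp)


class TestArrheniusTransform:
    def test_exact_arrhenius_law_is_colinear(self):
        arr = arrhenius_transform(_arrhenius_trace(slope=5000.0))
        r = np.corrcoef(arr["inv_TK"], arr["ln_I"])[0, 1]
        assert r**2 > 1.0 - 1e-10

    def test_constant_current_zero_slope(self):
        arr = arrhenius_transform(_arrhenius_trace(slope=0.0))
        assert np.ptp(arr["ln_I"]) == pytest.approx(0.0, abs=1e-12)

    def test_mixed_sign_current_rejected(self):
        tr = _arrhenius_trace(slope=0.0)
        tr.current[0] = -1.0
        with pytest.raises(ValueError, match="sign"):
            arrhenius_transform(tr)

    def test_binning_deweights_dwell_time(self):
        # long dwell at one temperature collapses to a single grid point
        temp = np.concatenate([np.full(500, 20.0), np.linspace(35.0, 10.0, 50)])
        cur = np.exp(1000.0 / (temp + KELVIN_OFFSET))
        tr = CurrentTrace(times=np.arange(temp.size, dtype=float), current=cur, temperature=temp)
        arr = arrhenius_transform(tr, bin_width_C=0.5)
        assert (np.abs(arr["temp_C"] - 20.0) < 0.25).sum() == 1


class TestFitThreshold:
    def test_constructed_breakpoint_at_24C_recovered(self):
        temp = np.linspace(37.0, 10.0, 400)
        x = 1.0 / (temp + KELVIN_OFFSET)
        xb = 1.0 / (24.0 + KELVIN_OFFSET)
        y = 800.0 * x + 12000.0 * np.maximum(0.0, x - xb)
        tr = CurrentTrace(times=np.arange(400, dtype=float), current=np.exp(y - 6),
                          temperature=temp)
        fit = fit_threshold(arrhenius_transform(tr))
        assert fit.has_threshold
        assert fit.threshold_T == pytest.approx(24.0, abs=0.1)

    def test_single_slope_data_flagged_monophasic(self):
        fit = fit_threshold(arrhenius_transform(_arrhenius_trace(slope=4000.0)))
        assert not fit.has_threshold
        assert np.isnan(fit.threshold_T)

    def test_too_few_points_rejected(self):
        arr = arrhenius_transform(_arrhenius_trace(slope=100.0, n=6, t_lo=20.0, t_hi=22.0))
        with pytest.raises(ValueError, match="spanning"):
            fit_threshold(arr)

    @pytest.mark.parametrize("noise_sd", [2e-4, 5e-4, 1e-3])
    def test_estimator_approaches_truth_as_noise_shrinks(self, broad_protocol, noise_sd):
        errs = []
        for seed in range(8):
            params = ChannelModelParams(noise_sd=noise_sd, threshold_T=22.4,
                                        q10_below=6.5, seed=seed)
            trace, _ = simulate_current_trace(params, broad_protocol, cgmp_uM=1.0)
            fit = fit_threshold(arrhenius_transform(trace))
            errs.append(abs(fit.threshold_T - 22.4))
        assert np.mean(errs) < 1.0 + 2.0 * noise_sd / 2e-4  # looser at higher noise
        if noise_sd == 2e-4:
            assert np.mean(errs) < 0.3


class TestQ10:
    def test_doubling_per_10C_gives_q10_of_2(self):
        slope = q10_to_slope(2.0, t_ref_c=20.0)
        assert compute_q10(slope, t_ref_c=20.0) == pytest.approx(2.0)

    def test_flat_current_gives_unity(self):
        assert compute_q10(0.0, t_ref_c=20.0) == pytest.approx(1.0)

    def test_q10_agrees_with_fitted_line_ratio_oracle(self):
        # oracle: evaluate the fitted Arrhenius line at T and T-10 and take the ratio
        slope = 9000.0
        arr = arrhenius_transform(_arrhenius_trace(slope=slope))
        coef = np.polyfit(arr["inv_TK"], arr["ln_I"], 1)
        t_ref = 25.0
        line = lambda tc: np.polyval(coef, 1.0 / (tc + KELVIN_OFFSET))
        oracle = np.exp(line(t_ref - 10.0) - line(t_ref))
        assert compute_q10(coef[0], t_ref) == pytest.approx(oracle, rel=1e-2)

    def test_folds_compose_over_two_adjacent_spans(self):
        slope = q10_to_slope(3.0, t_ref_c=25.0)
        # fold over a 20 degC span equals the product of the two 10 degC folds
        x = lambda tc: 1.0 / (tc + KELVIN_OFFSET)
        fold20 = np.exp(slope * (x(5.0) - x(25.0)))
        fold_a = np.exp(slope * (x(15.0) - x(25.0)))
        fold_b = np.exp(slope * (x(5.0) - x(15.0)))
        assert fold20 == pytest.approx(fold_a * fold_b, rel=1e-12)


class TestFoldActivation:
    @pytest.mark.parametrize("ic,iw,expected", [(4.0, 1.0, 4.0), (2.5, 2.5, 1.0)])
    def test_simple_ratios(self, ic, iw, expected):
        assert compute_fold_activation(ic, iw).fold == pytest.approx(expected)

    def test_leak_subtraction_recovers_true_fold(self):
        # true channel currents 4 and 1; shared leak of 2 biases the raw ratio
        fa_raw = compute_fold_activation(4.0 + 2.0, 1.0 + 2.0)
        fa_corr = compute_fold_activation(4.0 + 2.0, 1.0 + 2.0, leak_cold=2.0, leak_warm=2.0)
        assert fa_corr.fold == pytest.approx(4.0)
        assert fa_raw.fold != pytest.approx(4.0)
        assert fa_corr.leak_corrected

    def test_zero_warm_current_flagged_undefined(self):
        fa = compute_fold_activation(4.0, 0.0)
        assert not fa.defined and np.isnan(fa.fold)

    def test_reversibility_on_cool_rewarm_protocol(self):
        from coldsense.protocols import make_temperature_protocol

        prot = make_temperature_protocol("step_pair", duration_s=300.0)
        params = ChannelModelParams(noise_sd=0.0, seed=0)
        trace, _ = simulate_current_trace(params, prot, cgmp_uM=1.0)
        t = trace.times

        def level(name):
            a0, a1 = trace.annotations[name]
            return float(np.mean(trace.current[(t >= a0) & (t <= a1)]))

        fold_cool = compute_fold_activation(level("cold"), level("warm")).fold
        fold_rewarm = compute_fold_activation(level("cold"), level("rewarm")).fold
        assert fold_cool == pytest.approx(fold_rewarm, rel=1e-6)


class TestExtractCurrentAtVoltage:
    def _ramp(self, poly):
        v = np.linspace(-100.0, 100.0, 1000)
        return CurrentTrace(
            times=np.arange(v.size, dtype=float),
            current=np.polyval(poly, v),
            temperature=np.full(v.size, 22.0),
            voltage=v,
        )

    def test_linear_iv_through_origin(self):
        tr = self._ramp([0.05, 0.0])
        assert extract_current_at_voltage(tr, 60.0) == pytest.approx(3.0)

    def test_voltage_beyond_ramp_rejected(self):
        with pytest.raises(ValueError, match="outside ramp"):
            extract_current_at_voltage(self._ramp([1.0, 0.0]), 150.0)

    def test_polynomial_iv_interpolation_error_below_half_percent(self):
        poly = [1e-5, 2e-3, 0.04, 1.0]
        tr = self._ramp(poly)
        for v in (-55.3, 12.7, 60.0, 88.8):
            exact = np.polyval(poly, v)
            assert extract_current_at_voltage(tr, v) == pytest.approx(exact, rel=5e-3)

    def test_fold_from_ramp_pair(self):
        cold = self._ramp([0.2, 0.0])
        warm = self._ramp([0.05, 0.0])
        fa = fold_from_ramp_pair(cold, warm, voltage_mV=60.0)
        assert fa.fold == pytest.approx(4.0)


class TestInhibition:
    def _trace(self, drug_depth):
        t = np.arange(0.0, 100.0, 0.1)
        cur = np.zeros_like(t)
        cur[t >= 20.0] = -2.0
        drug = (t >= 50.0) & (t < 70.0)
        cur[drug] = -2.0 + drug_depth
        return CurrentTrace(
            times=t, current=cur, temperature=np.full_like(t, 12.0),
            annotations={"pre_cold": (0.0, 19.0), "cold": (20.0, 49.0), "drug": (50.0, 69.0)},
        )

    def test_full_block_is_100_percent(self):
        pct, in_range = compute_inhibition(self._trace(drug_depth=2.0))
        assert pct == pytest.approx(100.0) and in_range

    def test_no_effect_is_0_percent(self):
        pct, in_range = compute_inhibition(self._trace(drug_depth=0.0))
        assert pct == pytest.approx(0.0) and in_range

    def test_heteromer_with_twice_the_block_depth(self):
        homo, _ = compute_inhibition(self._trace(drug_depth=0.6))
        hetero, _ = compute_inhibition(self._trace(drug_depth=1.2))
        assert hetero / homo == pytest.approx(2.0)

    def test_missing_annotation_rejected(self):
        tr = self._trace(1.0)
        del tr.annotations["drug"]
        with pytest.raises(ValueError, match="drug"):
            compute_inhibition(tr)
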