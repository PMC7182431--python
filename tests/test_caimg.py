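import numpy as np
import pytest

from coldsense.caimg import (
    CellAssessment,
    QCCriteria,
    apply_qc,
    assess_cell,
    classify_cell,
    compute_baseline_stats,
    compute_high_k_amplitude,
    compute_response_amplitude,
    select_collection_targets,
    summarize_coverslip,
)

from conftest import IMAGING_ANNOTATIONS, flat_trace


class TestBaselineStats:
    def test_constant_trace(self):
        mean, sd = compute_baseline_stats(flat_trace(fr_level=0.5))
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(0.0)

    def test_alternating_values_match_direct_formula(self):
        tr = flat_trace()
        tr.fr[:200] = np.where(np.arange(200) % 2 == 0, 0.4, 0.6)
        mean, sd = compute_baseline_stats(tr)
        window = tr.fr[tr.times < 45.0]
        exp_mean = window.sum() / window.size
        exp_sd = np.sqrt(((window - exp_mean) ** 2).sum() / (window.size - 1))
        assert mean == pytest.approx(exp_mean)
        assert sd == pytest.approx(exp_sd)

    def test_noisy_baseline_estimates_within_3_standard_errors(self):
        rng = np.random.default_rng(7)
        tr = flat_trace()
        tr.fr[:45] = rng.normal(0.5, 0.02, size=45)
        mean, sd = compute_baseline_stats(tr)
        assert abs(mean - 0.5) < 3 * 0.02 / np.sqrt(45)
        assert abs(sd - 0.02) < 3 * 0.02 / np.sqrt(2 * 44)

    def test_short_recording_rejected(self):
        tr = flat_trace()
        short = tr.times < 30
        with pytest.raises(ValueError, match="extends past"):
            compute_baseline_stats(
                type(tr)(cell_id="s", times=tr.times[short], fr=tr.fr[short],
                         annotations=tr.annotations)
            )


class TestResponseAmplitude:
    def test_peak_minus_baseline(self):
        tr = flat_trace(fr_level=0.5, response_peak=1.2)
        assert compute_response_amplitude(tr) == pytest.approx(0.7)

    def test_flat_trace_zero(self):
        assert compute_response_amplitude(flat_trace(high_k_level=0.5)) == pytest.approx(0.0)

    @pytest.mark.parametrize("lag_s,included", [(10.0, True), (11.0, False)])
    def test_10s_grace_window_boundary(self, lag_s, included):
        ramp_end = IMAGING_ANNOTATIONS["ramp"][1]
        tr = flat_trace(response_peak=1.5, peak_t=ramp_end + lag_s)
        amp = compute_response_amplitude(tr)
        assert amp == pytest.approx(1.0 if included else 0.0)

    def test_missing_ramp_annotation_rejected(self):
        tr = flat_trace()
        del tr.annotations["ramp"]
        with pytest.raises(ValueError, match="ramp"):
            compute_response_amplitude(tr)


class TestHighKAmplitude:
    def test_peak_minus_pre_epoch_mean(self):
        tr = flat_trace(fr_level=0.5, high_k_level=1.3)
        assert compute_high_k_amplitude(tr) == pytest.approx(0.8)

    def test_flat_trace_zero(self):
        assert compute_high_k_amplitude(flat_trace(high_k_level=0.5)) == pytest.approx(0.0)

    def test_insufficient_pre_epoch_rejected(self):
        t = np.arange(0.0, 60.0)
        tr_args = dict(times=t, fr=np.full_like(t, 0.5))
        from coldsense.caimg import RatioTrace

        tr = RatioTrace(cell_id="x", annotations={"high_k": (0.0, 30.0)}, **tr_args)
        with pytest.raises(ValueError, match="precede"):
            compute_high_k_amplitude(tr)


class TestQC:
    def test_baseline_mean_just_over_threshold_fails_named(self):
        tr = flat_trace(fr_level=0.71, high_k_level=1.5)
        qc_pass, failures, _ = apply_qc(tr)
        assert not qc_pass
        assert failures == ["baseline_mean"]

    def test_inclusive_boundaries_pass(self):
        # baseline mean exactly 0.7 and High-K amplitude exactly 0.5
        tr = flat_trace(fr_level=0.7, high_k_level=1.2)
        qc_pass, failures, _ = apply_qc(tr)
        assert qc_pass and failures == []

    def test_all_four_criteria_reported(self):
        tr = flat_trace(fr_level=0.8, high_k_level=0.85)
        rng = np.random.default_rng(0)
        tr.fr[:45] += rng.normal(0, 0.2, 45)  # noisy baseline
        tr.fr[(tr.times >= 100) & (tr.times < 200)] = 1.6  # no recovery
        tr.fr = np.clip(tr.fr, 0, None)
        _, failures, _ = apply_qc(tr)
        assert len(failures) == 4

    def test_recovery_uses_absolute_difference(self):
        # signal settles 0.6 units BELOW baseline: symmetric drift disqualifies
        tr = flat_trace(fr_level=0.65, high_k_level=1.2)
        tr.fr[(tr.times >= 100) & (tr.times < 200)] = 0.05
        _, failures, _ = apply_qc(tr)
        assert "recovery" in failures


class TestClassification:
    @pytest.mark.parametrize(
        "amplitude,expected",
        [(0.575, "sensitive"), (0.574, "insensitive"), (2.0, "sensitive")],
    )
    def test_inclusive_amplitude_threshold(self, amplitude, expected):
        tr = flat_trace(fr_level=0.5, response_peak=0.5 + amplitude)
        assert assess_cell(tr).cell_class == expected

    def test_qc_failure_takes_precedence(self):
        a = CellAssessment(
            cell_id="c", coverslip_id="cs", baseline_mean=0.8, baseline_sd=0.01,
            response_amplitude=2.0, high_k_amplitude=1.0, recovery_diff=0.0,
            qc_pass=False, qc_failures=["baseline_mean"],
        )
        assert classify_cell(a) == "excluded"

    def test_partition_into_three_classes(self):
        traces = [
            flat_trace(fr_level=0.5, response_peak=1.5, cell_id="sens"),
            flat_trace(fr_level=0.5, cell_id="insens"),
            flat_trace(fr_level=0.75, cell_id="excl"),
        ]
        classes = {assess_cell(t).cell_class for t in traces}
        assert classes == {"sensitive", "insensitive", "excluded"}

    def test_raising_threshold_never_increases_sensitive_count(self):
        rng = np.random.default_rng(11)
        traces = [
            flat_trace(fr_level=0.5, response_peak=0.5 + rng.uniform(0, 1.2),
                       cell_id=f"c{i}")
            for i in range(30)
        ]
        counts = []
        for thr in (0.3, 0.575, 0.9):
            counts.append(
                sum(assess_cell(t, threshold_fr=thr).cell_class == "sensitive"
                    for t in traces)
            )
        assert counts == sorted(counts, reverse=True)


def _assessment(cell_id, amplitude, qc_pass=True):
    return CellAssessment(
        cell_id=cell_id, coverslip_id="cs", baseline_mean=0.5, baseline_sd=0.01,
        response_amplitude=amplitude, high_k_amplitude=1.0, recovery_diff=0.0,
        qc_pass=qc_pass, qc_failures=[] if qc_pass else ["baseline_mean"],
        cell_class=("sensitive" if qc_pass and amplitude >= 0.575
                    else "insensitive" if qc_pass else "excluded"),
    )


class TestCoverslipSummary:
    def test_percentage_over_qc_passing_cells(self):
        a = [_assessment(f"c{i}", 1.0 if i < 7 else 0.1) for i in range(63)]
        s = summarize_coverslip(a)
        assert s.pct_sensitive == pytest.approx(100.0 * 7 / 63)

    def test_zero_sensitive(self):
        a = [_assessment(f"c{i}", 0.1) for i in range(50)]
        assert summarize_coverslip(a).pct_sensitive == pytest.approx(0.0)

    def test_zero_passing_flagged_nan(self):
        a = [_assessment(f"c{i}", 1.0, qc_pass=False) for i in range(5)]
        with pytest.warns(UserWarning, match="zero QC-passing"):
            s = summarize_coverslip(a)
        assert np.isnan(s.pct_sensitive)
        assert s.n_pass_qc == 0


class TestCollectionTargets:
    def test_top7_bottom14_counts(self):
        a = [_assessment(f"c{i:03d}", i / 100.0) for i in range(100)]
        top, bottom = select_collection_targets(a)
        assert len(top) == 7 and len(bottom) == 14
        assert set(top) == {f"c{i:03d}" for i in range(93, 100)}
        assert set(bottom) == {f"c{i:03d}" for i in range(14)}
        assert not set(top) & set(bottom)

    def test_all_equal_amplitudes_tie_break_by_input_order(self):
        a = [_assessment(f"c{i}", 0.5) for i in range(100)]
        top, bottom = select_collection_targets(a)
        assert top == [f"c{i}" for i in range(7)]
        assert bottom[0] == "c7"  # first non-top cell in input order

    def test_small_n_floors_with_minimum_one(self):
        a = [_assessment(f"c{i}", i * 0.1) for i in range(7)]
        with pytest.warns(UserWarning):
            top, bottom = select_collection_targets(a)
        assert len(top) == 1 and len(bottom) == 1
        assert not set(top) & set(bottom)
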