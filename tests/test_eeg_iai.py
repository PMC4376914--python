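import numpy as np
import pandas as pd
import pytest

from riskimagery import (
    IAITable,
    Segment,
    aggregate_iai,
    alpha_power,
    bandpass_filter,
    compute_iai,
    epoch_and_reject,
    gen_study3,
    iai_table_from_recording,
)
from riskimagery.exceptions import (
    CoverageError,
    DegenerateDataError,
    ParameterError,
    SegmentError,
)
from riskimagery.synthetic_data import Study3Config

FS = 200.0


def sinusoid(freq, amp=1.0, seconds=30.0, fs=FS, phase=0.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestBandpassFilter:
    def test_inband_10hz_amplitude_preserved(self):
        x = sinusoid(10.0, amp=5.0, seconds=60)
        y = bandpass_filter(x, FS)
        core = slice(2000, -2000)  # avoid edge transients
        ratio = y[core].std() / x[core].std()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_50hz_attenuated_at_least_90_percent(self):
        x = sinusoid(50.0, amp=5.0, seconds=60)
        y = bandpass_filter(x, FS)
        assert y[2000:-2000].std() <= 0.1 * x[2000:-2000].std()

    def test_dc_offset_removed(self):
        x = np.full(int(60 * FS), 7.5)
        y = bandpass_filter(x, FS)
        assert np.abs(y[2000:-2000]).max() < 0.05

    def test_output_length_equals_input_length(self):
        x = sinusoid(10.0, seconds=10)
        assert bandpass_filter(x, FS).shape == x.shape

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            bandpass_filter(sinusoid(10.0), FS, high=100.0)


class TestEpoching:
    def test_30s_segment_yields_15_epochs_of_400_samples(self):
        x = sinusoid(10.0, seconds=30)
        es = epoch_and_reject(x, FS)
        assert es.epochs.shape == (15, 400)
        assert es.kept_mask.all()

    def test_partial_trailing_window_discarded_no_sample_reused(self):
        x = sinusoid(10.0, seconds=31.5)
        es = epoch_and_reject(x, FS)
        assert es.n_epochs == 15  # 31.5 s -> 15 full 2 s epochs
        assert es.n_epochs * 400 <= len(x)

    def test_threshold_rejects_spike_and_keeps_capped_epoch(self):
        x = sinusoid(10.0, amp=30.0, seconds=4)
        spike = x.copy()
        spike[100] = 100.0
        es = epoch_and_reject(spike, FS)
        assert not es.kept_mask[0] and es.kept_mask[1]
        capped = x.copy()
        capped[100] = 69.0
        assert epoch_and_reject(capped, FS).kept_mask.all()

    def test_segment_shorter_than_one_epoch_rejected(self):
        with pytest.raises(SegmentError):
            epoch_and_reject(sinusoid(10.0, seconds=1.5), FS)

    def test_peak_to_peak_criterion(self):
        x = sinusoid(10.0, amp=40.0, seconds=2)  # p2p = 80 > 70, |x| <= 40
        assert epoch_and_reject(x, FS, criterion="absolute").kept_mask.all()
        assert not epoch_and_reject(x, FS, criterion="peak_to_peak").kept_mask.any()

    def test_injected_artifact_rate_recovered(self):
        cfg = Study3Config(n_subjects=1, n_scenarios=4, baseline_seconds=60.0, artifact_rate=0.05)
        rec = gen_study3(cfg, seed=11)["recordings"][0]
        total = kept = 0
        for ev in rec.events:
            es = epoch_and_reject(rec.channel("O1"), FS, segment=ev)
            total += es.n_epochs
            kept += es.n_kept
        frac = 1 - kept / total
        # binomial(150, .05) three-sigma band
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / total)


class TestAlphaPower:
    def test_parseval_closed_form_for_pure_10hz(self):
        # one-sided periodogram of amplitude-A sinusoid at an exact bin:
        # density A^2/2 / df with df = 0.5 Hz -> A^2 at the 10 Hz bin; the
        # 8-13 Hz band holds 11 bins, so the band mean is A^2/11
        A = 4.0
        es = epoch_and_reject(sinusoid(10.0, amp=A, seconds=30), FS)
        p = alpha_power(es, FS).power
        assert p == pytest.approx(A**2 / 11.0, rel=0.01)

    def test_doubling_amplitude_quadruples_power(self):
        p1 = alpha_power(epoch_and_reject(sinusoid(10.0, amp=2.0, seconds=30), FS), FS).power
        p2 = alpha_power(epoch_and_reject(sinusoid(10.0, amp=4.0, seconds=30), FS), FS).power
        assert p2 / p1 == pytest.approx(4.0, rel=1e-6)

    def test_out_of_band_20hz_contributes_nothing(self):
        es = epoch_and_reject(sinusoid(20.0, amp=5.0, seconds=30), FS)
        p10 = alpha_power(epoch_and_reject(sinusoid(10.0, amp=5.0, seconds=30), FS), FS).power
        assert alpha_power(es, FS).power < 1e-10 * p10

    def test_spectral_additivity(self):
        x = sinusoid(10.0, amp=3.0, seconds=30) + sinusoid(20.0, amp=5.0, seconds=30)
        p_sum = alpha_power(epoch_and_reject(x, FS), FS).power
        p_10 = alpha_power(epoch_and_reject(sinusoid(10.0, amp=3.0, seconds=30), FS), FS).power
        assert p_sum == pytest.approx(p_10, rel=0.01)

    def test_all_epochs_rejected_raises_with_counts(self):
        x = sinusoid(10.0, amp=200.0, seconds=10)
        es = epoch_and_reject(x, FS)
        with pytest.raises(DegenerateDataError, match="5"):
            alpha_power(es, FS)


class TestIAI:
    @pytest.mark.parametrize(
        "base,task,expected", [((2.0, 2.0), (2.0, 2.0), 1.0), ((4.0, 4.0), (2.0, 2.0), 2.0)]
    )
    def test_identities(self, base, task, expected):
        assert compute_iai(base, task) == pytest.approx(expected)

    def test_amplitude_halved_gives_iai_4(self):
        pb = alpha_power(epoch_and_reject(sinusoid(10.0, amp=10.0, seconds=30), FS), FS).power
        pt = alpha_power(epoch_and_reject(sinusoid(10.0, amp=5.0, seconds=30), FS), FS).power
        assert compute_iai((pb, pb), (pt, pt)) == pytest.approx(4.0, rel=0.01)

    def test_zero_power_rejected(self):
        with pytest.raises(DegenerateDataError):
            compute_iai((1.0, 1.0), (0.0, 1.0))

    def test_monotone_decreasing_in_task_power(self):
        vals = [compute_iai((3.0, 3.0), (t, t)) for t in (1.0, 2.0, 3.0, 4.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_scale_invariance_of_full_chain(self, small_study3):
        # scaling the recording and the artifact threshold by the same
        # constant leaves every IAI unchanged (the power ratio cancels the
        # scale; the threshold must follow it or the rejected set changes)
        rec = small_study3["recordings"][0]
        tab1 = iai_table_from_recording(rec)
        rec2 = type(rec)(
            subject_id=rec.subject_id,
            sampling_rate=rec.sampling_rate,
            channels=rec.channels,
            signal=rec.signal * 3.7,
            events=rec.events,
        )
        tab2 = iai_table_from_recording(rec2, threshold=70.0 * 3.7)
        merged = tab1.df.merge(tab2.df, on=["subject_id", "electrode", "domain", "phase"])
        np.testing.assert_allclose(merged["iai_x"], merged["iai_y"], rtol=1e-9)


class TestAggregate:
    def _table(self, iais):
        rows = []
        for el, v in iais.items():
            rows.append(
                {"subject_id": "s1", "electrode": el, "domain": "financial",
                 "phase": "visualization", "iai": v}
            )
        return IAITable(pd.DataFrame(rows))

    def test_arithmetic_mean_over_imagery_sites(self):
        tab = self._table({"O1": 1.00, "O2": 1.02, "P3": 1.04, "P4": 1.06})
        agg = aggregate_iai(tab)
        assert agg["iai_mean"].iloc[0] == pytest.approx(1.03)

    def test_equal_iais_pass_through(self):
        tab = self._table({"O1": 1.05, "O2": 1.05, "P3": 1.05, "P4": 1.05})
        assert aggregate_iai(tab)["iai_mean"].iloc[0] == pytest.approx(1.05)

    def test_missing_electrode_is_coverage_error(self):
        tab = self._table({"O1": 1.0, "O2": 1.0, "P3": 1.0})
        with pytest.raises(CoverageError, match="P4"):
            aggregate_iai(tab)
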