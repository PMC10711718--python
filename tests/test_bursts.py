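import numpy as np
import pytest

from betaburst.bursts import (Burst, DetectionConfig, burst_duration_cycles,
                              detect_bursts, extract_waveform)
from betaburst.spectral import FrequencyBand
from betaburst.tf import TFMatrix

SFREQ = 500.0
BAND = FrequencyBand(18.0, 26.0, 22.0, label="beta")


def make_tf(amplitude, f_lo=13.0, f_step=0.5, sfreq=SFREQ):
    n_f, n_t = amplitude.shape
    return TFMatrix(
        times=np.arange(n_t) / sfreq,
        frequencies=f_lo + f_step * np.arange(n_f),
        amplitude=amplitude,
        valid=np.ones((n_f, n_t), dtype=bool),
    )


def blob(n_f, n_t, fi, ti, amp, sig_f, sig_t):
    f = np.arange(n_f)[:, None]
    t = np.arange(n_t)[None, :]
    return amp * np.exp(-((f - fi) ** 2) / (2 * sig_f**2)
                        - ((t - ti) ** 2) / (2 * sig_t**2))


class TestDetect:
    def test_all_zero_tf_empty(self):
        tf = make_tf(np.zeros((30, 500)))
        assert detect_bursts(tf, None, DetectionConfig(band=BAND)) == []

    def test_single_blob_recovered(self, rng):
        n_f, n_t = 35, 900
        noise = np.abs(0.05 * rng.standard_normal((n_f, n_t)))
        sig_f, sig_t = 4.0, 40.0
        amp = 10 * 0.05
        tf = make_tf(noise + blob(n_f, n_t, 18, 450, amp, sig_f, sig_t))
        bursts = detect_bursts(tf, None, DetectionConfig(band=BAND))
        strong = [b for b in bursts if b.residual_amplitude > amp / 2]
        assert len(strong) == 1
        b = strong[0]
        assert abs(b.peak_freq - (13.0 + 18 * 0.5)) <= 0.5
        assert abs(b.peak_time - 450 / SFREQ) <= 1 / SFREQ + 1e-12
        assert b.fwhm_time == pytest.approx(2.355 * sig_t / SFREQ, rel=0.2)
        assert b.fwhm_freq == pytest.approx(2.355 * sig_f * 0.5, rel=0.2)

    def test_out_of_band_peak_discarded(self, rng):
        """A blob at band_high + 2 Hz sits inside the padded search window,
        is detected and removed, but is not returned."""
        n_f, n_t = 37, 600  # 13 .. 31 Hz
        noise = np.abs(0.02 * rng.standard_normal((n_f, n_t)))
        fi = int((BAND.high + 2.0 - 13.0) / 0.5)
        tf = make_tf(noise + blob(n_f, n_t, fi, 300, 1.0, 3.0, 30.0))
        bursts = detect_bursts(tf, None, DetectionConfig(band=BAND))
        assert all(BAND.low < b.peak_freq < BAND.high for b in bursts)
        assert not any(b.peak_amplitude > 0.5 for b in bursts)

    def test_masked_tf_empty(self):
        tf = make_tf(np.ones((30, 500)))
        tf.valid[:] = False
        assert detect_bursts(tf, None, DetectionConfig(band=BAND)) == []

    def test_amplitude_from_presubtraction_matrix(self, rng):
        """Reported amplitude is the aperiodic-subtracted value before any
        Gaussian removal, so overlapping removals cannot deflate it."""
        n_f, n_t = 35, 900
        noise = np.abs(0.02 * rng.standard_normal((n_f, n_t)))
        base = noise + blob(n_f, n_t, 18, 300, 1.0, 3.5, 30.0) \
                     + blob(n_f, n_t, 18, 600, 0.8, 3.5, 30.0)
        tf = make_tf(base.copy())
        bursts = detect_bursts(tf, None, DetectionConfig(band=BAND))
        for b in bursts:
            ti = int(round(b.peak_time * SFREQ))
            fi = int(round((b.peak_freq - 13.0) / 0.5))
            assert b.peak_amplitude == pytest.approx(base[fi, ti])

    def test_residual_amplitude_monotone_in_order(self, rng):
        n_f, n_t = 35, 900
        field = np.abs(rng.standard_normal((n_f, n_t))) \
            + blob(n_f, n_t, 18, 450, 8.0, 4.0, 40.0)
        tf = make_tf(field)
        bursts = detect_bursts(tf, None, DetectionConfig(band=BAND))
        res = [b.residual_amplitude for b in sorted(bursts,
                                                    key=lambda b: b.order)]
        assert all(x >= y - 1e-9 for x, y in zip(res, res[1:]))


class TestDurationCycles:
    def test_dimensional_identity(self):
        b = Burst(peak_time=0, peak_freq=20.0, peak_amplitude=1,
                  fwhm_time=0.2, fwhm_freq=2.0, order=0)
        assert burst_duration_cycles(b) == pytest.approx(4.0)

    def test_zero_duration(self):
        b = Burst(peak_time=0, peak_freq=20.0, peak_amplitude=1,
                  fwhm_time=0.0, fwhm_freq=2.0, order=0)
        assert burst_duration_cycles(b) == 0.0

    def test_injected_cycle_count_recovered(self):
        """A 5-cycle injected burst's measured TF duration matches the
        analytic wavelet-broadened envelope FWHM within +-1 cycle."""
        from betaburst.tf import expected_tf_duration, superlet_tf

        n = 3000
        t = (np.arange(n) - n // 2) / SFREQ
        f0, cycles = 21.5, 5.0
        sigma = cycles / f0 / 2.355
        x = -10 * np.cos(2 * np.pi * f0 * t) * np.exp(-(t**2) / (2 * sigma**2))
        tf = superlet_tf(x, SFREQ, freqs=np.arange(13.0, 31.0, 0.5),
                         tmin=-n / 2 / SFREQ)
        bursts = detect_bursts(tf, None, DetectionConfig(band=BAND))
        main = max(bursts, key=lambda b: b.peak_amplitude)
        expected_cycles = expected_tf_duration(f0, cycles) * f0
        assert burst_duration_cycles(main) == pytest.approx(expected_cycles,
                                                            abs=1.0)


class TestExtractWaveform:
    def trial_with_burst(self, invert=False, f0=21.0, n=1800):
        t = (np.arange(n) - n // 2) / SFREQ
        sigma = 5 / f0 / 2.355
        wave = -8 * np.cos(2 * np.pi * f0 * t) * np.exp(-(t**2) / (2 * sigma**2))
        if invert:
            wave = -wave
        return wave, Burst(peak_time=0.0, peak_freq=f0, peak_amplitude=5.0,
                           fwhm_time=0.24, fwhm_freq=3.0, order=0)

    def test_alignment_minimum_at_center(self):
        x, burst = self.trial_with_burst()
        out = extract_waveform(x, np.zeros_like(x), burst, 101, SFREQ,
                               tmin=-1.8)
        assert out is not None
        assert np.argmin(out.waveform) == 50
        assert not out.polarity_flipped

    def test_central_deflection_nonpositive_either_polarity(self):
        """Sign normalization: whatever the source polarity, the aligned
        waveform's central deflection is non-positive (an inverted burst
        trough-aligns half a period off, so its center is still a trough)."""
        x, burst = self.trial_with_burst()
        xi, burst_i = self.trial_with_burst(invert=True)
        a = extract_waveform(x, np.zeros_like(x), burst, 101, SFREQ, tmin=-1.8)
        b = extract_waveform(xi, np.zeros_like(xi), burst_i, 101, SFREQ,
                             tmin=-1.8)
        assert a.waveform[50] <= 0
        assert b.waveform[50] <= 0

    def test_positive_raw_center_flipped(self):
        """A slow oscillation pushing the raw center above the window mean
        triggers the sign flip; the band-passed trough alignment is
        unaffected because the slow component is filtered out."""
        x, burst = self.trial_with_burst()
        t = (np.arange(len(x)) - len(x) // 2) / SFREQ
        slow = 30.0 * np.cos(2 * np.pi * 3.0 * t)
        out = extract_waveform(x + slow, np.zeros_like(x), burst, 101, SFREQ,
                               tmin=-1.8)
        assert out is not None
        assert out.polarity_flipped
        assert out.waveform[50] <= 0

    def test_far_phase_minimum_discarded(self):
        """When the nearest trough is >30 ms from the TF peak time the burst
        is dropped: place the claimed peak time between troughs' reach."""
        x, burst = self.trial_with_burst(f0=6.0)
        # at 6 Hz troughs and crests alternate every 83 ms; a claimed peak
        # 40 ms off-phase is > 30 ms from every extremum
        burst.peak_time = 0.040
        burst.peak_freq = 6.0
        out = extract_waveform(x, np.zeros_like(x), burst, 101, SFREQ,
                               tmin=-1.8, tolerance_ms=30.0)
        assert out is None

    def test_window_beyond_edge_discarded(self):
        x, burst = self.trial_with_burst()
        burst.peak_time = -1.79
        out = extract_waveform(x, np.zeros_like(x), burst, 201, SFREQ,
                               tmin=-1.8)
        assert out is None

    def test_dc_offset_removed(self):
        x, burst = self.trial_with_burst()
        out = extract_waveform(x + 40.0, np.zeros_like(x), burst, 101, SFREQ,
                               tmin=-1.8)
        assert abs(out.waveform.mean()) < 1e-9

    def test_erp_subtraction_applied(self):
        x, burst = self.trial_with_burst()
        erp = 5.0 * np.sin(2 * np.pi * 0.5 * np.arange(len(x)) / SFREQ)
        out_with = extract_waveform(x + erp, erp, burst, 101, SFREQ, tmin=-1.8)
        out_clean = extract_waveform(x, np.zeros_like(x), burst, 101, SFREQ,
                                     tmin=-1.8)
        assert np.allclose(out_with.waveform, out_clean.waveform, atol=1e-9)


def test_recovery_on_synthetic_dataset(sparse_dataset, spectral_model,
                                       detection_products):
    """High-SNR sparse bursts: recall >= 0.9, FDR <= 0.1 for detections above
    the amplitude-qualification threshold (time/freq tolerances 50 ms, 2 Hz)."""
    from betaburst.tf import expected_tf_amplitude
    from betaburst.validation import match_recovery

    cfg, _, truth = sparse_dataset
    catalog, _ = detection_products
    a_weak = cfg.burst_amplitude_mean - 2 * cfg.burst_amplitude_sd
    c_weak = cfg.burst_duration_mean - 2 * cfg.burst_duration_sd
    thr = 0.5 * expected_tf_amplitude(a_weak, cfg.beta_center, c_weak)
    m = match_recovery(catalog, truth.table, tol_time=0.05, tol_freq=2.0,
                       min_residual_amplitude=thr,
                       valid_interval=(-0.85, 0.85))
    assert m.recall >= 0.9
    assert m.fdr <= 0.1
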