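"""Lagged coherence: distinguishing sustained rhythms from transient bursts.

Lagged coherence measures how well the phase of a band-limited signal
predicts its own phase a fixed number of cycles later. For each frequency
``f`` and lag ``l`` (in cycles), the trial is tiled with 50%-overlapping
Hann-tapered segments of width ``l/f`` seconds; the Fourier coefficient at
``f`` is taken in each segment, and coherence is the magnitude of the sum
over segment pairs separated by exactly ``l/f`` seconds of
``F(t) * conj(F(t + l/f))``, normalized by the geometric mean power of the
paired segments. A sustained oscillation keeps values near 1 across lags;
a transient burst loses phase predictability within a few cycles.

The FWHM in lag of the band-averaged profile sets the waveform-extraction
window for burst analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .containers import EpochSet
from .spectral import FWHM_PER_SIGMA, FrequencyBand


@dataclass
class LaggedCoherenceMap:
    frequencies: np.ndarray              # Hz
    lags: np.ndarray                     # cycles
    values: np.ndarray                   # (n_channels, n_freqs, n_lags), NaN = missing
    ch_names: list[str]
    normalization_max: float = 1.0       # divisor used for max-normalization

    def normalized(self) -> "LaggedCoherenceMap":
        """Divide by the maximum over all channels/frequencies/lags."""
        vmax = np.nanmax(self.values)
        if not np.isfinite(vmax) or vmax <= 0:
            raise ValueError("map has no finite positive values to normalize by")
        return LaggedCoherenceMap(
            frequencies=self.frequencies, lags=self.lags,
            values=self.values / vmax, ch_names=list(self.ch_names),
            normalization_max=float(vmax),
        )

    def band_profile(self, band: FrequencyBand) -> np.ndarray:
        """Lag profile averaged over channels and band frequencies.

        Missing cells are excluded from the average, not zero-filled.
        """
        sel = (self.frequencies >= band.low) & (self.frequencies <= band.high)
        if not sel.any():
            raise ValueError("band lies outside the map's frequency range")
        return np.nanmean(self.values[:, sel, :], axis=(0, 1))


def _segment_coefficients(x: np.ndarray, sfreq: float, f: float,
                          width_s: float) -> tuple[np.ndarray, int]:
    """Hann-windowed Fourier coefficients at ``f`` for 50%-overlap segments.

    Returns the coefficients for all segment start positions and the step
    (in segments) corresponding to one full segment width, i.e. the pair
    separation that realizes the requested lag.
    """
    n_seg = int(round(width_s * sfreq))
    step = n_seg // 2
    if n_seg < 4 or step < 1 or x.shape[-1] < n_seg + 2 * step:
        return np.empty((x.shape[0], 0), dtype=complex), 2
    n_starts = (x.shape[-1] - n_seg) // step + 1
    idx = np.arange(n_seg)
    window = np.hanning(n_seg)
    kernel = window * np.exp(-2j * np.pi * f * idx / sfreq)
    starts = np.arange(n_starts) * step
    segs = x[:, starts[:, None] + idx]              # (n_trials, n_starts, n_seg)
    return segs @ kernel, 2                         # pair separation = 2 steps


def lagged_coherence(epochs: EpochSet,
                     freqs: np.ndarray | None = None,
                     lags: np.ndarray | None = None,
                     normalize: bool = True) -> LaggedCoherenceMap:
    """Lagged-coherence map over frequency x lag for each channel.

    Cells whose segment tiling does not fit in the trial are NaN (missing),
    never zero. With ``normalize`` the map is divided by its maximum over
    all channels, frequencies, and lags (per-participant normalization when
    called on one participant's epochs).
    """
    if freqs is None:
        freqs = np.arange(5.0, 101.0, 1.0)
    if lags is None:
        lags = np.arange(2.0, 4.51, 0.1)
    freqs = np.asarray(freqs, dtype=float)
    lags = np.asarray(lags, dtype=float)
    values = np.full((epochs.n_channels, len(freqs), len(lags)), np.nan)
    for fi, f in enumerate(freqs):
        for li, lag in enumerate(lags):
            width_s = lag / f
            for ci in range(epochs.n_channels):
                coeffs, sep = _segment_coefficients(
                    epochs.data[:, ci, :], epochs.sfreq, f, width_s)
                if coeffs.shape[1] <= sep:
                    continue
                a = coeffs[:, :-sep]
                b = coeffs[:, sep:]
                num = np.abs(np.sum(a * np.conj(b)))
                den = np.sqrt(np.sum(np.abs(a) ** 2) * np.sum(np.abs(b) ** 2))
                if den > 0:
                    values[ci, fi, li] = num / den
    out = LaggedCoherenceMap(frequencies=freqs, lags=lags, values=values,
                             ch_names=list(epochs.ch_names))
    return out.normalized() if normalize else out


@dataclass
class WaveformWindow:
    cycles: float
    ms: float
    n_samples: int
    fallback: bool = False   # True when the lag profile never crossed half-max


def waveform_window(lc_map: LaggedCoherenceMap, band: FrequencyBand,
                    sfreq: float, clip_cycles: tuple[float, float] = (2.0, 8.0),
                    ) -> WaveformWindow:
    """Waveform-extraction window from the FWHM of band-averaged coherence.

    When the profile crosses half its maximum inside the lag range, the FWHM
    is read off by linear interpolation. The measured lag range (2-4.5
    cycles) often cannot contain the full width of a slowly decaying
    profile; in that case a Gaussian (centered at lag 0, since lagged
    coherence is symmetric in lag sign) is fit to the profile and its
    analytic FWHM used, clipped to ``clip_cycles`` and flagged.
    """
    profile = lc_map.band_profile(band)
    lags = lc_map.lags
    valid = np.isfinite(profile)
    if valid.sum() < 3:
        raise ValueError("band-averaged lag profile has too few valid cells")
    profile = profile[valid]
    lags = lags[valid]
    i_peak = int(np.argmax(profile))
    half = profile[i_peak] / 2
    l_peak = lags[i_peak]

    def _crossing(direction: int) -> float | None:
        i = i_peak
        while 0 <= i + direction < len(profile):
            j = i + direction
            if profile[j] < half:
                frac = (profile[i] - half) / (profile[i] - profile[j])
                return abs(lags[i] + frac * (lags[j] - lags[i]) - l_peak)
            i = j
        return None

    hw_left = _crossing(-1)
    hw_right = _crossing(+1)
    fallback = False
    boundary_peak = i_peak == 0 or i_peak == len(profile) - 1
    if hw_left is not None and hw_right is not None:
        fwhm_cycles = hw_left + hw_right
    elif not boundary_peak and (hw_left is not None or hw_right is not None):
        fwhm_cycles = 2 * (hw_left if hw_left is not None else hw_right)
    else:
        # the profile peaks at the edge of the measured lag range (a
        # decaying profile whose true peak lies below the first lag) or
        # never halves: fit a Gaussian to the whole profile and use its
        # analytic FWHM, clipped — this is how window lengths longer than
        # the lag range itself arise
        fallback = True

        def gauss(x, amp, mu, sigma):
            return amp * np.exp(-((x - mu) ** 2) / (2 * sigma**2))

        try:
            popt, _ = curve_fit(gauss, lags, profile,
                                p0=(profile.max(), 0.0, lags[-1]), maxfev=5000)
            fwhm_cycles = FWHM_PER_SIGMA * abs(popt[2])
        except RuntimeError:
            fwhm_cycles = clip_cycles[1]
        fwhm_cycles = float(np.clip(fwhm_cycles, *clip_cycles))
    ms = 1000.0 * fwhm_cycles / band.center
    n_samples = int(ms / 1000.0 * sfreq)
    return WaveformWindow(cycles=float(fwhm_cycles), ms=float(ms),
                          n_samples=n_samples, fallback=fallback)
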