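"""Power spectra, aperiodic/periodic decomposition, and band identification.

PSDs are computed with Welch's method (1 s Hamming windows, 50% overlap,
10x zero-padded oversampling, giving a 0.1 Hz grid). Each channel's
spectrum is split into an aperiodic 1/f component — fit as a line in
log-log space with iterative masking of narrowband peaks — and a periodic
residual (log10 power above the aperiodic fit). Group-level frequency
bands are then found by iteratively fitting and subtracting Gaussians from
the group-mean periodic spectrum until no peak exceeds the noise floor
(1 SD of the residual across all frequencies); band limits are the FWHM of
the fitted peak, and peaks are retained only if below 10 Hz with FWHM >= 1 Hz
or above 10 Hz with FWHM >= 3 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .containers import EpochSet

FWHM_PER_SIGMA = 2 * np.sqrt(2 * np.log(2))  # ~2.355


@dataclass
class PSD:
    frequencies: np.ndarray          # Hz, uniform 0.1 Hz grid
    power: np.ndarray                # (n_channels, n_freqs), µV²/Hz
    ch_names: list[str]
    welch_window: float = 1.0        # s
    overlap: float = 0.5
    oversampling: int = 10

    def __post_init__(self) -> None:
        steps = np.diff(self.frequencies)
        if len(steps) and not np.allclose(steps, steps[0], atol=1e-9):
            raise ValueError("frequency grid must be uniform")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class SpectralModel:
    frequencies: np.ndarray
    aperiodic_params: tuple[float, float]     # (offset log10-power, exponent)
    aperiodic_fit: np.ndarray                 # log10 power on `frequencies`
    periodic: np.ndarray                      # log10 power above the fit
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    noise_floor: float = 0.0                  # 1 SD of final residual

    @property
    def exponent(self) -> float:
        return self.aperiodic_params[1]

    def aperiodic_power(self, freqs: np.ndarray) -> np.ndarray:
        """Aperiodic fit evaluated at ``freqs``, in linear power units."""
        offset, exponent = self.aperiodic_params
        freqs = np.asarray(freqs, dtype=float)
        return 10**offset * np.maximum(freqs, 1e-6) ** (-exponent)


@dataclass
class FrequencyBand:
    low: float
    high: float
    center: float
    label: str = "other"

    def __post_init__(self) -> None:
        if not (self.low < self.center < self.high):
            raise ValueError("band must satisfy low < center < high")

    @property
    def width(self) -> float:
        return self.high - self.low


def compute_psd(epochs: EpochSet, fmin: float = 0.1, fmax: float = 100.0,
                window: float = 1.0, overlap: float = 0.5,
                oversampling: int = 10) -> PSD:
    """Per-channel Welch PSD averaged over trials, on a 0.1 Hz grid."""
    from mne.time_frequency import psd_array_welch

    n_per_seg = int(round(window * epochs.sfreq))
    if epochs.n_times < n_per_seg:
        raise ValueError("epoch shorter than the Welch window")
    power, freqs = psd_array_welch(
        epochs.data, epochs.sfreq, fmin=fmin, fmax=fmax,
        n_fft=n_per_seg * oversampling, n_per_seg=n_per_seg,
        n_overlap=int(round(n_per_seg * overlap)), remove_dc=True,
        verbose="error",
    )
    power = power.mean(axis=0) if power.ndim == 3 else power
    return PSD(frequencies=freqs, power=power, ch_names=list(epochs.ch_names),
               welch_window=window, overlap=overlap, oversampling=oversampling)


def parameterize(psd: PSD, fit_range: tuple[float, float] = (1.0, 90.0),
                 channel: int | str | None = None,
                 n_mask_iter: int = 3, mask_sd: float = 1.5) -> SpectralModel:
    """Split a PSD into aperiodic (1/f) and periodic components.

    The aperiodic component is a line in log10 power vs log10 frequency,
    fit by least squares with ``n_mask_iter`` rounds of masking points more
    than ``mask_sd`` residual SDs *above* the current fit (narrowband peaks
    must not drag the fit up). The periodic spectrum is the log-power
    residual above the fit.
    """
    if channel is None:
        power = psd.power.mean(axis=0)
    elif isinstance(channel, str):
        power = psd.power[psd.ch_names.index(channel)]
    else:
        power = psd.power[channel]
    if not np.all(np.isfinite(power)):
        raise ValueError("PSD contains non-finite power values")
    freqs = psd.frequencies
    sel = (freqs >= fit_range[0]) & (freqs <= fit_range[1]) & (power > 0)
    if sel.sum() < 4:
        raise ValueError("fit range leaves too few points")
    lf = np.log10(freqs[sel])
    lp = np.log10(power[sel])
    mask = np.ones(sel.sum(), dtype=bool)
    coef = np.polyfit(lf, lp, 1)
    for _ in range(n_mask_iter):
        resid = lp - np.polyval(coef, lf)
        sd = resid[mask].std()
        if sd == 0:
            break
        mask = resid < mask_sd * sd
        if mask.sum() < 4:
            break
        coef = np.polyfit(lf[mask], lp[mask], 1)
    exponent = -coef[0]
    offset = coef[1]
    fit_log = offset - exponent * np.log10(np.maximum(freqs[sel], 1e-12))
    periodic = np.log10(power[sel]) - fit_log
    return SpectralModel(
        frequencies=freqs[sel],
        aperiodic_params=(offset, exponent),
        aperiodic_fit=fit_log,
        periodic=periodic,
    )


def group_periodic_mean(models: list[SpectralModel]) -> SpectralModel:
    """Average periodic spectra over channels/participants (common grid)."""
    f0 = models[0].frequencies
    for m in models[1:]:
        if len(m.frequencies) != len(f0) or not np.allclose(m.frequencies, f0):
            raise ValueError("models must share a frequency grid")
    periodic = np.mean([m.periodic for m in models], axis=0)
    offset = float(np.mean([m.aperiodic_params[0] for m in models]))
    exponent = float(np.mean([m.aperiodic_params[1] for m in models]))
    fit = np.mean([m.aperiodic_fit for m in models], axis=0)
    return SpectralModel(frequencies=f0, aperiodic_params=(offset, exponent),
                         aperiodic_fit=fit, periodic=periodic)


def _gaussian(x, amp, center, sigma):
    return amp * np.exp(-((x - center) ** 2) / (2 * sigma**2))


def _fit_peak(freqs: np.ndarray, spectrum: np.ndarray, i_max: int):
    """Least-squares Gaussian fit on a window around the global maximum.

    The window spans +-2x the half-max half-width of the raw peak, which is
    robust on the 0.1 Hz grid. Returns (amp, center, sigma).
    """
    peak_h = spectrum[i_max]
    half = peak_h / 2
    left = i_max
    while left > 0 and spectrum[left] > half:
        left -= 1
    right = i_max
    while right < len(spectrum) - 1 and spectrum[right] > half:
        right += 1
    hw_bins = max(i_max - left, right - i_max, 2)
    lo = max(0, i_max - 2 * hw_bins)
    hi = min(len(spectrum), i_max + 2 * hw_bins + 1)
    df = freqs[1] - freqs[0]
    sigma0 = max(hw_bins * df / np.sqrt(2 * np.log(2)), df)
    try:
        popt, _ = curve_fit(
            _gaussian, freqs[lo:hi], spectrum[lo:hi],
            p0=(peak_h, freqs[i_max], sigma0),
            bounds=([0, freqs[lo], df / 4], [np.inf, freqs[hi - 1], freqs[-1]]),
            maxfev=2000,
        )
    except RuntimeError:
        popt = (peak_h, freqs[i_max], sigma0)
    return float(popt[0]), float(popt[1]), float(popt[2])


def find_bands(model: SpectralModel, beta_range: tuple[float, float] = (13.0, 30.0),
               max_iterations: int = 30,
               recompute_floor: bool = True) -> list[FrequencyBand]:
    """Iterative Gaussian fit-and-subtract band identification.

    At each step a Gaussian is fit at the global maximum of the residual
    periodic spectrum and subtracted; iteration stops when the maximum no
    longer exceeds the noise floor (1 SD of the residual across all
    frequencies, recomputed per iteration by default). Band limits are the
    FWHM of the fitted peak; retention requires FWHM >= 1 Hz for peaks below
    10 Hz and >= 3 Hz above 10 Hz. The retained peak with the largest height
    inside ``beta_range`` is labeled ``beta``; the nearest retained peak
    below the beta band is labeled ``alpha_mu``.
    """
    freqs = model.frequencies
    residual = model.periodic.copy()
    floor = residual.std()
    peaks: list[tuple[float, float, float]] = []
    for _ in range(max_iterations):
        if recompute_floor:
            floor = residual.std()
        i_max = int(np.argmax(residual))
        if residual[i_max] <= floor or residual[i_max] <= 0:
            break
        amp, center, sigma = _fit_peak(freqs, residual, i_max)
        new_resid = residual - _gaussian(freqs, amp, center, sigma)
        if new_resid.max() >= residual.max() - 1e-12:
            # fit failed to reduce the maximum; remove the raw peak to
            # guarantee termination
            df = freqs[1] - freqs[0]
            sigma = max(sigma, df)
            new_resid = residual - _gaussian(freqs, residual[i_max],
                                             freqs[i_max], sigma)
            center = freqs[i_max]
            amp = residual[i_max]
        residual = new_resid
        peaks.append((center, amp, FWHM_PER_SIGMA * sigma))
    model.peaks = peaks
    model.noise_floor = float(residual.std())

    bands = []
    for center, height, fwhm in peaks:
        if center < 10.0:
            if fwhm < 1.0:
                continue
        elif fwhm < 3.0:
            continue
        bands.append(FrequencyBand(low=center - fwhm / 2, high=center + fwhm / 2,
                                   center=center))
    # label beta: tallest retained peak inside the canonical range
    heights = {id(b): h for b, (c, h, f) in zip(bands, [p for p in peaks
               if _retained(p)])}
    beta = None
    for b in bands:
        if beta_range[0] <= b.center <= beta_range[1]:
            if beta is None or heights[id(b)] > heights[id(beta)]:
                beta = b
    if beta is not None:
        beta.label = "beta"
        below = [b for b in bands if b.center < beta.low]
        if below:
            max(below, key=lambda b: b.center).label = "alpha_mu"
    return bands


def _retained(peak: tuple[float, float, float]) -> bool:
    center, _, fwhm = peak
    if center < 10.0:
        return fwhm >= 1.0
    return fwhm >= 3.0
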