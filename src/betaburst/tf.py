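"""Adaptive superlet time-frequency decomposition of single trials.

A superlet of order ``o`` at frequency ``f`` combines Morlet wavelets with
cycle counts ``c, 2c, ..., o*c`` (additive progression, base ``c`` = 4) by
taking the geometric mean of their response magnitudes. Short wavelets give
temporal precision, long ones frequency precision; their geometric mean
sharpens the joint resolution beyond any single wavelet. The order is
adapted linearly across the frequency axis (1 at 1 Hz up to 40 at 100 Hz),
so slow frequencies keep temporal resolution while fast ones gain
frequency resolution.

Wavelet responses are amplitude-normalized: a unit-amplitude sinusoid at
the wavelet's center frequency yields magnitude ~1, so TF values carry the
input's units (µV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.fft import next_fast_len


@dataclass
class TFMatrix:
    times: np.ndarray                  # s
    frequencies: np.ndarray            # Hz
    amplitude: np.ndarray              # (n_freqs, n_times), µV, >= 0
    valid: np.ndarray | None = None    # (n_freqs, n_times) bool edge mask
    base_cycles: float = 4.0
    order_range: tuple[float, float] = (1.0, 40.0)

    def __post_init__(self) -> None:
        if self.amplitude.shape != (len(self.frequencies), len(self.times)):
            raise ValueError("amplitude shape does not match axes")


def adaptive_order(freqs: np.ndarray, order_range: tuple[float, float] = (1.0, 40.0),
                   freq_range: tuple[float, float] = (1.0, 100.0)) -> np.ndarray:
    """Rounded linear order map over the frequency range (>= 1)."""
    o_lo, o_hi = order_range
    f_lo, f_hi = freq_range
    orders = o_lo + (np.asarray(freqs, float) - f_lo) * (o_hi - o_lo) / (f_hi - f_lo)
    return np.maximum(np.round(orders).astype(int), 1)


@lru_cache(maxsize=4096)
def _morlet(f: float, cycles: float, sfreq: float) -> np.ndarray:
    """Complex Morlet wavelet, amplitude-normalized, support +-3.5 sigma."""
    sigma_t = cycles / (2 * np.pi * f)
    half = int(np.ceil(3.5 * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    env = np.exp(-(t**2) / (2 * sigma_t**2))
    wavelet = env * np.exp(2j * np.pi * f * t)
    # normalize so |response| to cos(2*pi*f*t) is ~1 (analytic half => 2/sum)
    return wavelet * (2.0 / env.sum())


@lru_cache(maxsize=4096)
def _morlet_fft(f: float, cycles: float, sfreq: float, n_fft: int) -> np.ndarray:
    return np.fft.fft(_morlet(f, cycles, sfreq), n_fft)


def expected_tf_amplitude(amplitude: float, freq: float, cycles: float,
                          base_cycles: float = 4.0,
                          order_range: tuple[float, float] = (1.0, 40.0),
                          order_freq_range: tuple[float, float] = (1.0, 100.0),
                          ) -> float:
    """Expected superlet peak response to a Gaussian-windowed burst.

    A burst with envelope FWHM of ``cycles`` cycles has envelope SD
    ``sigma_b = cycles / freq / 2.355``; each Morlet of ``k * base_cycles``
    cycles attenuates its peak response by
    ``sigma_b / sqrt(sigma_b**2 + sigma_k**2)``, and the superlet output is
    the geometric mean over the wavelet set. Useful for converting a
    waveform amplitude (µV) into the TF amplitude the transform reports.
    """
    order = int(adaptive_order(np.array([freq]), order_range,
                               order_freq_range)[0])
    sigma_b = cycles / freq / (2 * np.sqrt(2 * np.log(2)))
    att = 0.0
    for k in range(1, order + 1):
        sigma_k = k * base_cycles / (2 * np.pi * freq)
        att += np.log(sigma_b / np.sqrt(sigma_b**2 + sigma_k**2))
    return float(amplitude * np.exp(att / order))


def expected_tf_duration(freq: float, cycles: float,
                         base_cycles: float = 4.0,
                         order_range: tuple[float, float] = (1.0, 40.0),
                         order_freq_range: tuple[float, float] = (1.0, 100.0),
                         ) -> float:
    """Expected FWHM (s) of a burst's superlet blob along the time axis.

    Each wavelet smears a Gaussian burst envelope to
    ``sqrt(sigma_b**2 + sigma_k**2)``; the geometric mean of Gaussians has
    inverse-variance equal to the mean of the inverse variances. The
    measured TF duration of a burst is therefore systematically wider than
    its waveform envelope.
    """
    order = int(adaptive_order(np.array([freq]), order_range,
                               order_freq_range)[0])
    fwhm = 2 * np.sqrt(2 * np.log(2))
    sigma_b = cycles / freq / fwhm
    inv = 0.0
    for k in range(1, order + 1):
        sigma_k = k * base_cycles / (2 * np.pi * freq)
        inv += 1.0 / (sigma_b**2 + sigma_k**2)
    return float(fwhm * np.sqrt(order / inv))


def superlet_tf(signal: np.ndarray, sfreq: float,
                freqs: np.ndarray | None = None,
                base_cycles: float = 4.0,
                order_range: tuple[float, float] = (1.0, 40.0),
                order_freq_range: tuple[float, float] = (1.0, 100.0),
                tmin: float = 0.0,
                multiplicative: bool = True) -> TFMatrix:
    """Adaptive superlet transform of a single-trial, single-channel series.

    Parameters
    ----------
    signal : 1D array
        Voltage series, µV.
    freqs : array or None
        Analysis frequencies; default 1-100 Hz in 0.5 Hz steps.
    multiplicative : bool
        Geometric mean across the wavelet set (default); when False, the
        arithmetic mean (additive superlet) is used instead.

    The ``valid`` mask marks samples farther than half the longest wavelet
    support from either edge; burst detection ignores masked bins.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    if freqs is None:
        freqs = np.arange(1.0, 100.0 + 1e-9, 0.5)
    freqs = np.asarray(freqs, dtype=float)
    orders = adaptive_order(freqs, order_range, order_freq_range)
    n_t = len(signal)
    amplitude = np.empty((len(freqs), n_t))
    valid = np.ones((len(freqs), n_t), dtype=bool)
    floor = 1e-12

    # all wavelets share one zero-padded FFT of the signal
    longest = 1
    for f, order in zip(freqs, orders):
        sigma_t = order * base_cycles / (2 * np.pi * f)
        longest = max(longest, 2 * int(np.ceil(3.5 * sigma_t * sfreq)) + 1)
    n_fft = next_fast_len(n_t + longest - 1)
    sig_fft = np.fft.fft(signal, n_fft)

    for fi, (f, order) in enumerate(zip(freqs, orders)):
        acc = np.zeros(n_t)
        max_half = 0
        for k in range(1, order + 1):
            wavelet = _morlet(float(f), float(k * base_cycles), float(sfreq))
            half = len(wavelet) // 2
            max_half = max(max_half, half)
            if len(wavelet) > n_t:
                # wavelet longer than the trial: responses are edge-dominated
                valid[fi] = False
            conv = np.fft.ifft(sig_fft * _morlet_fft(float(f), float(k * base_cycles),
                                                     float(sfreq), n_fft))
            resp = np.abs(conv[half:half + n_t])
            if multiplicative:
                acc += np.log(np.maximum(resp, floor))
            else:
                acc += resp
        if multiplicative:
            amplitude[fi] = np.exp(acc / order)
        else:
            amplitude[fi] = acc / order
        lim = min(max_half, n_t)
        valid[fi, :lim] = False
        valid[fi, n_t - lim:] = False
    times = tmin + np.arange(n_t) / sfreq
    return TFMatrix(times=times, frequencies=freqs, amplitude=amplitude,
                    valid=valid, base_cycles=base_cycles, order_range=order_range)
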