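"""Adaptive burst detection and phase-aligned waveform extraction.

Detection operates on a single-trial TF amplitude matrix restricted to the
beta band plus a search pad. The aperiodic spectrum (converted to
amplitude units) is first subtracted row-wise. Then, iteratively: find the
global maximum, measure its symmetric FWHM along time and frequency
(half-width = the smaller of the two distances to the half-max crossings,
mirrored), subtract the corresponding 2D Gaussian, and repeat while the
maximum exceeds the noise floor (mean + 2 SD of the current residual).
Only bursts whose peak frequency lies strictly inside the band are kept.

Waveforms are then cut from the raw trace (ERP removed), centered on the
phase minimum of the burst's band-passed signal nearest the TF peak time,
sign-normalized so the central deflection is negative, and discarded when
the recentering shift exceeds the alignment tolerance or the window leaves
the trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import filtfilt, firwin, hilbert

from .spectral import FrequencyBand, SpectralModel
from .tf import TFMatrix

FWHM_PER_SIGMA = 2 * np.sqrt(2 * np.log(2))

#: maximum ratio between the two half-max half-widths of a detected peak
_SIDE_CAP = 1.75


@dataclass
class DetectionConfig:
    band: FrequencyBand
    search_pad: float = 5.0          # Hz either side of the band
    noise_floor_sd: float = 2.0      # threshold = mean + this many SDs
    max_iterations: int = 200
    alignment_tolerance_ms: float = 30.0

    def __post_init__(self) -> None:
        if self.search_pad < 0:
            raise ValueError("search_pad must be >= 0")
        if self.noise_floor_sd <= 0:
            raise ValueError("noise_floor_sd must be > 0")


@dataclass
class Burst:
    peak_time: float                 # s
    peak_freq: float                 # Hz
    peak_amplitude: float            # µV, pre-subtraction TF value at the peak
    fwhm_time: float                 # s
    fwhm_freq: float                 # Hz (frequency span)
    order: int                       # detection-iteration index
    residual_amplitude: float = 0.0  # µV, residual TF value when detected
    trial: int = -1
    channel: str = ""
    cluster: str = ""
    laterality: str = "n/a"
    epoch_phase: str = ""
    waveform: np.ndarray | None = None
    polarity_flipped: bool = False

    @property
    def duration_cycles(self) -> float:
        return burst_duration_cycles(self)


def burst_duration_cycles(burst: Burst) -> float:
    """Burst duration expressed in cycles: FWHM duration (s) x peak frequency (Hz)."""
    return burst.fwhm_time * burst.peak_freq


def _halfwidths(profile: np.ndarray, i_peak: int) -> tuple[float, float]:
    """Half-max half-widths (left, right) in bins along one axis.

    A side that never crosses half max falls back to the distance to the
    matrix edge. TF blobs of short bursts are noticeably skewed (wavelet
    bandwidth varies with analysis frequency), so both sides are measured
    and the subtracted Gaussian uses a per-side width; a single symmetric
    width leaves shoulder residue that re-triggers detection.
    """
    half = profile[i_peak] / 2.0
    left = None
    for i in range(i_peak - 1, -1, -1):
        if profile[i] < half:
            frac = (profile[i + 1] - half) / (profile[i + 1] - profile[i])
            left = (i_peak - i - 1) + frac
            break
    right = None
    for i in range(i_peak + 1, len(profile)):
        if profile[i] < half:
            frac = (profile[i - 1] - half) / (profile[i - 1] - profile[i])
            right = (i - i_peak - 1) + frac
            break
    if left is None:
        left = right if right is not None else max(i_peak, 1)
    if right is None:
        right = left if left is not None else max(len(profile) - 1 - i_peak, 1)
    return max(float(left), 0.5), max(float(right), 0.5)


def detect_bursts(tf: TFMatrix, aperiodic: SpectralModel | None,
                  cfg: DetectionConfig) -> list[Burst]:
    """Iterative 2D-Gaussian peak removal on one trial's TF matrix.

    Returns bursts (TF features only) whose peak frequency is strictly
    inside the configured band; peaks found in the search pad are detected
    (their energy is removed) but not returned. Reported amplitudes come
    from the aperiodic-subtracted matrix before any Gaussian removal.
    """
    freqs = tf.frequencies
    fsel = (freqs >= cfg.band.low - cfg.search_pad) & \
           (freqs <= cfg.band.high + cfg.search_pad)
    if not fsel.any():
        return []
    sub_freqs = freqs[fsel]
    amp = tf.amplitude[fsel].copy()
    if aperiodic is not None:
        ap_amp = np.sqrt(aperiodic.aperiodic_power(sub_freqs))
        amp = np.clip(amp - ap_amp[:, None], 0.0, None)
    valid = tf.valid[fsel] if tf.valid is not None else np.ones_like(amp, bool)
    if not valid.any():
        return []
    original = amp.copy()
    residual = amp
    times = tf.times
    dt = times[1] - times[0]
    df = sub_freqs[1] - sub_freqs[0] if len(sub_freqs) > 1 else 1.0
    tgrid = np.arange(residual.shape[1])
    fgrid = np.arange(residual.shape[0])
    bursts: list[Burst] = []
    for iteration in range(cfg.max_iterations):
        masked = np.where(valid, residual, -np.inf)
        i_flat = int(np.argmax(masked))
        fi, ti = np.unravel_index(i_flat, residual.shape)
        peak_val = residual[fi, ti]
        vals = residual[valid]
        floor = vals.mean() + cfg.noise_floor_sd * vals.std()
        if peak_val <= floor or not np.isfinite(peak_val) or peak_val <= 0:
            break
        lt, rt = _halfwidths(residual[fi, :], ti)
        lf, rf = _halfwidths(residual[:, ti], fi)
        # cap side asymmetry: an overlapping neighbor can push a half-max
        # crossing far out, and an uncapped width would absorb that neighbor
        lt, rt = min(lt, _SIDE_CAP * rt), min(rt, _SIDE_CAP * lt)
        lf, rf = min(lf, _SIDE_CAP * rf), min(rf, _SIDE_CAP * lf)
        # two-piece Gaussian subtraction, evaluated on a +-5 sigma window
        # around the peak (it is numerically zero outside)
        t_lo = max(0, ti - int(np.ceil(5 * 2 * lt / FWHM_PER_SIGMA)))
        t_hi = min(len(tgrid), ti + int(np.ceil(5 * 2 * rt / FWHM_PER_SIGMA)) + 1)
        f_lo = max(0, fi - int(np.ceil(5 * 2 * lf / FWHM_PER_SIGMA)))
        f_hi = min(len(fgrid), fi + int(np.ceil(5 * 2 * rf / FWHM_PER_SIGMA)) + 1)
        t_loc = tgrid[t_lo:t_hi]
        f_loc = fgrid[f_lo:f_hi]
        sig_t = np.where(t_loc < ti, 2 * lt, 2 * rt) / FWHM_PER_SIGMA
        sig_f = np.where(f_loc < fi, 2 * lf, 2 * rf) / FWHM_PER_SIGMA
        gauss = peak_val * np.exp(
            -((f_loc[:, None] - fi) ** 2) / (2 * sig_f[:, None] ** 2)
            - ((t_loc[None, :] - ti) ** 2) / (2 * sig_t[None, :] ** 2)
        )
        residual[f_lo:f_hi, t_lo:t_hi] = np.clip(
            residual[f_lo:f_hi, t_lo:t_hi] - gauss, 0.0, None)
        burst = Burst(
            peak_time=float(times[ti]),
            peak_freq=float(sub_freqs[fi]),
            peak_amplitude=float(original[fi, ti]),
            residual_amplitude=float(peak_val),
            fwhm_time=float((lt + rt) * dt),
            fwhm_freq=float((lf + rf) * df),
            order=iteration,
        )
        if cfg.band.low < burst.peak_freq < cfg.band.high:
            bursts.append(burst)
    return _merge_duplicates(bursts)


def _merge_duplicates(bursts: list[Burst]) -> list[Burst]:
    """Merge later detections that sit inside an earlier burst's extent.

    A detection within half the earlier burst's time FWHM and within its
    full frequency FWHM is a fragment of that burst's TF blob (imperfect
    Gaussian removal), not a new event: distinct bursts on one channel are
    separated in time (sensorimotor bursts have an effective refractory
    period), while blob fragments split along the frequency axis.
    """
    kept: list[Burst] = []
    for b in sorted(bursts, key=lambda b: b.order):
        dup = any(
            abs(b.peak_time - k.peak_time) < 0.5 * max(k.fwhm_time, 1e-9)
            and abs(b.peak_freq - k.peak_freq) < max(k.fwhm_freq, 1e-9)
            for k in kept
        )
        if not dup:
            kept.append(b)
    return kept


def extract_waveform(raw_trial: np.ndarray, erp: np.ndarray, burst: Burst,
                     n_samples: int, sfreq: float, tmin: float,
                     tolerance_ms: float = 30.0) -> Burst | None:
    """Fill ``burst.waveform`` from the raw trace, or return None (discarded).

    The trial-average ERP is removed, the trace band-passed over the burst's
    detected frequency span (zero-phase FIR, Hamming design), the phase
    minimum (signal trough) nearest the TF peak found via the Hilbert
    transform, and the raw (unfiltered) waveform recentered there. Discards:
    recentering shift beyond the tolerance, or window crossing a trial edge.
    """
    x = np.asarray(raw_trial, dtype=float) - np.asarray(erp, dtype=float)
    f_lo = max(burst.peak_freq - burst.fwhm_freq / 2, 1.0)
    f_hi = min(burst.peak_freq + burst.fwhm_freq / 2, sfreq / 2 - 1.0)
    if f_hi <= f_lo:
        f_lo, f_hi = max(burst.peak_freq - 1.0, 0.5), burst.peak_freq + 1.0
    numtaps = int(round(3 * sfreq / f_lo))
    numtaps = min(numtaps if numtaps % 2 else numtaps + 1, 2 * (len(x) // 3) - 1)
    taps = firwin(numtaps, [f_lo, f_hi], pass_zero=False, fs=sfreq,
                  window="hamming")
    filtered = filtfilt(taps, 1.0, x)
    phase = np.angle(hilbert(filtered))
    peak_idx = int(round((burst.peak_time - tmin) * sfreq))

    # troughs: local maxima of -cos(phase), i.e. instantaneous phase at
    # +-pi. The TF peak time can err by up to half a period, which makes
    # the literally nearest trough ambiguous between the burst's central
    # trough and its one-period neighbor; of the troughs inside the
    # alignment tolerance we therefore take the deepest one (the burst
    # center carries the envelope maximum, and consecutive troughs are a
    # full period apart, where the envelope contrast is reliable).
    score = -np.cos(phase)
    troughs = np.where((score[1:-1] >= score[:-2]) & (score[1:-1] > score[2:])
                       & (score[1:-1] > 0.9))[0] + 1
    tol_samples = tolerance_ms / 1000.0 * sfreq
    cand = troughs[np.abs(troughs - peak_idx) <= tol_samples]
    if cand.size == 0:
        return None
    center = int(cand[np.argmin(filtered[cand])])
    flipped = False
    half = n_samples // 2
    lo, hi = center - half, center - half + n_samples
    if lo < 0 or hi > len(x):
        return None
    wave = -x[lo:hi].copy() if flipped else x[lo:hi].copy()
    wave -= wave.mean()
    if wave[half] > 0:
        wave = -wave
        flipped = not flipped
    burst.waveform = wave
    burst.polarity_flipped = bool(flipped)
    return burst


def detect_epochs(epochs, model: SpectralModel | None, cfg: DetectionConfig,
                  window_samples: int, freq_step: float = 0.5,
                  channels: list[str] | None = None,
                  extract: bool = True) -> tuple[pd.DataFrame, np.ndarray]:
    """Run TF decomposition + detection + waveform extraction over an EpochSet.

    The ERP is computed per participant x condition x epoch phase x channel
    and removed before waveform extraction. Returns the burst catalog (one
    row per retained burst, with provenance and laterality) and the aligned
    waveform matrix (n_bursts x window_samples).

    ``channels`` restricts detection to a channel subset (default: all
    channels belonging to a cluster).
    """
    from .synthetic import resolve_laterality
    from .tf import superlet_tf

    meta = epochs.metadata
    if channels is None:
        channels = [ch for chs in epochs.clusters.values() for ch in chs]
    lo = max(cfg.band.low - cfg.search_pad, 1.0)
    hi = cfg.band.high + cfg.search_pad
    freqs = np.arange(np.floor(lo / freq_step) * freq_step, hi + 1e-9, freq_step)
    cluster_names = tuple(epochs.clusters.keys())

    # ERPs per (participant, condition, phase, channel index)
    erp_cache: dict[tuple, np.ndarray] = {}
    groups = meta.groupby(["participant", "condition", "epoch_phase"]).indices
    for key, idx in groups.items():
        erp_cache[key] = epochs.data[idx].mean(axis=0)

    all_bursts: list[Burst] = []
    waveforms: list[np.ndarray] = []
    for ei in range(epochs.n_epochs):
        row = meta.iloc[ei]
        erp_all = erp_cache[(row["participant"], row["condition"],
                             row["epoch_phase"])]
        for ch in channels:
            ci = epochs.channel_index(ch)
            signal = epochs.data[ei, ci]
            tf = superlet_tf(signal, epochs.sfreq, freqs=freqs, tmin=epochs.tmin)
            found = detect_bursts(tf, model, cfg)
            cluster = epochs.cluster_of(ch) or ""
            lat = resolve_laterality(cluster, row.get("hand", "n/a"),
                                     row["condition"], cluster_names)
            for b in found:
                b.trial = int(row["trial"])
                b.channel = ch
                b.cluster = cluster
                b.laterality = lat
                b.epoch_phase = row["epoch_phase"]
                if extract:
                    b = extract_waveform(signal, erp_all[ci], b, window_samples,
                                         epochs.sfreq, epochs.tmin,
                                         cfg.alignment_tolerance_ms)
                    if b is None:
                        continue
                    waveforms.append(b.waveform)
                all_bursts.append(b)
                b.participant = int(row["participant"])  # provenance
    frame = catalog_to_frame(all_bursts)
    if len(all_bursts):
        frame["participant"] = [b.participant for b in all_bursts]
    else:
        frame["participant"] = []
    wf = np.asarray(waveforms) if waveforms else np.empty((0, window_samples))
    return frame, wf


def catalog_to_frame(bursts: list[Burst], extra: dict | None = None) -> pd.DataFrame:
    rows = []
    for b in bursts:
        row = {
            "trial": b.trial, "channel": b.channel, "cluster": b.cluster,
            "laterality": b.laterality, "epoch_phase": b.epoch_phase,
            "peak_time": b.peak_time, "peak_freq": b.peak_freq,
            "peak_amplitude": b.peak_amplitude,
            "residual_amplitude": b.residual_amplitude,
            "fwhm_time": b.fwhm_time,
            "fwhm_freq": b.fwhm_freq, "duration_cycles": b.duration_cycles,
            "polarity_flipped": b.polarity_flipped, "order": b.order,
        }
        if extra:
            row.update(extra)
        rows.append(row)
    columns = ["trial", "channel", "cluster", "laterality", "epoch_phase",
               "peak_time", "peak_freq", "peak_amplitude",
               "residual_amplitude", "fwhm_time", "fwhm_freq",
               "duration_cycles", "polarity_flipped", "order"]
    if extra:
        columns += [k for k in extra if k not in columns]
    return pd.DataFrame(rows, columns=columns)
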