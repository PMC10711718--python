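"""Synthetic epoched EEG with a known ground-truth burst catalog.

Emulates the statistical structure of event-centered sensorimotor EEG:
a 1/f aperiodic background (spectrally shaped white noise), a sustained
alpha/mu oscillation, and transient beta bursts injected as Gaussian-windowed
wavelets whose shape is perturbed along a small orthonormal motif basis.
Burst timing follows a thinned Poisson process with a hard refractory
period, which makes inter-burst intervals more regular than Poisson
(coefficient of variation < 1). Burst rates can be modulated per epoch
phase and per hemisphere cluster, and — to emulate shape-specific rate
modulation — bursts with extreme motif weights can be selectively thinned
after the centering event of a chosen epoch phase.

Every injected burst is recorded in a :class:`GroundTruth` table, so each
downstream stage (detection, waveform extraction, PCA, rate statistics)
can be validated against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .containers import EPOCH_PHASES, EpochSet

__all__ = ["SimConfig", "GroundTruth", "generate_dataset", "default_motif_basis",
           "background_sigma", "age_preset", "resolve_laterality"]

#: seconds of waveform support either side of a burst center; the motif basis
#: lives on this grid (its length is ``2 * support * sampling_rate + 1``)
BURST_SUPPORT_S = 0.45


def default_channels() -> list[str]:
    return [f"C3_{i}" for i in range(1, 5)] + [f"C4_{i}" for i in range(1, 5)]


def default_motif_basis(n_samples: int, center_freq: float, sfreq: float) -> np.ndarray:
    """Three orthonormal waveform-perturbation vectors on the burst grid.

    Gaussian-windowed harmonic perturbations: left/right asymmetry of the
    flanking deflections at the second harmonic, sharpness of the central
    trough (second harmonic), and extra peaky deflections (third
    harmonic). Motifs built on the *fundamental* frequency are avoided on
    purpose: small trough-alignment shifts, per-burst duration and
    frequency jitter all perturb the waveform along fundamental-frequency
    directions (sin, t*sin, t^2*cos at the carrier frequency) and would
    swamp such motif weights downstream; harmonic motifs are orthogonal to
    those nuisance directions. All are first orthogonalized against the
    windowed carrier (so a motif weight is shape change, not amplitude
    change), then Gram-Schmidt orthonormalized among themselves.
    Deterministic given the grid.
    """
    t = (np.arange(n_samples) - n_samples // 2) / sfreq
    sigma = 0.8 / center_freq
    env = np.exp(-(t**2) / (2 * sigma**2))
    carrier = np.cos(2 * np.pi * center_freq * t) * env
    carrier = carrier / np.linalg.norm(carrier)
    raw = np.stack(
        [
            np.cos(4 * np.pi * center_freq * t) * (t / sigma) * env,
            np.cos(4 * np.pi * center_freq * t) * env,
            np.cos(6 * np.pi * center_freq * t) * env,
        ]
    )
    basis: list[np.ndarray] = []
    for v in raw:
        v = v - (v @ carrier) * carrier
        for u in basis:
            v = v - (v @ u) * u
        basis.append(v / np.linalg.norm(v))
    return np.stack(basis)


@dataclass
class SimConfig:
    """Generator settings; defaults emulate an adult-like recording session.

    ``burst_base_rate`` is the rate of the underlying Poisson driver before
    refractory deletion; for a homogeneous profile the observed burst rate is
    ``rate / (1 + rate * refractory)`` and the IBI coefficient of variation is
    ``1 / (1 + rate * refractory)``.
    """

    sampling_rate: float = 500.0
    epoch_duration: float = 3.6
    n_trials: int = 20
    n_participants: int = 10
    channels: list[str] = field(default_factory=default_channels)
    cluster_names: tuple[str, str] = ("C3", "C4")
    aperiodic_exponent: float = 1.5
    aperiodic_offset: float = 0.0          # log10 power at 1 Hz
    alpha_freq: float = 9.5
    alpha_amplitude: float = 4.0           # µV
    beta_center: float = 21.5              # Hz
    beta_freq_sd: float = 1.0              # SD of burst peak frequency, Hz
    burst_base_rate: float = 15 / 7        # Poisson driver, bursts/s (CV 0.7 with 0.2 s refractory)
    rate_profile: dict = field(default_factory=dict)
    burst_amplitude_mean: float = 12.0     # µV
    burst_amplitude_sd: float = 4.0
    burst_duration_mean: float = 5.0       # cycles (FWHM of the envelope)
    burst_duration_sd: float = 1.0
    motif_basis: np.ndarray | None = None  # (n_motifs, n_samples), unit-norm rows
    # distinct variances keep the motif principal axes identifiable (equal
    # variances would make the PCA rotationally degenerate in their span)
    motif_weight_sd: Sequence[float] = (0.8, 1.0, 1.3)
    motif_gating: dict | None = None
    refractory: float = 0.2                # s
    right_hand_prob: float = 1.0
    condition: str = "execution"
    epoch_phases: tuple[str, ...] = EPOCH_PHASES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.epoch_duration <= 0:
            raise ValueError("sampling_rate and epoch_duration must be positive")
        if self.burst_base_rate < 0 or self.refractory < 0:
            raise ValueError("rates and refractory must be non-negative")
        if self.burst_base_rate * self.refractory >= 1:
            raise ValueError(
                "infeasible configuration: burst_base_rate x refractory >= 1, "
                "the refractory period cannot sustain the requested rate"
            )
        if len(self.channels) < 2 or len(self.channels) % 2:
            raise ValueError("channels must split into two equal clusters")
        for phase, per_cluster in self.rate_profile.items():
            for mults in per_cluster.values():
                if np.any(np.asarray(mults) < 0):
                    raise ValueError("rate multipliers must be >= 0")
        n_sup = 2 * int(round(BURST_SUPPORT_S * self.sampling_rate)) + 1
        if self.motif_basis is None:
            self.motif_basis = default_motif_basis(n_sup, self.beta_center, self.sampling_rate)
        self.motif_basis = np.asarray(self.motif_basis, dtype=float)
        gram = self.motif_basis @ self.motif_basis.T
        if not np.allclose(gram, np.eye(len(self.motif_basis)), atol=1e-8):
            raise ValueError("motif basis vectors must be orthonormal (tol 1e-8)")
        if len(self.motif_weight_sd) != len(self.motif_basis):
            raise ValueError("motif_weight_sd length must match motif basis")

    @property
    def clusters(self) -> dict[str, list[str]]:
        half = len(self.channels) // 2
        return {
            self.cluster_names[0]: self.channels[:half],
            self.cluster_names[1]: self.channels[half:],
        }

    def rate_multiplier(self, phase: str, cluster: str, post_event: bool) -> float:
        per_cluster = self.rate_profile.get(phase, {})
        mults = per_cluster.get(cluster, (1.0, 1.0))
        return float(mults[1] if post_event else mults[0])


@dataclass
class GroundTruth:
    """Catalog of every injected burst, one row per burst.

    Columns: participant, trial, epoch_phase, condition, channel, cluster,
    hand, laterality, peak_time (s, relative to the centering event),
    peak_freq (Hz), amplitude (µV), duration (s, envelope FWHM),
    duration_cycles, and weight_<k> per motif.
    """

    table: pd.DataFrame
    motif_basis: np.ndarray

    def __len__(self) -> int:
        return len(self.table)

    @property
    def empty(self) -> bool:
        return self.table.empty

    def weights(self) -> np.ndarray:
        cols = [c for c in self.table.columns if c.startswith("weight_")]
        return self.table[cols].to_numpy()


def resolve_laterality(cluster: str, hand: str, condition: str = "execution",
                       cluster_names: tuple[str, str] = ("C3", "C4")) -> str:
    """Map an electrode cluster to contra/ipsilateral given the hand used.

    The first cluster sits over the left hemisphere, hence is contralateral
    to right-hand movements. In the observation condition there is no
    performing hand, so laterality is not applicable.
    """
    if condition != "execution" or hand not in ("left", "right"):
        return "n/a"
    left_cluster = cluster_names[0]
    if hand == "right":
        return "contralateral" if cluster == left_cluster else "ipsilateral"
    return "ipsilateral" if cluster == left_cluster else "contralateral"


def _shaped_noise(rng: np.random.Generator, n_t: int, sfreq: float,
                  exponent: float, offset: float) -> np.ndarray:
    """White noise spectrally shaped to a 1/f**exponent power law.

    The amplitude filter is ``10**(offset/2) * f**(-exponent/2)`` so the PSD
    of the output follows ``10**offset * f**-exponent`` (µV²/Hz).
    """
    white = rng.standard_normal(n_t)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_t, 1 / sfreq)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = 10 ** (offset / 2) * freqs[nz] ** (-exponent / 2)
    # scale so a unit-variance white input yields the target PSD level:
    # Welch PSD of white noise is 2/sfreq per rfft bin (one-sided)
    out = np.fft.irfft(spec * shape * np.sqrt(sfreq / 2), n=n_t)
    return out


def background_sigma(config: SimConfig, n_epochs: int = 50) -> float:
    """Empirical SD (µV) of the burst-free background (noise + alpha)."""
    rng = np.random.default_rng(config.seed + 987654321)
    n_t = int(round(config.epoch_duration * config.sampling_rate))
    t = np.arange(n_t) / config.sampling_rate
    samples = []
    for _ in range(n_epochs):
        x = _shaped_noise(rng, n_t, config.sampling_rate,
                          config.aperiodic_exponent, config.aperiodic_offset)
        phase = rng.uniform(0, 2 * np.pi)
        x = x + config.alpha_amplitude * np.sin(2 * np.pi * config.alpha_freq * t + phase)
        samples.append(x)
    return float(np.std(np.concatenate(samples)))


def _driver_rate(base_driver: float, refractory: float, multiplier: float) -> float:
    """Poisson driver rate that realizes ``multiplier`` x the observed rate.

    The refractory period compresses driver-rate changes (observed rate is
    ``lam / (1 + lam * d)``), so profile multipliers are defined on the
    observed burst rate and inverted here to driver units.
    """
    base_obs = base_driver / (1 + base_driver * refractory)
    target_obs = multiplier * base_obs
    if target_obs * refractory >= 1:
        raise ValueError("rate multiplier infeasible under the refractory period")
    return target_obs / (1 - target_obs * refractory)


def _place_bursts(rng: np.random.Generator, cfg: SimConfig, phase: str,
                  cluster: str, tmin: float, tmax: float) -> np.ndarray:
    """Thinned Poisson placement with hard refractory period.

    Candidates are drawn at the maximum of the rate profile and thinned to
    the local rate; a candidate closer than ``refractory`` to the last
    accepted burst is rejected. Rate-profile multipliers scale the observed
    (post-refractory) rate.
    """
    pre = _driver_rate(cfg.burst_base_rate, cfg.refractory,
                       cfg.rate_multiplier(phase, cluster, False))
    post = _driver_rate(cfg.burst_base_rate, cfg.refractory,
                        cfg.rate_multiplier(phase, cluster, True))
    lam_max = max(pre, post)
    if lam_max == 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * (tmax - tmin))
    times = np.sort(rng.uniform(tmin, tmax, size=n_cand))
    accept_u = rng.uniform(size=n_cand)
    out = []
    last = -np.inf
    for t, u in zip(times, accept_u):
        lam = post if t >= 0 else pre
        if u < lam / lam_max and t - last >= cfg.refractory:
            out.append(t)
            last = t
    return np.asarray(out)


def generate_dataset(config: SimConfig) -> tuple[EpochSet, GroundTruth]:
    """Generate epoched EEG plus its ground-truth burst catalog.

    Deterministic: the same config (including seed) yields bit-identical
    voltages and catalogs. Epochs span ``[-duration/2, duration/2)`` around
    the centering event of each epoch phase.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sfreq = cfg.sampling_rate
    n_t = int(round(cfg.epoch_duration * sfreq))
    tmin = -cfg.epoch_duration / 2
    times = tmin + np.arange(n_t) / sfreq
    half_sup = int(round(BURST_SUPPORT_S * sfreq))
    n_sup = 2 * half_sup + 1
    sup_t = (np.arange(n_sup) - half_sup) / sfreq
    motifs = cfg.motif_basis
    n_motifs = len(motifs)
    weight_sd = np.asarray(cfg.motif_weight_sd, dtype=float)
    clusters = cfg.clusters
    gating = cfg.motif_gating or None

    epochs_data = []
    meta_rows = []
    gt_rows = []

    for p in range(cfg.n_participants):
        for trial in range(cfg.n_trials):
            hand = "right" if rng.uniform() < cfg.right_hand_prob else "left"
            for phase in cfg.epoch_phases:
                epoch = np.empty((len(cfg.channels), n_t))
                for ci, ch in enumerate(cfg.channels):
                    cluster = next(k for k, v in clusters.items() if ch in v)
                    x = _shaped_noise(rng, n_t, sfreq, cfg.aperiodic_exponent,
                                      cfg.aperiodic_offset)
                    # sustained alpha: amplitude-modulated (waxing/waning)
                    # sinusoid — the slow envelope broadens the spectral peak
                    # without the phase drift that would destroy rhythmicity
                    phi = rng.uniform(0, 2 * np.pi)
                    env_noise = gaussian_filter1d(
                        rng.standard_normal(n_t), 0.06 * sfreq, mode="wrap")
                    env_noise /= max(np.abs(env_noise).max(), 1e-12)
                    alpha_env = np.clip(1.0 + 1.2 * env_noise, 0.05, None)
                    x += cfg.alpha_amplitude * alpha_env * np.sin(
                        2 * np.pi * cfg.alpha_freq * times + phi)
                    burst_times = _place_bursts(rng, cfg, phase, cluster, tmin, -tmin)
                    for t0 in burst_times:
                        f = rng.normal(cfg.beta_center, cfg.beta_freq_sd)
                        f = float(np.clip(f, 5.0, sfreq / 4))
                        cyc = float(np.clip(
                            rng.normal(cfg.burst_duration_mean, cfg.burst_duration_sd),
                            2.0, 9.0))
                        amp = float(np.clip(
                            rng.normal(cfg.burst_amplitude_mean, cfg.burst_amplitude_sd),
                            0.1 * cfg.burst_amplitude_mean, None))
                        w = rng.normal(0.0, weight_sd) if n_motifs else np.empty(0)
                        if gating is not None and phase == gating.get("phase", "touch") \
                                and t0 >= 0:
                            comps = gating.get("components", range(n_motifs))
                            z = max((abs(w[k]) / weight_sd[k] for k in comps), default=0.0)
                            if z > gating["z_threshold"] \
                                    and rng.uniform() >= gating["post_multiplier"]:
                                continue
                        fwhm_t = cyc / f
                        sigma_env = fwhm_t / 2.355
                        carrier = -np.cos(2 * np.pi * f * sup_t)
                        shape = carrier + (w @ motifs if n_motifs else 0.0)
                        wave = amp * shape * np.exp(-(sup_t**2) / (2 * sigma_env**2))
                        c_idx = int(round((t0 - tmin) * sfreq))
                        lo = c_idx - half_sup
                        hi = c_idx + half_sup + 1
                        w_lo = max(0, -lo)
                        w_hi = n_sup - max(0, hi - n_t)
                        x[max(0, lo):min(n_t, hi)] += wave[w_lo:w_hi]
                        row = {
                            "participant": p, "trial": trial, "epoch_phase": phase,
                            "condition": cfg.condition, "channel": ch,
                            "cluster": cluster, "hand": hand,
                            "laterality": resolve_laterality(
                                cluster, hand, cfg.condition, cfg.cluster_names),
                            "peak_time": float(t0), "peak_freq": f,
                            "amplitude": amp, "duration": fwhm_t,
                            "duration_cycles": cyc,
                        }
                        for k in range(n_motifs):
                            row[f"weight_{k}"] = float(w[k])
                        gt_rows.append(row)
                    epoch[ci] = x
                epochs_data.append(epoch)
                meta_rows.append({
                    "participant": p, "trial": trial, "epoch_phase": phase,
                    "condition": cfg.condition, "hand": hand,
                })

    gt_cols = ["participant", "trial", "epoch_phase", "condition", "channel",
               "cluster", "hand", "laterality", "peak_time", "peak_freq",
               "amplitude", "duration", "duration_cycles"] + \
              [f"weight_{k}" for k in range(n_motifs)]
    gt = pd.DataFrame(gt_rows, columns=gt_cols)
    epoch_set = EpochSet(
        data=np.asarray(epochs_data).reshape(len(meta_rows), len(cfg.channels), n_t),
        sfreq=sfreq,
        ch_names=list(cfg.channels),
        metadata=pd.DataFrame(meta_rows),
        clusters=clusters,
        tmin=tmin,
    )
    return epoch_set, GroundTruth(table=gt, motif_basis=motifs)


def age_preset(group: str, **overrides) -> SimConfig:
    """Presets mirroring the age-dependent beta-band centers.

    ``"9m"`` ~14.5 Hz, ``"12m"`` ~15.25 Hz, ``"adult"`` ~21.5 Hz.
    """
    centers = {"9m": 14.5, "12m": 15.25, "adult": 21.5}
    if group not in centers:
        raise ValueError(f"unknown age group {group!r}")
    params = dict(beta_center=centers[group])
    if group != "adult":
        params.update(burst_duration_mean=4.4, burst_amplitude_mean=18.0)
    params.update(overrides)
    return SimConfig(**params)
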