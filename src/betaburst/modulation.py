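"""Burst-rate, amplitude and waveform-score dynamics across the trial.

Bursts are binned in time (25 ms for rates, 50 ms for score and quartile
analyses), smoothed with a Gaussian kernel (sigma = 3 or 2 time bins),
and baseline-corrected against the 1.5 s preceding the start of the trial
— i.e. the pre-event window of the trial-start epoch — as percentage
change (rates, amplitude) or subtraction (scores). Statistics operate on
the participant dimension: each participant contributes one corrected
time course, and deviations from baseline are tested with the
hat-t / TFCE / max-statistic sign-flip machinery from :mod:`.stats`.

The quartile analysis splits bursts by their score along one waveform
motif (PCA component) into four near-equal groups, each baseline-corrected
against its own quartile-specific baseline rate, asking whether bursts of
a particular shape are selectively rate-modulated.

The inter-burst-interval (IBI) analysis compares the coefficient of
variation of within-trial IBIs with surrogate catalogs in which each burst
receives a uniformly random peak time (counts per trial preserved): a CV
below the surrogate distribution's lower confidence bound indicates
refractory (more-regular-than-Poisson) burst timing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .stats import ClusterTestResult, max_stat_permutation

BASELINE_WINDOW = (-1.5, 0.0)   # s, relative to trial start


@dataclass
class RateTimecourse:
    times: np.ndarray                       # bin centers, s
    values: np.ndarray                      # participants x bins, corrected
    per_participant_baseline: np.ndarray
    epoch_phase: str
    laterality: str
    bin_width: float
    kernel_width: float
    kind: str = "rate"                      # rate | amplitude | score
    test: ClusterTestResult | None = None

    def mean(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)


def _bin_edges(tmin: float, tmax: float, width: float) -> np.ndarray:
    n = int(round((tmax - tmin) / width))
    return tmin + np.arange(n + 1) * width


def _smooth(arr: np.ndarray, kernel_width: float) -> np.ndarray:
    if kernel_width <= 0:
        return arr
    return gaussian_filter1d(arr, sigma=kernel_width, axis=-1,
                             mode="reflect", truncate=3.0)


def _percent_change(rates: np.ndarray, baselines: np.ndarray) -> np.ndarray:
    out = np.full_like(rates, np.nan)
    ok = baselines > 0
    out[ok] = 100.0 * (rates[ok] - baselines[ok, None]) / baselines[ok, None]
    if not ok.all():
        warnings.warn("zero baseline rate for some participants; their time "
                      "courses are set to missing", stacklevel=2)
    return out


def _participant_rates(catalog: pd.DataFrame, participants: np.ndarray,
                       trial_counts: pd.Series, edges: np.ndarray,
                       n_streams: int) -> np.ndarray:
    """Counts -> rate (bursts/s per stream) per participant per bin."""
    width = edges[1] - edges[0]
    rates = np.zeros((len(participants), len(edges) - 1))
    for pi, p in enumerate(participants):
        sub = catalog[catalog["participant"] == p]
        counts, _ = np.histogram(sub["peak_time"], bins=edges)
        n_tr = trial_counts.get(p, 0)
        if n_tr > 0:
            rates[pi] = counts / (n_tr * n_streams * width)
    return rates


def rate_timecourse(catalog: pd.DataFrame, epochs_meta: pd.DataFrame,
                    epoch_phase: str, laterality: str | None = None,
                    bin_width: float = 0.025, kernel_width: float = 3.0,
                    time_range: tuple[float, float] = (-1.8, 1.8),
                    baseline_phase: str = "start",
                    baseline_window: tuple[float, float] = BASELINE_WINDOW,
                    n_streams: int | None = None,
                    test_kwargs: dict | None = None) -> RateTimecourse:
    """Baseline-corrected burst-rate time course (% change), per participant.

    ``catalog`` must carry participant/trial/epoch_phase/peak_time (and
    laterality when requested). The baseline is each participant's smoothed
    rate in ``baseline_window`` of the ``baseline_phase`` epoch, restricted
    to the same laterality. ``epochs_meta`` supplies per-participant trial
    counts so rates are in bursts per second per channel stream
    (``n_streams`` = number of channels pooled; inferred from the catalog
    when omitted).
    """
    sel = catalog[catalog["epoch_phase"] == epoch_phase]
    base_sel = catalog[catalog["epoch_phase"] == baseline_phase]
    if laterality is not None:
        sel = sel[sel["laterality"] == laterality]
        base_sel = base_sel[base_sel["laterality"] == laterality]
    participants = np.sort(epochs_meta["participant"].unique())
    if n_streams is None:
        n_streams = max(catalog["channel"].nunique(), 1)
        if laterality is not None:
            n_streams = max(sel["channel"].nunique(), 1)
    meta_phase = epochs_meta[epochs_meta["epoch_phase"] == epoch_phase]
    trial_counts = meta_phase.groupby("participant")["trial"].nunique()
    meta_base = epochs_meta[epochs_meta["epoch_phase"] == baseline_phase]
    base_trials = meta_base.groupby("participant")["trial"].nunique()

    edges = _bin_edges(*time_range, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2
    rates = _participant_rates(sel, participants, trial_counts, edges, n_streams)
    rates = _smooth(rates, kernel_width)

    base_edges = _bin_edges(*baseline_window, bin_width)
    base_rates = _participant_rates(base_sel, participants, base_trials,
                                    base_edges, n_streams)
    base_rates = _smooth(base_rates, kernel_width)
    baselines = base_rates.mean(axis=1)
    values = _percent_change(rates, baselines)

    tc = RateTimecourse(times=centers, values=values,
                        per_participant_baseline=baselines,
                        epoch_phase=epoch_phase,
                        laterality=laterality or "channel-cluster",
                        bin_width=bin_width, kernel_width=kernel_width)
    if test_kwargs is not None:
        tc.test = _test_timecourse(values, **test_kwargs)
    return tc


def _test_timecourse(values: np.ndarray, **kwargs) -> ClusterTestResult:
    ok_rows = ~np.isnan(values).any(axis=1)
    return max_stat_permutation(values[ok_rows], **kwargs)


def amplitude_timecourse(tf_amplitudes: np.ndarray, times: np.ndarray,
                         participants: np.ndarray,
                         baseline_amplitudes: np.ndarray,
                         baseline_times: np.ndarray,
                         bin_width: float = 0.025, kernel_width: float = 3.0,
                         baseline_window: tuple[float, float] = BASELINE_WINDOW,
                         test_kwargs: dict | None = None) -> RateTimecourse:
    """Mean band-amplitude time course as % change from baseline.

    ``tf_amplitudes``: per-trial band-averaged amplitude traces
    (n_trials x n_times) for the analyzed epoch phase;
    ``baseline_amplitudes``: same for the trial-start epoch. ``participants``
    assigns each trial row to a participant.
    """
    participants = np.asarray(participants)
    uniq = np.unique(participants[: len(tf_amplitudes)]) if len(participants) \
        else np.array([])
    edges = _bin_edges(times[0], times[-1] + 1e-9, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2
    bin_idx = np.clip(np.digitize(times, edges) - 1, 0, len(centers) - 1)
    base_mask = (baseline_times >= baseline_window[0]) & \
                (baseline_times < baseline_window[1])
    rows = []
    baselines = []
    for p in uniq:
        trials = tf_amplitudes[participants[: len(tf_amplitudes)] == p]
        mean_trace = trials.mean(axis=0)
        binned = np.array([mean_trace[bin_idx == b].mean()
                           for b in range(len(centers))])
        rows.append(binned)
        base_trials = baseline_amplitudes[
            participants[: len(baseline_amplitudes)] == p]
        baselines.append(base_trials.mean(axis=0)[base_mask].mean())
    values = _smooth(np.asarray(rows), kernel_width)
    baselines = np.asarray(baselines)
    values = _percent_change(values, baselines)
    tc = RateTimecourse(times=centers, values=values,
                        per_participant_baseline=baselines,
                        epoch_phase="", laterality="channel-cluster",
                        bin_width=bin_width, kernel_width=kernel_width,
                        kind="amplitude")
    if test_kwargs is not None:
        tc.test = _test_timecourse(values, **test_kwargs)
    return tc


def score_timecourse(catalog: pd.DataFrame, epochs_meta: pd.DataFrame,
                     scores: np.ndarray, epoch_phase: str,
                     bin_width: float = 0.05, kernel_width: float = 2.0,
                     time_range: tuple[float, float] = (-1.8, 1.8),
                     baseline_phase: str = "start",
                     baseline_window: tuple[float, float] = BASELINE_WINDOW,
                     test_kwargs: dict | None = None) -> RateTimecourse:
    """Mean burst waveform score per time bin, baseline-subtracted.

    ``scores`` aligns with ``catalog`` rows (one component's score per
    burst). Pooled over both electrode clusters, as the motif analysis
    treats shape independently of hemisphere.
    """
    catalog = catalog.assign(_score=scores)
    participants = np.sort(epochs_meta["participant"].unique())
    edges = _bin_edges(*time_range, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2
    sel = catalog[catalog["epoch_phase"] == epoch_phase]
    base_sel = catalog[catalog["epoch_phase"] == baseline_phase]
    base_mask = (base_sel["peak_time"] >= baseline_window[0]) & \
                (base_sel["peak_time"] < baseline_window[1])
    base_sel = base_sel[base_mask]
    rows = []
    baselines = []
    for p in participants:
        sub = sel[sel["participant"] == p]
        bin_idx = np.clip(np.digitize(sub["peak_time"], edges) - 1,
                          0, len(centers) - 1)
        means = np.full(len(centers), np.nan)
        for b in range(len(centers)):
            vals = sub["_score"].to_numpy()[bin_idx == b]
            if vals.size:
                means[b] = vals.mean()
        base_scores = base_sel[base_sel["participant"] == p]["_score"]
        baselines.append(base_scores.mean() if len(base_scores) else np.nan)
        rows.append(means)
    values = np.asarray(rows)
    # empty bins carry no bursts; fill with the participant baseline so the
    # corrected value is 0 there (no evidence of deviation)
    baselines = np.asarray(baselines)
    for i in range(values.shape[0]):
        values[i, np.isnan(values[i])] = baselines[i]
    values = _smooth(values, kernel_width) - baselines[:, None]
    tc = RateTimecourse(times=centers, values=values,
                        per_participant_baseline=baselines,
                        epoch_phase=epoch_phase, laterality="channel-cluster",
                        bin_width=bin_width, kernel_width=kernel_width,
                        kind="score")
    if test_kwargs is not None:
        tc.test = _test_timecourse(values, **test_kwargs)
    return tc


@dataclass
class QuartileAnalysis:
    component: int
    boundaries: np.ndarray                  # 3 interior score quantiles
    timecourses: list[RateTimecourse]       # one per quartile (1..4)
    flagged: list[int] = field(default_factory=list)   # empty-baseline quartiles


def quartile_rates(catalog: pd.DataFrame, epochs_meta: pd.DataFrame,
                   scores: np.ndarray, component: int, epoch_phase: str,
                   laterality: str | None = None,
                   bin_width: float = 0.05, kernel_width: float = 2.0,
                   time_range: tuple[float, float] = (-1.8, 1.8),
                   baseline_phase: str = "start",
                   baseline_window: tuple[float, float] = BASELINE_WINDOW,
                   test_kwargs: dict | None = None) -> QuartileAnalysis:
    """Per-quartile burst-rate modulation along one waveform motif.

    Quartile boundaries are linear-interpolation sample quantiles of the
    scores over the whole catalog; each quartile's baseline uses only that
    quartile's bursts. A quartile with an empty baseline window is flagged
    rather than silently zeroed.
    """
    scores = np.asarray(scores, dtype=float)
    bounds = np.quantile(scores, [0.25, 0.5, 0.75])
    quartile = np.digitize(scores, bounds)       # 0..3
    cat = catalog.assign(_quartile=quartile)
    tcs = []
    flagged = []
    for q in range(4):
        sub = cat[cat["_quartile"] == q]
        tc = rate_timecourse(sub, epochs_meta, epoch_phase, laterality,
                             bin_width, kernel_width, time_range,
                             baseline_phase, baseline_window,
                             n_streams=max(catalog["channel"].nunique(), 1),
                             test_kwargs=test_kwargs)
        if np.all(np.isnan(tc.values)) or np.all(tc.per_participant_baseline == 0):
            flagged.append(q)
        tcs.append(tc)
    return QuartileAnalysis(component=component, boundaries=bounds,
                            timecourses=tcs, flagged=flagged)


@dataclass
class IBIStats:
    ibis: np.ndarray
    cv: float
    surrogate_cvs: np.ndarray
    ci95_low: float
    histogram: tuple[np.ndarray, np.ndarray]
    unstable: bool = False


def ibi_cv(catalog: pd.DataFrame, n_surrogates: int = 1000,
           trial_duration: float = 3.6, tmin: float = -1.8,
           seed: int | None = 0, hist_bins: int = 40) -> IBIStats:
    """Coefficient of variation of inter-burst intervals vs surrogate nulls.

    IBIs are consecutive peak-time differences within each
    (participant, trial, epoch_phase, channel) stream. Surrogates assign
    each burst a uniform random time in its trial, preserving per-stream
    counts; the 95% lower confidence bound is the 2.5th percentile of the
    surrogate CV distribution.
    """
    rng = np.random.default_rng(seed)
    stream_cols = ["participant", "trial", "epoch_phase", "channel"]
    stream_counts = []
    ibis = []
    for _, grp in catalog.groupby([c for c in stream_cols
                                   if c in catalog.columns]):
        t = np.sort(grp["peak_time"].to_numpy())
        stream_counts.append(len(t))
        if len(t) >= 2:
            ibis.append(np.diff(t))
    ibis = np.concatenate(ibis) if ibis else np.empty(0)
    if len(ibis) < 2:
        raise ValueError("need at least 2 IBIs")
    cv = float(ibis.std() / ibis.mean())
    unstable = len(ibis) < 10
    if unstable:
        warnings.warn("fewer than 10 IBIs; CV is unstable", stacklevel=2)
    surr = np.empty(n_surrogates)
    counts = np.asarray(stream_counts)
    counts = counts[counts >= 2]
    for s in range(n_surrogates):
        s_ibis = []
        for c in counts:
            t = np.sort(rng.uniform(tmin, tmin + trial_duration, size=c))
            s_ibis.append(np.diff(t))
        s_all = np.concatenate(s_ibis)
        surr[s] = s_all.std() / s_all.mean()
    if np.ptp(ibis) > 1e-9:
        hist = np.histogram(ibis, bins=hist_bins)
    else:  # degenerate (perfectly periodic) intervals
        center = float(ibis[0])
        hist = np.histogram(ibis, bins=hist_bins,
                            range=(center - 0.5, center + 0.5))
    return IBIStats(ibis=ibis, cv=cv, surrogate_cvs=surr,
                    ci95_low=float(np.percentile(surr, 2.5)),
                    histogram=hist, unstable=unstable)
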