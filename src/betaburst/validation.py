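"""Ground-truth matching utilities for synthetic-recovery evaluation.

The adaptive detector deliberately catalogs events down to the noise
floor, so recovery metrics are computed on the amplitude-qualified subset:
detections whose newly explained TF amplitude (``residual_amplitude``, the
residual value at the moment of detection) exceeds a threshold tied to the
background TF field. Recall is assessed over ground-truth bursts inside
the TF validity region (edge-masked samples cannot host detections).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RecoveryMetrics:
    recall: float
    fdr: float
    n_true: int
    n_detected: int
    n_matched: int
    time_mae: float       # s, over matched pairs
    freq_mae: float       # Hz, over matched pairs


def tf_background_sd(config, model, band, search_pad: float = 5.0,
                     n_epochs: int = 10, freq_step: float = 0.5) -> float:
    """SD of the aperiodic-subtracted TF amplitude field without bursts.

    Generates a burst-free replica of ``config`` and measures the residual
    TF field inside the detection window; used to set the
    amplitude-qualification threshold for recovery metrics.
    """
    from dataclasses import replace

    from .synthetic import generate_dataset
    from .tf import superlet_tf

    quiet = replace(config, burst_base_rate=0.0, n_trials=max(n_epochs, 1),
                    n_participants=1, epoch_phases=("start",),
                    channels=config.channels[:2], motif_basis=None)
    epochs, _ = generate_dataset(quiet)
    lo = max(band.low - search_pad, 1.0)
    hi = band.high + search_pad
    freqs = np.arange(np.floor(lo / freq_step) * freq_step, hi + 1e-9, freq_step)
    ap = np.sqrt(model.aperiodic_power(freqs))
    vals = []
    for ei in range(epochs.n_epochs):
        tf = superlet_tf(epochs.data[ei, 0], epochs.sfreq, freqs=freqs,
                         tmin=epochs.tmin)
        amp = np.clip(tf.amplitude - ap[:, None], 0.0, None)
        vals.append(amp[tf.valid])
    return float(np.concatenate(vals).std())


def match_recovery(catalog: pd.DataFrame, truth: pd.DataFrame,
                   tol_time: float = 0.05, tol_freq: float = 2.0,
                   min_residual_amplitude: float = 0.0,
                   valid_interval: tuple[float, float] | None = None,
                   ) -> RecoveryMetrics:
    """One-to-one greedy matching (by detection amplitude, descending).

    ``valid_interval`` restricts both ground truth and detections to peak
    times in that range (the TF validity region). FDR counts qualified
    detections without a match; recall counts ground-truth bursts with one.
    """
    det = catalog.copy()
    tru = truth.copy()
    if valid_interval is not None:
        lo, hi = valid_interval
        det = det[(det["peak_time"] >= lo) & (det["peak_time"] <= hi)]
        tru = tru[(tru["peak_time"] >= lo) & (tru["peak_time"] <= hi)]
    if min_residual_amplitude > 0 and "residual_amplitude" in det:
        det = det[det["residual_amplitude"] >= min_residual_amplitude]
    keys = ["trial", "channel"]
    if "participant" in det.columns and "participant" in tru.columns:
        keys = ["participant"] + keys
    if "epoch_phase" in det.columns and "epoch_phase" in tru.columns:
        keys = keys + ["epoch_phase"]
    det = det.sort_values("peak_amplitude", ascending=False)
    matched_truth: set = set()
    n_matched = 0
    dts, dfs = [], []
    truth_groups = {k: g for k, g in tru.groupby(keys)}
    for _, d in det.iterrows():
        key = tuple(d[k] for k in keys)
        grp = truth_groups.get(key if len(keys) > 1 else key[0])
        if grp is None:
            continue
        cand = grp[(np.abs(grp["peak_time"] - d["peak_time"]) <= tol_time)
                   & (np.abs(grp["peak_freq"] - d["peak_freq"]) <= tol_freq)]
        cand = cand[~cand.index.isin(matched_truth)]
        if len(cand):
            idx = (np.abs(cand["peak_time"] - d["peak_time"])).idxmin()
            matched_truth.add(idx)
            n_matched += 1
            dts.append(abs(tru.loc[idx, "peak_time"] - d["peak_time"]))
            dfs.append(abs(tru.loc[idx, "peak_freq"] - d["peak_freq"]))
    n_det = len(det)
    n_true = len(tru)
    return RecoveryMetrics(
        recall=n_matched / n_true if n_true else float("nan"),
        fdr=(n_det - n_matched) / n_det if n_det else 0.0,
        n_true=n_true, n_detected=n_det, n_matched=n_matched,
        time_mae=float(np.mean(dts)) if dts else float("nan"),
        freq_mae=float(np.mean(dfs)) if dfs else float("nan"),
    )
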