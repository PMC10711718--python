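"""Cluster-permutation inference for baseline-deviation time courses.

Three pieces, shared by every rate/amplitude/score analysis:

* ``hat_t`` — a one-sample t statistic with relative variance
  regularization: each time point's sample variance is inflated by
  ``sigma`` times the maximum variance over time points, damping spurious
  t values at near-zero-variance points.
* ``tfce`` — threshold-free cluster enhancement of a 1D statistic map:
  for each time point, integrate ``extent**E * height**H`` of the
  contiguous supra-threshold run containing it over a ladder of thresholds,
  removing the need for a fixed cluster-forming cutoff. Two-sided maps are
  enhanced separately per sign.
* ``max_stat_permutation`` — family-wise error control by sign-flipping
  participants: the null distribution is the maximum enhanced statistic
  over all time points (and both signs) per permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ClusterTestResult:
    observed_stat: np.ndarray       # hat t per time point
    enhanced_stat: np.ndarray       # signed TFCE-enhanced statistic
    null_max: np.ndarray            # one entry per permutation
    p: np.ndarray                   # per time point
    significant: np.ndarray         # boolean mask at alpha
    alpha: float
    hat_sigma: float
    n_permutations: int
    seed: int | None


def hat_t(samples: np.ndarray, sigma: float = 0.001) -> np.ndarray:
    """Variance-regularized one-sample t across the first axis.

    ``samples`` is participants x time points; the adjusted variance is
    ``var + sigma * max_t(var)``. With ``sigma=0`` this is the ordinary
    one-sample t. All-zero variance with zero mean yields t = 0.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n = samples.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    mean = samples.mean(axis=0)
    var = samples.var(axis=0, ddof=1)
    var_adj = var + sigma * var.max() if var.max() > 0 else var
    denom = np.sqrt(var_adj / n)
    t = np.zeros_like(mean)
    nz = denom > 0
    t[nz] = mean[nz] / denom[nz]
    # zero variance, nonzero mean: infinite evidence, keep sign with inf
    t[~nz & (mean != 0)] = np.sign(mean[~nz & (mean != 0)]) * np.inf
    return t


def tfce(stat_map: np.ndarray, start: float = 0.0, step: float = 0.01,
         E: float = 0.5, H: float = 2.0) -> np.ndarray:
    """Threshold-free cluster enhancement of 1D maps.

    ``stat_map`` may be one map ``(n_points,)`` or a stack
    ``(n_maps, n_points)``; enhancement is per map. Values are assumed
    non-negative (use :func:`tfce_two_sided` for signed maps):
    ``enhanced(i) = sum over h in (start+step, start+2*step, ...] of
    extent(i, h)**E * h**H * step`` where ``extent`` is the length of the
    contiguous run above ``h`` containing ``i``.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    maps = np.atleast_2d(np.asarray(stat_map, dtype=float))
    finite_max = np.nanmax(maps) if maps.size else 0.0
    out = np.zeros_like(maps)
    if not np.isfinite(finite_max):
        finite = maps[np.isfinite(maps)]
        finite_max = finite.max() if finite.size else 0.0
    if finite_max <= start:
        return out[0] if np.asarray(stat_map).ndim == 1 else out
    heights = np.arange(start + step, finite_max + step, step)
    n_maps, n_pts = maps.shape
    idx = np.arange(n_pts)
    for h in heights:
        above = maps >= h  # (n_maps, n_pts); inf counts at every height
        if not above.any():
            continue
        # start index of the run containing each point (vectorized run-length)
        is_start = above & ~np.pad(above[:, :-1], ((0, 0), (1, 0)))
        start_idx = np.where(is_start, idx, -1)
        start_idx = np.maximum.accumulate(start_idx, axis=1)
        is_end = above & ~np.pad(above[:, 1:], ((0, 0), (0, 1)))
        end_idx = np.where(is_end, idx, n_pts)
        end_idx = np.minimum.accumulate(end_idx[:, ::-1], axis=1)[:, ::-1]
        extent = np.where(above, end_idx - start_idx + 1, 0)
        out += np.where(above, extent.astype(float) ** E * h**H * step, 0.0)
    return out[0] if np.asarray(stat_map).ndim == 1 else out


def tfce_two_sided(stat_map: np.ndarray, start: float = 0.0, step: float = 0.01,
                   E: float = 0.5, H: float = 2.0) -> np.ndarray:
    """Signed enhancement: positive and negative parts enhanced separately."""
    maps = np.asarray(stat_map, dtype=float)
    pos = tfce(np.clip(maps, 0, None), start, step, E, H)
    neg = tfce(np.clip(-maps, 0, None), start, step, E, H)
    return pos - neg


def max_stat_permutation(samples: np.ndarray, n_perm: int = 1000,
                         alpha: float = 0.05, seed: int | None = 0,
                         hat_sigma: float = 0.001, tfce_step: float = 0.01,
                         tfce_E: float = 0.5, tfce_H: float = 2.0,
                         ) -> ClusterTestResult:
    """Sign-flip permutation test with a TFCE max statistic.

    ``samples`` is participants x time points of baseline-corrected values
    (null: symmetric around zero). Each permutation flips every
    participant's sign independently; the null distribution collects the
    maximum absolute enhanced statistic over time points. p-values use the
    add-one estimator; a warning is raised when ``n_perm`` cannot resolve
    the requested alpha.
    """
    import warnings

    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n_subj, n_pts = samples.shape
    if 1.0 / (n_perm + 1) > alpha:
        warnings.warn(
            f"n_perm={n_perm} cannot reach alpha={alpha}; the smallest "
            f"attainable p-value is {1 / (n_perm + 1):.4g}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    t_obs = hat_t(samples, hat_sigma)
    enhanced = tfce_two_sided(t_obs, 0.0, tfce_step, tfce_E, tfce_H)

    # sign flips leave x^2 unchanged, so per-permutation variance follows
    # from the flipped mean and the fixed sum of squares
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    mean_p = flips @ samples / n_subj
    ss = np.sum(samples**2, axis=0)
    var_p = np.clip((ss - n_subj * mean_p**2) / (n_subj - 1), 0.0, None)
    vmax = var_p.max(axis=1, keepdims=True)
    var_adj = var_p + hat_sigma * vmax
    denom = np.sqrt(var_adj / n_subj)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_p = np.where(denom > 0, mean_p / denom, 0.0)
    enh_pos = tfce(np.clip(t_p, 0, None), 0.0, tfce_step, tfce_E, tfce_H)
    enh_neg = tfce(np.clip(-t_p, 0, None), 0.0, tfce_step, tfce_E, tfce_H)
    null_max = np.maximum(enh_pos.max(axis=1), enh_neg.max(axis=1))

    abs_enh = np.abs(enhanced)
    p = (1.0 + (null_max[:, None] >= abs_enh[None, :]).sum(axis=0)) / (n_perm + 1.0)
    return ClusterTestResult(
        observed_stat=t_obs, enhanced_stat=enhanced, null_max=null_max,
        p=p, significant=p < alpha, alpha=alpha, hat_sigma=hat_sigma,
        n_permutations=n_perm, seed=seed,
    )
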