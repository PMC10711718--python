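"""Waveform warping and motif analysis of burst shapes.

Infant-group median waveforms are aligned to the adult median with dynamic
time warping under the Rabiner-Juang Type-V local constraint with
slope-weighting (c): allowed net moves (1,1), (1,2), (1,3), (2,1), (3,1)
— slopes between 1/3 and 3 — with each elementary move weighted by its
query-axis increment and the accumulated distance normalized by the query
length. The resulting alignment is applied to every burst waveform of the
group, mapping it onto the reference time base (many-to-one mappings
averaged, one-to-many filled by the repeated query sample).

Burst-shape motifs are the principal components of the warped waveform
matrix (centered, not variance-scaled: amplitude is meaningful). Component
significance is assessed by independently permuting each time point
(column) across bursts — destroying inter-timepoint correlation while
preserving marginal amplitude distributions — and comparing each rank's
explained-variance fraction with its permutation distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

# Rabiner-Juang Type V productions as (d_query, d_reference) net moves
_RJ5_PRODUCTIONS = ((1, 1), (1, 2), (1, 3), (2, 1), (3, 1))


@dataclass
class WarpModel:
    reference: np.ndarray
    query: np.ndarray
    alignment_path: list[tuple[int, int]]   # (query index, reference index)
    normalized_distance: float

    def to_json(self) -> str:
        import json

        return json.dumps({
            "reference": self.reference.tolist(),
            "query": self.query.tolist(),
            "alignment_path": [list(p) for p in self.alignment_path],
            "normalized_distance": self.normalized_distance,
        })

    @classmethod
    def from_json(cls, text: str) -> "WarpModel":
        import json

        raw = json.loads(text)
        return cls(reference=np.asarray(raw["reference"]),
                   query=np.asarray(raw["query"]),
                   alignment_path=[tuple(p) for p in raw["alignment_path"]],
                   normalized_distance=raw["normalized_distance"])


def _production_cells(p: int, q: int) -> list[tuple[int, int, float]]:
    """Cells visited by a production, diagonal-first, with type-(c) weights.

    Each elementary move is weighted by its query increment: the initial
    diagonal move weighs 1, trailing horizontal (reference-only) moves weigh
    0, trailing vertical (query-only) moves weigh 1.
    """
    cells = []
    if p == 1:
        # moves: (1,1) then (0,1) x (q-1); offsets relative to the start cell
        for step in range(1, q + 1):
            weight = 1.0 if step == 1 else 0.0
            cells.append((1, step, weight))
    else:
        # moves: (1,1) then (1,0) x (p-1)
        for step in range(1, p + 1):
            cells.append((step, 1, 1.0))
    return cells


def dtw_median(query_median: np.ndarray, reference_median: np.ndarray) -> WarpModel:
    """Align a normalized median waveform to the reference median.

    Both inputs should be amplitude-normalized (unit maximum absolute
    value); this is asserted loosely, not enforced. The accumulated cost is
    normalized by the query length (the Type-(c) normalization), so
    aligning a signal to itself gives distance 0 on the diagonal path.

    Note: the slope weighting is asymmetric, so the distance is not in
    general symmetric under swapping query and reference.
    """
    query = np.asarray(query_median, dtype=float)
    ref = np.asarray(reference_median, dtype=float)
    if query.size == 0 or ref.size == 0:
        raise ValueError("cannot warp length-0 waveforms")
    n, m = len(query), len(ref)
    d = np.abs(query[:, None] - ref[None, :])
    g = np.full((n, m), np.inf)
    back = np.full((n, m), -1, dtype=int)
    g[0, 0] = d[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            best_k = -1
            for k, (p, q) in enumerate(_RJ5_PRODUCTIONS):
                pi, pj = i - p, j - q
                if pi < 0 or pj < 0 or not np.isfinite(g[pi, pj]):
                    continue
                cost = g[pi, pj]
                for di, dj, w in _production_cells(p, q):
                    cost += w * d[pi + di, pj + dj]
                if cost < best:
                    best = cost
                    best_k = k
            g[i, j] = best
            back[i, j] = best_k
    if not np.isfinite(g[n - 1, m - 1]):
        raise ValueError("no admissible warping path under the step pattern")
    # trace back through production end-points, then expand intermediate cells
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        p, q = _RJ5_PRODUCTIONS[back[i, j]]
        pi, pj = i - p, j - q
        inter = [(pi + di, pj + dj) for di, dj, _ in _production_cells(p, q)]
        for cell in reversed(inter[:-1]):
            path.append(cell)
        path.append((pi, pj))
        i, j = pi, pj
    path.reverse()
    return WarpModel(reference=ref, query=query, alignment_path=path,
                     normalized_distance=float(g[n - 1, m - 1] / n))


def identity_warp(length: int) -> WarpModel:
    """Diagonal (no-op) warp for waveforms already on the reference base."""
    x = np.zeros(length)
    return WarpModel(reference=x, query=x,
                     alignment_path=[(i, i) for i in range(length)],
                     normalized_distance=0.0)


def apply_warp(warp: WarpModel, waveforms: np.ndarray) -> np.ndarray:
    """Map waveforms from the query time base onto the reference time base.

    Reference samples hit by several query indices receive their average;
    reference samples sharing one query index repeat it.
    """
    waveforms = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if waveforms.shape[1] != len(warp.query):
        raise ValueError("waveform length does not match the warp's query")
    m = len(warp.reference)
    out = np.zeros((waveforms.shape[0], m))
    counts = np.zeros(m)
    qi = np.array([p[0] for p in warp.alignment_path])
    rj = np.array([p[1] for p in warp.alignment_path])
    np.add.at(counts, rj, 1.0)
    for b in range(waveforms.shape[0]):
        acc = np.zeros(m)
        np.add.at(acc, rj, waveforms[b, qi])
        out[b] = acc / counts
    return out


@dataclass
class WaveformSpace:
    matrix: np.ndarray                  # bursts x time points
    eigenvectors: np.ndarray            # n_components x time points
    explained_variance: np.ndarray      # fraction per component
    scores: np.ndarray                  # bursts x components
    mean_: np.ndarray
    significant: np.ndarray | None = None
    p_values: np.ndarray | None = None
    alpha: float = 0.0035
    n_permutations: int = 100

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[0]

    def project(self, waveforms: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(waveforms) - self.mean_) @ self.eigenvectors.T


def fit_pca(matrix: np.ndarray, n_components: int = 20) -> WaveformSpace:
    """PCA of the (centered, unscaled) warped waveform matrix.

    Rank-deficient input yields as many components as the matrix rank.
    """
    matrix = np.asarray(matrix, dtype=float)
    k = min(n_components, matrix.shape[0] - 1 if matrix.shape[0] > 1 else 1,
            matrix.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(matrix)
    # drop numerically null components (rank deficiency)
    rank = int(np.sum(pca.explained_variance_ > 1e-12 * max(
        pca.explained_variance_[0], 1e-30)))
    rank = max(rank, 1)
    return WaveformSpace(
        matrix=matrix,
        eigenvectors=pca.components_[:rank],
        explained_variance=pca.explained_variance_ratio_[:rank],
        scores=scores[:, :rank],
        mean_=pca.mean_,
    )


def permutation_significance(space: WaveformSpace, n_perm: int = 100,
                             alpha: float = 0.0035,
                             seed: int | None = 0) -> WaveformSpace:
    """Column-shuffle permutation test on explained-variance fractions.

    Each permutation shuffles every time point (column) independently across
    bursts and refits the PCA; the p-value at rank k is the add-one estimate
    of how often the shuffled rank-k explained-variance fraction reaches the
    observed one. Components with p < alpha are flagged significant.
    """
    import warnings

    if 1.0 / (n_perm + 1) > alpha:
        warnings.warn(
            f"n_perm={n_perm} cannot reach alpha={alpha}; the smallest "
            f"attainable p-value is {1 / (n_perm + 1):.4g}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    matrix = space.matrix
    k = space.n_components
    observed = space.explained_variance
    exceed = np.zeros(k)
    shuffled = matrix.copy()
    for _ in range(n_perm):
        for col in range(matrix.shape[1]):
            shuffled[:, col] = matrix[rng.permutation(matrix.shape[0]), col]
        sp = PCA(n_components=k, svd_solver="full").fit(shuffled)
        ev = np.zeros(k)
        ev[: len(sp.explained_variance_ratio_)] = sp.explained_variance_ratio_[:k]
        exceed += ev >= observed
    p = (1.0 + exceed) / (n_perm + 1.0)
    space.p_values = p
    space.significant = p < alpha
    space.alpha = alpha
    space.n_permutations = n_perm
    return space


def compare_pca(space_a: WaveformSpace, space_b: WaveformSpace,
                waveforms: np.ndarray | None = None):
    """Absolute correlation matrices between two PCA spaces.

    Returns ``(eig_r, eig_rowmax, score_r, score_rowmax)``: the |r| matrix
    between eigenvectors (rows: ``space_a`` components) and its per-row
    maximum, and — when ``waveforms`` (a common burst set) is given — the
    same for the burst scores after projecting those waveforms into both
    spaces. PCA sign ambiguity is handled by the absolute value.
    """
    if space_a.eigenvectors.shape[1] != space_b.eigenvectors.shape[1]:
        raise ValueError("spaces have different waveform lengths")
    eig_r = np.abs(_corr_rows(space_a.eigenvectors, space_b.eigenvectors))
    eig_rowmax = eig_r.max(axis=1)
    score_r = score_rowmax = None
    if waveforms is not None:
        sa = space_a.project(waveforms)
        sb = space_b.project(waveforms)
        score_r = np.abs(_corr_rows(sa.T, sb.T))
        score_rowmax = score_r.max(axis=1)
    return eig_r, eig_rowmax, score_r, score_rowmax


def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (a / na[:, None]) @ (b / nb[:, None]).T
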