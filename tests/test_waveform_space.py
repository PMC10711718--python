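from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from betaburst.waveform_space import (WaveformSpace, apply_warp, compare_pca,
                                      dtw_median, fit_pca, identity_warp,
                                      permutation_significance)


def oracle_rj5c_distance(query, reference):
    """Independent top-down dynamic program for the Type-V/(c) step pattern.

    Memoized recursion over production end-points; charges each elementary
    move by its query-axis increment with a diagonal-first decomposition,
    and normalizes by the query length.
    """
    q = np.asarray(query, float)
    r = np.asarray(reference, float)

    def d(i, j):
        return abs(q[i] - r[j])

    @lru_cache(maxsize=None)
    def g(i, j):
        if i == 0 and j == 0:
            return d(0, 0)
        best = np.inf
        # (1,1)
        if i >= 1 and j >= 1:
            best = min(best, g(i - 1, j - 1) + d(i, j))
        # (1,2): diagonal to (i, j-1), then reference-only (weight 0)
        if i >= 1 and j >= 2:
            best = min(best, g(i - 1, j - 2) + d(i, j - 1))
        # (1,3)
        if i >= 1 and j >= 3:
            best = min(best, g(i - 1, j - 3) + d(i, j - 2))
        # (2,1): diagonal to (i-1, j), then query-only (weight 1 each)
        if i >= 2 and j >= 1:
            best = min(best, g(i - 2, j - 1) + d(i - 1, j) + d(i, j))
        # (3,1)
        if i >= 3 and j >= 1:
            best = min(best, g(i - 3, j - 1) + d(i - 2, j) + d(i - 1, j)
                       + d(i, j))
        return best

    return g(len(q) - 1, len(r) - 1) / len(q)


class TestDtw:
    def test_identity_zero_distance_diagonal_path(self):
        x = np.sin(np.linspace(0, 3 * np.pi, 40))
        warp = dtw_median(x, x)
        assert warp.normalized_distance == pytest.approx(0.0, abs=1e-12)
        assert warp.alignment_path == [(i, i) for i in range(40)]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(8):
            q = rng.standard_normal(20)
            r = rng.standard_normal(20)
            warp = dtw_median(q, r)
            assert warp.normalized_distance == pytest.approx(
                oracle_rj5c_distance(q, r), abs=1e-10)

    def test_asymmetric_lengths_against_oracle(self, rng):
        q = rng.standard_normal(15)
        r = rng.standard_normal(22)
        warp = dtw_median(q, r)
        assert warp.normalized_distance == pytest.approx(
            oracle_rj5c_distance(q, r), abs=1e-10)

    def test_known_stretch_recovers_slope(self):
        t = np.linspace(0, 1, 60)
        ref = np.sin(2 * np.pi * 3 * t) * np.exp(-((t - 0.5) ** 2) / 0.02)
        ref = ref / np.abs(ref).max()
        tq = np.linspace(0, 1, 90)  # query is the same shape, 1.5x longer
        query = np.sin(2 * np.pi * 3 * tq) * np.exp(-((tq - 0.5) ** 2) / 0.02)
        query = query / np.abs(query).max()
        warp = dtw_median(query, ref)
        path = np.asarray(warp.alignment_path)
        lo, hi = int(0.1 * len(path)), int(0.9 * len(path))
        slope = np.polyfit(path[lo:hi, 1], path[lo:hi, 0], 1)[0]
        assert slope == pytest.approx(1.5, abs=0.15)

    def test_path_monotone_and_endpoints(self, rng):
        q, r = rng.standard_normal(25), rng.standard_normal(30)
        warp = dtw_median(q, r)
        path = np.asarray(warp.alignment_path)
        assert tuple(path[0]) == (0, 0)
        assert tuple(path[-1]) == (24, 29)
        assert (np.diff(path[:, 0]) >= 0).all()
        assert (np.diff(path[:, 1]) >= 0).all()

    def test_distance_not_symmetric_in_general(self, rng):
        """Type-(c) slope weighting is asymmetric by construction; document
        rather than assume symmetry."""
        q = rng.standard_normal(20)
        r = rng.standard_normal(20)
        d_qr = dtw_median(q, r).normalized_distance
        d_rq = dtw_median(r, q).normalized_distance
        # both are valid oracle values; equality is not required
        assert d_qr == pytest.approx(oracle_rj5c_distance(q, r), abs=1e-10)
        assert d_rq == pytest.approx(oracle_rj5c_distance(r, q), abs=1e-10)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            dtw_median(np.array([]), np.ones(5))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, st.integers(4, 15),
                      elements=st.floats(-2, 2)),
           hnp.arrays(np.float64, st.integers(4, 15),
                      elements=st.floats(-2, 2)))
    def test_property_path_valid_and_matches_oracle(self, q, r):
        try:
            warp = dtw_median(q, r)
        except ValueError:
            # slope constraints can make extreme length ratios inadmissible
            assert max(len(q), len(r)) - 1 > 3 * (min(len(q), len(r)) - 1)
            return
        path = np.asarray(warp.alignment_path)
        assert tuple(path[0]) == (0, 0)
        assert tuple(path[-1]) == (len(q) - 1, len(r) - 1)
        assert (np.diff(path, axis=0) >= 0).all()
        assert warp.normalized_distance == pytest.approx(
            oracle_rj5c_distance(q, r), abs=1e-10)


class TestApplyWarp:
    def test_identity_warp_is_noop(self, rng):
        w = rng.standard_normal((5, 30))
        out = apply_warp(identity_warp(30), w)
        assert np.allclose(out, w)

    def test_constant_waveform_stays_constant(self):
        t = np.linspace(0, 1, 40)
        ref = np.sin(2 * np.pi * 2 * t)
        query = np.sin(2 * np.pi * 2 * np.linspace(0, 1, 50))
        warp = dtw_median(query, ref)
        out = apply_warp(warp, np.full((1, 50), 3.3))
        assert out.shape == (1, 40)
        assert np.allclose(out, 3.3)

    def test_zero_crossings_preserved(self):
        """Warping a mild stretch preserves oscillatory structure."""
        t = np.linspace(-1, 1, 80)
        ref = np.cos(2 * np.pi * 3 * t) * np.exp(-(t**2) / 0.2)
        tq = np.linspace(-1, 1, 96)
        query = np.cos(2 * np.pi * 3 * tq) * np.exp(-(tq**2) / 0.2)
        warp = dtw_median(query / np.abs(query).max(),
                          ref / np.abs(ref).max())
        out = apply_warp(warp, query[None, :])[0]
        zc = lambda v: int(np.sum(np.diff(np.sign(v)) != 0))
        assert abs(zc(out) - zc(ref)) <= 1

    def test_length_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="length"):
            apply_warp(identity_warp(30), rng.standard_normal((2, 31)))

    def test_warp_model_json_round_trip(self, rng):
        from betaburst.waveform_space import WarpModel

        warp = dtw_median(rng.standard_normal(20), rng.standard_normal(25))
        back = WarpModel.from_json(warp.to_json())
        assert back.alignment_path == warp.alignment_path
        assert back.normalized_distance == warp.normalized_distance
        assert np.allclose(back.query, warp.query)


class TestPca:
    def test_identical_rows_degenerate(self):
        matrix = np.tile(np.sin(np.linspace(0, 6, 50)), (30, 1))
        space = fit_pca(matrix)
        assert space.scores.shape[0] == 30
        assert np.allclose(space.scores, 0.0, atol=1e-8)

    def test_rank_one_dominates(self, rng):
        direction = rng.standard_normal(60)
        weights = rng.standard_normal(100)[:, None]
        matrix = weights * direction + 1e-3 * rng.standard_normal((100, 60))
        space = fit_pca(matrix)
        assert space.explained_variance[0] > 0.99

    def test_full_rank_reconstruction(self, rng):
        matrix = rng.standard_normal((40, 20))
        space = fit_pca(matrix, n_components=20)
        recon = space.scores @ space.eigenvectors + space.mean_
        assert np.abs(recon - matrix).max() < 1e-6

    def test_eigenvectors_orthonormal_variance_sorted(self, rng):
        matrix = rng.standard_normal((80, 30))
        space = fit_pca(matrix)
        gram = space.eigenvectors @ space.eigenvectors.T
        assert np.allclose(gram, np.eye(space.n_components), atol=1e-8)
        assert (np.diff(space.explained_variance) <= 1e-12).all()


class TestPermutation:
    def test_iid_noise_rarely_significant(self, rng):
        hits = 0
        for rep in range(5):
            matrix = rng.standard_normal((120, 30))
            space = fit_pca(matrix, n_components=10)
            space = permutation_significance(space, n_perm=99, alpha=0.01,
                                             seed=rep)
            hits += int(space.significant.any())
        assert hits <= 1

    def test_rank_one_signal_minimal_p(self, rng):
        direction = rng.standard_normal(40)
        matrix = rng.standard_normal(200)[:, None] * direction \
            + 0.05 * rng.standard_normal((200, 40))
        space = fit_pca(matrix, n_components=5)
        space = permutation_significance(space, n_perm=99, alpha=0.05, seed=0)
        assert space.p_values[0] == pytest.approx(1 / 100)
        assert space.significant[0]

    def test_seed_determinism(self, rng):
        matrix = rng.standard_normal((60, 20))
        space1 = permutation_significance(fit_pca(matrix, 5), n_perm=30,
                                          alpha=0.5, seed=7)
        space2 = permutation_significance(fit_pca(matrix, 5), n_perm=30,
                                          alpha=0.5, seed=7)
        assert np.array_equal(space1.p_values, space2.p_values)

    def test_unreachable_alpha_warns(self, rng):
        space = fit_pca(rng.standard_normal((30, 10)), 3)
        with pytest.warns(UserWarning, match="cannot reach"):
            permutation_significance(space, n_perm=10, alpha=0.0035)


class TestComparePca:
    def test_self_comparison_perfect(self, rng):
        space = fit_pca(rng.standard_normal((50, 20)), 5)
        eig_r, rowmax, _, _ = compare_pca(space, space)
        assert np.allclose(rowmax, 1.0, atol=1e-8)

    def test_sign_flip_invariance(self, rng):
        space = fit_pca(rng.standard_normal((50, 20)), 5)
        flipped = WaveformSpace(
            matrix=space.matrix, eigenvectors=-space.eigenvectors,
            explained_variance=space.explained_variance,
            scores=-space.scores, mean_=space.mean_)
        _, rowmax, _, score_rowmax = compare_pca(space, flipped,
                                                 waveforms=space.matrix)
        assert np.allclose(rowmax, 1.0, atol=1e-8)
        assert np.allclose(score_rowmax, 1.0, atol=1e-8)

    def test_split_half_stability_on_motif_data(self, rng):
        """Two PCAs fit on disjoint halves of motif-structured data agree on
        the motif-carrying components."""
        n, p = 400, 50
        motifs = np.linalg.qr(rng.standard_normal((p, 3)))[0][:, :3].T
        weights = rng.standard_normal((n, 3)) * [3.0, 2.0, 1.5]
        data = weights @ motifs + 0.1 * rng.standard_normal((n, p))
        a = fit_pca(data[: n // 2], 5)
        b = fit_pca(data[n // 2:], 5)
        _, rowmax, _, _ = compare_pca(a, b)
        assert (rowmax[:3] >= 0.9).all()

    def test_dimension_mismatch_errors(self, rng):
        a = fit_pca(rng.standard_normal((30, 10)), 3)
        b = fit_pca(rng.standard_normal((30, 12)), 3)
        with pytest.raises(ValueError, match="length"):
            compare_pca(a, b)
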