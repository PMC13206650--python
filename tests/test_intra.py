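"""Intra-tissue correlation matrices, summaries, clustering, comparisons."""

import itertools
import math

import numpy as np
import pytest

from circsync.datasets import minmax_normalize
from circsync.errors import ConstantProfileError, ValidationError
from circsync.intra import (
    cluster_waveform,
    compare_intra,
    correlation_matrix,
    hierarchical_order,
    pair_overlap,
    pearson_r,
    significant_pairs,
    summarize_matrix,
)
from circsync.stats import critical_r, pearson_pvalue

from conftest import ZT12, make_series


# -- independent oracles ------------------------------------------------------

def textbook_pearson(x, y):
    """Direct textbook formula: covariance over product of standard deviations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = math.sqrt(n * (x * x).sum() - sx * sx) * math.sqrt(n * (y * y).sum() - sy * sy)
    return num / den


def naive_complete_linkage_heights(d):
    """O(G^3) agglomeration: returns sorted merge heights."""
    clusters = [[i] for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            h = max(d[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(heights)


class TestPearson:
    def test_perfect_positive_and_negative(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x, y = [1, 2, 3, 5], [2, 1, 4, 6]
        assert pearson_r(x, y) == pytest.approx(textbook_pearson(x, y), abs=1e-12)

    def test_constant_profile_rejected(self):
        with pytest.raises(ConstantProfileError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_pvalue_extremes_and_boundary(self):
        assert pearson_pvalue(0.0, 12) == pytest.approx(1.0)
        assert pearson_pvalue(1.0, 4) == 0.0
        # r = 0.576 at n = 12 sits at the two-sided 5% boundary (t = 2.228, 10 df)
        assert pearson_pvalue(0.576, 12) == pytest.approx(0.05, abs=0.002)

    def test_critical_r_at_twelve_timepoints(self):
        assert critical_r(12, 0.05) == pytest.approx(0.576, abs=0.001)


class TestCorrelationMatrix:
    def test_three_gene_sign_structure(self):
        ts = make_series([[1, 2, 3, 2], [2, 4, 6, 4], [3, 2, 1, 2]],
                         genes=["x", "y", "z"])
        mat = correlation_matrix(ts)
        expected = np.array([[1, 1, -1], [1, 1, -1], [-1, -1, 1]], dtype=float)
        np.testing.assert_allclose(mat.r, expected, atol=1e-12)

    def test_symmetry_exact(self, random_series):
        mat = correlation_matrix(random_series)
        np.testing.assert_array_equal(mat.r, mat.r.T)
        np.testing.assert_allclose(np.diag(mat.r), 1.0)

    def test_matches_brute_force_double_loop(self, random_series):
        mat = correlation_matrix(random_series)
        for i in range(mat.n_genes):
            for j in range(i + 1, mat.n_genes):
                expected = textbook_pearson(
                    random_series.values[i], random_series.values[j]
                )
                assert mat.r[i, j] == pytest.approx(expected, abs=1e-12)


class TestSummaries:
    def test_fully_correlated_matrix(self):
        ts = make_series([[1, 2, 3, 2], [2, 4, 6, 4], [3, 2, 1, 2]])
        s = summarize_matrix(correlation_matrix(ts))
        assert s.mean_abs_r == pytest.approx(1.0)
        assert s.n_significant == 3 and s.n_pairs == 3

    def test_pair_below_critical_r_not_significant(self):
        # two genes engineered to r = 0.5 over 12 points: 0.5 < 0.576 critical
        x = np.arange(12.0)
        u = (x - x.mean()) / np.linalg.norm(x - x.mean())
        v = np.sin(np.arange(12.0))
        v -= v.mean()
        v -= (v @ u) * u  # Gram-Schmidt: v now orthogonal to the x direction
        y = 0.5 * u + math.sqrt(0.75) * v / np.linalg.norm(v)
        ts = make_series(np.array([x, y]), timepoints=ZT12)
        mat = correlation_matrix(ts)
        assert mat.r[0, 1] == pytest.approx(0.5, abs=1e-12)
        s = summarize_matrix(mat)
        assert s.mean_abs_r == pytest.approx(0.5, abs=1e-12)
        assert s.n_significant == 0

    def test_matches_brute_force_recount(self, random_series):
        mat = correlation_matrix(random_series)
        s = summarize_matrix(mat, alpha=0.05)
        vals, sig = [], 0
        for i in range(mat.n_genes):
            for j in range(i + 1, mat.n_genes):
                r = textbook_pearson(random_series.values[i], random_series.values[j])
                vals.append(abs(r))
                if pearson_pvalue(r, 12) < 0.05:
                    sig += 1
        assert s.mean_abs_r == pytest.approx(np.mean(vals), abs=1e-12)
        assert s.n_significant == sig

    def test_significance_count_monotone_in_alpha(self, random_series):
        mat = correlation_matrix(random_series)
        counts = [summarize_matrix(mat, alpha=a).n_significant
                  for a in (0.2, 0.1, 0.05, 0.01, 0.001)]
        assert counts == sorted(counts, reverse=True)

    def test_mean_abs_r_invariant_to_gene_order_and_affine_rescale(self, rng):
        values = rng.uniform(1, 9, (10, 12))
        base = summarize_matrix(correlation_matrix(make_series(values, timepoints=ZT12)))
        perm = rng.permutation(10)
        scales = rng.uniform(0.5, 3.0, (10, 1))
        offsets = rng.uniform(-5, 5, (10, 1))
        rescaled = make_series(values[perm] * scales + offsets, timepoints=ZT12)
        other = summarize_matrix(correlation_matrix(rescaled))
        assert other.mean_abs_r == pytest.approx(base.mean_abs_r, abs=1e-10)
        assert other.n_significant == base.n_significant


class TestHierarchicalOrder:
    def test_identical_genes_merge_at_zero(self):
        ts = make_series([[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]])
        _, Z = hierarchical_order(correlation_matrix(ts))
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_two_antiphase_pairs_merge_structure(self):
        # two perfectly correlated pairs, r = -1 across pairs
        p = np.array([0.0, 1.0, 2.0, 1.0])
        ts = make_series([p, 2 * p + 1, -p, 1 - 3 * p])
        order, Z = hierarchical_order(correlation_matrix(ts))
        heights = sorted(Z[:, 2])
        assert heights[0] == pytest.approx(0.0, abs=1e-12)
        assert heights[1] == pytest.approx(0.0, abs=1e-12)
        assert heights[2] == pytest.approx(2.0, abs=1e-12)
        assert {frozenset(order[:2]), frozenset(order[2:])} == {
            frozenset({"g0", "g1"}), frozenset({"g2", "g3"})
        }

    def test_merge_heights_match_naive_agglomeration(self, rng):
        for _ in range(3):
            values = rng.uniform(0, 5, (6, 12))
            mat = correlation_matrix(make_series(values, timepoints=ZT12))
            d = 1.0 - mat.r
            np.fill_diagonal(d, 0.0)
            _, Z = hierarchical_order(mat)
            np.testing.assert_allclose(
                sorted(Z[:, 2]), naive_complete_linkage_heights(d), atol=1e-10
            )


class TestClusterWaveform:
    def test_single_gene_mean_is_profile_sd_zero(self, random_series):
        mean, sd = cluster_waveform(random_series, ["g3"])
        expected = minmax_normalize(random_series).profile("g3")
        np.testing.assert_allclose(mean, expected)
        np.testing.assert_array_equal(sd, np.zeros(12))

    def test_antiphase_pair_mean_flat(self):
        ts = make_series([[0.0, 1.0, 0.5], [1.0, 0.0, 0.5]])
        mean, _ = cluster_waveform(ts, ["g0", "g1"], normalize=False)
        np.testing.assert_allclose(mean, [0.5, 0.5, 0.5])

    def test_matches_direct_column_statistics(self, random_series):
        subset = [f"g{i}" for i in range(10)]
        mean, sd = cluster_waveform(random_series, subset)
        normed = minmax_normalize(random_series)
        mat = np.array([normed.profile(g) for g in subset])
        np.testing.assert_allclose(mean, mat.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(sd, mat.std(axis=0, ddof=1), atol=1e-12)

    def test_unknown_gene_named_in_error(self, random_series):
        with pytest.raises(KeyError, match="nope"):
            cluster_waveform(random_series, ["g0", "nope"])


class TestCompareAndOverlap:
    def test_identical_matrices_no_change(self, random_series):
        mat = correlation_matrix(random_series)
        cmp = compare_intra(mat, mat)
        assert cmp.delta == pytest.approx(0.0)
        assert cmp.t == pytest.approx(0.0)
        assert cmp.p == pytest.approx(1.0)
        assert cmp.classification == "unchanged"

    def test_pooled_t_matches_hand_formula(self, rng):
        a = make_series(rng.uniform(0, 5, (30, 12)), timepoints=ZT12)
        b = make_series(rng.uniform(0, 5, (30, 12)) + 0.1, timepoints=ZT12)
        ma, mb = correlation_matrix(a), correlation_matrix(b)
        cmp = compare_intra(ma, mb)
        iu = np.triu_indices(30, 1)
        xa, xb = np.abs(ma.r[iu]), np.abs(mb.r[iu])
        na, nb = len(xa), len(xb)
        sp2 = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / (na + nb - 2)
        t_hand = (xa.mean() - xb.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert cmp.t == pytest.approx(t_hand, abs=1e-10)

    def test_overlap_identity_and_disjoint(self, random_series, rng):
        mat = correlation_matrix(random_series)
        same = pair_overlap(mat, mat)
        n_sig = len(significant_pairs(mat))
        assert same.n_shared == n_sig
        assert same.n_unique_a == same.n_unique_b == 0

    def test_overlap_matches_set_algebra_oracle(self, rng):
        a = correlation_matrix(make_series(rng.uniform(0, 5, (12, 12)), timepoints=ZT12))
        b = correlation_matrix(make_series(rng.uniform(0, 5, (12, 12)), timepoints=ZT12))
        ov = pair_overlap(a, b)
        sa, sb = significant_pairs(a), significant_pairs(b)
        assert ov.n_shared == len(sa & sb)
        assert ov.n_unique_a == len(sa - sb)
        assert ov.n_unique_b == len(sb - sa)

    def test_two_gene_matrix_rejected_as_degenerate(self):
        ts = make_series([[1.0, 2.0, 3.0]])
        with pytest.raises(ValidationError):
            correlation_matrix(ts)
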