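"""Aggregation, balancing, P(s), insulation, boundaries, melting."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from drophic import (
    BinnedMatrix,
    BinTrack,
    SimConfig,
    aggregate,
    balance,
    boundary_usage,
    call_boundaries,
    fit_ps_slope,
    insulation,
    make_bins,
    melting_score,
    ps_curve,
    sim_cells,
)
from tests.conftest import contacts_frame


def block_matrix(bins, block_edges, value=5.0):
    n = bins.n_bins
    A = np.zeros((n, n))
    lo = 0
    for hi in list(block_edges) + [n]:
        A[lo:hi, lo:hi] = value
        lo = hi
    return BinnedMatrix(bins, sp.csr_matrix(A))


class TestAggregate:
    def test_counts_mirrored(self, toy_bins):
        df = contacts_frame([
            ("a", "chrA", 5_000, "chrA", 15_000),
            ("a", "chrA", 15_000, "chrA", 5_000),
            ("a", "chrA", 25_000, "chrA", 25_000),
        ])
        mats, n_unlab = aggregate(df, {"a": "g"}, toy_bins)
        C = mats["g"].counts.toarray()
        assert C[0, 1] == 2 and C[1, 0] == 2
        assert C[2, 2] == 1
        assert n_unlab == 0

    def test_mass_conservation_across_groups(self, toy_bins):
        rng = np.random.default_rng(4)
        rows = [(f"bc{i % 6}", "chrA", int(rng.integers(1, 90_000)),
                 "chrA", int(rng.integers(1, 90_000))) for i in range(300)]
        df = contacts_frame([(b, c1, min(p1, p2), c2, max(p1, p2))
                             for b, c1, p1, c2, p2 in rows])
        labels = {f"bc{i}": f"g{i % 2}" for i in range(6)}
        mats, _ = aggregate(df, labels, toy_bins)
        assert sum(m.mass for m in mats.values()) == len(df)

    def test_single_relabel_reproduces_pool(self, toy_bins):
        df = contacts_frame([
            ("a", "chrA", 5_000, "chrA", 45_000),
            ("b", "chrA", 5_000, "chrA", 45_000),
        ])
        sep, _ = aggregate(df, {"a": "x", "b": "y"}, toy_bins)
        pooled, _ = aggregate(df, {"a": "all", "b": "all"}, toy_bins)
        total = sep["x"].counts + sep["y"].counts
        assert (total != pooled["all"].counts).nnz == 0

    def test_unlabeled_dropped_and_counted(self, toy_bins):
        df = contacts_frame([("a", "chrA", 5_000, "chrA", 45_000),
                             ("zz", "chrA", 5_000, "chrA", 45_000)])
        mats, n_unlab = aggregate(df, {"a": "g"}, toy_bins)
        assert n_unlab == 1 and mats["g"].mass == 1


class TestBalance:
    def test_doubly_stochastic_fixed_point(self, toy_bins):
        n = toy_bins.n_bins
        A = np.ones((n, n))
        m = BinnedMatrix(toy_bins, sp.csr_matrix(A))
        w = balance(m, mad_max=None)
        np.testing.assert_allclose(w, w[0])
        assert m.balance_converged

    def test_block_scaling_closed_form(self):
        bins = make_bins({"x": 20_000}, 10_000)
        m = BinnedMatrix(bins, sp.csr_matrix(np.diag([2.0, 1.0])))
        w = balance(m, mad_max=None)
        # weights proportional to 1/sqrt(row mass)
        assert (w[0] / w[1]) ** 2 == pytest.approx(0.5, rel=1e-4)

    def test_marginals_equal_on_random_matrices(self, toy_bins):
        n = toy_bins.n_bins
        for seed in range(20):
            rng = np.random.default_rng(seed)
            A = rng.poisson(3, (n, n)).astype(float)
            A = np.triu(A) + np.triu(A, 1).T
            m = BinnedMatrix(toy_bins, sp.csr_matrix(A))
            w = balance(m, mad_max=None, tol=1e-10)
            ok = np.isfinite(w)
            W = A[np.ix_(ok, ok)] * np.outer(w[ok], w[ok])
            marg = W.sum(1)
            assert np.std(marg) / np.mean(marg) < 1e-3

    def test_filtered_bins_masked(self, toy_bins):
        n = toy_bins.n_bins
        A = np.ones((n, n)) * 10
        A[3, :] = 0
        A[:, 3] = 0
        m = BinnedMatrix(toy_bins, sp.csr_matrix(A))
        w = balance(m)
        assert np.isnan(w[3])


class TestPsCurve:
    def test_single_distance(self):
        df = contacts_frame([("a", "chr1", 1, "chr1", 100_001)] * 10)
        ps = ps_curve(df, {"chr1": 1_000_000})
        assert len(ps) == 1 and ps.iloc[0].n_contacts == 10

    def test_linearity_in_counts(self):
        df = contacts_frame([("a", "chr1", 1, "chr1", 50_001),
                             ("a", "chr1", 1, "chr1", 400_001)])
        ps1 = ps_curve(df, {"chr1": 1_000_000})
        ps2 = ps_curve(pd.concat([df, df], ignore_index=True), {"chr1": 1_000_000})
        np.testing.assert_allclose(ps2.freq.values, 2 * ps1.freq.values)

    def test_simulated_slope_matches_exponent(self):
        """Log-log slope of generated cis contacts is ps_exponent +- 0.1."""
        cfg = SimConfig(seed=17, n_cells=10, n_ambient=0, contacts_mean=15_000,
                        dup_rate=0.0)
        sc = sim_cells(cfg)
        ps = ps_curve(sc.contacts, cfg.chrom_sizes)
        assert ps.n_contacts.sum() >= 1e5
        assert fit_ps_slope(ps) == pytest.approx(cfg.ps_exponent, abs=0.1)


class TestInsulation:
    def bins(self):
        return make_bins({"c": 400_000}, 10_000)

    def test_uniform_matrix_normalized_zero(self):
        bins = self.bins()
        m = BinnedMatrix(bins, sp.csr_matrix(np.ones((bins.n_bins, bins.n_bins))))
        t = insulation(m, 50_000, balanced=False)
        interior = np.isfinite(t.normalized.values)
        assert interior.any()
        np.testing.assert_allclose(t.normalized.values[interior], 0.0, atol=1e-12)

    def test_edges_missing(self):
        bins = self.bins()
        m = BinnedMatrix(bins, sp.csr_matrix(np.ones((bins.n_bins, bins.n_bins))))
        t = insulation(m, 50_000, balanced=False)
        w = 5
        assert np.isnan(t.normalized.values[:w]).all()
        assert np.isnan(t.normalized.values[-w:]).all()

    def test_block_junction_is_global_minimum(self):
        bins = self.bins()
        m = block_matrix(bins, [20])
        t = insulation(m, 50_000, balanced=False)
        v = t.normalized.values
        # the fully-cross diamond at the junction is empty: -inf is the minimum
        assert np.nanargmin(np.where(np.isnan(v), np.inf, v)) == 20

    def test_scale_invariance(self):
        bins = self.bins()
        rng = np.random.default_rng(0)
        A = rng.poisson(4, (bins.n_bins, bins.n_bins)).astype(float)
        A = np.triu(A) + np.triu(A, 1).T
        m1 = BinnedMatrix(bins, sp.csr_matrix(A))
        m2 = BinnedMatrix(bins, sp.csr_matrix(A * 7.5))
        t1 = insulation(m1, 50_000, balanced=False).normalized.values
        t2 = insulation(m2, 50_000, balanced=False).normalized.values
        np.testing.assert_allclose(t1, t2, atol=1e-10, equal_nan=True)

    def test_short_chromosome_all_missing(self):
        bins = make_bins({"tiny": 60_000}, 10_000)
        m = BinnedMatrix(bins, sp.csr_matrix(np.ones((6, 6))))
        t = insulation(m, 40_000, balanced=False)
        assert np.isnan(t.normalized.values).all()

    def test_window_too_small_rejected(self):
        bins = self.bins()
        m = BinnedMatrix(bins, sp.csr_matrix((40, 40)))
        with pytest.raises(ValueError):
            insulation(m, 10_000)


class TestBoundaries:
    def bins(self):
        return make_bins({"c": 400_000}, 10_000)

    def test_single_dip(self):
        bins = self.bins()
        t = insulation(block_matrix(bins, [20]), 50_000, balanced=False)
        bs = call_boundaries(t, 0.1)
        assert list(bs.boundary_bins) == [20]
        assert (bs.strengths > 0).all()

    def test_monotone_track_empty(self):
        bins = self.bins()
        vals = np.linspace(1, 0, bins.n_bins)
        track = insulation(block_matrix(bins, []), 50_000, balanced=False)
        track.normalized = BinTrack(bins, vals)
        assert len(call_boundaries(track, 0.1).boundary_bins) == 0

    def test_weak_dip_filtered(self):
        bins = self.bins()
        vals = np.zeros(bins.n_bins)
        vals[10] = -0.5   # strong dip
        vals[30] = -0.05  # weak dip
        track = insulation(block_matrix(bins, []), 50_000, balanced=False)
        track.normalized = BinTrack(bins, vals)
        bs = call_boundaries(track, 0.1)
        assert list(bs.boundary_bins) == [10]

    def test_mirror_symmetry(self):
        """Boundaries on the coordinate-reversed matrix mirror exactly."""
        bins = self.bins()
        n = bins.n_bins
        m = block_matrix(bins, [13, 27])
        rev = BinnedMatrix(bins, sp.csr_matrix(m.counts.toarray()[::-1, ::-1]))
        b1 = call_boundaries(insulation(m, 50_000, balanced=False), 0.1)
        b2 = call_boundaries(insulation(rev, 50_000, balanced=False), 0.1)
        # a boundary *between* bins i-1 and i maps to one between n-1-i
        # and n-i under reversal, i.e. boundary bin i -> n - i
        assert sorted(n - b2.boundary_bins) == sorted(b1.boundary_bins)


class TestBoundaryUsage:
    def test_usage_fractions(self):
        bins = make_bins({"c": 400_000}, 10_000)
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["c"], "tss": [205_000]})
        tss_bin = bins.bin_of("c", 205_000, one_based=False)
        sets = []
        for i in range(10):
            t = insulation(block_matrix(bins, [20]), 50_000, balanced=False)
            bs = call_boundaries(t, 0.1)
            if i >= 4:  # 6 members without the boundary
                bs.boundary_bins = np.array([], dtype=int)
            sets.append(bs)
        assert tss_bin == 20
        usage = boundary_usage(sets, genes, bins)
        assert usage["g"] == pytest.approx(0.4)

    def test_zero_and_full_usage(self):
        bins = make_bins({"c": 400_000}, 10_000)
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["c"], "tss": [205_000]})
        t = insulation(block_matrix(bins, [20]), 50_000, balanced=False)
        hit = call_boundaries(t, 0.1)
        miss = call_boundaries(insulation(block_matrix(bins, []), 50_000,
                                          balanced=False), 0.1)
        assert boundary_usage([hit] * 3, genes, bins)["g"] == 1.0
        assert boundary_usage([miss] * 3, genes, bins)["g"] == 0.0

    def test_absent_chromosome_missing(self):
        bins = make_bins({"c": 400_000}, 10_000)
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["zz"], "tss": [1]})
        t = insulation(block_matrix(bins, [20]), 50_000, balanced=False)
        usage = boundary_usage([call_boundaries(t, 0.1)], genes, bins)
        assert np.isnan(usage["g"])


class TestMelting:
    def tracks(self, a_vals, b_vals, n=40):
        bins = make_bins({"c": n * 50_000}, 50_000)
        genes = pd.DataFrame({"gene": ["G"], "chrom": ["c"], "start": [0],
                              "end": [n * 50_000]})
        return (BinTrack(bins, np.asarray(a_vals, float)),
                BinTrack(bins, np.asarray(b_vals, float)), genes)

    def test_identical_tracks_score_zero(self):
        v = np.linspace(1, 2, 40)
        a, b, genes = self.tracks(v, v)
        out = melting_score(a, b, genes)
        assert out.iloc[0].ks_stat == 0.0
        assert out.iloc[0].score == pytest.approx(0.0, abs=1e-12)

    def test_halved_values_melted_with_high_score(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(1, 2, 40)
        a, b, genes = self.tracks(v, v / 2)
        out = melting_score(a, b, genes)
        assert out.iloc[0].direction == "melted"
        assert out.iloc[0].score > 3

    def test_constant_offset_established(self):
        v = np.linspace(1, 2, 40)
        a, b, genes = self.tracks(v, v + 0.5)
        assert melting_score(a, b, genes).iloc[0].direction == "established"

    def test_direction_antisymmetric(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(1, 2, 40)
        a, b, genes = self.tracks(v, v * 0.7)
        fwd = melting_score(a, b, genes).iloc[0]
        rev = melting_score(b, a, genes).iloc[0]
        assert {fwd.direction, rev.direction} == {"melted", "established"}
        assert fwd.score == pytest.approx(rev.score)

    def test_short_genes_excluded_and_underpowered_flagged(self):
        bins = make_bins({"c": 2_000_000}, 50_000)
        vals = np.ones(bins.n_bins)
        short = pd.DataFrame({"gene": ["s"], "chrom": ["c"], "start": [0],
                              "end": [200_000]})   # < 300 kb
        out = melting_score(BinTrack(bins, vals), BinTrack(bins, vals), short)
        assert len(out) == 0
        sparse = vals.copy()
        sparse[:] = np.nan
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["c"], "start": [0],
                              "end": [1_900_000]})
        out = melting_score(BinTrack(bins, sparse), BinTrack(bins, vals), genes)
        assert out.iloc[0].direction == "underpowered"
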