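"""Metacell construction, rank-sum/BH kernel, differential compartments."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drophic import (
    ScABMatrix,
    bh_adjust,
    build_metacells,
    compare_module_groups,
    diff_compartment,
    gene_module_score,
    make_bins,
    ranksum_test,
)


def enumeration_ranksum(x, y):
    """Oracle: exact two-sided p by enumerating all group assignments."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    n, m = len(x), len(y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # tie-free inputs only
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    mu = n * m / 2
    # rank-sums of every possible choice of n positions among the pooled ranks
    total = 0
    extreme = 0
    for idx in combinations(range(1, n + m + 1), n):
        u = sum(idx) - n * (n + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


def stepup_bh(p):
    """Oracle: direct step-up formula."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def toy_matrix(values, barcodes):
    values = np.asarray(values, float)
    bins = make_bins({"c": values.shape[1] * 10_000}, 10_000)
    return ScABMatrix(values, barcodes, bins)


class TestRanksum:
    def test_known_exact_p(self):
        stat, p = ranksum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        _, p = ranksum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.99

    def test_all_identical_values(self):
        _, p = ranksum_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_symmetry_two_sided(self):
        x, y = [1.2, 3.4, 2.2, 8.0], [0.5, 4.4, 9.9]
        _, p1 = ranksum_test(x, y)
        _, p2 = ranksum_test(y, x)
        assert p1 == pytest.approx(p2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ranksum_test([], [1.0])

    def test_exact_branch_matches_enumeration_all_small_sizes(self):
        """Exact p == full enumeration for every group size pair <= 6."""
        rng = np.random.default_rng(0)
        for n in range(1, 7):
            for m in range(1, 7):
                x = rng.normal(size=n)
                y = rng.normal(size=m)
                _, p = ranksum_test(x, y)
                assert p == pytest.approx(enumeration_ranksum(x, y)), (n, m)

    def test_tie_handling_uses_asymptotic(self):
        # ties force the midrank + correction branch; p must be in (0, 1]
        x = [1.0, 1.0, 2.0]
        y = [1.0, 3.0, 3.0]
        _, p = ranksum_test(x, y)
        assert 0 < p <= 1


class TestBH:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])

    def test_empty(self):
        assert len(bh_adjust([])) == 0

    def test_matches_stepup_formula_on_random_vectors(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), stepup_bh(p), atol=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_stepup_equivalence_property(self, p):
        np.testing.assert_allclose(bh_adjust(p), stepup_bh(p), atol=1e-12)

    def test_bounds_and_order(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestBuildMetacells:
    def test_median_and_mask_rule(self):
        m = toy_matrix([[0.1, 0.1], [0.2, np.nan], [0.6, 0.3]], ["a", "b", "c"])
        assign = pd.DataFrame({"barcode": ["a", "b", "c"], "metacell": ["M"] * 3})
        mt = build_metacells(assign, m)
        assert mt.values[0, 0] == pytest.approx(0.2)
        # bin 1: 2/3 members unmasked >= 0.5 -> median over unmasked
        assert mt.values[0, 1] == pytest.approx(0.2)

    def test_masked_when_under_half_members(self):
        m = toy_matrix([[np.nan, 1.0], [np.nan, 1.0], [0.3, 1.0]], list("abc"))
        assign = pd.DataFrame({"barcode": list("abc"), "metacell": ["M"] * 3})
        mt = build_metacells(assign, m)
        assert np.isnan(mt.values[0, 0])

    def test_contact_pooling_conserved(self):
        m = toy_matrix([[0.1, 0.2], [0.3, 0.4]], ["a", "b"])
        contacts = pd.DataFrame({"barcode": ["a"] * 3 + ["b"] * 5})
        assign = pd.DataFrame({"barcode": ["a", "b"], "metacell": ["M", "M"]})
        mt = build_metacells(assign, m, contacts=contacts)
        assert mt.meta.loc["M", "n_contacts"] == 8

    def test_singleton_flagged(self):
        m = toy_matrix([[0.1, 0.2]], ["a"])
        assign = pd.DataFrame({"barcode": ["a"], "metacell": ["M"]})
        mt = build_metacells(assign, m)
        assert bool(mt.meta.loc["M", "singleton"])


class TestDiffCompartment:
    def synthetic_table(self, seed=0, n_bins=60, shift_bins=(5, 6, 7), delta=0.5,
                        n_per_group=12, noise=0.1):
        rng = np.random.default_rng(seed)
        base = rng.normal(0, 1, n_bins)
        rows = []
        names = []
        tps = []
        for g, shift in (("A", delta), ("B", 0.0)):
            for i in range(n_per_group):
                v = base + rng.normal(0, noise, n_bins)
                v[list(shift_bins)] += shift
                rows.append(v)
                names.append(f"{g}{i}")
                tps.append(g)
        m = toy_matrix(np.array(rows), names)
        assign = pd.DataFrame({"barcode": names,
                               "metacell": names, "timepoint": tps})
        return build_metacells(assign, m), names[:n_per_group], names[n_per_group:]

    def test_planted_bins_recovered(self):
        mt, ga, gb = self.synthetic_table()
        res = diff_compartment(mt, ga, gb)
        hits = set(res[res.significant].bin)
        assert {5, 6, 7} <= hits
        assert len(hits - {5, 6, 7}) == 0

    def test_delta_filter_excludes_small_effects(self):
        mt, ga, gb = self.synthetic_table(delta=0.04, noise=0.001)
        res = diff_compartment(mt, ga, gb, min_delta=0.05)
        planted = res[res.bin.isin([5, 6, 7])]
        # significant by p but excluded from the direction summary
        assert planted.significant.all()
        assert (planted.direction == "ns").all()

    def test_retained_set_monotone_in_alpha(self):
        mt, ga, gb = self.synthetic_table(noise=0.3)
        res1 = diff_compartment(mt, ga, gb, alpha=0.05)
        res2 = diff_compartment(mt, ga, gb, alpha=0.001)
        assert set(res2[res2.significant].bin) <= set(res1[res1.significant].bin)

    def test_masked_bins_untested(self):
        mt, ga, gb = self.synthetic_table()
        mt.values[: len(ga), 0] = np.nan  # bin 0 fully masked in group A
        res = diff_compartment(mt, ga, gb)
        assert 0 in res.attrs["untested_bins"]
        assert 0 not in set(res.bin)

    def test_too_few_metacells_rejected(self):
        mt, ga, gb = self.synthetic_table()
        with pytest.raises(ValueError):
            diff_compartment(mt, ga[:1], gb)


class TestGeneModules:
    def test_module_mean(self):
        m = toy_matrix([[0.1, 0.3], [0.5, 0.7]], ["a", "b"])
        assign = pd.DataFrame({"barcode": ["a", "b"], "metacell": ["m1", "m2"]})
        mt = build_metacells(assign, m)
        genes = pd.DataFrame({"gene": ["g1", "g2"], "chrom": ["c", "c"],
                              "start": [0, 10_000], "end": [9_000, 19_000]})
        s = gene_module_score(mt, ["g1", "g2"], genes)
        assert s["m1"] == pytest.approx(0.2)
        assert s["m2"] == pytest.approx(0.6)

    def test_unmappable_module_raises(self):
        m = toy_matrix([[0.1, 0.3]], ["a"])
        mt = build_metacells(pd.DataFrame({"barcode": ["a"], "metacell": ["m"]}), m)
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["zz"], "start": [0], "end": [5]})
        with pytest.raises((ValueError, KeyError)):
            gene_module_score(mt, ["g"], genes)

    def test_random_split_not_significant(self):
        """Same-timepoint random splits stay null in >= 19/20 seeds."""
        rng = np.random.default_rng(123)
        scores = pd.Series(rng.normal(0, 1, 20),
                           index=[f"m{i}" for i in range(20)])
        n_sig = 0
        for seed in range(20):
            r2 = np.random.default_rng(seed)
            perm = r2.permutation(scores.index)
            groups = pd.Series(["x"] * 10 + ["y"] * 10, index=perm)
            res = compare_module_groups(scores, groups.reindex(scores.index),
                                        [("x", "y")])
            n_sig += int(res.significant.any())
        assert n_sig <= 1
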