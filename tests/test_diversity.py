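"""Tests for OTU-table diversity: alpha, beta partitioning, ordination,
and permutation tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from streamcsa.assay import ValidationError
from streamcsa.diversity import (
    OTUTable,
    alpha_profile,
    beta_multisite,
    beta_pairwise,
    bray_curtis,
    chao1,
    corrected_singletons,
    dispersion_test,
    fisher_alpha,
    normalize_table,
    ordinate_nmds,
    permanova_strata,
    rarefied_richness,
)


def _table(counts: dict, meta: dict | None = None) -> OTUTable:
    df = pd.DataFrame(counts)
    df.index = [f"OTU{i}" for i in range(len(df))]
    if meta is None:
        meta = {s: {"site": "S1", "location": "U1", "marker": "16S-like"} for s in df}
    return OTUTable(counts=df, metadata=pd.DataFrame(meta).T)


class TestNormalize:
    def test_relative(self):
        t = _table({"a": [2, 2, 4], "b": [1, 0, 1]})
        rel = normalize_table(t, "relative")
        assert list(rel.counts["a"]) == pytest.approx([0.25, 0.25, 0.5])
        assert rel.counts.sum(axis=0).tolist() == pytest.approx([1.0, 1.0])

    def test_presence_absence(self):
        t = _table({"a": [0, 3, 1]})
        pa = normalize_table(t, "presence_absence")
        assert list(pa.counts["a"]) == [0.0, 1.0, 1.0]

    def test_zero_total_sample_named(self):
        t = _table({"a": [1, 2, 3], "bad": [0, 0, 0]})
        with pytest.raises(ValidationError, match="bad"):
            normalize_table(t, "relative")


class TestRarefaction:
    def test_endpoints(self):
        counts = [5, 3, 1, 1]
        n = sum(counts)
        assert rarefied_richness(counts, n) == pytest.approx(4.0, abs=1e-12)
        assert rarefied_richness(counts, 1) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_curve_and_extrapolation(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3, 40) + (rng.random(40) < 0.3)
        counts = counts[counts > 0]
        n = int(counts.sum())
        grid = [rarefied_richness(counts, m) for m in range(1, 2 * n, 5)]
        assert all(b >= a - 1e-9 for a, b in zip(grid, grid[1:]))
        assert rarefied_richness(counts, 3 * n) >= len(counts)

    def test_chao1_hand_example(self):
        # counts [1,1,2]: n=4, f1=2, f2=1 -> 3 + (3/4)*(4/2) = 4.5
        assert chao1([1, 1, 2]) == pytest.approx(4.5, abs=1e-12)

    def test_extrapolation_approaches_chao1(self):
        counts = [1, 1, 2]
        far = rarefied_richness(counts, 100_000)
        assert far == pytest.approx(chao1(counts), abs=1e-3)

    def test_invalid_m(self):
        with pytest.raises(ValidationError):
            rarefied_richness([1, 2], 0)


class TestAlphaProfile:
    def test_single_taxon(self):
        p = alpha_profile([10], target_depth=10)
        assert p.hill_1 == pytest.approx(1.0)
        assert p.berger_parker == 1.0
        assert p.pielou_j is None

    def test_equal_abundances(self):
        k = 5
        p = alpha_profile([10] * k, target_depth=50)
        assert p.hill_1 == pytest.approx(k)
        assert p.pielou_j == pytest.approx(1.0)
        assert p.berger_parker == pytest.approx(1 / k)

    def test_fisher_alpha_against_bisection_oracle(self):
        # independent bisection for S = alpha * ln(1 + n/alpha)
        s, n = 2, 10

        def f(a):
            return a * np.log(1 + n / a) - s

        lo, hi = 1e-9, 10.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        oracle = (lo + hi) / 2
        assert fisher_alpha(s, n) == pytest.approx(oracle, abs=1e-8)
        assert fisher_alpha(s, n) == pytest.approx(0.7518, abs=1e-4)

    def test_all_zero_error(self):
        with pytest.raises(ValidationError):
            alpha_profile([0, 0])


def test_corrected_singletons_good_turing_cap():
    # f1=6, f2=3, f3=2 -> f1_hat = 2*9/6 = 3: three singletons dropped
    counts = np.array([1] * 6 + [2] * 3 + [3] * 2 + [10])
    out = corrected_singletons(counts)
    assert int((out == 1).sum()) == 3
    with pytest.warns(UserWarning):
        corrected_singletons(np.array([1, 1, 2]))  # f3 = 0 -> raw counts


class TestBetaPartition:
    def test_pairwise_degenerate_cases(self):
        same = beta_pairwise({1, 2, 3}, {1, 2, 3})
        assert (same.beta_sor, same.beta_sim, same.beta_nes) == (0.0, 0.0, 0.0)
        disj = beta_pairwise({1, 2}, {3, 4})
        assert disj.beta_sor == 1.0 and disj.beta_sim == 1.0 and disj.beta_nes == 0.0
        nested = beta_pairwise({1, 2, 3, 4}, {1, 2})
        assert nested.beta_sim == 0.0
        assert nested.beta_sor == pytest.approx(1 / 3)
        assert nested.beta_nes == pytest.approx(1 / 3)

    @given(st.integers(0, 50), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=200, deadline=None)
    def test_additivity_property(self, s, ua, ub):
        a = set(range(s)) | set(range(100, 100 + ua))
        b = set(range(s)) | set(range(200, 200 + ub))
        if not a or not b:
            return
        p = beta_pairwise(a, b)
        assert p.beta_sor == pytest.approx(p.beta_sim + p.beta_nes, abs=1e-12)
        assert 0.0 <= p.beta_sim <= p.beta_sor <= 1.0

    def test_multisite_identical_and_disjoint(self):
        same = pd.DataFrame([[1, 1, 0, 1]] * 4)
        p = beta_multisite(same)
        assert (p.beta_sor, p.beta_sim, p.beta_nes) == (0.0, 0.0, 0.0)
        disj = pd.DataFrame(np.eye(3))
        p = beta_multisite(disj)
        assert p.beta_sim == pytest.approx(1.0)

    def test_multisite_hand_example(self):
        # three samples: {A,B,C}, {A,B}, {B,D}
        # S_i = 3,2,2; S_T = 4; pairwise uniques: (1,0), (2,1), (1,1)
        # sum_min = 0+1+1 = 2; sum_max = 1+2+1 = 4; core = 7-4 = 3
        # sim = 2/(3+2) = 0.4; sor = 6/(6+6) = 0.5; nes = 0.1
        pa = pd.DataFrame(
            [[1, 1, 1, 0], [1, 1, 0, 0], [0, 1, 0, 1]],
            columns=list("ABCD"),
        )
        p = beta_multisite(pa)
        assert p.beta_sim == pytest.approx(0.4, abs=1e-12)
        assert p.beta_sor == pytest.approx(0.5, abs=1e-12)
        assert p.beta_nes == pytest.approx(0.1, abs=1e-12)

    def test_multisite_additivity_random(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            pa = pd.DataFrame((rng.random((4, 20)) < 0.4).astype(int))
            pa = pa.loc[pa.sum(axis=1) > 0]
            if len(pa) < 3:
                continue
            p = beta_multisite(pa)
            assert p.beta_sor == pytest.approx(p.beta_sim + p.beta_nes, abs=1e-12)

    def test_multisite_requires_three(self):
        with pytest.raises(ValidationError, match="beta_pairwise"):
            beta_multisite(pd.DataFrame([[1, 0], [0, 1]]))


class TestBrayCurtis:
    def test_hand_values_and_metric_properties(self):
        t = pd.DataFrame({"a": [0.5, 0.5], "b": [1.0, 0.0], "c": [0.5, 0.5]})
        d = bray_curtis(t)
        assert d.loc["a", "c"] == 0.0
        assert d.loc["a", "b"] == pytest.approx(0.5)
        disjoint = pd.DataFrame({"x": [1.0, 0.0], "y": [0.0, 1.0]})
        assert bray_curtis(disjoint).loc["x", "y"] == pytest.approx(1.0)
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.all(np.diag(arr) == 0)
        assert ((arr >= 0) & (arr <= 1)).all()


class TestNMDS:
    def test_block_structure_recovered(self):
        # two tight pairs far apart
        d = np.array(
            [
                [0.0, 0.05, 0.9, 0.95],
                [0.05, 0.0, 0.95, 0.9],
                [0.9, 0.95, 0.0, 0.05],
                [0.95, 0.9, 0.05, 0.0],
            ]
        )
        dist = pd.DataFrame(d, index=list("abcd"), columns=list("abcd"))
        res = ordinate_nmds(dist, k_axes=2, seed=0)
        ax1 = res.scores["NMDS1"]
        assert np.sign(ax1["a"]) == np.sign(ax1["b"])
        assert np.sign(ax1["c"]) == np.sign(ax1["d"])
        assert np.sign(ax1["a"]) != np.sign(ax1["c"])
        assert res.stress < 0.05

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        pts = rng.random((6, 4))
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(pts)))
        r1 = ordinate_nmds(d, seed=11)
        r2 = ordinate_nmds(d, seed=11)
        assert np.allclose(r1.scores, r2.scores)

    def test_degenerate_inputs(self):
        zeros = pd.DataFrame(np.zeros((4, 4)))
        with pytest.raises(ValidationError):
            ordinate_nmds(zeros)
        small = pd.DataFrame(np.ones((2, 2)) - np.eye(2))
        with pytest.raises(ValidationError):
            ordinate_nmds(small, k_axes=2)


def _paired_distance_data(rng, n_sites=10, separated=False):
    rows, groups, strata = [], [], []
    for i in range(n_sites):
        for loc in ("U1", "D"):
            if separated:
                vec = np.zeros(20)
                vec[:10] = rng.poisson(5, 10) + 1 if loc == "U1" else 0
                vec[10:] = rng.poisson(5, 10) + 1 if loc == "D" else 0
            else:
                vec = rng.poisson(5, 20).astype(float)
            rows.append(vec)
            groups.append(loc)
            strata.append(f"site{i}")
    df = pd.DataFrame(np.array(rows).T, columns=[f"s{j}" for j in range(len(rows))])
    return bray_curtis(df), np.array(groups), np.array(strata)


class TestPermanovaStrata:
    def test_extreme_separation_minimum_p(self):
        """Disjoint taxon sets across 10 strata reach the resolution floor.

        Strata hold two U1 samples and one D sample so that no within-strata
        relabelling reproduces the observed partition by symmetry.
        """
        rng = np.random.default_rng(17)
        rows, groups, strata = [], [], []
        for i in range(10):
            for loc in ("U1", "U1", "D"):
                vec = np.zeros(20)
                if loc == "U1":
                    vec[:10] = rng.poisson(5, 10) + 1
                else:
                    vec[10:] = rng.poisson(5, 10) + 1
                rows.append(vec)
                groups.append(loc)
                strata.append(f"site{i}")
        df = pd.DataFrame(np.array(rows).T, columns=[f"s{j}" for j in range(30)])
        dist = bray_curtis(df)
        res = permanova_strata(dist, np.array(groups), np.array(strata),
                               n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1.0 / 200.0)

    def test_statistic_matches_independent_implementation(self):
        """Pseudo-F agrees with the scikit-bio PERMANOVA statistic."""
        rng = np.random.default_rng(23)
        dist, groups, strata = _paired_distance_data(rng)
        ours = permanova_strata(dist, groups, strata, n_perm=49, seed=1)
        dm = DistanceMatrix(dist.to_numpy(), ids=list(dist.index))
        ref = skbio_permanova(dm, groups, permutations=0)
        assert ours.statistic == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_single_group_strata_cannot_permute(self):
        """When every stratum holds one group, within-strata shuffles are
        no-ops, so every permuted F equals the observed F and p = 1."""
        rng = np.random.default_rng(29)
        data = pd.DataFrame(rng.poisson(5, size=(20, 8)).astype(float))
        dist = bray_curtis(data)
        groups = np.repeat(["U1", "D"], 4)
        strata = np.repeat(["s1", "s2"], 4)  # stratum == group
        res = permanova_strata(dist, groups, strata, n_perm=99, seed=2)
        assert res.p_value == 1.0

    def test_constant_grouping_rejected(self):
        rng = np.random.default_rng(31)
        data = pd.DataFrame(rng.poisson(5, size=(10, 4)).astype(float))
        dist = bray_curtis(data)
        with pytest.raises(ValidationError):
            permanova_strata(dist, ["U1"] * 4, ["s"] * 4, n_perm=9, seed=0)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(37)
        dist, groups, strata = _paired_distance_data(rng)
        a = permanova_strata(dist, groups, strata, n_perm=99, seed=5)
        b = permanova_strata(dist, groups, strata, n_perm=99, seed=5)
        assert a.p_value == b.p_value and a.statistic == b.statistic


class TestDispersion:
    def test_zero_dispersion_group_detected(self):
        rng = np.random.default_rng(41)
        tight = np.tile(rng.poisson(8, 15), (8, 1)).astype(float)
        tight += rng.normal(0, 0.01, tight.shape)  # distinct ids, ~zero spread
        loose = rng.poisson(8, size=(8, 15)).astype(float)
        df = pd.DataFrame(np.vstack([tight, loose]).T,
                          columns=[f"s{j}" for j in range(16)])
        dist = bray_curtis(df)
        groups = np.repeat(["tight", "loose"], 8)
        res = dispersion_test(dist, groups, n_perm=199, seed=3)
        assert res.p_value < 0.05

    def test_singleton_group_excluded_with_warning(self):
        rng = np.random.default_rng(43)
        data = pd.DataFrame(rng.poisson(5, size=(9, 10)).astype(float).T,
                            columns=[f"s{j}" for j in range(9)])
        dist = bray_curtis(data)
        groups = ["a"] * 4 + ["b"] * 4 + ["c"]
        with pytest.warns(UserWarning, match="size-1"):
            res = dispersion_test(dist, groups, n_perm=99, seed=1)
        assert 0.0 < res.p_value <= 1.0
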