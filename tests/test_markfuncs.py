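import math

import numpy as np
import pytest
from shapely.geometry import box

from markcorr.envelopes import shuffle_marks
from markcorr.geometry import nearest_neighbours, normalize_marks
from markcorr.markfuncs import (
    aggregation_indices,
    clark_evans_neighbourhood,
    edge_filter_nn,
    f1_nn_mark_mean,
    f2_schlather,
    f3_density_corr,
    f4_aggregation_corr,
    make_bins,
    _neighbourhood_ce,
)

from .conftest import make_pattern
from . import bruteforce as bf

BIG = {"A": box(0, 0, 1000, 1000)}


class TestMakeBins:
    def test_near_5_centers(self):
        b = make_bins("near_5")
        np.testing.assert_allclose(b.centers, np.arange(5.0, 146.0, 10.0))
        assert b.halfwidth == 5.0

    def test_near_1p5_first_last(self):
        b = make_bins("near_1.5")
        assert b.centers[0] == 1.5 and b.centers[-1] == 148.5

    def test_cumulative_has_35_radii(self):
        b = make_bins("cumulative")
        assert b.n_bins == 35
        assert b.centers[0] == 10.0 and b.centers[-1] == 350.0

    def test_far_schemes_cover_150_350(self):
        for name, h in [("far_3", 3.0), ("far_10", 10.0), ("far_20", 20.0)]:
            b = make_bins(name)
            assert b.centers[0] == 150.0 + h
            assert b.centers[-1] + h <= 350.0 + 1e-9

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="unknown scheme"):
            make_bins("near_42")

    def test_boundary_distance_goes_to_lower_bin(self):
        b = make_bins("near_5")
        # 10.0 is the shared edge of bins [0,10] and [10,20]
        assert b.assign(np.array([10.0]))[0] == 0


class TestEdgeFilter:
    def test_hand_cases(self):
        # tree 0: 5 m from edge, NN at 3 m -> retained; tree 2: NN farther
        # than the edge -> dropped
        xy = [(5, 500), (8, 500), (996, 500), (988.5, 500)]
        p = make_pattern(xy, "A", BIG)
        mask, frac = edge_filter_nn(p)
        assert mask.tolist() == [True, True, False, True]
        assert frac == pytest.approx(0.25)

    def test_matches_rule_applied_by_hand(self, uniform_pattern):
        nbr = nearest_neighbours(uniform_pattern)
        mask, _ = edge_filter_nn(uniform_pattern, nbr)
        want = (nbr["edge_dist"] >= nbr["nn_dist"]).to_numpy()
        np.testing.assert_array_equal(mask, want)


class TestF1:
    def test_constant_marks_give_one(self, uniform_pattern):
        res = f1_nn_mark_mean(uniform_pattern, np.ones(200), make_bins("near_10"))
        t = res.table
        assert np.allclose(t.loc[t["n_contributing"] > 0, "statistic"], 1.0)

    def test_empty_bins_flagged_not_zero(self):
        xy = [(500, 500), (503, 500), (400, 400), (404, 400)]
        p = make_pattern(xy, "A", BIG)
        res = f1_nn_mark_mean(p, np.ones(4), make_bins("near_5"))
        t = res.table
        empty = t["n_contributing"] == 0
        assert empty.sum() == len(t) - 1
        assert t.loc[empty, "statistic"].isna().all()
        assert (t.loc[empty, "flag"] == "empty").all()

    def test_group_by_oracle_marks_equal_nn_dist(self, uniform_pattern):
        """With mark_i := nn_dist_i, bin means equal a brute-force group-by."""
        nbr = nearest_neighbours(uniform_pattern)
        marks = np.nan_to_num(nbr["nn_dist"].to_numpy())
        bins = make_bins("near_10")
        res = f1_nn_mark_mean(uniform_pattern, marks, bins)
        want, cnt = bf.f1_brute(
            nbr["nn_dist"].to_numpy(),
            nbr["edge_dist"].to_numpy(),
            marks,
            bins.centers,
            bins.halfwidth,
        )
        np.testing.assert_allclose(res.table["statistic"].to_numpy(), want, atol=1e-10)
        np.testing.assert_array_equal(res.table["n_contributing"].to_numpy(), cnt)


class TestF2:
    def test_hand_fixture_three_pairs(self):
        """6 trees forming 3 isolated mutual-NN pairs in one distance bin:
        the statistic equals the hand-computed Pearson over ordered pairs."""
        xy = [
            (300, 300), (307, 300),
            (600, 600), (600, 608),
            (300, 700), (306, 700),
        ]
        marks = np.array([1.0, 2.0, 3.0, 5.0, 4.0, 4.5])
        p = make_pattern(xy, "A", BIG, marks=marks)
        res = f2_schlather(p, marks, make_bins("near_5"))
        # ordered pairs: both directions of each mutual pair
        x = [1, 2, 3, 5, 4, 4.5]
        y = [2, 1, 5, 3, 4.5, 4]
        want = bf.pearson_brute(x, y)
        k = 0  # all separations are in [0, 10]
        assert res.table.loc[k, "statistic"] == pytest.approx(want, abs=1e-12)
        assert res.table.loc[k, "n_contributing"] == 6

    def test_shuffled_marks_near_zero(self, rng):
        xy = rng.uniform(0, 2000, (500, 2))
        marks = rng.lognormal(3, 0.8, 500)
        p = make_pattern(xy, "A", {"A": box(0, 0, 2000, 2000)}, marks=marks)
        res = f2_schlather(p, shuffle_marks(marks, seed=1), make_bins("near_10"))
        t = res.table
        vals = t.loc[t["n_contributing"] >= 30, "statistic"]
        assert np.abs(vals.mean()) < 0.15

    def test_imposed_pair_equality_drives_correlation_to_one(self, uniform_pattern):
        """Equal marks within every connected component of the NN graph make
        all (focal, neighbour) pairs identical, so the correlation is 1."""
        nbr = nearest_neighbours(uniform_pattern)
        nn = nbr["nn_index"].to_numpy()
        comp = np.arange(200)

        def root(i):
            while comp[i] != i:
                comp[i] = comp[comp[i]]
                i = comp[i]
            return i

        for i in range(200):
            if nn[i] >= 0:
                comp[root(i)] = root(nn[i])
        rng = np.random.default_rng(5)
        comp_marks = rng.lognormal(0, 0.5, 200)
        marks = comp_marks[np.array([root(i) for i in range(200)])]
        res = f2_schlather(uniform_pattern, marks, make_bins("near_10"))
        t = res.table
        good = t.loc[t["n_contributing"] >= 3, "statistic"].dropna()
        assert len(good) > 3
        assert (good > 0.999).all()

    def test_zero_variance_flagged(self):
        xy = [(300, 300), (307, 300), (600, 600), (600, 608)]
        p = make_pattern(xy, "A", BIG)
        res = f2_schlather(p, np.ones(4), make_bins("near_5"))
        row = res.table.iloc[0]
        assert np.isnan(row["statistic"]) and row["flag"] == "zero_variance"

    def test_sparse_bins_flagged_unstable(self):
        # a single mutual pair yields 2 ordered pairs: below the 3-pair
        # stability threshold (mirrors truncating the function where NN
        # distances become rare)
        xy = [(300, 300), (307, 300)]
        p = make_pattern(xy, "A", BIG)
        res = f2_schlather(p, np.array([1.0, 2.0]), make_bins("near_5"))
        assert res.table.loc[0, "n_contributing"] == 2
        assert res.table.loc[0, "flag"] == "unstable"


class TestF3:
    def test_matches_bruteforce(self, uniform_pattern):
        marks = normalize_marks(uniform_pattern)
        radii = np.arange(50.0, 351.0, 50.0)
        res = f3_density_corr(uniform_pattern, marks, radii)
        want = bf.f3_brute(
            uniform_pattern.coords(),
            uniform_pattern.trees["concession_id"].to_numpy(),
            nearest_neighbours(uniform_pattern)["edge_dist"].to_numpy(),
            marks,
            radii,
        )
        np.testing.assert_allclose(res.table["statistic"].to_numpy(), want, atol=1e-10)

    def test_independent_marks_near_zero(self, rng):
        xy = rng.uniform(0, 3000, (800, 2))
        p = make_pattern(xy, "A", {"A": box(0, 0, 3000, 3000)}, marks=rng.lognormal(0, 1, 800))
        res = f3_density_corr(p, rng.permutation(normalize_marks(p)), np.arange(50.0, 301.0, 50.0))
        assert np.nanmax(np.abs(res.table["statistic"])) < 0.2

    def test_imposed_density_effect_recovered_negative(self, rng):
        from markcorr.geometry import neighbour_counts

        xy = rng.uniform(0, 2000, (1500, 2))
        p = make_pattern(xy, "A", {"A": box(0, 0, 2000, 2000)})
        counts = neighbour_counts(p, [100.0])[:, 0]
        marks = np.exp(-0.4 * counts) * rng.lognormal(0, 0.2, 1500)
        res = f3_density_corr(p, marks, [100.0])
        assert res.table.loc[0, "statistic"] < -0.3


class TestClarkEvans:
    def test_square_lattice_closed_form(self):
        # lattice members at spacing s with rho = 1/s^2 -> index 2
        s = 5.0
        xy = np.array([(x, y) for x in np.arange(0, 100.0, s) for y in np.arange(0, 100.0, s)])
        center = np.array([50.0, 50.0])
        d_focal = np.linalg.norm(xy - center, axis=1)
        members = (d_focal <= 30.0) & (d_focal > 0)
        dbar, _, n_used, ce = _neighbourhood_ce(xy[members], d_focal[members], 30.0, 1 / s**2)
        assert n_used > 10
        assert dbar == pytest.approx(s, abs=1e-12)
        assert ce == pytest.approx(2.0, abs=1e-12)

    def test_clumped_members_index_near_zero(self):
        rng = np.random.default_rng(3)
        xy = rng.normal([50, 50], 0.05, (30, 2))
        d_focal = np.linalg.norm(xy - [45.0, 50.0], axis=1)
        *_, ce = _neighbourhood_ce(xy, d_focal, 30.0, 30 / (math.pi * 30**2))
        assert ce < 0.05

    def test_csr_calibration_near_one(self, rng):
        lam = 0.02  # 200/ha in m^-2
        L = 500.0
        xy = rng.uniform(0, L, (rng.poisson(lam * L * L), 2))
        p = make_pattern(xy, "A", {"A": box(0, 0, L, L)})
        edge = p.neighbours()["edge_dist"].to_numpy()
        focal = np.flatnonzero(edge >= 100.0)
        ce = aggregation_indices(p, 100.0, focal)[focal]
        assert abs(np.nanmean(ce) - 1.0) < 0.06

    def test_matches_bruteforce(self, uniform_pattern):
        t = uniform_pattern.trees
        rho = {c: w.density_rho for c, w in uniform_pattern.windows.items()}
        cids = t["concession_id"].to_numpy()
        ce = aggregation_indices(uniform_pattern, 150.0)
        for i in range(0, 200, 7):
            want = bf.ce_brute(uniform_pattern.coords(), cids, rho, i, 150.0)
            if math.isnan(want):
                assert np.isnan(ce[i])
            else:
                assert ce[i] == pytest.approx(want, abs=1e-10)

    def test_single_focal_api_and_eligibility(self, uniform_pattern):
        nbr = uniform_pattern.neighbours()
        interior = nbr.loc[nbr["edge_dist"] >= 150.0, "tree_id"].iloc[0]
        agg = clark_evans_neighbourhood(uniform_pattern, interior, 150.0)
        assert agg.radius == 150.0
        if agg.defined:
            assert agg.ce_index == pytest.approx(
                2 * agg.mean_nn_dist * math.sqrt(uniform_pattern.windows["A"].density_rho)
            )
        near_edge = nbr.loc[nbr["edge_dist"] < 150.0, "tree_id"].iloc[0]
        with pytest.raises(ValueError, match="closer than the neighbourhood radius"):
            clark_evans_neighbourhood(uniform_pattern, near_edge, 150.0)

    def test_invariant_to_rigid_motion_and_rescaling(self):
        rng = np.random.default_rng(9)
        xy = rng.uniform(0, 60, (40, 2))
        d_focal = np.linalg.norm(xy - [30.0, 30.0], axis=1)
        rho = 40 / 3600.0
        *_, ce = _neighbourhood_ce(xy, d_focal, 40.0, rho)
        # rotation + translation
        a = 0.7
        R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        xy2 = xy @ R.T + [123.0, -45.0]
        *_, ce2 = _neighbourhood_ce(xy2, d_focal, 40.0, rho)
        assert ce2 == pytest.approx(ce, rel=1e-10)
        # rescaling x -> c x with rho -> rho / c^2
        c = 3.7
        *_, ce3 = _neighbourhood_ce(xy * c, d_focal * c, 40.0 * c, rho / c**2)
        assert ce3 == pytest.approx(ce, rel=1e-10)


class TestF4:
    def test_matches_bruteforce(self, uniform_pattern):
        marks = normalize_marks(uniform_pattern)
        radii = [100.0, 200.0, 300.0]
        res = f4_aggregation_corr(uniform_pattern, marks, radii)
        t = uniform_pattern.trees
        want = bf.f4_brute(
            uniform_pattern.coords(),
            t["concession_id"].to_numpy(),
            {c: w.density_rho for c, w in uniform_pattern.windows.items()},
            uniform_pattern.neighbours()["edge_dist"].to_numpy(),
            marks,
            radii,
        )
        np.testing.assert_allclose(res.table["statistic"].to_numpy(), want, atol=1e-10)

    def test_imposed_aggregation_effect_recovers_sign(self, rng):
        xy = rng.uniform(0, 1500, (1200, 2))
        p = make_pattern(xy, "A", {"A": box(0, 0, 1500, 1500)})
        ce = aggregation_indices(p, 100.0)
        noise = rng.normal(0, 0.1, 1200)
        marks = 1.0 + 0.8 * np.nan_to_num(ce, nan=1.0) + noise
        res = f4_aggregation_corr(p, marks, [100.0])
        assert res.table.loc[0, "statistic"] > 0.3

    def test_independent_marks_near_zero(self, rng):
        xy = rng.uniform(0, 1500, (800, 2))
        p = make_pattern(xy, "A", {"A": box(0, 0, 1500, 1500)}, marks=rng.lognormal(0, 1, 800))
        res = f4_aggregation_corr(p, rng.permutation(normalize_marks(p)), [150.0])
        assert abs(res.table.loc[0, "statistic"]) < 0.2


def test_constant_marks_f2_f3_f4_flagged_not_zero(uniform_pattern):
    ones = np.ones(200)
    r2 = f2_schlather(uniform_pattern, ones, make_bins("near_10"))
    assert r2.table["statistic"].isna().all()
    r3 = f3_density_corr(uniform_pattern, ones, [100.0, 200.0])
    assert r3.table["statistic"].isna().all()
    assert (r3.table["flag"] == "zero_variance").all()
    r4 = f4_aggregation_corr(uniform_pattern, ones, [200.0])
    assert r4.table["statistic"].isna().all()
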