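"""EOO/AOO geometry, criterion B/C rules, dispersal scenarios, A3(c) bands."""

import itertools

import numpy as np
import pytest

import sdmrisk as s
from sdmrisk.grid import RasterGrid
from sdmrisk.redlist import aoo_origin_sensitivity, occupied_cells


def brute_force_hull_area(pts: np.ndarray) -> float:
    """O(n^3) convex hull + shoelace, independent of shapely.

    A point pair is a hull edge iff every other point lies on one side.
    """
    pts = np.unique(np.asarray(pts, dtype=float), axis=0)
    n = len(pts)
    if n < 3:
        return 0.0
    edges = []
    for i, j in itertools.permutations(range(n), 2):
        d = pts[j] - pts[i]
        rel = pts - pts[i]
        cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
        if np.all(cross <= 1e-12):
            edges.append((i, j))
    if not edges:
        return 0.0
    # walk the hull from the edge list
    nxt = dict(edges)
    start = edges[0][0]
    hull = [start]
    cur = nxt[start]
    while cur != start and len(hull) <= n:
        hull.append(cur)
        cur = nxt[cur]
    poly = pts[hull]
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestEoo:
    def test_right_triangle(self):
        assert s.eoo([[0, 0], [10, 0], [0, 10]]) == pytest.approx(50.0)

    def test_collinear_is_zero(self):
        assert s.eoo([[0, 0], [1, 1], [2, 2], [5, 5]]) == 0.0

    def test_matches_brute_force_hull(self, rng):
        for _ in range(25):
            pts = rng.uniform(0, 50, size=(rng.integers(5, 50), 2))
            assert s.eoo(pts) == pytest.approx(brute_force_hull_area(pts),
                                               rel=1e-9)

    def test_hull_vertices_suffice(self, rng):
        pts = rng.uniform(0, 20, size=(50, 2))
        from shapely.geometry import MultiPoint
        hull = np.array(MultiPoint(pts.tolist()).convex_hull.exterior.coords)
        assert s.eoo(hull) == pytest.approx(s.eoo(pts))

    def test_monotone_under_point_addition(self, rng):
        pts = rng.uniform(0, 10, size=(10, 2))
        base = s.eoo(pts)
        for extra in rng.uniform(-5, 15, size=(10, 2)):
            assert s.eoo(np.vstack([pts, extra])) >= base - 1e-12

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            s.eoo([[np.nan, 0.0], [1, 1], [2, 0]])


class TestAoo:
    def test_single_point_is_one_cell(self):
        assert s.aoo([[0.5, 0.5]]) == 4.0

    def test_cell_index_enumeration(self):
        pts = [[0.5, 0.5], [1.5, 1.5], [3.0, 3.0]]
        # first two share the (0,0) 2-km cell; third occupies (1,1)
        assert occupied_cells(pts) == 2
        assert s.aoo(pts) == 8.0

    def test_thirty_six_cells_gives_144(self):
        pts = [[4 * i + 1.0, 4 * j + 1.0] for i in range(6) for j in range(6)]
        assert s.aoo(pts) == 144.0

    def test_multiple_of_cell_area_and_monotone(self, rng):
        pts = rng.uniform(0, 30, size=(40, 2))
        a = s.aoo(pts)
        assert a % 4 == 0
        assert s.aoo(np.vstack([pts, [[100, 100]]])) >= a

    def test_origin_sensitivity_brackets_default(self, rng):
        pts = rng.uniform(0, 30, size=(25, 2))
        lo, hi = aoo_origin_sensitivity(pts)
        assert lo <= s.aoo(pts) <= hi


class TestCriterionB:
    def test_printed_range_tuples_all_endangered(self):
        # the three narrow-range endemics' published range statistics
        cases = [
            (880.117, 144, 2, ("i", "iii", "iv", "v"), False),
            (1542.2, 156, 2, ("i", "iv", "v"), True),
            (901.618, 88, 2, ("i", "iv", "v"), True),
        ]
        for eoo_km2, aoo_km2, locs, decline, frag in cases:
            cat, crit = s.criterion_b(
                eoo_km2, aoo_km2, locs,
                s.ConditionFlags(severely_fragmented=frag,
                                 continuing_decline=decline))
            assert cat == "EN"
            d = ",".join(decline)
            assert crit == f"B1ab({d})+2ab({d})"

    def test_wide_range_not_listed(self):
        cat, crit = s.criterion_b(
            50_000, 3_000, 20,
            s.ConditionFlags(continuing_decline=("i",)))
        assert cat == "LC" and crit == ""

    def test_needs_two_conditions(self):
        # small range but only decline, many locations, not fragmented
        cat, _ = s.criterion_b(
            880, 144, 100, s.ConditionFlags(continuing_decline=("i",)))
        assert cat == "LC"

    def test_cr_band(self):
        cat, crit = s.criterion_b(
            50, 8, 1, s.ConditionFlags(continuing_decline=("ii",)))
        assert cat == "CR" and crit.startswith("B1ab")

    def test_b2_only_listing(self):
        cat, crit = s.criterion_b(
            30_000, 400, 3, s.ConditionFlags(continuing_decline=("v",)))
        assert cat == "EN" and crit == "B2ab(v)"


class TestCriterionC:
    def test_cr_small_declining(self):
        cat, crit = s.criterion_c(200, 40, True)
        assert (cat, crit) == ("CR", "CR C2a(i)")

    def test_large_population_not_listed(self):
        assert s.criterion_c(10**6, 100, True)[0] == "LC"

    def test_published_population_bounds_give_en(self):
        # 1,000 mature in subpopulations of at most 50, declining
        cat, crit = s.criterion_c(1000, 50, True)
        assert (cat, crit) == ("EN", "EN C2a(i)")

    def test_requires_decline_and_consistency(self):
        assert s.criterion_c(100, 10, False)[0] == "LC"
        with pytest.raises(ValueError):
            s.criterion_c(100, 200, True)


class TestProjectedAoo:
    def binary(self, arr):
        return RasterGrid(np.asarray(arr, dtype=float))

    def test_identity_future_no_loss(self, rng):
        cur = self.binary(rng.random((10, 10)) < 0.4)
        for dispersal in ("full", "limited"):
            _, loss = s.projected_aoo(cur, cur, dispersal)
            assert loss == 0.0

    def test_half_loss_under_both(self):
        vals = np.zeros((2, 8))
        vals[0, :] = 1  # 8 suitable 1-km cells in a row -> 4 distinct 2-km cells
        cur = self.binary(vals)
        fut_vals = np.zeros((2, 8))
        fut_vals[0, :4] = 1  # half the cells, nested inside current
        fut = self.binary(fut_vals)
        for dispersal in ("full", "limited"):
            _, loss = s.projected_aoo(cur, fut, dispersal)
            assert loss == pytest.approx(50.0)

    def test_gains_help_full_but_not_limited(self):
        cur = self.binary([[1, 0, 0], [0, 0, 0], [0, 0, 0]])
        fut = self.binary([[0, 0, 1], [0, 0, 0], [0, 0, 1]])
        _, loss_full = s.projected_aoo(cur, fut, "full", cell_km=1.0)
        _, loss_lim = s.projected_aoo(cur, fut, "limited", cell_km=1.0)
        assert loss_full == 0.0  # new cells offset the lost one
        assert loss_lim == 100.0

    def test_full_loss_never_exceeds_limited(self, rng):
        for _ in range(100):
            cur = self.binary(rng.random((8, 8)) < 0.35)
            fut = self.binary(rng.random((8, 8)) < 0.35)
            if not (cur.values == 1).any():
                continue
            _, lf = s.projected_aoo(cur, fut, "full")
            _, ll = s.projected_aoo(cur, fut, "limited")
            assert lf <= ll + 1e-12

    def test_zero_current_rejected(self):
        empty = self.binary(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            s.projected_aoo(empty, empty, "full")


class TestA3cCategory:
    @pytest.mark.parametrize("loss,expected", [
        (0.0, "LC"), (7.7, "LC"), (14.99, "LC"), (15.0, "NT"), (29.9, "NT"),
        (30.0, "VU"), (49.9, "VU"), (55.0, "EN"), (79.9, "EN"), (80.0, "CR"),
        (85.0, "CR"), (100.0, "CR")])
    def test_bands(self, loss, expected):
        assert s.a3c_category(loss) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            s.a3c_category(-1)
        with pytest.raises(ValueError):
            s.a3c_category(101)


class TestAssess:
    def flags(self):
        return s.ConditionFlags(severely_fragmented=True,
                                continuing_decline=("i", "iv", "v"))

    def test_most_threatened_wins(self):
        rm = s.RangeMetrics(880.0, 144.0, 2, 36)
        a = s.assess(rm, self.flags(), population=(200, 40, True))
        assert a.category == "CR"
        assert a.basis["B"].startswith("EN") and a.basis["C"].startswith("CR")

    def test_all_criteria_unmet_is_lc(self):
        rm = s.RangeMetrics(10**6, 10**5, 50, 100)
        a = s.assess(rm, s.ConditionFlags())
        assert a.category == "LC"

    def test_eoo_floored_to_aoo(self):
        # EOO 0 (collinear points) floors to AOO before B1
        rm = s.RangeMetrics(0.0, 144.0, 2, 36)
        a = s.assess(rm, self.flags())
        assert a.category == "EN"
        assert "B1" in a.basis["B"]

    def test_projected_losses_annotated(self):
        rm = s.RangeMetrics(880.0, 144.0, 2, 36)
        a = s.assess(rm, self.flags(),
                     projected_losses={"SSP585_2061-2080": 85.0})
        assert a.basis["A3c:SSP585_2061-2080"] == "CR"

    def test_category_never_below_triggered_criterion(self, rng):
        for _ in range(50):
            eoo_km2 = float(rng.uniform(0, 30000))
            aoo_km2 = float(rng.uniform(0, 3000))
            locs = int(rng.integers(1, 15))
            rm = s.RangeMetrics(max(eoo_km2, aoo_km2), aoo_km2, locs, 1)
            pop = (int(rng.integers(0, 20000)), 0, True)
            pop = (pop[0], int(rng.integers(0, pop[0] + 1)), True)
            a = s.assess(rm, self.flags(), population=pop)
            b_cat, _ = s.criterion_b(max(eoo_km2, aoo_km2), aoo_km2, locs,
                                     self.flags())
            c_cat, _ = s.criterion_c(*pop)
            from sdmrisk.redlist import category_rank
            assert category_rank(a.category) >= category_rank(b_cat)
            assert category_rank(a.category) >= category_rank(c_cat)
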