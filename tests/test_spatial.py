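"""Queen weights, Moran statistics and Gi* against independent oracles."""

import itertools
import logging
import math

import numpy as np
import pytest
from shapely.geometry import box

from lightodr import (
    SpatialWeights,
    ZonePolygons,
    build_queen_weights,
    classify_significance,
    generate_lattice_zones,
    getis_ord_gistar,
    global_moran,
    lattice_queen_weights,
    local_moran,
    read_gal,
    write_gal,
)


def brute_force_moran(x, w):
    """Double-loop evaluation of the global cross-product statistic."""
    x = np.asarray(x, float)
    n = len(x)
    xb = x.mean()
    num = s0 = 0.0
    for i in range(n):
        for jpos, j in enumerate(w.neighbors[i]):
            wij = w.weights[i][jpos]
            num += wij * (x[i] - xb) * (x[j] - xb)
            s0 += wij
    return n * num / (s0 * np.sum((x - xb) ** 2))


def brute_force_local(x, w):
    x = np.asarray(x, float)
    n = len(x)
    xb = x.mean()
    m2 = np.sum((x - xb) ** 2)
    out = []
    for i in range(n):
        lag = sum(wij * (x[j] - xb)
                  for j, wij in zip(w.neighbors[i], w.weights[i]))
        out.append(n * (x[i] - xb) * lag / m2)
    return np.array(out)


def brute_force_gistar(x, w):
    """Term-by-term evaluation of the self-inclusive hot-spot statistic."""
    x = np.asarray(x, float)
    n = len(x)
    xb = x.mean()
    s = math.sqrt(np.mean(x**2) - xb**2)
    ws = w.with_self()
    out = []
    for i in range(n):
        wsum = w2sum = lag = 0.0
        for j, wij in zip(ws.neighbors[i], ws.weights[i]):
            lag += wij * x[j]
            wsum += wij
            w2sum += wij**2
        denom = s * math.sqrt((n * w2sum - wsum**2) / (n - 1))
        out.append((lag - xb * wsum) / denom if denom > 0 else np.nan)
    return np.array(out)


class TestQueenWeights:
    def test_2x2_lattice_all_have_three(self):
        w = build_queen_weights(generate_lattice_zones(2, 2))
        assert [nb.size for nb in w.neighbors] == [3, 3, 3, 3]

    def test_3x3_textbook_counts(self):
        w = build_queen_weights(generate_lattice_zones(3, 3))
        degs = [nb.size for nb in w.neighbors]
        assert degs[4] == 8                         # center
        assert [degs[i] for i in (0, 2, 6, 8)] == [3, 3, 3, 3]  # corners

    def test_polygon_queen_matches_analytic_lattice(self):
        zones = generate_lattice_zones(5, 4)
        w_poly = build_queen_weights(zones)
        w_true = lattice_queen_weights(5, 4)
        for nb_p, nb_t in zip(w_poly.neighbors, w_true.neighbors):
            np.testing.assert_array_equal(nb_p, nb_t)

    def test_random_rectangles_match_allpairs_oracle(self, rng):
        """Neighbor pairs equal a brute-force boundary-intersection test."""
        geoms, k = [], 0
        while len(geoms) < 50:
            x0 = rng.uniform(0, 40)
            y0 = rng.uniform(0, 40)
            g = box(x0, y0, x0 + rng.uniform(1, 5), y0 + rng.uniform(1, 5))
            if all(g.intersection(h).area == 0 for h in geoms):  # non-overlapping
                geoms.append(g)
            k += 1
            assert k < 5000
        zones = ZonePolygons([f"z{i:02d}" for i in range(50)], geoms)
        w = build_queen_weights(zones)
        for i in range(50):
            expected = {j for j in range(50)
                        if j != i and not geoms[i].boundary.intersection(
                            geoms[j].boundary).is_empty}
            assert set(w.neighbors[i]) == expected

    def test_island_retained_and_logged(self, caplog):
        zones = ZonePolygons(
            ["a", "b", "island"],
            [box(0, 0, 1, 1), box(1, 0, 2, 1), box(10, 10, 11, 11)])
        with caplog.at_level(logging.WARNING, logger="lightodr.spatial"):
            w = build_queen_weights(zones)
        assert w.islands == [2]
        assert any("island" in m for m in caplog.messages)

    def test_asymmetric_relation_rejected(self):
        with pytest.raises(ValueError, match="asymmetric"):
            SpatialWeights.from_neighbor_sets({0: {1}, 1: set()})

    def test_row_standardization_sums_to_one(self, queen_5x5_row):
        for wrow in queen_5x5_row.weights:
            assert wrow.sum() == pytest.approx(1.0, abs=1e-12)

    def test_gal_round_trip_with_island(self, tmp_path):
        w = SpatialWeights.from_neighbor_sets(
            {0: {1}, 1: {0}, 2: set()}, ids=["a", "b", "c"])
        path = tmp_path / "w.gal"
        write_gal(w, path)
        back = read_gal(path)
        assert back.ids == ["a", "b", "c"]
        for nb1, nb2 in zip(back.neighbors, w.neighbors):
            np.testing.assert_array_equal(nb1, nb2)


class TestGlobalMoran:
    def test_perfect_dispersion_pair(self):
        w = SpatialWeights.from_neighbor_sets({0: {1}, 1: {0}})
        res = global_moran([3.0, -3.0], w, inference="permutation",
                           n_perm=9, seed=0)
        assert res.I == pytest.approx(-1.0, abs=1e-12)

    def test_exhaustive_null_expectation_n4(self):
        """Mean of I over all 4! relabellings equals -1/(n-1)."""
        w = lattice_queen_weights(2, 2).row_standardized()
        x = np.array([0.3, -1.2, 2.0, 0.5])
        vals = [brute_force_moran(np.array(p), w)
                for p in itertools.permutations(x)]
        assert np.mean(vals) == pytest.approx(-1.0 / 3.0, abs=1e-12)

    def test_matches_bruteforce_on_5x5(self, rng, queen_5x5_row):
        x = rng.normal(size=25)
        res = global_moran(x, queen_5x5_row)
        assert res.I == pytest.approx(brute_force_moran(x, queen_5x5_row), abs=1e-12)
        assert res.z == pytest.approx(
            (res.I - res.expectation) / math.sqrt(res.variance), abs=1e-12)

    def test_permutation_pseudo_p_definition(self, rng, queen_5x5_row):
        x = rng.normal(size=25)
        res = global_moran(x, queen_5x5_row, inference="permutation",
                           n_perm=99, seed=42)
        assert 1 / 100 <= res.pseudo_p <= 1.0
        assert res.n_permutations == 99

    def test_permutation_seed_reproducible(self, rng, queen_5x5_row):
        x = rng.normal(size=25)
        a = global_moran(x, queen_5x5_row, "permutation", n_perm=99, seed=7)
        b = global_moran(x, queen_5x5_row, "permutation", n_perm=99, seed=7)
        assert a.pseudo_p == b.pseudo_p and a.variance == b.variance

    def test_constant_x_rejected(self, queen_5x5_row):
        with pytest.raises(ValueError, match="constant"):
            global_moran(np.ones(25), queen_5x5_row)

    def test_scale_invariance(self, rng, queen_5x5_row):
        x = rng.normal(size=25)
        base = global_moran(x, queen_5x5_row).I
        for a, b in ((2.5, 10.0), (-3.0, 1.0)):
            assert global_moran(a * x + b, queen_5x5_row).I == pytest.approx(
                base, abs=1e-12)

    def test_all_island_refused(self):
        w = SpatialWeights.from_neighbor_sets({0: set(), 1: set(), 2: set()})
        with pytest.raises(ValueError, match="no connectivity"):
            global_moran([1.0, 2.0, 3.0], w)


class TestLocalMoran:
    def test_mirror_of_global_pair(self):
        w = SpatialWeights.from_neighbor_sets({0: {1}, 1: {0}})
        res = local_moran([3.0, -3.0], w, n_perm=9, seed=0)
        assert res[0].Ii == pytest.approx(-1.0, abs=1e-12)
        assert res[1].Ii == pytest.approx(-1.0, abs=1e-12)

    def test_sum_identity_under_row_standardization(self, rng, queen_5x5_row):
        x = rng.normal(size=25)
        res = local_moran(x, queen_5x5_row, n_perm=49, seed=1)
        total = sum(r.Ii for r in res) / 25
        assert total == pytest.approx(global_moran(x, queen_5x5_row).I, abs=1e-12)

    def test_matches_bruteforce_values(self, rng, queen_5x5_row):
        x = rng.normal(size=25)
        res = local_moran(x, queen_5x5_row, n_perm=49, seed=1)
        expect = brute_force_local(x, queen_5x5_row)
        np.testing.assert_allclose([r.Ii for r in res], expect, atol=1e-12)

    def test_quadrants_coherent(self, rng, queen_5x5_row):
        x = rng.normal(size=25)
        z = x - x.mean()
        lag = queen_5x5_row.lag(z)
        for i, r in enumerate(local_moran(x, queen_5x5_row, n_perm=49, seed=1)):
            if r.quadrant == "HH":
                assert z[i] > 0 and lag[i] > 0
            elif r.quadrant == "LL":
                assert z[i] <= 0 and lag[i] <= 0

    def test_null_size_close_to_nominal(self):
        """Spatially random fields: conditional-permutation pseudo-p <= 0.05
        at roughly the nominal rate."""
        w = lattice_queen_weights(5, 5).row_standardized()
        hits = total = 0
        for seed in range(60):
            x = np.random.default_rng(seed).normal(size=25)
            for r in local_moran(x, w, n_perm=199, seed=seed):
                hits += r.pseudo_p <= 0.05
                total += 1
        assert 0.02 <= hits / total <= 0.09

    def test_island_excluded_with_flag(self):
        w = SpatialWeights.from_neighbor_sets(
            {0: {1}, 1: {0, 2}, 2: {1}, 3: set()})
        res = local_moran([1.0, 2.0, 5.0, 3.0], w, n_perm=19, seed=0)
        assert res[3].island and np.isnan(res[3].Ii)
        assert not res[0].island


class TestGiStar:
    def test_constant_field_rejected(self):
        w = lattice_queen_weights(3, 3)
        with pytest.raises(ValueError, match="constant"):
            getis_ord_gistar(np.full(9, 2.0), w)

    def test_single_spike_locality(self):
        """One bright unit on a dark lattice: the spike and its Queen
        neighborhood carry the top Gi* values."""
        w = lattice_queen_weights(5, 5)
        x = np.zeros(25)
        x[12] = 100.0  # center
        res = getis_ord_gistar(x, w)
        g = np.array([r.gi_star for r in res])
        hot = {12} | set(w.neighbors[12].tolist())
        cold = set(range(25)) - hot
        assert min(g[list(hot)]) > max(g[list(cold)])

    def test_matches_formula_oracle_4x4(self, rng):
        w = lattice_queen_weights(4, 4)
        x = rng.normal(size=16)
        res = getis_ord_gistar(x, w)
        expect = brute_force_gistar(x, w)
        np.testing.assert_allclose([r.gi_star for r in res], expect, atol=1e-12)

    def test_classes_consistent_with_thresholds(self, rng):
        w = lattice_queen_weights(6, 6)
        x = rng.normal(size=36) * 5
        for r in getis_ord_gistar(x, w):
            if r.cls == "hot_99":
                assert r.gi_star >= 2.58
            elif r.cls == "hot_95":
                assert 1.96 <= r.gi_star < 2.58
            elif r.cls == "ns":
                assert abs(r.gi_star) < 1.96


class TestClassifySignificance:
    @pytest.mark.parametrize("z,expected", [
        (0.0, "ns"), (1.9599, "ns"),
        (1.96, "p05"), (-1.96, "p05"), (2.5799, "p05"),
        (2.58, "p01"), (-2.58, "p01"), (13.5308, "p01"),
    ])
    def test_thresholds_boundary_inclusive(self, z, expected):
        assert classify_significance(z) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_significance(float("nan"))
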