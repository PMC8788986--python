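"""Haversine geometry, route fitness functions, clustering, GeoJSON export."""

import itertools
import json
import math

import numpy as np
import pytest

from medalloc.ga import GAConfig
from medalloc.routing import (
    EARTH_RADIUS_KM,
    GeoLocation,
    cluster_and_route,
    distance_matrix,
    elbow_select_k,
    export_route_geojson,
    ff3_route_fitness,
    ff4_route_fitness,
    haversine_km,
    kmeans_cluster,
    optimize_route,
    recovery_cost,
)


def loc(id, lat, lon, patients=1.0, cost=1.0, rating=1.0):
    return GeoLocation(
        id=id, latitude=lat, longitude=lon,
        patients=patients, recovery_cost=cost, rating=rating,
    )


def circle_locations(n, radius_deg=1.0, **attrs):
    pts = []
    for i in range(n):
        angle = 2 * math.pi * i / n
        pts.append(
            loc(f"c{i}", radius_deg * math.sin(angle), radius_deg * math.cos(angle),
                **attrs)
        )
    return pts


def brute_force_ff4(dist):
    n = dist.shape[0]
    best = -np.inf
    for perm in itertools.permutations(range(1, n)):
        order = np.array([0, *perm])
        best = max(best, ff4_route_fitness(order, dist))
    return best


def routing_config(seed, iters=300, patience=60):
    return GAConfig(
        encoding="permutation", population_size=60, mutation_prob=0.2,
        crossover_prob=0.9, max_iterations=iters,
        patience=min(patience, iters), seed=seed,
    )


class TestHaversine:
    def test_identical_points_zero(self):
        a = loc("a", 38.0, -77.0)
        assert haversine_km(a, a) == 0.0

    def test_antipodal_closed_form(self):
        d = haversine_km(loc("a", 0.0, 0.0), loc("b", 0.0, 180.0))
        assert d == pytest.approx(math.pi * EARTH_RADIUS_KM, rel=1e-12)

    def test_equatorial_degree_arc(self):
        d = haversine_km(loc("a", 0.0, 0.0), loc("b", 0.0, 1.0))
        assert d == pytest.approx(2 * math.pi * EARTH_RADIUS_KM / 360.0, rel=1e-12)

    def test_matrix_symmetry_and_triangle_inequality(self, rng):
        locs = [
            loc(f"r{i}", float(rng.uniform(-60, 60)), float(rng.uniform(-170, 170)))
            for i in range(12)
        ]
        d = distance_matrix(locs)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0.0)
        for i, j, k in itertools.permutations(range(12), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestRecoveryCost:
    def test_product_and_linearity(self):
        assert recovery_cost(10.0, 100.0) == 1000.0
        assert recovery_cost(0.0, 100.0) == 0.0
        assert recovery_cost(20.0, 100.0) == 2 * recovery_cost(10.0, 100.0)
        assert recovery_cost(10.0, 200.0) == 2 * recovery_cost(10.0, 100.0)


class TestFF4:
    def test_unit_square_perimeter(self):
        # Unit-edge square in abstract km units.
        dist = np.array(
            [[0, 1, math.sqrt(2), 1],
             [1, 0, 1, math.sqrt(2)],
             [math.sqrt(2), 1, 0, 1],
             [1, math.sqrt(2), 1, 0]], dtype=float,
        )
        assert ff4_route_fitness([0, 1, 2, 3], dist) == pytest.approx(0.25)

    def test_reversal_and_rotation_invariance(self, rng):
        locs = [
            loc(f"r{i}", float(rng.uniform(-50, 50)), float(rng.uniform(-100, 100)))
            for i in range(6)
        ]
        dist = distance_matrix(locs)
        order = np.array([0, 3, 1, 5, 2, 4])
        f = ff4_route_fitness(order, dist)
        assert ff4_route_fitness(order[::-1], dist) == pytest.approx(f, rel=1e-12)
        assert ff4_route_fitness(np.roll(order, 2), dist) == pytest.approx(f, rel=1e-12)

    def test_two_locations(self):
        dist = np.array([[0.0, 7.0], [7.0, 0.0]])
        assert ff4_route_fitness([0, 1], dist) == pytest.approx(1.0 / 14.0)

    def test_coincident_points_guarded(self):
        dist = np.zeros((3, 3))
        with pytest.raises(ZeroDivisionError):
            ff4_route_fitness([0, 1, 2], dist)


class TestFF3:
    def test_single_leg_contribution(self):
        # Two-point closed tour: legs 0->1 and 1->0 with d = 5 each.
        # Destination 1 contributes 100/(10*5*2) = 1.0; destination 0 has
        # no patients, so the tour total is exactly 1.0.
        locs = [
            loc("a", 0.0, 0.0, patients=0.0, cost=10.0, rating=2.0),
            loc("b", 0.0, 0.0449, patients=100.0, cost=10.0, rating=2.0),
        ]
        dist = np.full((2, 2), 5.0)
        np.fill_diagonal(dist, 0.0)
        assert ff3_route_fitness([0, 1], locs, dist) == pytest.approx(1.0)

    def test_no_patients_zero_fitness(self):
        locs = [loc(f"z{i}", float(i), 0.0, patients=0.0, cost=2.0, rating=1.0)
                for i in range(3)]
        dist = distance_matrix(locs)
        assert ff3_route_fitness([0, 1, 2], locs, dist) == 0.0

    def test_inverse_linearity_in_distance(self):
        locs = [
            loc("a", 0.0, 0.0, patients=3.0, cost=2.0, rating=1.0),
            loc("b", 1.0, 0.0, patients=4.0, cost=5.0, rating=2.0),
            loc("c", 0.0, 1.0, patients=5.0, cost=3.0, rating=1.5),
        ]
        dist = distance_matrix(locs)
        f1 = ff3_route_fitness([0, 1, 2], locs, dist)
        f2 = ff3_route_fitness([0, 1, 2], locs, dist / 2.0)
        assert f2 == pytest.approx(2.0 * f1, rel=1e-12)

    def test_aggregate_variant_depends_only_on_total_distance(self):
        locs = [
            loc("a", 0.0, 0.0, patients=3.0, cost=2.0, rating=1.0),
            loc("b", 1.0, 1.0, patients=4.0, cost=5.0, rating=2.0),
            loc("c", 0.0, 2.0, patients=5.0, cost=3.0, rating=1.5),
            loc("d", -1.0, 1.0, patients=2.0, cost=4.0, rating=1.0),
        ]
        dist = distance_matrix(locs)
        f = ff3_route_fitness([0, 1, 2, 3], locs, dist, aggregate=True)
        total = sum(dist[a, b] for a, b in [(0, 1), (1, 2), (2, 3), (3, 0)])
        expected = (3 + 4 + 5 + 2) / ((2 + 5 + 3 + 4) * total * (1 + 2 + 1.5 + 1))
        assert f == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_attributes_rejected(self):
        locs = [
            loc("a", 0.0, 0.0, patients=1.0, cost=0.0, rating=1.0),
            loc("b", 1.0, 0.0, patients=1.0, cost=2.0, rating=1.0),
        ]
        dist = distance_matrix(locs)
        with pytest.raises(ValueError):
            ff3_route_fitness([0, 1], locs, dist)


class TestOptimizeRoute:
    def test_circle_recovers_angular_order(self):
        locs = circle_locations(6)
        dist = distance_matrix(locs)
        optimal = brute_force_ff4(dist)
        hits = 0
        for seed in range(20):
            sol = optimize_route(locs, objective="ff4", config=routing_config(seed))
            if sol.fitness == pytest.approx(optimal, rel=1e-9):
                hits += 1
        assert hits >= 19

    def test_leg_distances_sum_to_total_and_tour_closes(self):
        locs = circle_locations(5)
        sol = optimize_route(locs, objective="ff4", config=routing_config(1))
        assert sorted(sol.order) == sorted(l.id for l in locs)
        assert sol.order[0] == locs[0].id  # fixed start
        assert len(sol.leg_distances) == 5  # return leg included
        assert sum(sol.leg_distances) == pytest.approx(sol.total_distance)

    def test_two_locations_unique_tour(self):
        locs = circle_locations(2)
        sol = optimize_route(locs, objective="ff4", config=routing_config(0))
        assert sol.order == ("c0", "c1")

    def test_normalized_ff3_beats_unnormalized(self, rng):
        # Raw attributes on real-data scales (thousands of patients, costs
        # in the tens of thousands) drive per-leg fitness toward zero;
        # min-max scaling restores O(1) magnitudes.
        locs = [
            loc(f"s{i}", float(rng.uniform(30, 45)), float(rng.uniform(-120, -75)),
                patients=float(rng.uniform(100, 8000)),
                cost=float(rng.uniform(5e4, 5e5)),
                rating=float(rng.uniform(5, 40)))
            for i in range(8)
        ]
        raw = optimize_route(locs, objective="ff3", config=routing_config(4))
        norm = optimize_route(
            locs, objective="ff3", config=routing_config(4), normalize=True
        )
        assert norm.fitness > raw.fitness

    def test_requires_two_locations_and_known_objective(self):
        with pytest.raises(ValueError):
            optimize_route(circle_locations(1))
        with pytest.raises(ValueError):
            optimize_route(circle_locations(3), objective="ff9")


class TestClustering:
    def test_k1_centroid_is_mean(self):
        locs = [loc("a", 0.0, 0.0), loc("b", 2.0, 2.0), loc("c", 4.0, 4.0)]
        res = kmeans_cluster(locs, 1, seed=0)
        assert np.allclose(res.centroids[0], [2.0, 2.0])
        assert set(res.labels.tolist()) == {0}

    def test_k_equals_n_zero_sse(self):
        locs = [loc(f"x{i}", float(i), float(i)) for i in range(4)]
        res = kmeans_cluster(locs, 4, seed=0)
        assert res.sse == pytest.approx(0.0, abs=1e-12)
        assert len(set(res.labels.tolist())) == 4

    def test_two_separated_blobs_perfectly_split(self, rng):
        a = [loc(f"a{i}", float(rng.normal(0, 0.1)), float(rng.normal(0, 0.1)))
             for i in range(10)]
        b = [loc(f"b{i}", float(rng.normal(20, 0.1)), float(rng.normal(20, 0.1)))
             for i in range(10)]
        res = kmeans_cluster(a + b, 2, seed=0)
        assert len(set(res.labels[:10].tolist())) == 1
        assert len(set(res.labels[10:].tolist())) == 1
        assert res.labels[0] != res.labels[10]

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            kmeans_cluster([loc("a", 0, 0)], 2)

    def test_elbow_finds_four_blobs(self, rng):
        centers = [(0, 0), (0, 30), (30, 0), (30, 30)]
        locs = [
            loc(f"b{c}{i}", float(rng.normal(cy, 0.3)), float(rng.normal(cx, 0.3)))
            for c, (cy, cx) in enumerate(centers)
            for i in range(8)
        ]
        assert elbow_select_k(locs, k_max=8, seed=0) == 4

    def test_elbow_deterministic_on_single_blob(self, rng):
        locs = [loc(f"t{i}", float(rng.normal(0, 0.5)), float(rng.normal(0, 0.5)))
                for i in range(12)]
        k1 = elbow_select_k(locs, k_max=6, seed=0)
        k2 = elbow_select_k(locs, k_max=6, seed=0)
        assert k1 == k2


class TestClusterAndRoute:
    def two_blob_locs(self, rng):
        a = [loc(f"a{i}", float(rng.normal(0, 0.2)), float(rng.normal(0, 0.2)))
             for i in range(6)]
        b = [loc(f"b{i}", float(rng.normal(0, 0.2)), float(rng.normal(40, 0.2)))
             for i in range(6)]
        return a + b

    def test_clustered_average_beats_global(self, rng):
        locs = self.two_blob_locs(rng)
        result = cluster_and_route(
            locs, objective="ff4", config=routing_config(0, iters=200), k=2
        )
        assert result.mean_fitness > result.global_fitness

    def test_k1_matches_plain_route(self, rng):
        locs = self.two_blob_locs(rng)
        cfg = routing_config(3, iters=150)
        result = cluster_and_route(locs, objective="ff4", config=cfg, k=1)
        # same GA seed stream as the direct call with the cluster-0 config
        direct_cfg = GAConfig(**{**cfg.__dict__, "seed": cfg.seed + 1})
        direct = optimize_route(locs, objective="ff4", config=direct_cfg)
        assert result.routes[0].fitness == pytest.approx(direct.fitness)

    def test_singleton_clusters_warn_and_yield_no_route(self):
        locs = [loc("a", 0.0, 0.0), loc("b", 40.0, 40.0)]
        with pytest.warns(UserWarning):
            result = cluster_and_route(
                locs, objective="ff4", config=routing_config(0, iters=50), k=2
            )
        assert all(r is None for r in result.routes.values())
        assert math.isnan(result.mean_fitness)


class TestGeoJSONExport:
    def test_three_point_route_structure(self, tmp_path):
        locs = circle_locations(3)
        sol = optimize_route(locs, objective="ff4", config=routing_config(0, iters=50))
        path = tmp_path / "route.geojson"
        export_route_geojson(sol, locs, path)
        payload = json.loads(path.read_text())
        assert payload["type"] == "FeatureCollection"
        lines = [f for f in payload["features"]
                 if f["geometry"]["type"] == "LineString"]
        points = [f for f in payload["features"]
                  if f["geometry"]["type"] == "Point"]
        assert len(lines) == 1 and len(points) == 3
        ring = lines[0]["geometry"]["coordinates"]
        assert len(ring) == 4 and ring[0] == ring[-1]  # closed tour
        # GeoJSON is (longitude, latitude)
        by_id = {l.id: l for l in locs}
        first = by_id[sol.order[0]]
        assert ring[0] == [first.longitude, first.latitude]

    def test_empty_route_rejected(self, tmp_path):
        from medalloc.routing import RouteSolution

        empty = RouteSolution(order=(), fitness=0.0, total_distance=0.0,
                              leg_distances=())
        with pytest.raises(ValueError):
            export_route_geojson(empty, [], tmp_path / "x.geojson")
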