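import itertools

import numpy as np
import pandas as pd
import pytest

from emsloc.io_formats import RoadNetwork
from emsloc.travel_time import (ResponseTimePolicy, SpeedCorrectionRules,
                                build_time_graph, corrected_speed,
                                coverage_matrix, snap_to_network,
                                travel_time_matrix)

IDENTITY_RULES = SpeedCorrectionRules(factor_at_threshold=1.0,
                                      factor_above_threshold=1.0,
                                      road_overrides={})


def make_network(nodes, edges):
    """nodes: {id: (lon, lat)}; edges: (u, v, length_m, speed, name, oneway)."""
    ndf = pd.DataFrame([{"id": i, "longitude": c[0], "latitude": c[1]}
                        for i, c in nodes.items()])
    edf = pd.DataFrame(edges, columns=["from", "to", "length_m", "speed_kmh",
                                       "name", "oneway"])
    return RoadNetwork(nodes=ndf, edges=edf)


class TestCorrectedSpeed:
    @pytest.mark.parametrize("limit,name,expected", [
        (30, None, 30.0),              # below threshold: limit kept
        (39.9, None, 39.9),
        (40, None, 46.0),              # at threshold: x1.15
        (50, None, 60.0),              # above threshold: x1.20
        (60, "Lågendalsveien", 84.0),  # named-road override x1.40
        (50, "Kirkeveien", 65.0),      # override x1.30
        (60, "Riksvei 19", 84.0),
        (60, "Storgata", 72.0),        # unknown name falls back to generic
        (30, "Kirkeveien", 30.0),      # below threshold: no factor to override
    ])
    def test_three_bands_and_overrides(self, limit, name, expected):
        assert corrected_speed(limit, name) == pytest.approx(expected)

    def test_nonpositive_limit_rejected(self):
        with pytest.raises(ValueError):
            corrected_speed(0)

    def test_multipliers_below_one_rejected(self):
        with pytest.raises(ValueError):
            SpeedCorrectionRules(factor_at_threshold=0.9)


class TestSnapping:
    NET = None

    @classmethod
    def setup_class(cls):
        cls.NET = make_network(
            {3: (10.0, 59.0), 7: (10.1, 59.0), 9: (10.2, 59.0)}, [])

    def test_coincident_node(self):
        assert snap_to_network(10.1, 59.0, self.NET) == 7

    def test_tie_broken_by_lowest_id(self):
        # nodes 9 and 3 share a location: exact tie goes to the lower id
        net = make_network({9: (10.05, 59.0), 3: (10.05, 59.0)}, [])
        assert snap_to_network(10.05, 59.0, net) == 3

    def test_empty_network_rejected(self):
        empty = make_network({}, [])
        with pytest.raises(ValueError):
            snap_to_network(10.0, 59.0, empty)


class TestTravelTimeMatrix:
    def test_single_edge_closed_form(self):
        # 1 km at an effective 60 km/h is exactly one minute
        net = make_network({1: (10, 59), 2: (10.02, 59)},
                           [(1, 2, 1000.0, 60.0, "", False)])
        ttm = travel_time_matrix(net, [1], [2], IDENTITY_RULES)
        assert ttm[0, 0] == pytest.approx(1.0)

    def test_triangle_prefers_two_arc_route(self):
        # direct arc 10 min vs 4 + 5 min via the third node
        net = make_network(
            {1: (10, 59), 2: (10.1, 59), 3: (10.05, 59.05)},
            [(1, 2, 10_000.0, 60.0, "", False),   # 10 min at 60 km/h
             (1, 3, 4_000.0, 60.0, "", False),    # 4 min
             (3, 2, 5_000.0, 60.0, "", False)])   # 5 min
        ttm = travel_time_matrix(net, [1], [2], IDENTITY_RULES)
        assert ttm[0, 0] == pytest.approx(9.0)

    def test_disconnected_component_is_inf(self):
        net = make_network({1: (10, 59), 2: (10.1, 59), 3: (11, 60)},
                           [(1, 2, 1000.0, 50.0, "", False)])
        ttm = travel_time_matrix(net, [1], [2, 3], IDENTITY_RULES)
        assert np.isfinite(ttm[0, 0]) and np.isinf(ttm[0, 1])

    def test_oneway_asymmetry(self):
        net = make_network({1: (10, 59), 2: (10.1, 59)},
                           [(1, 2, 1000.0, 60.0, "", True)])
        forward = travel_time_matrix(net, [1], [2], IDENTITY_RULES)
        backward = travel_time_matrix(net, [2], [1], IDENTITY_RULES)
        assert np.isfinite(forward[0, 0]) and np.isinf(backward[0, 0])

    def test_matches_exhaustive_path_enumeration(self):
        """Dijkstra result equals brute-force simple-path enumeration on
        random graphs of up to 6 nodes."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(3, 7))
            coords = {i: (10 + 0.01 * i, 59.0) for i in range(n)}
            edges = []
            for u, v in itertools.combinations(range(n), 2):
                if rng.random() < 0.5:
                    edges.append((u, v, float(rng.integers(500, 5000)),
                                  float(rng.choice([30, 50, 80])), "", False))
            if not edges:
                continue
            net = make_network(coords, edges)
            ttm = travel_time_matrix(net, [0], list(range(n)), IDENTITY_RULES)

            # independent oracle: DFS over all simple paths
            minutes = {}
            for u, v, length, speed, _, _ in edges:
                t = length / 1000 / speed * 60
                minutes.setdefault(u, {})[v] = min(t, minutes.get(u, {}).get(v, np.inf))
                minutes.setdefault(v, {})[u] = min(t, minutes.get(v, {}).get(u, np.inf))
            best = {i: np.inf for i in range(n)}
            best[0] = 0.0

            def dfs(node, cost, visited):
                for nb, t in minutes.get(node, {}).items():
                    if nb not in visited:
                        if cost + t < best[nb]:
                            best[nb] = cost + t
                        dfs(nb, cost + t, visited | {nb})

            dfs(0, 0.0, {0})
            np.testing.assert_allclose(ttm[0], [best[i] for i in range(n)], rtol=1e-12)


class TestCoverage:
    def test_budget_arithmetic(self):
        policy = ResponseTimePolicy()
        assert policy.driving_budget("urban") == pytest.approx(9.0)
        assert policy.driving_budget("rural") == pytest.approx(22.0)

    def test_inclusive_threshold_and_budgets(self):
        ttm = np.array([[9.0, 9.0, 22.0, 22.5, np.inf]])
        labels = ["urban", "rural", "rural", "rural", "urban"]
        a = coverage_matrix(ttm, labels)
        # urban at exactly 9 covered; rural at 9 covered; rural at exactly 22
        # covered; 22.5 not; unreachable never covered
        assert a[:, 0].tolist() == [True, True, True, False, False]

    def test_urban_stricter_than_rural(self):
        ttm = np.array([[15.0]])
        assert not coverage_matrix(ttm, ["urban"])[0, 0]
        assert coverage_matrix(ttm, ["rural"])[0, 0]

    def test_unlabeled_point_rejected(self):
        with pytest.raises(ValueError):
            coverage_matrix(np.array([[1.0]]), [None])

    def test_targets_must_exceed_pretrip_delay(self):
        with pytest.raises(ValueError):
            ResponseTimePolicy(pre_trip_delay=13.0)

    def test_coverage_monotone_in_speed_multiplier(self):
        """Raising speed multipliers never uncovers a covered point."""
        rng = np.random.default_rng(11)
        n = 6
        coords = {i: (10 + 0.01 * i, 59 + 0.005 * (i % 3)) for i in range(n)}
        edges = [(u, v, float(rng.integers(2000, 20000)),
                  float(rng.choice([30, 40, 50, 80])), "", False)
                 for u, v in itertools.combinations(range(n), 2)
                 if rng.random() < 0.6]
        net = make_network(coords, edges)
        labels = ["urban", "rural", "urban", "rural", "urban", "rural"]
        slow = SpeedCorrectionRules()
        fast = SpeedCorrectionRules(factor_at_threshold=1.5,
                                    factor_above_threshold=1.6,
                                    road_overrides={})
        a_slow = coverage_matrix(travel_time_matrix(net, [0, 1], range(n), slow), labels)
        a_fast = coverage_matrix(travel_time_matrix(net, [0, 1], range(n), fast), labels)
        assert (a_fast | a_slow).sum() == a_fast.sum()  # a_slow implies a_fast

    def test_relabeling_urban_to_rural_keeps_coverage(self):
        """Rural budget >= urban budget: whatever covers an urban point also
        covers it relabeled rural."""
        rng = np.random.default_rng(5)
        ttm = rng.uniform(0, 30, size=(3, 8))
        urban = coverage_matrix(ttm, ["urban"] * 8)
        rural = coverage_matrix(ttm, ["rural"] * 8)
        assert (urban <= rural).all()
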