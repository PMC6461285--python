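"""Ambulance travel times and the boolean coverage matrix.

Pipeline: speed-limit → corrected ambulance speed → per-arc driving minutes
→ Dijkstra shortest-path time matrix between candidate bases and demand
points → boolean coverage under the dual (urban/rural) driving-time
budgets.

Empirically, ambulances drive faster than the posted limit except on slow
streets.  The correction has three bands plus named-road overrides: below
a threshold (default 40 km/h) the limit is kept as the actual speed, at
the threshold the speed is multiplied by 1.15, above it by 1.20; specific
roads may carry their own multiplier that replaces the generic factor.

Response-time targets (defaults 12 min urban, 25 min rural) minus a fixed
pre-trip delay (default 3 min, the region's median mobilisation time)
give driving-time budgets of 9 and 22 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_formats import RoadNetwork

__all__ = [
    "SpeedCorrectionRules",
    "ResponseTimePolicy",
    "corrected_speed",
    "snap_to_network",
    "build_time_graph",
    "travel_time_matrix",
    "coverage_matrix",
    "great_circle_km",
]

#: mean Earth radius, km
_EARTH_RADIUS_KM = 6371.0088

#: named-road speed multipliers calibrated on hospital trip logs
DEFAULT_ROAD_OVERRIDES = {
    "Kirkeveien": 1.30,
    "Lågendalsveien": 1.40,
    "Riksvei 19": 1.40,
}


@dataclass(frozen=True)
class SpeedCorrectionRules:
    """Speed-limit to ambulance-speed correction.

    ``road_overrides`` maps road names to multipliers replacing the generic
    factor; an override applies only at or above the threshold (below it
    the limit itself is the best estimate of the actual speed).
    """

    low_speed_threshold: float = 40.0
    factor_at_threshold: float = 1.15
    factor_above_threshold: float = 1.20
    road_overrides: dict = field(default_factory=lambda: dict(DEFAULT_ROAD_OVERRIDES))

    def __post_init__(self):
        if self.low_speed_threshold <= 0:
            raise ValueError("speed threshold must be positive")
        factors = [self.factor_at_threshold, self.factor_above_threshold,
                   *self.road_overrides.values()]
        if any(f < 1 for f in factors):
            raise ValueError("speed multipliers must be >= 1")


@dataclass(frozen=True)
class ResponseTimePolicy:
    """Response-time targets and pre-trip delay, minutes."""

    pre_trip_delay: float = 3.0
    urban_target: float = 12.0
    rural_target: float = 25.0

    def __post_init__(self):
        if self.pre_trip_delay < 0:
            raise ValueError("pre-trip delay must be non-negative")
        if min(self.urban_target, self.rural_target) <= self.pre_trip_delay:
            raise ValueError("targets must exceed the pre-trip delay")

    def driving_budget(self, urbanity: str) -> float:
        """Driving-time budget in minutes for an ``urban`` or ``rural`` point."""
        if urbanity == "urban":
            return self.urban_target - self.pre_trip_delay
        if urbanity == "rural":
            return self.rural_target - self.pre_trip_delay
        raise ValueError(f"unlabeled demand point (urbanity={urbanity!r})")


def corrected_speed(speed_limit_kmh: float, road_name: str | None = None,
                    rules: SpeedCorrectionRules | None = None) -> float:
    """Estimated ambulance driving speed (km/h) for a road segment."""
    rules = rules or SpeedCorrectionRules()
    if speed_limit_kmh <= 0:
        raise ValueError("speed limit must be positive")
    if speed_limit_kmh < rules.low_speed_threshold:
        return float(speed_limit_kmh)
    override = rules.road_overrides.get(road_name) if road_name else None
    if override is not None:
        return float(speed_limit_kmh * override)
    if speed_limit_kmh == rules.low_speed_threshold:
        return float(speed_limit_kmh * rules.factor_at_threshold)
    return float(speed_limit_kmh * rules.factor_above_threshold)


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine great-circle distance in km (vectorised)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def snap_to_network(lon: float, lat: float, network: RoadNetwork) -> int:
    """Nearest road node (great-circle) to a point; ties to the lowest node id.

    Snapping to nodes rather than perpendicularly to edges is a deliberate
    simplification: at 1 km grid resolution the difference is below the
    model's granularity.
    """
    if len(network.nodes) == 0:
        raise ValueError("cannot snap to an empty network")
    d = great_circle_km(lon, lat,
                        network.nodes["longitude"].to_numpy(),
                        network.nodes["latitude"].to_numpy())
    ids = network.nodes["id"].to_numpy()
    best = d.min()
    # exact-tie rule: among nodes at the minimal distance, smallest id
    return int(ids[d == best].min())


def build_time_graph(network: RoadNetwork,
                     rules: SpeedCorrectionRules | None = None) -> nx.DiGraph:
    """Directed graph with arc weights in driving minutes.

    Arc time = length / corrected speed; undirected edges become two arcs.
    """
    rules = rules or SpeedCorrectionRules()
    g = nx.DiGraph()
    g.add_nodes_from(int(i) for i in network.nodes["id"])
    ed = network.edges
    for u, v, length, limit, name, oneway in zip(
            ed["from"], ed["to"], ed["length_m"], ed["speed_kmh"],
            ed["name"], ed["oneway"]):
        speed = corrected_speed(limit, name or None, rules)
        minutes = (length / 1000.0) / speed * 60.0
        _add_min_arc(g, int(u), int(v), minutes)
        if not oneway:
            _add_min_arc(g, int(v), int(u), minutes)
    return g


def _add_min_arc(g: nx.DiGraph, u: int, v: int, minutes: float) -> None:
    # parallel edges collapse to the fastest one
    if g.has_edge(u, v):
        g[u][v]["minutes"] = min(g[u][v]["minutes"], minutes)
    else:
        g.add_edge(u, v, minutes=minutes)


def travel_time_matrix(network: RoadNetwork, base_nodes, demand_nodes,
                       rules: SpeedCorrectionRules | None = None) -> np.ndarray:
    """Shortest driving times, minutes; shape (bases, demand points).

    One Dijkstra pass per base node; unreachable pairs are ``inf``.
    """
    g = build_time_graph(network, rules)
    known = set(g.nodes)
    for n in list(base_nodes) + list(demand_nodes):
        if int(n) not in known:
            raise ValueError(f"node {n} not in network")
    demand_nodes = [int(n) for n in demand_nodes]
    out = np.full((len(base_nodes), len(demand_nodes)), np.inf)
    for j, b in enumerate(base_nodes):
        dist = nx.single_source_dijkstra_path_length(g, int(b), weight="minutes")
        out[j] = [dist.get(n, np.inf) for n in demand_nodes]
    return out


def coverage_matrix(ttm: np.ndarray, urbanity,
                    policy: ResponseTimePolicy | None = None) -> np.ndarray:
    """Boolean matrix a[i, j]: demand point i reachable from base j in budget.

    ``ttm`` is (bases, demand); the result is (demand, bases) to match the
    a_ij orientation of the optimization model.  The comparison is
    inclusive: an arrival exactly at the budget counts as covered.
    """
    policy = policy or ResponseTimePolicy()
    urbanity = list(urbanity)
    if ttm.shape[1] != len(urbanity):
        raise ValueError("one urbanity label per demand point required")
    budgets = np.array([policy.driving_budget(u) for u in urbanity])
    return (ttm.T <= budgets[:, None])
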