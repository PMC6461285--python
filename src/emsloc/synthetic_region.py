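"""Self-contained synthetic mixed urban-rural regions.

Generates everything the pipeline consumes — a 1 km demand grid with a few
high-population urban clusters over a sparse rural background, incident
counts, a routable lattice road network with mixed speed classes, candidate
and "current" bases, and hourly busy logs — with known ground truth, so
every stage is testable without external downloads.  The emitted CSVs use
the exact layouts of the real supplementary inputs, making synthetic and
real data interchangeable.

Incidents are sampled as Poisson counts with expectation population ×
per-capita rate; the urban rate may exceed the rural one to decouple
incident weight from raw population.  A deterministic mode replaces
sampling by rounded expectations for exact tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import RoadNetwork

__all__ = ["RegionParams", "SyntheticRegion", "generate_region",
           "generate_busy_log", "deferral_region_params"]

# geographic anchor of the synthetic grid (southern Norway latitudes, so
# lon/lat round-trips through the classification grid are exercised)
_LON0, _LAT0 = 10.0, 59.2
_KM_PER_DEG_LAT = 111.2
_KM_PER_DEG_LON = _KM_PER_DEG_LAT * math.cos(math.radians(_LAT0))


@dataclass(frozen=True)
class RegionParams:
    """Knobs of the synthetic region.

    Defaults sketch a small mixed urban-rural county: a handful of compact
    towns of 10–30 thousand inhabitants on a sparse (≈20 people/km²)
    rural background, with per-capita emergency-incident rates of the
    order of 0.15 incidents per inhabitant over a multi-year window and a
    denser incident stream in towns.
    """

    width_km: int = 24
    height_km: int = 18
    n_clusters: int = 3
    cluster_population_range: tuple = (12_000, 30_000)
    cluster_populations: tuple | None = None  # explicit per-cluster totals
    cluster_centers: tuple | None = None      # explicit (col, row) centers
    cluster_radius: int = 2                   # squares
    rural_density: float = 20.0               # mean inhabitants per rural km²
    urban_incident_rate: float = 0.20         # incidents per inhabitant
    rural_incident_rate: float = 0.12
    road_spacing_km: int = 1
    speed_classes: tuple = (30, 40, 50, 60, 80)
    candidate_spacing_km: int = 3
    n_current_bases: int = 3
    deterministic: bool = False               # expectations instead of draws
    seed: int = 0

    def __post_init__(self):
        if min(self.width_km, self.height_km, self.n_clusters,
               self.cluster_radius, self.n_current_bases) < 1:
            raise ValueError("all counts must be positive")
        if self.rural_density < 0 or min(self.urban_incident_rate,
                                         self.rural_incident_rate) < 0:
            raise ValueError("densities and rates must be non-negative")


@dataclass
class SyntheticRegion:
    """Generated region plus ground-truth metadata."""

    demand: pd.DataFrame        # S1 layout + eligible flag
    bases: pd.DataFrame         # S2 layout (kind column), candidates + current
    network: RoadNetwork
    cluster_members: list       # list of id-tuples, one per cluster
    true_urbanity: pd.Series    # intended labels, aligned with demand
    params: RegionParams

    @property
    def current_base_ids(self) -> list:
        return self.bases.loc[self.bases["kind"] == "current_station", "id"].tolist()


def _cell_lonlat(col: np.ndarray, row: np.ndarray):
    """Center of grid cell (col, row) in lon/lat degrees."""
    lon = _LON0 + (col + 0.5) / _KM_PER_DEG_LON
    lat = _LAT0 + (row + 0.5) / _KM_PER_DEG_LAT
    return lon, lat


def _place_clusters(params: RegionParams, rng: np.random.Generator) -> list:
    if params.cluster_centers is not None:
        centers = [tuple(c) for c in params.cluster_centers]
        if len(centers) != params.n_clusters:
            raise ValueError("cluster_centers length must equal n_clusters")
    else:
        min_sep = 2 * params.cluster_radius + 2
        centers = []
        for _ in range(2000):
            c = (int(rng.integers(params.cluster_radius,
                                  params.width_km - params.cluster_radius)),
                 int(rng.integers(params.cluster_radius,
                                  params.height_km - params.cluster_radius)))
            if all(max(abs(c[0] - o[0]), abs(c[1] - o[1])) >= min_sep for o in centers):
                centers.append(c)
            if len(centers) == params.n_clusters:
                break
        else:
            raise ValueError(
                "could not place clusters disjointly; reduce n_clusters or cluster_radius")
    r = params.cluster_radius
    for c in centers:
        if not (r <= c[0] < params.width_km - r and r <= c[1] < params.height_km - r):
            raise ValueError(f"cluster center {c} too close to the region border")
    for i, a in enumerate(centers):
        for b in centers[i + 1:]:
            if max(abs(a[0] - b[0]), abs(a[1] - b[1])) <= 2 * r + 1:
                raise ValueError("cluster footprints overlap or touch; "
                                 "reduce cluster_radius or spread the centers")
    return centers


def generate_region(params: RegionParams) -> SyntheticRegion:
    """Build a synthetic region; identical output for identical params."""
    rng = np.random.default_rng(params.seed)
    w, h = params.width_km, params.height_km
    cols, rows = np.meshgrid(np.arange(w), np.arange(h), indexing="ij")
    cols, rows = cols.ravel(), rows.ravel()
    n_sq = w * h
    cell_index = {(int(c), int(r)): i for i, (c, r) in enumerate(zip(cols, rows))}

    centers = _place_clusters(params, rng)
    if params.cluster_populations is not None:
        totals = list(params.cluster_populations)
        if len(totals) != params.n_clusters:
            raise ValueError("cluster_populations length must equal n_clusters")
    else:
        lo, hi = params.cluster_population_range
        totals = [int(rng.integers(lo, hi + 1)) for _ in centers]

    population = np.zeros(n_sq, dtype=float)
    cluster_of = np.full(n_sq, -1, dtype=int)
    radius = params.cluster_radius
    for ci, ((cc, cr), total) in enumerate(zip(centers, totals)):
        # Gaussian-profile weights over the (2r+1)² footprint, scaled to the total
        weights, cells = [], []
        for dc in range(-radius, radius + 1):
            for dr in range(-radius, radius + 1):
                cell = (cc + dc, cr + dr)
                if cell in cell_index:
                    cells.append(cell_index[cell])
                    weights.append(math.exp(-(dc * dc + dr * dr) / (radius ** 2 + 1e-9)))
        weights = np.array(weights) / np.sum(weights)
        alloc = np.floor(weights * total).astype(int)
        alloc[0] += total - alloc.sum()  # remainder to the center square
        population[cells] = alloc
        cluster_of[cells] = ci

    rural = cluster_of < 0
    if params.rural_density > 0:
        if params.deterministic:
            population[rural] = round(params.rural_density)
        else:
            population[rural] = rng.poisson(params.rural_density, rural.sum())

    rate = np.where(rural, params.rural_incident_rate, params.urban_incident_rate)
    mean_inc = population * rate
    if params.deterministic:
        incidents = np.round(mean_inc).astype(int)
    else:
        incidents = rng.poisson(mean_inc)

    lon, lat = _cell_lonlat(cols, rows)
    demand = pd.DataFrame({
        "id": np.arange(n_sq),
        "longitude": lon, "latitude": lat,
        "population": population.astype(int),
        "incidents": incidents.astype(int),
        "col": cols, "row": rows,
    })
    demand["eligible"] = (demand["population"] > 0) | (demand["incidents"] > 0)

    # road lattice: one node per square center, 4-neighbour edges with
    # speeds drawn from the class mix (always connected)
    edge_from, edge_to = [], []
    for c, r in zip(cols, rows):
        i = cell_index[(int(c), int(r))]
        for dc, dr in ((1, 0), (0, 1)):
            nb = (int(c) + dc, int(r) + dr)
            if nb in cell_index:
                edge_from.append(i)
                edge_to.append(cell_index[nb])
    n_edges = len(edge_from)
    if params.deterministic:
        speeds = np.array(params.speed_classes)[np.arange(n_edges) % len(params.speed_classes)]
    else:
        speeds = rng.choice(np.array(params.speed_classes, dtype=float), size=n_edges)
    edges = pd.DataFrame({
        "from": edge_from, "to": edge_to,
        "length_m": 1000.0 * params.road_spacing_km,
        "speed_kmh": speeds.astype(float),
        "name": "", "oneway": False,
    })
    network = RoadNetwork(
        nodes=demand[["id", "longitude", "latitude"]].copy(),
        edges=edges,
    )

    # candidate bases on a coarse sub-grid; current bases at the largest
    # cluster centers (mirrors bases sitting in towns)
    cand_cells = [(c, r) for c in range(0, w, params.candidate_spacing_km)
                  for r in range(0, h, params.candidate_spacing_km)]
    order = np.argsort([-t for t in totals])
    current_cells = [centers[i] for i in order[:min(params.n_current_bases, len(centers))]]
    base_rows = []
    bid = 0
    for cell in current_cells:
        lon_b, lat_b = _cell_lonlat(np.array([cell[0]]), np.array([cell[1]]))
        base_rows.append({"id": bid, "name": f"station_{bid}", "kind": "current_station",
                          "longitude": float(lon_b[0]), "latitude": float(lat_b[0])})
        bid += 1
    for cell in cand_cells:
        if cell in current_cells:
            continue
        lon_b, lat_b = _cell_lonlat(np.array([cell[0]]), np.array([cell[1]]))
        base_rows.append({"id": bid, "name": f"grid_{cell[0]}_{cell[1]}", "kind": "grid",
                          "longitude": float(lon_b[0]), "latitude": float(lat_b[0])})
        bid += 1
    bases = pd.DataFrame(base_rows)

    members = []
    for ci in range(len(centers)):
        members.append(tuple(int(i) for i in np.flatnonzero(cluster_of == ci)))
    true_urbanity = pd.Series(
        np.where(cluster_of >= 0, "urban", "rural"), index=demand.index, name="urbanity")
    return SyntheticRegion(demand=demand, bases=bases, network=network,
                           cluster_members=members, true_urbanity=true_urbanity,
                           params=params)


def deferral_region_params(seed: int = 7) -> RegionParams:
    """Study conditions for the urban-backup vs rural-single-coverage trade-off.

    One dominant town (30 000 inhabitants, urban, 9-minute driving budget)
    and one remote weak settlement (800 inhabitants, rural, 22-minute
    budget) at opposite ends of the region, with sparse rural background
    demand and a current base at each settlement.  The settlements are
    40 km apart so that the remote cluster lies outside the other base's
    rural driving budget under every road-speed draw (22 min at the
    fastest corrected speed, 80 km/h x 1.20, is under 36 km): its own base
    is the only source of coverage there.  On this region the fleet size
    at which the remote base is first staffed rises with the busy
    fraction: single coverage of the weak cluster loses out to backup
    coverage of the town as the system load grows.
    """
    return RegionParams(
        width_km=49, height_km=18, n_clusters=2,
        cluster_centers=((4, 9), (44, 9)),
        cluster_populations=(30_000, 800),
        cluster_radius=2, rural_density=2.0,
        urban_incident_rate=0.2, rural_incident_rate=0.1,
        n_current_bases=2, seed=seed)


def generate_busy_log(profile, on_duty_schedule, days: int, seed: int = 0) -> pd.DataFrame:
    """Hourly busy log with binomial busy counts around a 24-hour profile.

    Parameters
    ----------
    profile : 24 hourly busy-fraction values in [0, 1].
    on_duty_schedule : scalar or 24 per-hour on-duty ambulance counts.
    days : number of simulated days.
    seed : RNG seed.

    Applying the mean-of-ratios hourly profile estimator to the output
    recovers ``profile`` to within binomial sampling error.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (24,) or ((profile < 0) | (profile > 1)).any():
        raise ValueError("profile must be 24 values in [0, 1]")
    on_duty = np.broadcast_to(np.asarray(on_duty_schedule, dtype=int), (24,))
    rng = np.random.default_rng(seed)
    recs = []
    for d in range(days):
        busy = rng.binomial(on_duty, profile)
        for hr in range(24):
            recs.append({"date": f"day{d:04d}", "hour": hr,
                         "on_duty": int(on_duty[hr]), "busy": int(busy[hr])})
    return pd.DataFrame(recs)
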