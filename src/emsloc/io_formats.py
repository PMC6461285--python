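"""Readers and writers for the study's tabular formats.

All inputs are plain CSV (comma separator, dot decimal mark, UTF-8, header
row required):

* demand points  — ``id,longitude,latitude,population,incidents``
* candidate bases — ``id,name,type,longitude,latitude``
* busy logs      — ``date,hour,on_duty,busy`` (column names remappable)
* road networks  — nodes ``id,longitude,latitude`` +
  edges ``from,to,length_m,speed_kmh,name,oneway``

Validation is strict: a malformed row raises :class:`ValidationError`
naming the offending row rather than silently coercing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "BASE_KINDS",
    "RoadNetwork",
    "read_demand_points",
    "write_demand_points",
    "read_bases",
    "write_bases",
    "read_busy_log",
    "write_busy_log",
    "busy_fraction_profile",
    "read_road_network",
    "write_road_network",
]


class ValidationError(ValueError):
    """An input table violates the format contract."""


#: closed vocabulary for candidate-base kinds; CSV spellings use spaces.
BASE_KINDS = {"grid", "current_station", "standby_point"}

_BASE_KIND_ALIASES = {
    "grid": "grid",
    "current station": "current_station",
    "current_station": "current_station",
    "standby point": "standby_point",
    "standby_point": "standby_point",
}

DEMAND_COLUMNS = ["id", "longitude", "latitude", "population", "incidents"]
BASE_COLUMNS = ["id", "name", "type", "longitude", "latitude"]
BUSY_COLUMNS = ["date", "hour", "on_duty", "busy"]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, what: str, integer: bool = False) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if out.isna().any():
        row = int(np.flatnonzero(out.isna() | bad)[0])
        raise ValidationError(f"{what}: non-numeric or missing value in column '{col}', row {row}")
    if integer:
        if not np.allclose(out, np.round(out)):
            row = int(np.flatnonzero(~np.isclose(out, np.round(out)))[0])
            raise ValidationError(f"{what}: non-integer value in column '{col}', row {row}")
        out = out.astype(int)
    return out


def _unique_ids(ids: pd.Series, what: str) -> None:
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValidationError(f"{what}: duplicate id {dup.iloc[0]}")


# ---------------------------------------------------------------------------
# demand points (S1 layout)
# ---------------------------------------------------------------------------

def read_demand_points(path) -> pd.DataFrame:
    """Read a demand-point table.

    Returns a DataFrame with the five input columns plus:

    ``eligible``
        True when the square has non-zero population or non-zero incidents;
        only eligible squares enter the coverage analysis, but ineligible
        ones are retained because any square can still host a base.
    ``urbanity``
        carried through when present in the file (values ``urban``/``rural``),
        otherwise absent; it is normally assigned by the classification step.
    """
    df = pd.read_csv(path)
    _require_columns(df, DEMAND_COLUMNS, "demand points")
    out = pd.DataFrame({
        "id": _numeric(df, "id", "demand points", integer=True),
        "longitude": _numeric(df, "longitude", "demand points"),
        "latitude": _numeric(df, "latitude", "demand points"),
        "population": _numeric(df, "population", "demand points", integer=True),
        "incidents": _numeric(df, "incidents", "demand points", integer=True),
    })
    _unique_ids(out["id"], "demand points")
    if (out["population"] < 0).any():
        row = int(np.flatnonzero(out["population"] < 0)[0])
        raise ValidationError(f"demand points: negative population, row {row}")
    if (out["incidents"] < 0).any():
        row = int(np.flatnonzero(out["incidents"] < 0)[0])
        raise ValidationError(f"demand points: negative incidents, row {row}")
    out["eligible"] = (out["population"] > 0) | (out["incidents"] > 0)
    if "urbanity" in df.columns:
        labels = df["urbanity"].astype(str)
        bad = ~labels.isin(["urban", "rural"])
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(f"demand points: unknown urbanity label, row {row}")
        out["urbanity"] = labels.to_numpy()
    return out


def write_demand_points(df: pd.DataFrame, path) -> None:
    cols = [c for c in DEMAND_COLUMNS + ["urbanity"] if c in df.columns]
    df[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# candidate bases (S2 layout)
# ---------------------------------------------------------------------------

def read_bases(path) -> pd.DataFrame:
    """Read a candidate-base table; ``type`` is mapped onto the closed kind set."""
    df = pd.read_csv(path)
    _require_columns(df, BASE_COLUMNS, "bases")
    kinds = []
    for row, raw in enumerate(df["type"].astype(str)):
        key = raw.strip().lower()
        if key not in _BASE_KIND_ALIASES:
            raise ValidationError(f"bases: unknown type '{raw}', row {row}")
        kinds.append(_BASE_KIND_ALIASES[key])
    out = pd.DataFrame({
        "id": _numeric(df, "id", "bases", integer=True),
        "name": df["name"].astype(str).to_numpy(),
        "kind": kinds,
        "longitude": _numeric(df, "longitude", "bases"),
        "latitude": _numeric(df, "latitude", "bases"),
    })
    _unique_ids(out["id"], "bases")
    return out


def write_bases(df: pd.DataFrame, path) -> None:
    spellings = {"grid": "grid", "current_station": "current station",
                 "standby_point": "standby point"}
    out = pd.DataFrame({
        "id": df["id"],
        "name": df["name"],
        "type": df["kind"].map(spellings),
        "longitude": df["longitude"],
        "latitude": df["latitude"],
    })
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# busy logs (S3 layout)
# ---------------------------------------------------------------------------

def read_busy_log(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read an hourly busy log.

    The canonical layout is ``date,hour,on_duty,busy``.  Because the exact
    header of real logs varies, ``column_map`` maps canonical names to the
    file's column names, e.g. ``{"on_duty": "ambulances_on_duty"}``.
    """
    df = pd.read_csv(path)
    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    _require_columns(df, BUSY_COLUMNS, "busy log")
    out = pd.DataFrame({
        "date": df["date"].astype(str).to_numpy(),
        "hour": _numeric(df, "hour", "busy log", integer=True),
        "on_duty": _numeric(df, "on_duty", "busy log", integer=True),
        "busy": _numeric(df, "busy", "busy log", integer=True),
    })
    bad_hour = (out["hour"] < 0) | (out["hour"] > 23)
    if bad_hour.any():
        row = int(np.flatnonzero(bad_hour)[0])
        raise ValidationError(f"busy log: hour outside 0..23, row {row}")
    over = out["busy"] > out["on_duty"]
    if over.any():
        row = int(np.flatnonzero(over)[0])
        raise ValidationError(f"busy log: busy exceeds on_duty, row {row}")
    if (out[["on_duty", "busy"]] < 0).any().any():
        raise ValidationError("busy log: negative counts")
    return out


def write_busy_log(df: pd.DataFrame, path) -> None:
    df[BUSY_COLUMNS].to_csv(path, index=False)


def busy_fraction_profile(
    records: pd.DataFrame,
    day_filter=None,
    method: str = "mean_of_ratios",
) -> np.ndarray:
    """24 hourly busy fractions from a validated busy log.

    Each hour's value is, by default, the unweighted mean over records of
    ``busy / on_duty`` ("average busy fraction per hour"); the alternative
    ``ratio_of_sums`` divides total busy by total on duty.  Records with
    ``on_duty == 0`` carry no information and are skipped; an hour with no
    usable record is NaN (missing).

    Parameters
    ----------
    records : DataFrame as returned by :func:`read_busy_log`.
    day_filter : optional callable applied to the ``date`` column
        (vectorised, returns a boolean mask), e.g. a weekday selector.
    method : ``"mean_of_ratios"`` (default) or ``"ratio_of_sums"``.
    """
    if (records["busy"] > records["on_duty"]).any():
        raise ValidationError("busy log: busy exceeds on_duty")
    df = records
    if day_filter is not None:
        df = df[np.asarray(day_filter(df["date"]))]
    df = df[df["on_duty"] > 0]
    profile = np.full(24, np.nan)
    if method == "mean_of_ratios":
        ratios = df["busy"] / df["on_duty"]
        grouped = ratios.groupby(df["hour"]).mean()
    elif method == "ratio_of_sums":
        sums = df.groupby("hour")[["busy", "on_duty"]].sum()
        grouped = sums["busy"] / sums["on_duty"]
    else:
        raise ValueError(f"unknown method '{method}'")
    profile[grouped.index.to_numpy()] = grouped.to_numpy()
    return profile


# ---------------------------------------------------------------------------
# road networks
# ---------------------------------------------------------------------------

@dataclass
class RoadNetwork:
    """A validated road network.

    ``nodes``: DataFrame ``id,longitude,latitude``;
    ``edges``: DataFrame ``from,to,length_m,speed_kmh,name,oneway``.
    Undirected edges (``oneway == False``) count as two arcs.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame

    @property
    def n_arcs(self) -> int:
        if len(self.edges) == 0:
            return 0
        return int(len(self.edges) + (~self.edges["oneway"]).sum())

    def node_ids(self) -> np.ndarray:
        return self.nodes["id"].to_numpy()


def read_road_network(nodes_path, edges_path) -> RoadNetwork:
    """Read node and edge tables into a :class:`RoadNetwork`.

    ``name`` and ``oneway`` edge columns are optional (default: unnamed,
    undirected).  Referential integrity and positivity of length and speed
    are enforced.
    """
    ndf = pd.read_csv(nodes_path)
    _require_columns(ndf, ["id", "longitude", "latitude"], "road nodes")
    nodes = pd.DataFrame({
        "id": _numeric(ndf, "id", "road nodes", integer=True),
        "longitude": _numeric(ndf, "longitude", "road nodes"),
        "latitude": _numeric(ndf, "latitude", "road nodes"),
    })
    _unique_ids(nodes["id"], "road nodes")

    edf = pd.read_csv(edges_path)
    if len(edf) == 0:
        edges = pd.DataFrame({
            "from": pd.Series([], dtype=int), "to": pd.Series([], dtype=int),
            "length_m": pd.Series([], dtype=float),
            "speed_kmh": pd.Series([], dtype=float),
            "name": pd.Series([], dtype=str), "oneway": pd.Series([], dtype=bool),
        })
        return RoadNetwork(nodes=nodes, edges=edges)
    _require_columns(edf, ["from", "to", "length_m", "speed_kmh"], "road edges")
    edges = pd.DataFrame({
        "from": _numeric(edf, "from", "road edges", integer=True),
        "to": _numeric(edf, "to", "road edges", integer=True),
        "length_m": _numeric(edf, "length_m", "road edges"),
        "speed_kmh": _numeric(edf, "speed_kmh", "road edges"),
    })
    edges["name"] = edf["name"].fillna("").astype(str).to_numpy() if "name" in edf.columns else ""
    if "oneway" in edf.columns:
        ow = edf["oneway"]
        if ow.dtype == object:
            ow = ow.astype(str).str.strip().str.lower().isin(["1", "true", "yes"])
        edges["oneway"] = ow.astype(bool).to_numpy()
    else:
        edges["oneway"] = False

    known = set(nodes["id"])
    for col in ("from", "to"):
        dangling = ~edges[col].isin(known)
        if dangling.any():
            row = int(np.flatnonzero(dangling)[0])
            raise ValidationError(
                f"road edges: endpoint {edges[col].iloc[row]} not a node, row {row}")
    if (edges["length_m"] <= 0).any():
        row = int(np.flatnonzero(edges["length_m"] <= 0)[0])
        raise ValidationError(f"road edges: non-positive length, row {row}")
    if (edges["speed_kmh"] <= 0).any():
        row = int(np.flatnonzero(edges["speed_kmh"] <= 0)[0])
        raise ValidationError(f"road edges: non-positive speed limit, row {row}")
    return RoadNetwork(nodes=nodes, edges=edges)


def write_road_network(network: RoadNetwork, nodes_path, edges_path) -> None:
    network.nodes.to_csv(nodes_path, index=False)
    network.edges.to_csv(edges_path, index=False)
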