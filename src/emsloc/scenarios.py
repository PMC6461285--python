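"""Parameter sweeps over fleet size, busy fraction, and base restrictions.

The study design crosses fleet sizes 1..15 with busy fractions
{0, 0.15, 0.35, 0.5} and three base-restriction regimes of decreasing
severity:

``fixed_current``
    ambulances may only be placed at the existing bases;
``restricted_greenfield``
    any candidate square, but at most B (default 5) bases open;
``unrestricted_greenfield``
    any candidate square, no cap on the number of bases.

The default grid therefore enumerates 15 × 4 × 3 = 180 scenario cells,
each solved independently to proven optimality.  Alongside coverage, the
sweep reports which base each successive ambulance joins by differencing
consecutive optima ("selected base location"); optima need not be nested
across fleet sizes, so a non-nested step is flagged explicitly rather
than forced into a single base label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import label_demand_points
from .coverage_opt import Allocation, CoverageInstance, solve_exact
from .travel_time import (ResponseTimePolicy, SpeedCorrectionRules,
                          coverage_matrix, snap_to_network, travel_time_matrix)

__all__ = [
    "ScenarioGrid",
    "prepare_inputs",
    "run_sweep",
    "incremental_base_assignment",
    "single_coverage_table",
    "BASE_MODES",
]

BASE_MODES = ("fixed_current", "restricted_greenfield", "unrestricted_greenfield")


@dataclass(frozen=True)
class ScenarioGrid:
    """The sweep design: fleet sizes × busy fractions × base modes."""

    fleet_sizes: tuple = tuple(range(1, 16))
    busy_fractions: tuple = (0.0, 0.15, 0.35, 0.5)
    modes: tuple = BASE_MODES
    max_bases: int = 5  # cap B for the restricted_greenfield mode

    def __post_init__(self):
        if not (self.fleet_sizes and self.busy_fractions and self.modes):
            raise ValueError("fleet sizes, busy fractions and modes must be non-empty")
        if any(p < 1 for p in self.fleet_sizes):
            raise ValueError("fleet sizes must be positive")
        unknown = set(self.modes) - set(BASE_MODES)
        if unknown:
            raise ValueError(f"unknown base mode(s): {sorted(unknown)}")

    @property
    def n_cells(self) -> int:
        return len(self.fleet_sizes) * len(self.busy_fractions) * len(self.modes)

    def cells(self):
        """(mode, q, p) in reporting order: mode-major, then q, then p."""
        for mode in self.modes:
            for q in self.busy_fractions:
                for p in self.fleet_sizes:
                    yield mode, q, p


def prepare_inputs(
    demand: pd.DataFrame,
    bases: pd.DataFrame,
    network,
    policy: ResponseTimePolicy | None = None,
    rules: SpeedCorrectionRules | None = None,
    cutoff: int = 10_000,
    weight_column: str = "incidents",
):
    """From raw tables to the optimization inputs.

    Labels demand points urban/rural (unless pre-labelled), snaps eligible
    demand squares and candidate bases to the road network, computes the
    travel-time matrix and the boolean coverage matrix, and extracts demand
    weights.  Incident counts are the recommended weights; population is a
    proxy of last resort.

    Returns ``(weights, cover, current_base_idx, base_labels, eligible)``
    where ``eligible`` is the analysed subset of the demand table.
    """
    policy = policy or ResponseTimePolicy()
    rules = rules or SpeedCorrectionRules()
    labelled = label_demand_points(demand, cutoff=cutoff)
    eligible = labelled[labelled["eligible"]].reset_index(drop=True)
    demand_nodes = [snap_to_network(lon, lat, network)
                    for lon, lat in zip(eligible["longitude"], eligible["latitude"])]
    base_nodes = [snap_to_network(lon, lat, network)
                  for lon, lat in zip(bases["longitude"], bases["latitude"])]
    ttm = travel_time_matrix(network, base_nodes, demand_nodes, rules)
    cover = coverage_matrix(ttm, eligible["urbanity"], policy)
    weights = eligible[weight_column].to_numpy(dtype=float)
    current_idx = np.flatnonzero((bases["kind"] == "current_station").to_numpy())
    labels = bases["name"].astype(str).tolist()
    return weights, cover, current_idx, labels, eligible


def _mode_instance(weights, cover, q, p, mode, current_idx, max_bases):
    """Instance + column index map for one base-restriction regime."""
    if mode == "fixed_current":
        if current_idx is None or len(current_idx) == 0:
            raise ValueError("fixed_current mode requires current-base indices")
        cols = np.asarray(current_idx, dtype=int)
        return CoverageInstance(weights=weights, cover=cover[:, cols],
                                q=q, p=p, max_bases=None), cols
    cols = np.arange(cover.shape[1])
    cap = max_bases if mode == "restricted_greenfield" else None
    return CoverageInstance(weights=weights, cover=cover, q=q, p=p,
                            max_bases=cap), cols


def run_sweep(
    weights,
    cover,
    current_base_idx=None,
    grid: ScenarioGrid | None = None,
    base_labels=None,
    logger=None,
) -> pd.DataFrame:
    """Solve every scenario cell; one row per (mode, q, p).

    Parameters
    ----------
    weights, cover : demand weights d_i and boolean coverage matrix a_ij
        over the full candidate set.
    current_base_idx : candidate-column indices of the existing bases
        (required when the grid includes ``fixed_current``).
    grid : sweep design, defaults to the full 180-cell grid.
    base_labels : optional names per candidate column, used in the
        "selected base" report.
    logger : optional ``logging.Logger``; solver status is recorded per cell.

    Returns a long-format DataFrame with columns mode, q, p, coverage,
    objective, n_open_bases, opened, x, selected_base, non_nested.
    """
    grid = grid or ScenarioGrid()
    weights = np.asarray(weights, dtype=float)
    cover = np.asarray(cover, dtype=bool)
    if base_labels is None:
        base_labels = [str(j) for j in range(cover.shape[1])]

    rows = []
    prev: dict[tuple, Allocation] = {}
    for mode, q, p in grid.cells():
        inst, cols = _mode_instance(weights, cover, q, p, mode,
                                    current_base_idx, grid.max_bases)
        try:
            alloc = solve_exact(inst)
        except Exception as exc:
            raise RuntimeError(
                f"scenario cell failed (mode={mode}, q={q}, p={p}): {exc}") from exc
        if logger is not None:
            logger.info("cell mode=%s q=%.2f p=%d: objective=%.6f coverage=%.6f",
                        mode, q, p, alloc.objective, alloc.coverage_fraction)
        # lift x back onto the full candidate set for cross-mode comparisons
        x_full = np.zeros(cover.shape[1], dtype=int)
        x_full[cols] = alloc.x
        full_alloc = Allocation(x=x_full, objective=alloc.objective,
                                coverage_fraction=alloc.coverage_fraction)
        key = (mode, q)
        selected, non_nested = None, False
        if key in prev and prev[key].n_ambulances == p - 1:
            step = incremental_base_assignment(prev[key], full_alloc)
            if isinstance(step, int):
                selected = base_labels[step]
            else:
                non_nested = True
                selected = step[1]
        prev[key] = full_alloc
        rows.append({
            "mode": mode, "q": q, "p": p,
            "coverage": alloc.coverage_fraction,
            "objective": alloc.objective,
            "n_open_bases": len(full_alloc.opened),
            "opened": ",".join(base_labels[j] for j in full_alloc.opened),
            "x": ",".join(map(str, x_full)),
            "selected_base": selected,
            "non_nested": non_nested,
        })
    return pd.DataFrame(rows)


def incremental_base_assignment(alloc_p: Allocation, alloc_p_plus_1: Allocation):
    """Which base the (p+1)-th ambulance joins, if the optima are nested.

    Returns the base index when the larger allocation is the smaller one
    plus a single ambulance; otherwise ``("non_nested", description)``
    with the multiset difference spelled out.
    """
    diff = alloc_p_plus_1.x - alloc_p.x
    added = np.flatnonzero(diff > 0)
    removed = np.flatnonzero(diff < 0)
    if len(removed) == 0 and len(added) == 1 and diff[added[0]] == 1:
        return int(added[0])
    parts = [f"-{-diff[j]}x base{j}" for j in removed]
    parts += [f"+{diff[j]}x base{j}" for j in added]
    return ("non_nested", ", ".join(parts))


def single_coverage_table(
    weights,
    cover,
    current_base_idx,
    base_counts=range(1, 16),
) -> pd.DataFrame:
    """Single coverage (q = 0) versus the number of open bases.

    For each number of bases B, solves the MCLP with p = B (one ambulance
    per base suffices when no ambulance is ever busy), both over the
    current bases only and over all candidates (greenfield).  Current-base
    coverage is only defined for B up to the number of current bases.
    """
    weights = np.asarray(weights, dtype=float)
    cover = np.asarray(cover, dtype=bool)
    current_base_idx = np.asarray(current_base_idx, dtype=int)
    rows = []
    for b in base_counts:
        rec = {"n_bases": int(b)}
        if b <= len(current_base_idx):
            inst = CoverageInstance(weights=weights,
                                    cover=cover[:, current_base_idx],
                                    q=0.0, p=int(b), max_bases=int(b))
            rec["coverage_current"] = solve_exact(inst).coverage_fraction
        else:
            rec["coverage_current"] = np.nan
        inst = CoverageInstance(weights=weights, cover=cover, q=0.0,
                                p=int(b), max_bases=int(b))
        rec["coverage_greenfield"] = solve_exact(inst).coverage_fraction
        rows.append(rec)
    return pd.DataFrame(rows)
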