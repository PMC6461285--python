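"""Expected-coverage ambulance location: the MEXCLP model and variants.

The Maximum Expected Covering Location Problem (MEXCLP) distributes p
ambulances over candidate bases so as to maximize expected covered demand
when every ambulance is independently busy with probability q.  A demand
point i with weight d_i covered by k ambulances contributes
d_i · (1 − q^k); the marginal value of the k-th covering ambulance is
therefore d_i (1 − q) q^{k−1}, strictly decreasing in k for q ∈ (0, 1).
At q = 0 the model reduces to the classic Maximum Covering Location
Problem (MCLP), where only single coverage matters.

Two modifications of the textbook model are supported: a cap B on the
number of open bases (via binary opening indicators z_j with
x_j ≤ p·z_j and Σ z_j ≤ B), and dual response-time radii, which enter
through the precomputed boolean coverage matrix a_ij rather than the
formulation itself.

Exact solution is by integer linear programming::

    max  Σ_i Σ_{k=1..p} d_i (1−q) q^{k−1} y_ik
    s.t. Σ_k y_ik ≤ Σ_j a_ij x_j          for every demand point i
         Σ_j x_j ≤ p
         x_j ≤ p z_j,  Σ_j z_j ≤ B        (only when B is set)
         x_j ∈ Z≥0,  z_j ∈ {0,1},  y_ik ∈ [0,1]

The coverage-level variables y_ik may be left continuous: their marginal
weights are non-negative and non-increasing in k, and each i has a single
budget constraint, so for any integer x the LP optimum in y is attained
at 0/1 values (fill from k = 1 upward).  The MILP is solved to zero gap
with HiGHS via ``scipy.optimize.milp``.

A brute-force enumeration oracle over all ambulance multisets is provided
for verification on small instances.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import coo_matrix

__all__ = [
    "CoverageInstance",
    "Allocation",
    "SolverError",
    "expected_coverage",
    "evaluate_allocation",
    "solve_exact",
    "solve_mclp",
    "brute_force_optimum",
]


class SolverError(RuntimeError):
    """The MILP solver did not return a proven optimum."""


@dataclass(frozen=True)
class CoverageInstance:
    """Input to the expected-coverage model.

    Parameters
    ----------
    weights : demand weight d_i per demand point (incident counts in the
        primary analysis; population is a discouraged alternative).
    cover : boolean matrix, ``cover[i, j]`` true when base j reaches demand
        point i within its driving-time budget.
    q : system-wide busy fraction, 0 ≤ q < 1.
    p : fleet size (total ambulances to place), ≥ 1.
    max_bases : cap B on the number of open bases; ``None`` = unlimited.
    base_ids : optional labels for the candidate bases (reporting only).
    """

    weights: np.ndarray
    cover: np.ndarray
    q: float
    p: int
    max_bases: int | None = None
    base_ids: tuple = ()

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        a = np.asarray(self.cover, dtype=bool)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "cover", a)
        if a.ndim != 2 or a.shape[0] != w.shape[0]:
            raise ValueError("cover must be (n_demand, n_bases) aligned with weights")
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive total")
        if not (0 <= self.q < 1):
            raise ValueError("busy fraction must satisfy 0 <= q < 1")
        if self.p < 1:
            raise ValueError("fleet size p must be >= 1")
        if self.max_bases is not None and self.max_bases < 1:
            raise ValueError("base cap must be >= 1 (or None)")

    @property
    def n_demand(self) -> int:
        return self.cover.shape[0]

    @property
    def n_bases(self) -> int:
        return self.cover.shape[1]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    # -- compact serialization (weights, sparse coverage pairs, q, p, B) --

    def to_json(self) -> str:
        ii, jj = np.nonzero(self.cover)
        return json.dumps({
            "weights": self.weights.tolist(),
            "n_bases": self.n_bases,
            "cover_pairs": np.column_stack([ii, jj]).tolist(),
            "q": self.q, "p": self.p, "max_bases": self.max_bases,
            "base_ids": list(self.base_ids),
        })

    @classmethod
    def from_json(cls, text: str) -> "CoverageInstance":
        d = json.loads(text)
        a = np.zeros((len(d["weights"]), d["n_bases"]), dtype=bool)
        for i, j in d["cover_pairs"]:
            a[i, j] = True
        return cls(weights=np.array(d["weights"]), cover=a, q=d["q"], p=d["p"],
                   max_bases=d["max_bases"], base_ids=tuple(d["base_ids"]))


@dataclass(frozen=True)
class Allocation:
    """Ambulances per candidate base, with objective and coverage fraction."""

    x: np.ndarray
    objective: float
    coverage_fraction: float

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=int))

    @property
    def opened(self) -> tuple:
        return tuple(int(j) for j in np.flatnonzero(self.x > 0))

    @property
    def n_ambulances(self) -> int:
        return int(self.x.sum())


def expected_coverage(k: int, q: float) -> float:
    """Expected coverage 1 − q^k of a point covered by k ambulances."""
    if k < 0:
        raise ValueError("k must be a non-negative integer")
    if not (0 <= q < 1):
        raise ValueError("busy fraction must satisfy 0 <= q < 1")
    if k == 0:
        return 0.0
    return float(1.0 - q ** k)


def _check_feasible(x: np.ndarray, instance: CoverageInstance) -> np.ndarray:
    x = np.asarray(x, dtype=int)
    if x.shape != (instance.n_bases,):
        raise ValueError("allocation length must match number of candidate bases")
    if (x < 0).any():
        raise ValueError("infeasible allocation: negative ambulance count")
    if x.sum() > instance.p:
        raise ValueError(
            f"infeasible allocation: {x.sum()} ambulances exceed fleet size p={instance.p}")
    if instance.max_bases is not None and (x > 0).sum() > instance.max_bases:
        raise ValueError(
            f"infeasible allocation: {(x > 0).sum()} open bases exceed cap "
            f"B={instance.max_bases}")
    return x


def evaluate_allocation(x, instance: CoverageInstance) -> float:
    """Expected coverage fraction Σ d_i (1 − q^{k_i}) / Σ d_i of allocation x."""
    x = _check_feasible(x, instance)
    k = instance.cover.astype(int) @ x
    covered = np.where(k > 0, 1.0 - instance.q ** np.maximum(k, 1), 0.0)
    return float(instance.weights @ covered / instance.total_weight)


def _marginal_weights(q: float, p: int) -> np.ndarray:
    """(1−q)q^{k−1} for k = 1..p; at q=0 this is (1, 0, 0, ...)."""
    k = np.arange(1, p + 1)
    if q == 0:
        return (k == 1).astype(float)
    return (1 - q) * q ** (k - 1.0)


def solve_exact(instance: CoverageInstance,
                forced_open: tuple = ()) -> Allocation:
    """Solve the expected-coverage MILP to proven optimality.

    ``forced_open`` lists base indices whose opening indicator is fixed to 1
    (they still count against the base cap); useful for conditioning on an
    existing base structure.

    Raises :class:`SolverError` if the solver terminates without a proven
    optimum — a silent suboptimal return is never produced.
    """
    n, m, p = instance.n_demand, instance.n_bases, instance.p
    a = instance.cover.astype(float)
    w = _marginal_weights(instance.q, p)
    use_z = instance.max_bases is not None and instance.max_bases < m

    # variable layout: x_j (m ints) | y_ik (n*p cont, i-major) | z_j (m bins)
    n_x, n_y = m, n * p
    n_z = m if use_z else 0
    n_var = n_x + n_y + n_z

    c = np.zeros(n_var)
    c[n_x:n_x + n_y] = -np.repeat(instance.weights, p) * np.tile(w, n)

    integrality = np.zeros(n_var)
    integrality[:n_x] = 1
    lb = np.zeros(n_var)
    ub = np.concatenate([
        np.full(m, float(p)),
        np.ones(n_y),
        np.ones(n_z),
    ])
    if use_z:
        integrality[n_x + n_y:] = 1
        for j in forced_open:
            lb[n_x + n_y + int(j)] = 1.0

    rows, cols, vals, b_ub = [], [], [], []
    r = 0
    # Σ_k y_ik − Σ_j a_ij x_j ≤ 0
    for i in range(n):
        js = np.flatnonzero(a[i])
        cols.extend(js); rows.extend([r] * len(js)); vals.extend([-1.0] * len(js))
        cols.extend(n_x + i * p + np.arange(p)); rows.extend([r] * p)
        vals.extend([1.0] * p)
        b_ub.append(0.0)
        r += 1
    # Σ_j x_j ≤ p
    cols.extend(range(m)); rows.extend([r] * m); vals.extend([1.0] * m)
    b_ub.append(float(p)); r += 1
    if use_z:
        for j in range(m):  # x_j − p z_j ≤ 0
            rows += [r, r]; cols += [j, n_x + n_y + j]; vals += [1.0, -float(p)]
            b_ub.append(0.0); r += 1
        cols.extend(n_x + n_y + np.arange(m)); rows.extend([r] * m)
        vals.extend([1.0] * m)
        b_ub.append(float(instance.max_bases)); r += 1

    a_ub = coo_matrix((vals, (rows, cols)), shape=(r, n_var))
    constraint = LinearConstraint(a_ub, -np.inf, np.array(b_ub))
    res = milp(c=c, constraints=[constraint], integrality=integrality,
               bounds=Bounds(lb, ub), options={"mip_rel_gap": 0.0})
    if not res.success or res.status != 0:
        raise SolverError(f"MILP solve failed: status={res.status} ({res.message})")
    x = np.round(res.x[:n_x]).astype(int)
    objective = float(-res.fun)
    return Allocation(x=x, objective=objective,
                      coverage_fraction=evaluate_allocation(x, instance))


def solve_mclp(instance: CoverageInstance, forced_open: tuple = ()) -> Allocation:
    """Single-coverage (MCLP) solve; the instance must have q = 0."""
    if instance.q != 0:
        raise ValueError("solve_mclp requires a busy fraction of 0")
    return solve_exact(instance, forced_open=forced_open)


def brute_force_optimum(instance: CoverageInstance) -> Allocation:
    """Exhaustive-enumeration oracle over all ambulance multisets.

    Enumerates every placement of up to p ambulances over the candidate
    bases that respects the base cap, evaluates each with
    :func:`evaluate_allocation`, and returns the best; ties go to the
    lexicographically smallest x vector.  Guarded to ≤ 8 bases and p ≤ 5.
    """
    m, p = instance.n_bases, instance.p
    if m > 8 or p > 5:
        raise ValueError(f"instance too large for enumeration (|J|={m}, p={p}); "
                         "limits are 8 bases, p=5")
    best_x, best_obj = np.zeros(m, dtype=int), 0.0
    for size in range(p + 1):
        for combo in itertools.combinations_with_replacement(range(m), size):
            x = np.bincount(combo, minlength=m)
            if instance.max_bases is not None and (x > 0).sum() > instance.max_bases:
                continue
            frac = evaluate_allocation(x, instance)
            obj = frac * instance.total_weight
            if obj > best_obj + 1e-12 or (
                    abs(obj - best_obj) <= 1e-12 and tuple(x) < tuple(best_x)):
                best_x, best_obj = x, obj
    return Allocation(x=best_x, objective=best_obj,
                      coverage_fraction=best_obj / instance.total_weight)
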