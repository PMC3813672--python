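"""Equilibrium-shift model for soil potassium form transformation.

Soil potassium cycles between three pools, wsK <-> eK <-> neK.  For a
target pool (neK or eK) the shift of that equilibrium in a given sample
is scored by two *route values*: linear contribution-coefficient
functions of the sample's standardized soil characteristics,

    V_route = sum_j w_j . Z_j ,

one per transformation route feeding the target (wsK->neK and eK->neK
for the neK equilibrium; wsK->eK and neK->eK for the eK equilibrium).
The sample is at equilibrium when its standardized target-pool content
Z_target lies within a tolerance of the equilibrium threshold y, taken
as the dominant (largest-magnitude) route value.  The movement of the
balance is classified into a two-symbol direction label drawn from
{alpha, beta, gamma, chi} (neK block) and {epsilon, theta, lambda,
omega} (eK block).

The packaged default configuration is a calibration fixture: route
weights recovered by least squares from the published per-sample route
values (they reproduce all 64 published V/Z entries to +-0.01), and a
nearest-row decision table holding the published (V1, V2, Z) -> label
assignments.  No analytic form of the direction rule is claimed; the
decision table is deterministic and total (every triple maps to the
label of its nearest calibration row, earliest row winning ties).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .correlation import ZMatrix
from .datamodel import load_fixture
from .pathmodel import PathResult

__all__ = [
    "RouteCoefficients",
    "DecisionTable",
    "EquilibriumResult",
    "compute_route_value",
    "check_equilibrium",
    "classify_direction",
    "run_equilibrium_analysis",
    "default_config",
]

ROUTES = ("wsK->neK", "eK->neK", "wsK->eK", "neK->eK")

#: transformation-route source variables used when weights are built
#: from a fitted path model
ROUTE_SOURCES = {
    "wsK->neK": ["wsK", "PHA"],
    "eK->neK": ["eK", "PHA"],
    "wsK->eK": ["wsK", "PHA"],
    "neK->eK": ["neK", "PHA"],
}


@dataclass(frozen=True)
class RouteCoefficients:
    """Weights of one route's linear contribution-coefficient function."""

    route: str
    weights: dict[str, float]

    def __post_init__(self):
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}; valid: {ROUTES}")

    @classmethod
    def from_path_result(cls, route: str, result: PathResult, *, warn=warnings.warn):
        """Weights from a path model: total path-contribution coefficient of
        each of the route's source variables; sources the model did not
        retain get zero weight with a warning."""
        weights = {}
        for var in ROUTE_SOURCES[route]:
            if var in result.total:
                weights[var] = result.total[var]
            else:
                warn(f"route {route}: source variable {var!r} not retained; weight 0")
                weights[var] = 0.0
        return cls(route=route, weights=weights)


def compute_route_value(z_row: Mapping[str, float], coeffs: RouteCoefficients) -> float:
    """V = sum_j w_j * z_j for one sample's standardized row."""
    missing = [v for v in coeffs.weights if v not in z_row]
    if missing:
        raise KeyError(f"route {coeffs.route}: variables missing from Z row: {missing}")
    return float(sum(w * z_row[v] for v, w in coeffs.weights.items()))


def check_equilibrium(
    route_values: Sequence[float], z_target: float, tolerance: float = 0.05
) -> tuple[bool, float]:
    """Equilibrium test against the dominant route value.

    The threshold y is the route value of larger magnitude (first one on
    a tie); the sample is at equilibrium when |z_target - y| <= tolerance.
    Returns ``(at_equilibrium, y)``.
    """
    v1, v2 = route_values
    y = v1 if abs(v1) >= abs(v2) else v2
    return bool(abs(z_target - y) <= tolerance), float(y)


@dataclass
class DecisionTable:
    """Calibrated nearest-row direction classifier.

    ``rows`` hold reference triples with their two-symbol labels; a query
    triple is assigned the label of the nearest row (Euclidean distance,
    earliest row wins ties), which makes the rule total and
    deterministic.  A single-row table is a constant rule.
    """

    rows: list[tuple[float, float, float, tuple[str, str]]]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("decision table needs at least one row")
        for r in self.rows:
            if len(r[3]) != 2:
                raise ValueError(f"direction label must have exactly 2 symbols, got {r[3]!r}")

    def classify(self, v1: float, v2: float, z: float) -> tuple[str, str]:
        pts = np.array([[r[0], r[1], r[2]] for r in self.rows])
        d = np.sum((pts - np.array([v1, v2, z])) ** 2, axis=1)
        return self.rows[int(np.argmin(d))][3]

    @classmethod
    def from_config(cls, entries: list[dict]) -> "DecisionTable":
        return cls(
            rows=[(e["v1"], e["v2"], e["z"], tuple(e["symbols"])) for e in entries]
        )


def classify_direction(
    route_values: Sequence[float], z_target: float, rule: DecisionTable
) -> tuple[str, str]:
    """Two-symbol direction label for a (V1, V2, Z_target) triple."""
    v1, v2 = route_values
    return rule.classify(v1, v2, z_target)


@dataclass
class EquilibriumResult:
    """Per-sample equilibrium assessment for one target potassium form."""

    sample: str
    target: str
    route_values: dict[str, float]
    z_target: float
    threshold: float
    at_equilibrium: bool
    direction: tuple[str, str]

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["direction"] = list(self.direction)
        return json.dumps(d, ensure_ascii=False)

    @classmethod
    def from_json(cls, text: str) -> "EquilibriumResult":
        d = json.loads(text)
        d["direction"] = tuple(d["direction"])
        return cls(**d)


def default_config() -> dict:
    """The packaged calibrated configuration (routes, decision tables,
    tolerance, sample-group labels)."""
    return load_fixture("equilibrium_config")


def _routes_from_config(config: dict) -> dict[str, RouteCoefficients]:
    return {
        route: RouteCoefficients(route=route, weights=dict(w))
        for route, w in config["routes"].items()
    }


def run_equilibrium_analysis(
    z: ZMatrix,
    config: dict | None = None,
    path_results: Mapping[str, PathResult] | None = None,
    tolerance: float | None = None,
) -> list[EquilibriumResult]:
    """Score every sample's equilibrium state for both target forms.

    Route weights come from ``config`` (default: the packaged
    calibration); if ``path_results`` is given instead, weights are
    built from the fitted path-contribution coefficients of each
    target's model.  Emits one :class:`EquilibriumResult` per sample and
    target form.
    """
    config = config or default_config()
    tol = tolerance if tolerance is not None else config.get("tolerance", 0.05)
    if path_results is not None:
        routes = {}
        for target, spec in config["targets"].items():
            if target not in path_results:
                raise KeyError(f"path result for target {target!r} required")
            for route in spec["routes"]:
                routes[route] = RouteCoefficients.from_path_result(route, path_results[target])
    else:
        routes = _routes_from_config(config)
    tables = {
        name: DecisionTable.from_config(entries)
        for name, entries in config["decision_tables"].items()
    }
    labels = config.get("group_labels", {})
    results = []
    for group in z.index:
        row = z.row(group)
        sample = labels.get(group, group)
        for target, spec in config["targets"].items():
            vals = {r: compute_route_value(row, routes[r]) for r in spec["routes"]}
            pair = [vals[r] for r in spec["routes"]]
            z_t = row[target]
            at_eq, y = check_equilibrium(pair, z_t, tol)
            direction = classify_direction(pair, z_t, tables[spec["table"]])
            results.append(
                EquilibriumResult(
                    sample=sample,
                    target=target,
                    route_values=vals,
                    z_target=float(z_t),
                    threshold=y,
                    at_equilibrium=at_eq,
                    direction=direction,
                )
            )
    return results


def equilibrium_report(results: list[EquilibriumResult]) -> pd.DataFrame:
    """Wide per-sample report mirroring the published table layout:
    neK block (V_wsk->neK, V_ek->neK, ZneK, direction) then eK block."""
    by_sample: dict[str, dict] = {}
    for res in results:
        row = by_sample.setdefault(res.sample, {"sample": res.sample})
        if res.target == "neK":
            row["V_wsk_nek"] = res.route_values["wsK->neK"]
            row["V_ek_nek"] = res.route_values["eK->neK"]
            row["Z_nek"] = res.z_target
            row["direction_nek"] = ",".join(res.direction)
            row["at_equilibrium_nek"] = res.at_equilibrium
        else:
            row["V_wsk_ek"] = res.route_values["wsK->eK"]
            row["V_nek_ek"] = res.route_values["neK->eK"]
            row["Z_ek"] = res.z_target
            row["direction_ek"] = ",".join(res.direction)
            row["at_equilibrium_ek"] = res.at_equilibrium
    cols = [
        "V_wsk_nek", "V_ek_nek", "Z_nek", "direction_nek", "at_equilibrium_nek",
        "V_wsk_ek", "V_nek_ek", "Z_ek", "direction_ek", "at_equilibrium_ek",
    ]
    df = pd.DataFrame(list(by_sample.values())).set_index("sample")
    return df[[c for c in cols if c in df.columns]]
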