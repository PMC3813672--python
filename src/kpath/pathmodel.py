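"""Standardized regression path models: direct, indirect and residual effects.

A Wright-style path model on standardized data.  The direct path
coefficient of predictor j on response i is the standardized partial
regression coefficient P_ij, obtained from the normal equations

    R_xx . P = r_xy

where R_xx is the predictor correlation matrix and r_xy the vector of
simple predictor-response correlations.  Each simple correlation
decomposes into the direct path plus indirect paths transmitted through
the other predictors,

    r_ij = P_ij + sum_{k != j} r_jk . P_ik,

an exact identity of least squares when every predictor is retained.
The unexplained part of the response enters the diagram as the
uncorrelated residue e = sqrt(1 - R^2).

Backward elimination repeatedly drops the predictor with the largest
coefficient p-value (t test, df = n - p - 1) while it exceeds
``alpha_remove``; ties break toward the larger p-value, then the
lexicographically larger label, so the procedure is deterministic.

With only 16 sample groups and 8 predictors the full fit has 7 residual
degrees of freedom: feasible but fragile, so fits warn below 10 df and
refuse below 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import ZMatrix, pearson_matrix
from .datamodel import analysis_frame, load_fixture

__all__ = [
    "PathResult",
    "CollinearityError",
    "fit_standardized",
    "backward_eliminate",
    "decompose",
    "run_study_models",
    "export_path_diagram",
    "STUDY_PREDICTORS",
]

COND_BOUND = 1e8
DF_WARN = 10


class CollinearityError(ValueError):
    """Predictor correlation matrix is singular or nearly so."""


#: published predictor sets for the three response models (the second
#: listing of SOM in the neK set is a duplicate in the source and is
#: dropped)
STUDY_PREDICTORS = {
    "wsK": ["neK", "PHA", "S", "Na/K", "CIA", "Na", "SOM", "eK"],
    "neK": ["wsK", "SOM", "S", "Na/K", "TN", "Na", "eK"],
    "eK": ["neK", "SOM", "Na/K", "Na", "HMi", "TN", "wsK", "S"],
}


@dataclass
class PathResult:
    """Full decomposition of one response model."""

    response: str
    predictors: list[str]
    direct: dict[str, float]
    indirect: dict[str, dict[str, float]]
    indirect_total: dict[str, float]
    total: dict[str, float]
    simple_r: dict[str, float]
    r2: float
    residue: float
    eliminated: list[tuple[str, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "predictor": p,
                "simple_r": self.simple_r[p],
                "direct": self.direct[p],
                "indirect_total": self.indirect_total[p],
                "total": self.total[p],
            }
            for p in self.predictors
        ]
        df = pd.DataFrame(rows)
        return df.set_index("predictor") if rows else df

    def to_json(self) -> str:
        d = {
            "response": self.response,
            "predictors": self.predictors,
            "direct": self.direct,
            "indirect": self.indirect,
            "indirect_total": self.indirect_total,
            "total": self.total,
            "simple_r": self.simple_r,
            "r2": self.r2,
            "residue": self.residue,
            "eliminated": self.eliminated,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "PathResult":
        d = json.loads(text)
        d["eliminated"] = [tuple(t) for t in d["eliminated"]]
        return cls(**d)


def _check_fit_preconditions(z: ZMatrix, response: str, predictors: list[str]) -> None:
    if response in predictors:
        raise ValueError("response cannot be one of the predictors")
    unknown = [c for c in [response, *predictors] if c not in z.columns]
    if unknown:
        raise KeyError(f"columns not in Z matrix: {unknown}")
    df_resid = z.n - len(predictors) - 1
    if df_resid < 1:
        raise ValueError(
            f"{z.n} samples cannot support {len(predictors)} predictors (df = {df_resid})"
        )
    if df_resid < DF_WARN:
        warnings.warn(
            f"fit of {response!r} has only {df_resid} residual degrees of freedom",
            stacklevel=3,
        )


def fit_standardized(z: ZMatrix, response: str, predictors: list[str]):
    """Standardized partial regression coefficients via normal equations.

    Returns ``(direct, r2, pvalues)``: the path coefficients P (dict by
    predictor), the coefficient of determination r_xy . P, and per-
    coefficient two-tailed p-values (t test, df = n - p - 1).
    """
    predictors = list(predictors)
    _check_fit_preconditions(z, response, predictors)
    X = z.subset(predictors)
    y = z.column(response)
    n, p = X.shape
    Rxx = np.corrcoef(X, rowvar=False) if p > 1 else np.ones((1, 1))
    rxy = np.array([np.corrcoef(X[:, j], y)[0, 1] for j in range(p)])
    cond = np.linalg.cond(Rxx)
    if cond > COND_BOUND:
        off = np.abs(Rxx - np.eye(p))
        j, k = np.unravel_index(np.argmax(off), off.shape)
        raise CollinearityError(
            f"predictor correlation matrix ill-conditioned (cond={cond:.3g}); "
            f"worst pair: {predictors[j]!r}, {predictors[k]!r} (r={Rxx[j, k]:.4f})"
        )
    P = np.linalg.solve(Rxx, rxy)
    r2 = float(rxy @ P)
    df_resid = n - p - 1
    Rinv = np.linalg.inv(Rxx)
    sigma2 = max(1.0 - r2, 0.0) / df_resid
    se = np.sqrt(sigma2 * np.diag(Rinv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, P / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=df_resid)
    return (
        dict(zip(predictors, map(float, P))),
        r2,
        dict(zip(predictors, map(float, pvals))),
    )


def backward_eliminate(
    z: ZMatrix, response: str, predictors: list[str], alpha_remove: float = 0.05
):
    """Backward elimination on coefficient p-values.

    Returns ``(retained, trace)`` where ``trace`` lists
    ``(predictor, p_at_removal)`` in removal order.  If everything is
    eliminated the retained list is empty (the path model then consists
    of the residue alone, e = 1).
    """
    retained = list(predictors)
    trace: list[tuple[str, float]] = []
    while retained:
        _, _, pvals = fit_standardized(z, response, retained)
        # ties: larger p first, then lexicographically larger label
        worst = max(retained, key=lambda v: (pvals[v], v))
        if pvals[worst] > alpha_remove:
            retained.remove(worst)
            trace.append((worst, float(pvals[worst])))
        else:
            break
    if not retained:
        warnings.warn(
            f"all predictors of {response!r} eliminated at alpha={alpha_remove}", stacklevel=2
        )
    return retained, trace


def decompose(
    z: ZMatrix,
    response: str,
    retained: list[str],
    direct: dict[str, float] | None = None,
    eliminated: list[tuple[str, float]] | None = None,
) -> PathResult:
    """Split each simple correlation into direct and indirect effects.

    ``direct`` may carry coefficients already fitted on ``retained``;
    otherwise they are fitted here.  The indirect effect of predictor j
    through predictor k is r_jk * P_ik; the total effect is the direct
    path plus the summed indirect terms and, with no elimination, equals
    the simple correlation exactly.
    """
    retained = list(retained)
    if not retained:
        return PathResult(
            response=response,
            predictors=[],
            direct={},
            indirect={},
            indirect_total={},
            total={},
            simple_r={},
            r2=0.0,
            residue=1.0,
            eliminated=list(eliminated or []),
        )
    if direct is None:
        direct, r2, _ = fit_standardized(z, response, retained)
    else:
        missing = set(retained) - set(direct)
        if missing:
            raise ValueError(f"direct coefficients missing for {sorted(missing)}")
        rxy = np.array([np.corrcoef(z.column(p), z.column(response))[0, 1] for p in retained])
        r2 = float(rxy @ np.array([direct[p] for p in retained]))
    X = z.subset(retained)
    Rxx = np.corrcoef(X, rowvar=False) if len(retained) > 1 else np.ones((1, 1))
    y = z.column(response)
    simple = {p: float(np.corrcoef(z.column(p), y)[0, 1]) for p in retained}
    indirect: dict[str, dict[str, float]] = {}
    for j, pj in enumerate(retained):
        indirect[pj] = {
            pk: float(Rxx[j, k] * direct[pk]) for k, pk in enumerate(retained) if k != j
        }
    indirect_total = {p: float(sum(indirect[p].values())) for p in retained}
    total = {p: float(direct[p] + indirect_total[p]) for p in retained}
    return PathResult(
        response=response,
        predictors=retained,
        direct={p: float(direct[p]) for p in retained},
        indirect=indirect,
        indirect_total=indirect_total,
        total=total,
        simple_r=simple,
        r2=r2,
        residue=float(np.sqrt(max(1.0 - r2, 0.0))),
        eliminated=list(eliminated or []),
    )


def fit_path_model(
    z: ZMatrix,
    response: str,
    predictors: list[str],
    alpha_remove: float | None = None,
) -> PathResult:
    """Convenience wrapper: optional backward elimination, then decomposition."""
    if alpha_remove is None:
        retained, trace = list(predictors), []
    else:
        retained, trace = backward_eliminate(z, response, predictors, alpha_remove)
    return decompose(z, response, retained, eliminated=trace)


def run_study_models(
    z: ZMatrix | None = None, *, alpha_remove: float | None = None
) -> dict[str, PathResult]:
    """Fit the three published response models (wsK, neK, eK).

    By default the full published predictor sets are retained (no
    elimination), which makes the total-effect column reproduce the
    simple correlations exactly; pass ``alpha_remove`` to switch
    backward elimination on.
    """
    if z is None:
        frame = analysis_frame()
        cols = sorted({v for preds in STUDY_PREDICTORS.values() for v in preds} | set(STUDY_PREDICTORS))
        from .correlation import zscore

        z = zscore(frame, cols)
    return {
        resp: fit_path_model(z, resp, preds, alpha_remove=alpha_remove)
        for resp, preds in STUDY_PREDICTORS.items()
    }


_PATH_FIXTURES = {"wsK": "path_wsK", "neK": "path_neK", "eK": "path_eK"}


def compare_with_published(result: PathResult, z: ZMatrix) -> pd.DataFrame:
    """Per-cell report against the published coefficient table.

    The published tables list three columns whose semantics are
    internally inconsistent (the "direct" column demonstrably equals the
    simple correlations), so all three candidate quantities are emitted
    for every listed variable: the recomputed simple correlation and,
    where the variable is a retained predictor, the direct path and
    summed indirect effects.
    """
    ref = load_fixture(_PATH_FIXTURES[result.response])
    y = z.column(result.response)
    rows = []
    for rec in ref.itertuples():
        var = rec.variable
        row = {
            "variable": var,
            "printed_simple_r": rec.simple_r,
            "printed_indirect": rec.indirect,
            "printed_path": rec.path,
        }
        if var in z.columns:
            row["computed_simple_r"] = float(np.corrcoef(z.column(var), y)[0, 1])
            row["simple_r_dev"] = round(row["computed_simple_r"] - rec.simple_r, 3)
        if var in result.predictors:
            row["computed_direct"] = result.direct[var]
            row["computed_indirect_total"] = result.indirect_total[var]
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def export_path_diagram(
    result: PathResult,
    path: str | Path,
    z: ZMatrix | None = None,
    display_threshold: float = 0.5,
) -> str:
    """Write the path diagram as a Graphviz DOT file.

    Dashed single-headed edges run from each predictor to the response,
    weighted by the direct path coefficient; solid double-headed
    (``dir=both``) edges connect predictor pairs whose correlation
    magnitude reaches the display threshold; the residue node ``e``
    attaches to the response with weight sqrt(1 - R^2).  Returns the DOT
    text.
    """
    q = lambda s: '"%s"' % str(s).replace('"', r"\"")
    lines = ["digraph path_model {", "  rankdir=LR;"]
    lines.append(f"  {q(result.response)} [shape=box];")
    lines.append('  e [shape=circle];')
    for p in result.predictors:
        lines.append(f"  {q(p)} [shape=ellipse];")
        lines.append(
            f"  {q(p)} -> {q(result.response)} "
            f'[style=dashed, label="{result.direct[p]:+.2f}"];'
        )
    if z is not None and len(result.predictors) > 1:
        corr = pearson_matrix(z.to_frame()[result.predictors], display_threshold)
        for i, a in enumerate(result.predictors):
            for b in result.predictors[i + 1 :]:
                r_ab = corr.r.loc[a, b]
                if abs(r_ab) >= display_threshold:
                    lines.append(
                        f"  {q(a)} -> {q(b)} "
                        f'[dir=both, style=solid, label="{r_ab:+.2f}"];'
                    )
    lines.append(f'  e -> {q(result.response)} [label="{result.residue:.2f}"];')
    lines.append("}")
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text
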