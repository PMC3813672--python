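"""Synthetic soil-property tables with known statistical structure.

The analysis pipeline assumes a multivariate Gaussian covariate block
with a target correlation matrix and, optionally, linear structural
responses

    y = sum_j beta_j x_j + eps,   sd(eps) = sqrt(1 - beta' R_xx beta),

so each response has unit variance when the coefficients are
standardized.  A Gaussian copula is the minimal distributional
assumption compatible with Pearson-correlation screening; nothing
beyond second moments is emulated (no spatial fields, no non-Gaussian
marginals, no time dynamics).

Published correlation surfaces are sparse (cells below the display
threshold are blank), so target matrices are completed with zeros
(the least-informative value below the 0.5 threshold) and repaired to
positive definiteness by eigenvalue clipping before sampling.  Every
generated table ships with a truth record (coefficients, seed, repaired
matrix) so downstream tests never re-derive ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import analysis_frame, load_fixture

__all__ = ["SyntheticSpec", "nearest_pd_repair", "generate", "emulate_study", "study_target_matrix"]

MIN_EIGENVALUE = 1e-8


class InfeasibleSpecError(ValueError):
    """Structural coefficients imply negative response noise variance."""


def nearest_pd_repair(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Repair a symmetric unit-diagonal matrix to positive definiteness.

    Eigenvalues are clipped at 1e-8 and the result re-normalized to a
    unit diagonal.  Returns ``(repaired, clipped_mass)`` where the
    clipped mass is the total eigenvalue deficit that was removed; an
    already-PD matrix is returned unchanged (clipped mass 0).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-10):
        raise ValueError("matrix must have a unit diagonal")
    if np.any(np.abs(m) > 1.0 + 1e-12):
        raise ValueError("correlation entries must lie in [-1, 1]")
    vals, vecs = np.linalg.eigh(m)
    clipped_mass = float(np.sum(np.clip(MIN_EIGENVALUE - vals, 0.0, None)))
    if clipped_mass == 0.0:
        return m, 0.0
    vals = np.clip(vals, MIN_EIGENVALUE, None)
    r = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2.0, clipped_mass


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic table.

    ``structural`` maps a response label to a coefficient map; the
    response is overwritten by the structural equation with noise scaled
    to keep it at unit variance.  ``back_transform`` maps variable ->
    (mean, sd) to emit raw-scale values.
    """

    n: int
    variables: list[str]
    target_corr: np.ndarray
    structural: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0
    back_transform: dict[str, tuple[float, float]] = field(default_factory=dict)


def generate(spec: SyntheticSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a synthetic table; returns ``(table, truth_record)``.

    Identical spec + seed gives a bit-identical table.  The truth record
    stores the seed, repaired correlation matrix, structural
    coefficients and realized noise standard deviations.
    """
    p = len(spec.variables)
    target = np.asarray(spec.target_corr, dtype=float)
    if target.shape != (p, p):
        raise ValueError(f"target_corr must be {p}x{p}")
    repaired, clipped = nearest_pd_repair(target)
    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(repaired)
    X = rng.standard_normal((spec.n, p)) @ chol.T
    df = pd.DataFrame(X, columns=spec.variables)
    truth = {
        "seed": spec.seed,
        "n": spec.n,
        "variables": list(spec.variables),
        "repaired_corr": repaired.tolist(),
        "clipped_mass": clipped,
        "structural": {},
    }
    for resp, coeffs in spec.structural.items():
        preds = list(coeffs)
        missing = [v for v in preds if v not in spec.variables]
        if missing:
            raise KeyError(f"structural predictors not among variables: {missing}")
        beta = np.array([coeffs[v] for v in preds])
        idx = [spec.variables.index(v) for v in preds]
        Rxx = repaired[np.ix_(idx, idx)]
        explained = float(beta @ Rxx @ beta)
        if explained >= 1.0:
            raise InfeasibleSpecError(
                f"response {resp!r}: beta' R beta = {explained:.4f} >= 1 "
                "(noise variance would be negative)"
            )
        noise_sd = float(np.sqrt(1.0 - explained))
        df[resp] = df[preds].to_numpy() @ beta + noise_sd * rng.standard_normal(spec.n)
        truth["structural"][resp] = {
            "coefficients": dict(coeffs),
            "noise_sd": noise_sd,
            "explained_variance": explained,
        }
    for var, (mean, sd) in spec.back_transform.items():
        if var in df.columns:
            df[var] = mean + sd * df[var]
    return df, truth


def study_target_matrix(variables: list[str] | None = None) -> tuple[list[str], np.ndarray]:
    """Target correlation matrix completed from the published surface.

    Blank cells (below the 0.5 display threshold) become 0; the matrix
    is returned un-repaired (callers pass it through
    :func:`nearest_pd_repair`, which :func:`generate` does anyway).
    """
    ref = load_fixture("correlations")
    if variables is None:
        variables = sorted(set(ref.var_a) | set(ref.var_b))
    target = np.eye(len(variables))
    pos = {v: i for i, v in enumerate(variables)}
    for rec in ref.itertuples():
        if rec.var_a in pos and rec.var_b in pos:
            i, j = pos[rec.var_a], pos[rec.var_b]
            target[i, j] = target[j, i] = np.clip(rec.r, -1.0, 1.0)
    return list(variables), target


def emulate_study(seed: int, n: int = 16) -> tuple[pd.DataFrame, dict]:
    """Synthetic table statistically resembling the study's data.

    Samples ``n`` groups over the published correlation variable set
    (zero-filled, PD-repaired matrix) and back-transforms each variable
    to the mean/sd of the packaged measurement tables, so the result is
    accepted by every downstream stage.
    """
    variables, target = study_target_matrix()
    obs = analysis_frame()
    back = {
        v: (float(obs[v].mean()), float(obs[v].std(ddof=1)))
        for v in variables
        if v in obs.columns
    }
    spec = SyntheticSpec(
        n=n, variables=variables, target_corr=target, seed=seed, back_transform=back
    )
    df, truth = generate(spec)
    df.insert(0, "group", [f"SYN{i + 1}" for i in range(n)])
    return df, truth


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1))
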