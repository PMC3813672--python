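"""Z-score normalization and the significance-flagged Pearson correlation matrix.

The pipeline standardizes every analysis variable to the Z scale
(sample standard deviation, n-1 denominator) and screens pairwise
Pearson correlations.  Published convention quirks honoured here:

* significance letters follow the published caption literally
  (``a``: p < 0.01, ``b``: p < 0.05) even though the letters are, in
  fact, attached the other way round in the printed matrix; the
  alpha -> letter map is therefore configurable,
* entries with |r| below a display threshold (default 0.5, the smallest
  magnitude the published matrix prints) are masked in reports but kept
  in the full matrix,
* correlations are pairwise-complete: each pair uses every row where
  both variables are present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MIN_STAT_N, ValidationError

__all__ = ["ZMatrix", "CorrelationResult", "zscore", "pearson_matrix", "select_parameters"]

#: caption-literal letter map: letter applies when p < alpha
DEFAULT_ALPHA_FLAGS = (("a", 0.01), ("b", 0.05))


class ZeroVarianceError(ValueError):
    """A selected column is constant and cannot be standardized."""


@dataclass
class ZMatrix:
    """Column-standardized data matrix with retained column identities."""

    columns: list[str]
    values: np.ndarray  # n x p, mean 0 / sd 1 per column
    means: np.ndarray
    sds: np.ndarray
    index: list[str]  # sample-group labels, row order preserved

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.columns.index(label)]

    def row(self, group: str) -> dict[str, float]:
        i = self.index.index(group)
        return dict(zip(self.columns, self.values[i]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns, index=self.index)

    def subset(self, labels: list[str]) -> np.ndarray:
        return self.values[:, [self.columns.index(c) for c in labels]]


def zscore(frame: pd.DataFrame, variables: list[str] | None = None, *, dropna: bool = False) -> ZMatrix:
    """Standardize selected columns to mean 0, sample sd 1.

    Raises :class:`ZeroVarianceError` naming any constant column and
    refuses tables with fewer than three rows.  Missing values abort
    unless ``dropna=True`` drops incomplete rows first.
    """
    variables = list(variables) if variables is not None else list(frame.columns)
    missing = [v for v in variables if v not in frame.columns]
    if missing:
        raise KeyError(f"variables not in frame: {missing}")
    sub = frame[variables]
    if sub.isna().any().any():
        if not dropna:
            bad = sorted(sub.columns[sub.isna().any()])
            raise ValidationError(
                f"missing values in columns {bad}; pass dropna=True to drop incomplete rows"
            )
        sub = sub.dropna()
    if len(sub) < MIN_STAT_N:
        raise ValidationError(f"need at least {MIN_STAT_N} rows, got {len(sub)}")
    vals = sub.to_numpy(dtype=float)
    means = vals.mean(axis=0)
    sds = vals.std(axis=0, ddof=1)
    zero = [v for v, s in zip(variables, sds) if s == 0]
    if zero:
        raise ZeroVarianceError(f"zero-variance column(s): {zero}")
    return ZMatrix(
        columns=variables,
        values=(vals - means) / sds,
        means=means,
        sds=sds,
        index=[str(i) for i in sub.index],
    )


@dataclass
class CorrelationResult:
    """Symmetric Pearson matrix with two-tailed p-values and letter flags."""

    variables: list[str]
    r: pd.DataFrame
    pvalues: pd.DataFrame
    flags: pd.DataFrame
    display_threshold: float = 0.5
    alpha_flags: tuple = DEFAULT_ALPHA_FLAGS

    def masked_frame(self) -> pd.DataFrame:
        """Report view: blank below the display threshold, letters appended."""
        out = pd.DataFrame("", index=self.variables, columns=self.variables)
        for i in self.variables:
            for j in self.variables:
                rij = self.r.loc[i, j]
                if i != j and abs(rij) >= self.display_threshold:
                    out.loc[i, j] = f"{rij:.2f}{self.flags.loc[i, j]}"
        return out

    def to_frame(self) -> pd.DataFrame:
        return self.r.copy()

    def to_json(self) -> str:
        return json.dumps(
            {
                "variables": self.variables,
                "r": self.r.values.tolist(),
                "pvalues": self.pvalues.values.tolist(),
                "flags": self.flags.values.tolist(),
                "display_threshold": self.display_threshold,
                "alpha_flags": [list(x) for x in self.alpha_flags],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CorrelationResult":
        d = json.loads(text)
        v = d["variables"]
        return cls(
            variables=v,
            r=pd.DataFrame(d["r"], index=v, columns=v),
            pvalues=pd.DataFrame(d["pvalues"], index=v, columns=v),
            flags=pd.DataFrame(d["flags"], index=v, columns=v),
            display_threshold=d["display_threshold"],
            alpha_flags=tuple(tuple(x) for x in d["alpha_flags"]),
        )


def _flag(p: float, alpha_flags) -> str:
    for letter, alpha in sorted(alpha_flags, key=lambda t: t[1]):
        if p < alpha:
            return letter
    return ""


def corr_pvalue(r: float, n: int) -> float:
    """Two-tailed p-value of a Pearson r via the t statistic, df = n - 2."""
    if n < 3 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 else np.nan
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pearson_matrix(
    data: ZMatrix | pd.DataFrame,
    display_threshold: float = 0.5,
    alpha_flags=DEFAULT_ALPHA_FLAGS,
) -> CorrelationResult:
    """Pairwise-complete Pearson correlation matrix with significance flags.

    Accepts a :class:`ZMatrix` or a raw DataFrame (Pearson r is invariant
    under standardization, so both give identical matrices).
    """
    df = data.to_frame() if isinstance(data, ZMatrix) else data
    if len(df) < MIN_STAT_N:
        raise ValidationError(f"need at least {MIN_STAT_N} rows, got {len(df)}")
    variables = list(df.columns)
    r = df.corr(method="pearson", min_periods=MIN_STAT_N)
    notna = df.notna().to_numpy()
    counts = notna.T.astype(int) @ notna.astype(int)
    p = pd.DataFrame(np.nan, index=variables, columns=variables)
    flags = pd.DataFrame("", index=variables, columns=variables)
    for i, a in enumerate(variables):
        p.loc[a, a] = 0.0
        for j in range(i + 1, len(variables)):
            b = variables[j]
            pv = corr_pvalue(r.loc[a, b], int(counts[i, j]))
            p.loc[a, b] = p.loc[b, a] = pv
            f = _flag(pv, alpha_flags) if np.isfinite(pv) else ""
            flags.loc[a, b] = flags.loc[b, a] = f
    np.fill_diagonal(r.values, 1.0)
    return CorrelationResult(
        variables=variables,
        r=r,
        pvalues=p,
        flags=flags,
        display_threshold=display_threshold,
        alpha_flags=tuple(alpha_flags),
    )


def select_parameters(
    corr: CorrelationResult, response: str, k: int = 8, *, warn=None
) -> list[str]:
    """The ``k`` variables most strongly correlated with ``response``.

    Only variables carrying a significance flag against the response are
    eligible; ranking is by |r| descending with lexicographic label
    tie-break.  If fewer than ``k`` qualify, all qualifying variables
    are returned and a warning is emitted.
    """
    if response not in corr.variables:
        raise KeyError(f"response {response!r} not among correlation variables")
    if k <= 0:
        return []
    eligible = [
        v
        for v in corr.variables
        if v != response and corr.flags.loc[response, v] != ""
    ]
    eligible.sort(key=lambda v: (-abs(corr.r.loc[response, v]), v))
    if len(eligible) < k:
        msg = f"only {len(eligible)} significant partners for {response!r}, requested {k}"
        if warn is not None:
            warn(msg)
        else:
            import warnings

            warnings.warn(msg, stacklevel=2)
        return eligible
    return eligible[:k]


def compare_with_reference(corr: CorrelationResult, reference: pd.DataFrame) -> pd.DataFrame:
    """Deviation report against a printed long-form correlation table.

    ``reference`` has columns ``var_a, var_b, r`` (and optionally
    ``flag``).  Rows whose variables are absent from the computed matrix
    are skipped.  Nothing is hidden: every comparable printed cell gets
    a row with the recomputed value and the deviation.
    """
    rows = []
    for rec in reference.itertuples():
        a, b = rec.var_a, rec.var_b
        if a in corr.variables and b in corr.variables:
            computed = corr.r.loc[a, b]
            rows.append(
                {
                    "var_a": a,
                    "var_b": b,
                    "printed": rec.r,
                    "computed": round(float(computed), 3),
                    "deviation": round(float(computed) - rec.r, 3),
                }
            )
    return pd.DataFrame(rows)
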