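"""Domain types and tabular I/O for soil potassium status analysis.

The analysis unit is a *sample group*: one averaged row of soil-property
measurements (16 groups, each pooling 16 individual pots, covering
rhizosphere/non-rhizosphere soil of two cotton genotypes under four
fertilization treatments).  Measured blocks:

* elemental totals (Na, Mg, Al, Si, Fe, Ca, CO3 in mass %; P, S, Cl in ppm)
* potassium forms: total K (g/kg), water-soluble wsK, exchangeable eK and
  non-exchangeable neK (all ug/g), plus weathered counterparts
* organic matter: TC, TN, SOM, humic fractions PHA/NHA, humus bound to
  iron (HMi) and clay (HMc), all %
* physicochemistry: ORP (eV as printed), pH, and the weathering indices
  ba, Na/K, ICA, saf, CIA
* silicate-dissolving bacteria counts (x10^4 CFU/g) at three growth stages

Units are stored exactly as measured; no conversion happens at I/O time.
The elemental table carries two columns both headed "Mg%"; they are kept
as ``Mg_a`` (~0.39) and ``Mg_b`` (~1.49).  ``Mg_a`` is the one that
reproduces the published ba index and is exposed as the analysis
variable ``Mg``; the identity of ``Mg_b`` is unknown and it is carried
as data only.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

try:  # py>=3.9
    from importlib import resources
except ImportError:  # pragma: no cover
    import importlib_resources as resources  # type: ignore

__all__ = [
    "Genotype",
    "Treatment",
    "SampleRecord",
    "SampleTable",
    "SchemaError",
    "ValidationError",
    "read_sample_table",
    "write_results",
    "load_fixture",
    "analysis_frame",
    "FIXTURE_NAMES",
]


class SchemaError(ValueError):
    """Input table does not conform to the declared schema."""


class ValidationError(ValueError):
    """Input table violates a data invariant."""


class Genotype(enum.Enum):
    HEG = "HEG"  # high K-efficiency genotype
    LEG = "LEG"  # low K-efficiency genotype
    UNKNOWN = "unknown"


class Treatment(enum.Enum):
    OPT = "OPT"  # optimum fertilization
    SW = "SW"  # water limited
    SK = "SK"  # potassium limited
    SWK = "SWK"  # water and potassium limited
    UNKNOWN = "unknown"


# canonical variable labels and the column blocks they belong to
ELEMENT_COLS = ["Na", "Mg_a", "Al", "Si", "Fe", "Mg_b", "Ca", "P", "CO3", "S", "Cl"]
KFORM_COLS = ["K", "wsK", "neK", "eK", "wsK_weathered", "neK_weathered", "eK_weathered"]
ORGANIC_COLS = ["TC", "TN", "SOM", "PHA", "NHA", "HMi", "HMc"]
PHYSCHEM_COLS = ["ORP", "pH"]
INDEX_COLS = ["ba", "Na/K", "ICA", "saf", "CIA"]
BACTERIA_COLS = ["bacteria_seedling", "bacteria_budding", "bacteria_wadding"]

KNOWN_COLS = (
    ELEMENT_COLS + KFORM_COLS + ORGANIC_COLS + PHYSCHEM_COLS + INDEX_COLS + BACTERIA_COLS
)

_GROUP_ALIASES = {"group", "groupid", "sample", "samplegroup", "id"}


def _norm_header(name: str) -> str:
    """Case-insensitive, punctuation-tolerant header key ('Na/K' == 'na_k')."""
    return re.sub(r"[\s_/%\.\-\(\)]+", "", str(name)).lower()


_ALIAS_TO_CANON: dict[str, str] = {}
for _c in KNOWN_COLS:
    _ALIAS_TO_CANON[_norm_header(_c)] = _c
_ALIAS_TO_CANON.update(
    {
        "nak": "Na/K",
        "mga": "Mg_a",
        "mgb": "Mg_b",
        "mg": "Mg_a",
        "co32": "CO3",
        "hmi": "HMi",
        "hmc": "HMc",
        "wskw": "wsK_weathered",
        "nekw": "neK_weathered",
        "ekw": "eK_weathered",
        "bacteria": "bacteria_budding",
        "orpev": "ORP",
    }
)


@dataclass
class SampleRecord:
    """One soil sample group with every measured property.

    Numeric blocks are plain dicts keyed by canonical variable label;
    absent measurements are simply missing keys (never zero).
    """

    group_id: str
    rhizosphere: bool
    genotype: Genotype = Genotype.UNKNOWN
    treatment: Treatment = Treatment.UNKNOWN
    elements: dict[str, float] = field(default_factory=dict)
    k_forms: dict[str, float] = field(default_factory=dict)
    organics: dict[str, float] = field(default_factory=dict)
    physicochem: dict[str, float] = field(default_factory=dict)
    indices: dict[str, float] = field(default_factory=dict)
    bacteria: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for block in (self.elements, self.k_forms, self.bacteria):
            for k, v in block.items():
                if np.isfinite(v) and v < 0:
                    raise ValidationError(
                        f"{self.group_id}: {k} = {v} but mass fractions and counts must be >= 0"
                    )
        ph = self.physicochem.get("pH")
        if ph is not None and np.isfinite(ph) and not (0.0 < ph < 14.0):
            raise ValidationError(f"{self.group_id}: pH = {ph} outside (0, 14)")

    def value(self, label: str) -> float:
        for block in (
            self.elements,
            self.k_forms,
            self.organics,
            self.physicochem,
            self.indices,
            self.bacteria,
        ):
            if label in block:
                return block[label]
        raise KeyError(label)


MIN_STAT_N = 3  # statistical operations refuse smaller tables


@dataclass
class SampleTable:
    """Ordered collection of :class:`SampleRecord` plus the raw frame."""

    records: list[SampleRecord]
    frame: pd.DataFrame
    schema_version: str = "1"
    n_unparseable: int = 0

    def __len__(self) -> int:
        return len(self.records)

    @property
    def group_ids(self) -> list[str]:
        return [r.group_id for r in self.records]

    def require_stat_n(self) -> None:
        if len(self) < MIN_STAT_N:
            raise ValidationError(
                f"statistical operations need at least {MIN_STAT_N} sample groups, got {len(self)}"
            )

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()


def _record_from_row(group_id: str, row: Mapping[str, float]) -> SampleRecord:
    def pick(cols: Iterable[str]) -> dict[str, float]:
        out = {}
        for c in cols:
            v = row.get(c)
            if v is not None and not (isinstance(v, float) and np.isnan(v)):
                out[c] = float(v)
        return out

    gid = str(group_id)
    rec = SampleRecord(
        group_id=gid,
        rhizosphere=gid.upper().startswith("R"),
        elements=pick(ELEMENT_COLS),
        k_forms=pick(KFORM_COLS),
        organics=pick(ORGANIC_COLS),
        physicochem=pick(PHYSCHEM_COLS),
        indices=pick(INDEX_COLS),
        bacteria=pick(BACTERIA_COLS),
    )
    rec.validate()
    return rec


def _table_from_frame(df: pd.DataFrame, n_unparseable: int = 0) -> SampleTable:
    if "group" not in df.columns:
        raise SchemaError("missing mandatory column: group (aliases: sample, group_id)")
    dup = df["group"].astype(str).duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate group_id values: {sorted(df.loc[dup, 'group'].astype(str))}"
        )
    records = [
        _record_from_row(row["group"], row.drop(labels="group").to_dict())
        for _, row in df.iterrows()
    ]
    return SampleTable(records=records, frame=df.reset_index(drop=True), n_unparseable=n_unparseable)


def read_sample_table(path: str | Path, format: str | None = None) -> SampleTable:
    """Read a sample-group table from CSV or JSON.

    Headers are matched case-insensitively and punctuation-tolerantly
    against the canonical schema (``"Na/K"``, ``"Na_K"`` and ``"na k"``
    all map to ``Na/K``).  Unparseable numeric cells become missing
    values and are counted on the returned table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        try:
            raw = pd.read_csv(path, dtype=str)
        except pd.errors.EmptyDataError:
            raise SchemaError(f"{path}: empty file") from None
    elif fmt == "json":
        payload = json.loads(path.read_text())
        if not payload:
            raise SchemaError(f"{path}: empty file")
        raw = pd.DataFrame(payload).astype(str)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if raw.empty:
        raise SchemaError(f"{path}: no data rows")

    rename: dict[str, str] = {}
    for col in raw.columns:
        key = _norm_header(col)
        if key in _GROUP_ALIASES:
            rename[col] = "group"
        elif key in _ALIAS_TO_CANON:
            rename[col] = _ALIAS_TO_CANON[key]
    df = raw.rename(columns=rename)
    known = [c for c in df.columns if c == "group" or c in KNOWN_COLS]
    if "group" not in known:
        raise SchemaError(f"{path}: missing mandatory column: group")
    if len(known) < 2:
        raise SchemaError(f"{path}: no recognized measurement columns in header {list(raw.columns)}")
    df = df[known]

    n_bad = 0
    for c in df.columns:
        if c == "group":
            continue
        parsed = pd.to_numeric(df[c], errors="coerce")
        n_bad += int((parsed.isna() & df[c].notna()).sum())
        df[c] = parsed
    return _table_from_frame(df, n_unparseable=n_bad)


def write_results(obj, path: str | Path, format: str = "json") -> None:
    """Serialize a result object (anything with ``to_json``/``to_frame``).

    JSON writes the full-precision round-trippable form; CSV writes the
    tabular view.
    """
    path = Path(path)
    if format == "json":
        path.write_text(obj.to_json())
    elif format == "csv":
        obj.to_frame().to_csv(path, index=True)
    else:
        raise ValueError(f"unknown format {format!r}")


FIXTURE_NAMES = {
    "elements": "table2_elements.csv",
    "k_forms": "table3_kforms.csv",
    "bacteria": "table4_bacteria.csv",
    "organics": "table5_organics.csv",
    "indices": "table6_indices.csv",
    "correlations": "table7_correlations.csv",
    "path_wsK": "table8_wsk.csv",
    "path_neK": "table9_nek.csv",
    "path_eK": "table10_ek.csv",
    "equilibrium": "table12_equilibrium.csv",
    "fertilization": "table11_fertilization.json",
    "equilibrium_config": "equilibrium_config.json",
}

_INPUT_FIXTURES = {"elements", "k_forms", "bacteria", "organics", "indices"}


def fixture_path(name: str) -> Path:
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; valid names: {sorted(FIXTURE_NAMES)}")
    return Path(str(resources.files("kpath").joinpath("fixtures", FIXTURE_NAMES[name])))


def load_fixture(name: str):
    """Load a packaged verbatim table transcription.

    Input tables (``elements``, ``k_forms``, ``bacteria``, ``organics``,
    ``indices``) come back as :class:`SampleTable`; reference surfaces
    (``correlations``, ``path_wsK``, ``path_neK``, ``path_eK``,
    ``equilibrium``) as DataFrames; ``fertilization`` and
    ``equilibrium_config`` as dicts.
    """
    p = fixture_path(name)
    if p.suffix == ".json":
        return json.loads(p.read_text())
    if name in _INPUT_FIXTURES:
        return read_sample_table(p)
    df = pd.read_csv(p)
    if name == "correlations":
        df["flag"] = df["flag"].fillna("")
    return df


#: analysis-variable -> (fixture name, fixture column)
ANALYSIS_VARIABLES: dict[str, tuple[str, str]] = {
    "Na": ("elements", "Na"),
    "Mg": ("elements", "Mg_a"),
    "Al": ("elements", "Al"),
    "Si": ("elements", "Si"),
    "Fe": ("elements", "Fe"),
    "Ca": ("elements", "Ca"),
    "P": ("elements", "P"),
    "CO3": ("elements", "CO3"),
    "S": ("elements", "S"),
    "Cl": ("elements", "Cl"),
    "K": ("k_forms", "K"),
    "wsK": ("k_forms", "wsK"),
    "neK": ("k_forms", "neK"),
    "eK": ("k_forms", "eK"),
    "TC": ("organics", "TC"),
    "TN": ("organics", "TN"),
    "SOM": ("organics", "SOM"),
    "PHA": ("organics", "PHA"),
    "NHA": ("organics", "NHA"),
    "HMi": ("organics", "HMi"),
    "HMc": ("organics", "HMc"),
    "ORP": ("indices", "ORP"),
    "pH": ("indices", "pH"),
    "ba": ("indices", "ba"),
    "Na/K": ("indices", "Na/K"),
    "ICA": ("indices", "ICA"),
    "saf": ("indices", "saf"),
    "CIA": ("indices", "CIA"),
    "bacteria": ("bacteria", "bacteria_budding"),
}


def analysis_frame(tables: Mapping[str, SampleTable] | None = None) -> pd.DataFrame:
    """Merge the input tables into the canonical analysis matrix.

    One row per sample group (indexed by group id), one column per
    analysis variable.  With ``tables=None`` the packaged verbatim
    transcriptions are used.
    """
    if tables is None:
        tables = {n: load_fixture(n) for n in _INPUT_FIXTURES}
    frames = {}
    for var, (tname, col) in ANALYSIS_VARIABLES.items():
        if tname not in tables:
            continue
        t = tables[tname]
        df = t.frame.set_index(t.frame["group"].astype(str))
        if col in df.columns:
            frames[var] = df[col]
    out = pd.DataFrame(frames)
    out.index.name = "group"
    return out
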