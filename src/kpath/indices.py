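"""Chemical weathering indices computed from elemental totals.

All four indices (Na/K, CIA, saf, ba) are molar-oxide ratios rebuilt
from element mass fractions: for an element E with atomic mass ``m`` and
an oxide formula holding ``s`` cations (s = 2 for Al2O3, Fe2O3, Na2O,
K2O; s = 1 for CaO, MgO), the oxide mole amount per 100 g of soil is
``E% / m / s``.  Total K arrives in g/kg and is converted to mass %
(divide by 10) before entering any formula; that conversion is logged at
DEBUG level.

The oxide convention was validated against the published 16-row index
table: Na/K, saf and ba reproduce every printed value within +-0.01 at
two-decimal rounding (ba only when the first of the two Mg columns is
used).  CIA reproduces the printed values within the band implied by the
rounding of the printed elemental inputs (+-0.13); the printed CIA was
evidently computed from unrounded raw data, so exact two-decimal
agreement is not achievable from the published inputs.

ICA is not computed: no tested convention reproduces the printed
1.02-1.08 values, so printed ICA values are carried through as data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

__all__ = ["OxideBasis", "OXIDE_BASES", "na_k_ratio", "cia", "saf", "ba", "compute_indices"]

logger = logging.getLogger(__name__)


class DomainError(ValueError):
    """Inputs outside the mathematical domain of an index."""


@dataclass(frozen=True)
class OxideBasis:
    """Molar-oxide conversion constants for one element."""

    element: str
    atomic_mass: float  # g/mol
    stoichiometry: int  # cations per oxide formula unit

    def __post_init__(self) -> None:
        if self.atomic_mass <= 0:
            raise ValueError("atomic mass must be positive")
        if self.stoichiometry not in (1, 2):
            raise ValueError("oxide stoichiometry must be 1 or 2")

    def moles(self, mass_pct: float) -> float:
        """Oxide formula units per 100 g from an element mass fraction (%)."""
        return mass_pct / self.atomic_mass / self.stoichiometry


# fixed constants table: the acceptance surface is exact, so these are
# deliberately not configurable
OXIDE_BASES = {
    "Na": OxideBasis("Na", 22.99, 2),  # Na2O
    "Mg": OxideBasis("Mg", 24.31, 1),  # MgO
    "Al": OxideBasis("Al", 26.98, 2),  # Al2O3
    "Si": OxideBasis("Si", 28.09, 1),  # SiO2
    "K": OxideBasis("K", 39.10, 2),  # K2O
    "Ca": OxideBasis("Ca", 40.08, 1),  # CaO
    "Fe": OxideBasis("Fe", 55.85, 2),  # Fe2O3
}


def _k_pct(k_gkg: float) -> float:
    logger.debug("converting total K %.4g g/kg -> %.4g %% for index computation", k_gkg, k_gkg / 10)
    return k_gkg / 10.0


def na_k_ratio(na_pct: float, k_gkg: float) -> float:
    """Mass-fraction sodium/potassium ratio Na% / K%."""
    if k_gkg <= 0:
        raise DomainError(f"total K must be positive, got {k_gkg}")
    return na_pct / _k_pct(k_gkg)


def cia(al_pct: float, ca_pct: float, na_pct: float, k_gkg: float) -> float:
    """Chemical index of alteration, 100 * Al2O3 / (Al2O3 + CaO + Na2O + K2O).

    Molar oxide amounts from element mass fractions; CaO is the total
    (uncorrected) calcium oxide, which is what reproduces the published
    values.
    """
    if min(al_pct, ca_pct, na_pct, k_gkg) < 0:
        raise DomainError("element contents must be nonnegative")
    al2o3 = OXIDE_BASES["Al"].moles(al_pct)
    denom = (
        al2o3
        + OXIDE_BASES["Ca"].moles(ca_pct)
        + OXIDE_BASES["Na"].moles(na_pct)
        + OXIDE_BASES["K"].moles(_k_pct(k_gkg))
    )
    if denom <= 0:
        raise DomainError("all-zero input: CIA undefined")
    return 100.0 * al2o3 / denom


def saf(si_pct: float, al_pct: float, fe_pct: float) -> float:
    """Silica/sesquioxide ratio, molar SiO2 / (Al2O3 + Fe2O3)."""
    denom = OXIDE_BASES["Al"].moles(al_pct) + OXIDE_BASES["Fe"].moles(fe_pct)
    if denom <= 0:
        raise DomainError("Al + Fe must be positive")
    return OXIDE_BASES["Si"].moles(si_pct) / denom


def ba(ca_pct: float, mg_pct: float, na_pct: float, k_gkg: float, al_pct: float) -> float:
    """Base/alumina ratio, molar (CaO + MgO + Na2O + K2O) / Al2O3.

    ``mg_pct`` is the first of the two published Mg columns (the one
    verified to reproduce the printed ba values).
    """
    if al_pct <= 0:
        raise DomainError("Al must be positive")
    bases = (
        OXIDE_BASES["Ca"].moles(ca_pct)
        + OXIDE_BASES["Mg"].moles(mg_pct)
        + OXIDE_BASES["Na"].moles(na_pct)
        + OXIDE_BASES["K"].moles(_k_pct(k_gkg))
    )
    return bases / OXIDE_BASES["Al"].moles(al_pct)


def compute_indices(frame: pd.DataFrame) -> pd.DataFrame:
    """Compute Na/K, CIA, saf and ba for every row of an analysis frame.

    ``frame`` needs columns Na, Mg, Al, Si, Fe, Ca (mass %) and K (g/kg),
    e.g. the output of :func:`kpath.datamodel.analysis_frame`.  Returns a
    frame with one column per index, same index as the input.
    """
    required = {"Na", "Mg", "Al", "Si", "Fe", "Ca", "K"}
    missing = required - set(frame.columns)
    if missing:
        raise KeyError(f"analysis frame lacks columns {sorted(missing)}")
    out = pd.DataFrame(index=frame.index)
    out["Na/K"] = [na_k_ratio(r.Na, r.K) for r in frame.itertuples()]
    out["CIA"] = [cia(r.Al, r.Ca, r.Na, r.K) for r in frame.itertuples()]
    out["saf"] = [saf(r.Si, r.Al, r.Fe) for r in frame.itertuples()]
    out["ba"] = [ba(r.Ca, r.Mg, r.Na, r.K, r.Al) for r in frame.itertuples()]
    return out


def compare_indices(frame: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Deviation report: recomputed indices minus reference values.

    ``reference`` holds printed index columns (any subset of Na/K, CIA,
    saf, ba) aligned on the same index.
    """
    comp = compute_indices(frame)
    cols = [c for c in comp.columns if c in reference.columns]
    dev = comp[cols].round(2) - reference[cols]
    dev.columns = [f"{c}_dev" for c in cols]
    return pd.concat([comp[cols].round(2), dev], axis=1)
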