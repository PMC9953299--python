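"""Packaged reference datasets from published vitamin D studies.

Four small datasets illustrate the phenomena the molar-balance model is
built to quantify:

``pregnancy_study``
    serum 1,25(OH)₂D₃ (pmol/L), 25(OH)D₃ and 24,25(OH)₂D₃ (nmol/L) in
    non-pregnant controls, non-preeclamptic and later-preeclamptic pregnant
    women at 15 weeks — the canonical "uncoupling" of precursor and hormone.
``military_training``
    mean serum 25(OH)D₃ on days 1/10/20 of an arduous 21-day selection
    course — rising utilization draining the precursor pool.
``diurnal_case``
    midday serum 25(OH)D₃ on four days, including one during a brief cold.
``pregnancy_urine_m2``
    urinary 24,25(OH)₂D₃ in the pregnancy cohort groups.

Note: the pregnancy studies measured m2, an *initial* intermediate of
diverted precursor, not the terminal m6:7 the demand-ratio formulas require;
these fixtures therefore support the uncoupling illustration and directional
comparisons, not a full demand-ratio computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .units import Concentration, Unit, convert

__all__ = ["FixtureRecord", "FixtureDataset", "available_fixtures", "load_fixture", "uncoupling_ratio"]

_DESCRIPTIONS = {
    "pregnancy_study": "Serum m1/m0/m2 in non-pregnant, pregnant and preeclamptic groups at 15 weeks",
    "military_training": "Mean serum 25(OH)D3 across a 21-day military selection course",
    "diurnal_case": "Midday serum 25(OH)D3 on four days, one during an acute cold",
    "pregnancy_urine_m2": "Urinary 24,25(OH)2D3 in the pregnancy cohort groups",
}


@dataclass(frozen=True)
class FixtureRecord:
    label: str
    metabolite: str
    value: float
    unit: str
    provenance: str

    @property
    def concentration(self) -> Concentration:
        return Concentration(self.value, Unit(self.unit), self.metabolite)


@dataclass(frozen=True)
class FixtureDataset:
    name: str
    description: str
    records: tuple[FixtureRecord, ...]

    def get(self, label: str, metabolite: str) -> FixtureRecord:
        for r in self.records:
            if r.label == label and r.metabolite == metabolite:
                return r
        raise KeyError(f"no record ({label!r}, {metabolite!r}) in fixture {self.name!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


def _table() -> pd.DataFrame:
    with resources.files("vitd_balance.data").joinpath("fixtures.csv").open() as fh:
        return pd.read_csv(fh, dtype={"value": float})


def available_fixtures() -> list[str]:
    return sorted(_DESCRIPTIONS)


def load_fixture(name: str) -> FixtureDataset:
    """Load a packaged dataset by name; values are the published figures verbatim."""
    if name not in _DESCRIPTIONS:
        raise ValueError(
            f"unknown fixture {name!r}; available: {available_fixtures()}"
        )
    df = _table()
    rows = df[df["name"] == name]
    records = tuple(
        FixtureRecord(r.label, r.metabolite, float(r.value), r.unit, r.provenance)
        for r in rows.itertuples(index=False)
    )
    return FixtureDataset(name, _DESCRIPTIONS[name], records)


def uncoupling_ratio(m1_conc: Concentration, m0_conc: Concentration) -> float:
    """Molar ratio of two concentrations after canonicalization to nmol/L.

    Used for between-group hormone comparisons (e.g. pregnant vs control m1,
    where similar precursor levels accompany a ~4-fold hormone difference)
    and for hormone/precursor ratios within a group.
    """
    num = convert(m1_conc, Unit.NMOL_PER_L).value
    den = convert(m0_conc, Unit.NMOL_PER_L).value
    if den == 0:
        raise ValueError("denominator concentration is zero; ratio undefined")
    return num / den
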