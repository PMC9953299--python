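"""Concentration unit conversion and amount bookkeeping.

Canonical internal units: nmol/L for concentrations, nmol for amounts,
litres for volumes, hours for time. All estimator arithmetic happens in
canonical units; conversion occurs only at I/O boundaries.

Two conversion modes exist for the mass↔molar boundary:

``exact``
    nmol/L = ng/mL × 1000 / molar_mass, per-metabolite.
``approx``
    the clinical rule of thumb for 25(OH)D₃ only: multiply ng/mL by 2.5
    (the exact factor, 1000/400.64 = 2.496, rounds to 2.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .registry import METABOLITES

__all__ = ["Unit", "Concentration", "convert", "amount_in_volume", "APPROX_FACTOR_M0"]

#: Rule-of-thumb ng/mL -> nmol/L factor for 25(OH)D3 (m0).
APPROX_FACTOR_M0 = 2.5


class Unit(str, Enum):
    NG_PER_ML = "ng/mL"
    NMOL_PER_L = "nmol/L"
    PMOL_PER_L = "pmol/L"


def _as_unit(u: "Unit | str") -> Unit:
    try:
        return Unit(u)
    except ValueError:
        raise ValueError(
            f"unknown unit {u!r}; valid units: {[m.value for m in Unit]}"
        ) from None


@dataclass(frozen=True)
class Concentration:
    """A metabolite concentration tagged with its unit."""

    value: float
    unit: Unit
    metabolite: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"concentration must be >= 0, got {self.value}")
        object.__setattr__(self, "unit", _as_unit(self.unit))
        if self.metabolite not in METABOLITES:
            raise ValueError(f"unknown metabolite id {self.metabolite!r}")


def _to_nmol_per_L(c: Concentration, mode: str) -> float:
    if c.unit is Unit.NMOL_PER_L:
        return c.value
    if c.unit is Unit.PMOL_PER_L:
        return c.value / 1000.0
    # ng/mL
    if mode == "approx":
        if c.metabolite != "m0":
            raise ValueError("approx mode (×2.5) is defined only for m0 (25(OH)D3)")
        return c.value * APPROX_FACTOR_M0
    return c.value * 1000.0 / METABOLITES[c.metabolite].molar_mass


def convert(c: Concentration, target_unit: "Unit | str", mode: str = "exact") -> Concentration:
    """Convert a :class:`Concentration` to ``target_unit``.

    ``mode="exact"`` uses the metabolite's molar mass at the mass↔molar
    boundary; ``mode="approx"`` uses the ×2.5 rule of thumb and is only
    defined for m0. Molar↔molar (nmol/L ↔ pmol/L) is a pure power-of-ten
    rescale in either mode. Round trips are exact to 1e-9 relative.
    """
    if mode not in ("exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}; valid modes: ['exact', 'approx']")
    target = _as_unit(target_unit)
    nmol = _to_nmol_per_L(c, mode)
    if target is Unit.NMOL_PER_L:
        value = nmol
    elif target is Unit.PMOL_PER_L:
        value = nmol * 1000.0
    else:  # ng/mL
        if mode == "approx":
            if c.metabolite != "m0":
                raise ValueError("approx mode (×2.5) is defined only for m0 (25(OH)D3)")
            value = nmol / APPROX_FACTOR_M0
        else:
            value = nmol * METABOLITES[c.metabolite].molar_mass / 1000.0
    return Concentration(value, target, c.metabolite)


def amount_in_volume(c: Concentration, volume_L: float) -> float:
    """Amount (nmol) of a metabolite in ``volume_L`` litres at concentration ``c``.

    ``c`` must be in a molar unit; ng/mL inputs are converted exactly first.
    """
    if volume_L < 0:
        raise ValueError(f"volume must be >= 0, got {volume_L}")
    nmol_per_L = _to_nmol_per_L(c, "exact")
    return nmol_per_L * volume_L
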