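"""Canonical registry of the eleven vitamin D metabolites and body-compartment presets.

The molar-balance model tracks eleven species, labelled ``m0``–``m10``:
the circulating precursor 25(OH)D₃ (``m0``, calcifediol), the active hormone
1,25(OH)₂D₃ (``m1``, calcitriol), four initial/intermediate catabolites
(``m2``–``m5``), two terminal catabolites of *diverted* precursor (``m6``,
``m7``) and three terminal catabolites of the active hormone (``m8``–``m10``).
End metabolites are made intracellularly and exported down a concentration
gradient before excretion, so the intracellular concentration is assumed to
exceed the extracellular one by a constant factor β.

Body water is split into an extracellular compartment of volume ``Ve``
(containing the plasma sub-compartment ``Vp``) and an intracellular
compartment ``Vi`` ≈ 2·``Ve``. Two presets are shipped — a 70 kg male and a
55 kg female — together with the gradient factor β (default 1.1) and the
fraction of end-metabolite excretion leaving via urine (default 0.25, the
remainder via bile/stool).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from enum import Enum
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import yaml

__all__ = [
    "Role",
    "Metabolite",
    "BodyParameters",
    "METABOLITES",
    "DIVERTED_END",
    "ACTIVE_END",
    "END_METABOLITES",
    "get_preset",
    "volume_consistency_report",
    "save_parameters",
    "load_parameters",
]


class Role(str, Enum):
    """Functional role of a metabolite in the catabolic pathway."""

    PRECURSOR = "precursor"
    ACTIVE_HORMONE = "active_hormone"
    INITIAL_INTERMEDIATE = "initial_intermediate"
    DIVERTED_END = "diverted_end"
    ACTIVE_END = "active_end"


@dataclass(frozen=True)
class Metabolite:
    """A single vitamin D₃ species.

    Attributes
    ----------
    id : str
        Token ``m0`` … ``m10``.
    name : str
        Chemical name.
    role : Role
        Position in the pathway.
    molar_mass : float
        g/mol; used only for mass↔molar unit conversion.
    """

    id: str
    name: str
    role: Role
    molar_mass: float


# Molar masses are standard chemistry (PubChem monoisotopic-free average MW
# of the C27/C24/C23 secosteroid skeletons); the model itself only needs them
# at the ng/mL <-> nmol/L boundary.
METABOLITES: Mapping[str, Metabolite] = MappingProxyType(
    {
        "m0": Metabolite("m0", "25-hydroxyvitamin D3 (calcifediol)", Role.PRECURSOR, 400.64),
        "m1": Metabolite("m1", "1,25-dihydroxyvitamin D3 (calcitriol)", Role.ACTIVE_HORMONE, 416.64),
        "m2": Metabolite("m2", "24,25-dihydroxyvitamin D3", Role.INITIAL_INTERMEDIATE, 416.64),
        "m3": Metabolite("m3", "23,25-dihydroxyvitamin D3", Role.INITIAL_INTERMEDIATE, 416.64),
        "m4": Metabolite("m4", "1,24,25-trihydroxyvitamin D3", Role.INITIAL_INTERMEDIATE, 432.64),
        "m5": Metabolite("m5", "1,23,25-trihydroxyvitamin D3", Role.INITIAL_INTERMEDIATE, 432.64),
        "m6": Metabolite(
            "m6", "25,26,27-trinorcholecalciferol-24-carboxylic acid (cholacalcioic acid)",
            Role.DIVERTED_END, 372.54,
        ),
        "m7": Metabolite("m7", "25(OH)D3-26,23-lactone", Role.DIVERTED_END, 412.61),
        "m8": Metabolite(
            "m8", "1-OH-23-COOH-24,25,26,27-tetranor D3 (calcitroic acid)", Role.ACTIVE_END, 374.51,
        ),
        "m9": Metabolite("m9", "1,25R(OH)2D3-26,23S-lactone (calcitriol lactone)", Role.ACTIVE_END, 428.61),
        "m10": Metabolite("m10", "23-COOH-24,25,26,27-tetranor D3 (calcioic acid)", Role.ACTIVE_END, 358.52),
    }
)

#: End metabolites of diverted precursor (wasted 25(OH)D3).
DIVERTED_END: tuple[str, ...] = ("m6", "m7")
#: End metabolites of the active hormone.
ACTIVE_END: tuple[str, ...] = ("m8", "m9", "m10")
#: All five terminal catabolites, in canonical order.
END_METABOLITES: tuple[str, ...] = DIVERTED_END + ACTIVE_END


@dataclass(frozen=True)
class BodyParameters:
    """Compartment volumes and excretion constants of the molar-balance model.

    Attributes
    ----------
    label : str
        e.g. ``"male_default"``, ``"female_default"`` or ``"custom"``.
    Vp : float
        Plasma volume, litres.
    Ve : float
        Extracellular volume (includes plasma), litres.
    Vi : float
        Intracellular volume, litres; presets satisfy ``Vi == 2*Ve``.
    beta : float
        Intracellular/extracellular end-metabolite concentration ratio,
        ≥ 1 (gradient-driven export). Default 1.1.
    urine_fraction : float
        Fraction *f* of end-metabolite excretion leaving via urine; the
        remaining ``1-f`` leaves via bile/stool. Default 0.25.
    """

    label: str
    Vp: float
    Ve: float
    Vi: float
    beta: float = 1.1
    urine_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not self.Vp > 0:
            raise ValueError(f"Vp must be positive, got {self.Vp}")
        if self.Ve < self.Vp:
            raise ValueError(f"Ve ({self.Ve}) must be >= Vp ({self.Vp})")
        if not self.Vi > 0:
            raise ValueError(f"Vi must be positive, got {self.Vi}")
        if self.beta < 1:
            raise ValueError(f"beta must be >= 1, got {self.beta}")
        if not 0 < self.urine_fraction < 1:
            raise ValueError(f"urine_fraction must lie in (0, 1), got {self.urine_fraction}")

    @property
    def excretion_multiplier(self) -> float:
        """1/f — scales urinary excretion up to total (urine + stool) excretion."""
        return 1.0 / self.urine_fraction

    @property
    def body_amount_factor(self) -> float:
        """Ve·(2β+1), nmol per (nmol/L): converts an extracellular end-metabolite
        concentration into the total intra- plus extracellular body amount."""
        return self.Ve * (2.0 * self.beta + 1.0)

    def with_(self, **changes) -> "BodyParameters":
        """Return a copy with the given fields replaced (label -> 'custom' unless given)."""
        changes.setdefault("label", "custom")
        return replace(self, **changes)


_PRESETS: Mapping[str, BodyParameters] = MappingProxyType(
    {
        "male": BodyParameters("male_default", Vp=3.0, Ve=14.0, Vi=28.0),
        "female": BodyParameters("female_default", Vp=2.5, Ve=11.0, Vi=22.0),
    }
)


def get_preset(sex: str) -> BodyParameters:
    """Return the shipped body-parameter preset for ``"male"`` or ``"female"``.

    Male: Vp=3.0 L, Ve=14 L, Vi=28 L (42 L total aqueous).
    Female: Vp=2.5 L, Ve=11 L, Vi=22 L (33 L total aqueous).
    Both: β=1.1, urine fraction 0.25.
    """
    try:
        return _PRESETS[sex]
    except KeyError:
        raise ValueError(
            f"unknown sex preset {sex!r}; valid tokens: {sorted(_PRESETS)}"
        ) from None


def _truncate2(x: float) -> float:
    """Truncate (not round) to two decimals; 14/3 = 4.6667 -> 4.66."""
    return math.floor(x * 100.0) / 100.0


def volume_consistency_report(params: BodyParameters) -> dict[str, float]:
    """Named volume ratios for ``params`` plus the male/female preset contrasts.

    ``Ve_over_Vp`` is truncated to two decimals, matching the convention under
    which the male preset's 14/3 is quoted as 4.66. The preset contrasts
    (percent by which male volumes exceed female, and the male/female total
    aqueous volume as a percentage) are constants of the shipped presets and
    are included for reference regardless of ``params``.
    """
    male, female = _PRESETS["male"], _PRESETS["female"]
    total_m = male.Ve + male.Vi
    total_f = female.Ve + female.Vi
    return {
        "Ve_over_Vp": _truncate2(params.Ve / params.Vp),
        "Vi_over_Ve": params.Vi / params.Ve,
        "male_female_plasma_pct_greater": round((male.Vp / female.Vp - 1.0) * 100.0),
        "male_female_extracellular_pct_greater": round((male.Ve / female.Ve - 1.0) * 100.0),
        "male_female_intracellular_pct_greater": round((male.Vi / female.Vi - 1.0) * 100.0),
        "male_female_total_aqueous_pct": round(total_m / total_f * 100.0),
    }


# ---------------------------------------------------------------------------
# Parameter-file round-trip (YAML or JSON, keyed as in the CLI docs)

_PARAM_KEYS = ("label", "Vp_L", "Ve_L", "Vi_L", "beta", "urine_fraction")


def save_parameters(params: BodyParameters, path: str | Path) -> None:
    """Write a parameter file; ``.json`` gives JSON, anything else YAML."""
    payload = {
        "label": params.label,
        "Vp_L": params.Vp,
        "Ve_L": params.Ve,
        "Vi_L": params.Vi,
        "beta": params.beta,
        "urine_fraction": params.urine_fraction,
    }
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_parameters(path: str | Path) -> BodyParameters:
    """Read a parameter file written by :func:`save_parameters`."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    missing = [k for k in _PARAM_KEYS if k not in data]
    if missing:
        raise ValueError(f"parameter file {path} missing keys: {missing}")
    return BodyParameters(
        label=data["label"],
        Vp=float(data["Vp_L"]),
        Ve=float(data["Ve_L"]),
        Vi=float(data["Vi_L"]),
        beta=float(data["beta"]),
        urine_fraction=float(data["urine_fraction"]),
    )
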