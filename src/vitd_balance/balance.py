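"""Inverse estimators of active vitamin D synthesis, demand and utilization.

The molar-balance identity: active hormone synthesized over an interval
equals the synthesis of its end metabolites over the same interval, which in
turn equals the change in their total body amount plus their cumulative
excretion. With homogeneous extracellular concentrations, intracellular
concentration β times extracellular, and Vi = 2·Ve, the total body amount of
an end-metabolite pool with summed extracellular concentration C (nmol/L) is

    M = β·C·2·Ve + C·Ve = C·Ve·(2β + 1)              (point-in-time amount)

and the cumulative synthesis over (t0, t1) is

    ∫S dt = Ve·(2β+1)·[C(t1) − C(t0)] + (1/f)·C_u(t1)·V_u(t1)

where C_u·V_u is the amount recovered in a 24-h urine collection and f is
the urinary share of total excretion (stool is never measured; it is always
inferred as (1−f)/f times the urinary amount). The same estimator applied
to m6:7 measures precursor diverted away from hormone synthesis.

Demand ratio Dr = M(active ends m8:10)/M(diverted ends m6:7); percent
utilization Ut% = 100·Dr/(1+Dr) = 100·M₈:₁₀/(M₈:₁₀+M₆:₇).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, NamedTuple

from .registry import ACTIVE_END, DIVERTED_END, BodyParameters

__all__ = [
    "SerumPanel",
    "UrineCollection",
    "SynthesisEstimate",
    "DemandReport",
    "PrecursorCorrection",
    "BuildupReport",
    "body_amount_from_plasma",
    "synthesis_24h",
    "demand_ratio_body",
    "demand_ratio_urine",
    "utilization_point",
    "utilization_24h",
    "apply_precursor_correction",
    "intermediate_buildup_check",
]

log = logging.getLogger(__name__)

_SPECIES_GROUPS: dict[str, tuple[str, ...]] = {
    "active_end": ACTIVE_END,
    "diverted_end": DIVERTED_END,
}

_INTERVAL_TOL_H = 1e-6
#: an interval counts as "per 24 h" when within this margin of 24 h
_DAY_TOL_H = 0.5


@dataclass(frozen=True)
class SerumPanel:
    """Serum metabolite concentrations at one time point, canonical nmol/L."""

    time: float
    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        for mid, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {mid}: {c}")

    def sum_over(self, metabolites: tuple[str, ...]) -> float:
        missing = [m for m in metabolites if m not in self.concentrations]
        if missing:
            raise KeyError(f"serum panel at t={self.time} h is missing metabolite(s): {missing}")
        return sum(self.concentrations[m] for m in metabolites)


@dataclass(frozen=True)
class UrineCollection:
    """A timed urine collection (started empty at t0), canonical nmol/L."""

    t0: float
    t1: float
    volume: float
    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.t1 > self.t0:
            raise ValueError(f"t1 ({self.t1}) must exceed t0 ({self.t0})")
        if self.volume < 0:
            raise ValueError(f"volume must be >= 0, got {self.volume}")
        for mid, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative urine concentration for {mid}: {c}")

    def amount(self, metabolites: tuple[str, ...]) -> float:
        """Total nmol of the given metabolites recovered in the collection."""
        missing = [m for m in metabolites if m not in self.concentrations]
        if missing:
            raise KeyError(f"urine collection is missing metabolite(s): {missing}")
        return sum(self.concentrations[m] for m in metabolites) * self.volume


@dataclass(frozen=True)
class SynthesisEstimate:
    """Estimated cumulative synthesis of an end-metabolite pool over an interval.

    ``total == body_change_term + excretion_term`` exactly. A negative total
    is diagnostic of an assumption violation (e.g. intermediate build-up) and
    is flagged, never clamped.
    """

    interval: tuple[float, float]
    total: float
    body_change_term: float
    excretion_term: float
    species: str = "active_end"
    negative_flag: bool = field(default=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "negative_flag", self.total < 0)

    @property
    def per_24h(self) -> bool:
        """True when the interval is 24 h within ±0.5 h, so the estimate doubles
        as a daily synthesis rate."""
        return abs((self.interval[1] - self.interval[0]) - 24.0) <= _DAY_TOL_H


@dataclass(frozen=True)
class DemandReport:
    """Demand ratio and percent utilization, with explicit undefined states.

    ``demand_ratio`` is None when the diverted-end pool is zero; ``reason``
    then carries a code (``diverted_pool_zero`` — utilization is still 100% —
    or ``no_end_metabolites`` when both pools are empty and nothing is
    defined).
    """

    demand_ratio: float | None
    utilization_percent: float | None
    m1_level_estimate: float
    source: Literal["body_point", "urine_24h", "synthesis_24h"]
    reason: str | None = None


class PrecursorCorrection(NamedTuple):
    """Result of subtracting serum precursor from a driven-assay end total."""

    value: float
    floored: bool


@dataclass(frozen=True)
class BuildupReport:
    """Comparison of a direct end-metabolite assay against an enzyme-driven one."""

    discrepancy_fraction: float
    correction_needed: bool


# ---------------------------------------------------------------------------


def body_amount_from_plasma(c_sum: float, params: BodyParameters) -> float:
    """Total body amount (nmol) of an end-metabolite pool from its summed
    extracellular concentration (nmol/L): ``c_sum · Ve · (2β + 1)``.

    The intracellular share is β·c_sum over Vi = 2·Ve; the extracellular share
    is c_sum over Ve.
    """
    if c_sum < 0:
        raise ValueError(f"concentration sum must be >= 0, got {c_sum}")
    return c_sum * params.body_amount_factor


def synthesis_24h(
    panel_t0: SerumPanel,
    panel_t1: SerumPanel,
    urine: UrineCollection,
    params: BodyParameters,
    species: str = "active_end",
) -> SynthesisEstimate:
    """Cumulative synthesis (nmol) of an end-metabolite pool over (t0, t1).

    ``species="active_end"`` estimates active hormone synthesis from m8:10;
    ``species="diverted_end"`` estimates wasted precursor from m6:7.

    body-change term:  Ve·(2β+1)·Σ[Cₙ(t1) − Cₙ(t0)]
    excretion term:    (1/f)·Σ Cₙ,u(t1)·V_u(t1)

    The urine interval must match the serum panel times to 1e-6 h. Negative
    totals are returned flagged, never clamped.
    """
    try:
        group = _SPECIES_GROUPS[species]
    except KeyError:
        raise ValueError(
            f"unknown species {species!r}; valid: {sorted(_SPECIES_GROUPS)}"
        ) from None
    t0, t1 = panel_t0.time, panel_t1.time
    if abs(urine.t0 - t0) > _INTERVAL_TOL_H or abs(urine.t1 - t1) > _INTERVAL_TOL_H:
        raise ValueError(
            f"urine interval ({urine.t0}, {urine.t1}) h does not match serum "
            f"panel times ({t0}, {t1}) h"
        )
    delta_c = panel_t1.sum_over(group) - panel_t0.sum_over(group)
    body_change = params.body_amount_factor * delta_c
    excretion = params.excretion_multiplier * urine.amount(group)
    estimate = SynthesisEstimate(
        interval=(t0, t1),
        total=body_change + excretion,
        body_change_term=body_change,
        excretion_term=excretion,
        species=species,
    )
    log.info(
        "synthesis estimate [%s] over (%g, %g) h with %s (beta=%g, f=%g): "
        "total=%g nmol (body-change %g, excretion %g)%s",
        species, t0, t1, params.label, params.beta, params.urine_fraction,
        estimate.total, body_change, excretion,
        " NEGATIVE-FLAGGED" if estimate.negative_flag else "",
    )
    return estimate


def _demand_report(
    m_active: float, m_diverted: float, source: str
) -> DemandReport:
    if m_diverted == 0.0 and m_active == 0.0:
        return DemandReport(None, None, 0.0, source, reason="no_end_metabolites")
    if m_diverted == 0.0:
        # all consumed precursor went to hormone: utilization is 100% but the
        # ratio itself diverges
        return DemandReport(None, 100.0, m_active, source, reason="diverted_pool_zero")
    ratio = m_active / m_diverted
    utilization = 100.0 * m_active / (m_active + m_diverted)
    return DemandReport(ratio, utilization, m_active, source)


def demand_ratio_body(panel: SerumPanel, params: BodyParameters) -> DemandReport:
    """Point-in-time demand ratio M₈:₁₀/M₆:₇ from a single serum panel.

    Both amounts share the Ve·(2β+1) factor, so the ratio reduces to the
    concentration-sum ratio; ``m1_level_estimate`` is the absolute M₈:₁₀,
    the point-in-time proxy for recent active hormone synthesis.
    """
    m_active = body_amount_from_plasma(panel.sum_over(ACTIVE_END), params)
    m_diverted = body_amount_from_plasma(panel.sum_over(DIVERTED_END), params)
    return _demand_report(m_active, m_diverted, "body_point")


def demand_ratio_urine(urine: UrineCollection) -> DemandReport:
    """24-h urine demand ratio: urinary M₈:₁₀,u / M₆:₇,u (volume cancels)."""
    return _demand_report(
        urine.amount(ACTIVE_END), urine.amount(DIVERTED_END), "urine_24h"
    )


def utilization_point(panel: SerumPanel, params: BodyParameters) -> float | None:
    """Percent of consumed precursor routed to active hormone at time t:
    100·M₈:₁₀/(M₈:₁₀+M₆:₇). None when both pools are empty."""
    return demand_ratio_body(panel, params).utilization_percent


def utilization_24h(
    synth_active: SynthesisEstimate, synth_diverted: SynthesisEstimate
) -> float | None:
    """Percent utilization over an interval from two synthesis estimates:
    100·∫S₁/(∫S₁+∫S₆:₇). Negative-flagged inputs are rejected — re-measure or
    apply an intermediate-buildup correction first."""
    if synth_active.interval != synth_diverted.interval:
        raise ValueError(
            f"interval mismatch: {synth_active.interval} vs {synth_diverted.interval}"
        )
    if synth_active.negative_flag or synth_diverted.negative_flag:
        raise ValueError(
            "negative-flagged synthesis estimate: re-measure or apply a "
            "correction factor before computing utilization"
        )
    denom = synth_active.total + synth_diverted.total
    if denom == 0.0:
        return None
    return 100.0 * synth_active.total / denom


def apply_precursor_correction(
    measured_diverted_end_total: float, serum_m0_amount: float
) -> PrecursorCorrection:
    """Correct an enzyme-driven diverted-end total for the precursor that was
    still circulating in the sample.

    When the whole sample (precursor included) is driven to end metabolites,
    the serum m0 amount must be subtracted to isolate genuinely diverted
    precursor. A negative difference is floored at zero and flagged as an
    assay inconsistency.
    """
    if measured_diverted_end_total < 0 or serum_m0_amount < 0:
        raise ValueError("amounts must be >= 0")
    corrected = measured_diverted_end_total - serum_m0_amount
    if corrected < 0:
        return PrecursorCorrection(0.0, True)
    return PrecursorCorrection(corrected, False)


def intermediate_buildup_check(
    first_assay_end_total: float,
    enzyme_driven_total: float,
    tolerance_fraction: float = 0.1,
) -> BuildupReport:
    """Check the steady-state assumption that intermediate metabolites are
    negligible, by comparing a direct end-metabolite assay against a second
    assay in which excess CYP24A1 drives all intermediates to end metabolites.

    ``discrepancy_fraction`` is the relative shortfall of the direct assay; a
    value above ``tolerance_fraction`` means a correction factor is needed.
    """
    if first_assay_end_total < 0 or enzyme_driven_total < 0:
        raise ValueError("assay totals must be >= 0")
    if not 0 < tolerance_fraction < 1:
        raise ValueError(f"tolerance_fraction must lie in (0, 1), got {tolerance_fraction}")
    if enzyme_driven_total == 0.0:
        if first_assay_end_total > 0:
            raise ValueError(
                "inconsistent assays: enzyme-driven total is zero but the "
                "direct assay found end metabolites"
            )
        return BuildupReport(0.0, False)
    discrepancy = (enzyme_driven_total - first_assay_end_total) / enzyme_driven_total
    return BuildupReport(discrepancy, discrepancy > tolerance_fraction)
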