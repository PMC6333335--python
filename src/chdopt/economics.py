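"""Economic valuation of the four end states of the testing/treatment decision tree.

The decision model classifies each patient-path into one of four end states
over a 10-year horizon:

    I   no CHD event, no treatment   (true negative)
    II  no CHD event, treatment      (false positive)
    III CHD event, no treatment      (false negative)
    IV  CHD event, treatment         (true positive)

Here "CHD event" means the patient *would* suffer a coronary-heart-disease
event within the horizon absent treatment; statin therapy averts the event
with probability equal to the relative risk reduction.  Each state is valued
in discounted costs (2015 euros), discounted quality-adjusted life-years
(QALYs), and net monetary benefit

    NMB = QALY x lambda - Cost,

where lambda is the societal willingness-to-pay threshold (EUR/QALY).
Costs follow the reporting convention of health-economic tables: they are
carried with a negative sign in :class:`EndStateValues`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple

import pandas as pd

__all__ = [
    "EconomicParameters",
    "EndStateValues",
    "EventCostTable",
    "StateValue",
    "WeightedEventCost",
    "annuity_factor",
    "default_event_cost_table",
    "discount_factor",
    "endstate_values",
    "nmb",
    "treatment_threshold",
]


@dataclass(frozen=True)
class EconomicParameters:
    """Base-case model inputs for the 10-year CHD prevention model.

    Defaults are the Finnish base case: statin primary prevention, 3 %/yr
    discounting of both costs and health outcomes, and a willingness to pay
    of 50,000 EUR/QALY.  ``qol_chd_free`` is the population-weighted average
    quality of life of the CHD-free state (45+ population, 15D instrument);
    ``disutility_event`` is the one-year QALY loss of a non-fatal event and
    is negative by convention.  ``t_event`` is the expected event time given
    that an event occurs within the horizon.
    """

    horizon_years: float = 10.0
    discount_rate: float = 0.03
    wtp: float = 50_000.0
    qol_chd_free: float = 0.903
    disutility_event: float = -0.147
    p_death_given_event: float = 0.22
    t_event: float = 5.75
    statin_relative_risk_reduction: float = 0.27
    statin_annual_disutility: float = 0.002
    cost_trs: float = 173.0
    cost_grs: float = 200.0
    cost_statin_annual: float = 53.0
    cost_monitoring_annual: float = 173.0
    cost_secondary_annual: float = 451.0
    cost_nonfatal_event: float = 19_860.0
    cost_fatal_event: float = 2_417.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_death_given_event <= 1.0:
            raise ValueError("p_death_given_event must be in [0, 1]")
        if not 0.0 <= self.statin_relative_risk_reduction <= 1.0:
            raise ValueError("statin_relative_risk_reduction must be in [0, 1]")
        if not 0.0 < self.t_event < self.horizon_years:
            raise ValueError("t_event must lie strictly inside the horizon")
        if self.discount_rate < 0.0:
            raise ValueError("discount_rate must be non-negative")
        if self.wtp < 0.0:
            raise ValueError("wtp must be non-negative")
        if self.disutility_event > 0.0:
            raise ValueError("disutility_event is a QALY loss and must be <= 0")
        for name in (
            "cost_trs",
            "cost_grs",
            "cost_statin_annual",
            "cost_monitoring_annual",
            "cost_secondary_annual",
            "cost_nonfatal_event",
            "cost_fatal_event",
        ):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")

    def with_updates(self, **kwargs: float) -> "EconomicParameters":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **kwargs)


class StateValue(NamedTuple):
    """Valuation of one end state: cost (negative sign convention), QALY, NMB."""

    cost: float
    qaly: float
    nmb: float


@dataclass(frozen=True)
class EndStateValues:
    """Discounted cost/QALY/NMB of end states I-IV at a given WTP threshold."""

    no_chd_untreated: StateValue  # I, true negative
    no_chd_treated: StateValue  # II, false positive
    chd_untreated: StateValue  # III, false negative
    chd_treated: StateValue  # IV, true positive
    wtp: float

    def to_frame(self) -> pd.DataFrame:
        """End-state table (state, cost, qaly, nmb), costs with negative sign."""
        rows = [
            ("I_no_chd_untreated", *self.no_chd_untreated),
            ("II_no_chd_treated", *self.no_chd_treated),
            ("III_chd_untreated", *self.chd_untreated),
            ("IV_chd_treated", *self.chd_treated),
        ]
        return pd.DataFrame(rows, columns=["state", "cost", "qaly", "nmb"])


@dataclass(frozen=True)
class EventCostTable:
    """Per-category acute and one-year follow-up costs with event counts."""

    categories: tuple[str, ...]
    acute_cost: tuple[float, ...]
    followup_cost: tuple[float, ...]
    n_events: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.categories)
        if not (len(self.acute_cost) == len(self.followup_cost) == len(self.n_events) == n):
            raise ValueError("all columns must have equal length")
        if n == 0:
            raise ValueError("event cost table must be non-empty")
        if any(c <= 0 for c in self.n_events):
            raise ValueError("event counts must be positive")

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "EventCostTable":
        recs = list(records)
        return cls(
            categories=tuple(r["category"] for r in recs),
            acute_cost=tuple(float(r["acute_cost"]) for r in recs),
            followup_cost=tuple(float(r["followup_cost"]) for r in recs),
            n_events=tuple(int(r["n_events"]) for r in recs),
        )


def default_event_cost_table() -> EventCostTable:
    """Finnish 2011 national-register CHD event costs in 2015 euros.

    Categories: myocardial infarction, unstable angina pectoris, coronary
    artery bypass grafting, and percutaneous transluminal coronary
    angioplasty, with national annual event counts as weights.
    """
    return EventCostTable(
        categories=("MI", "unstable_AP", "CABG", "PTCA"),
        acute_cost=(8_585.0, 6_702.0, 19_483.0, 7_122.0),
        followup_cost=(9_814.0, 10_147.0, 23_666.0, 8_523.0),
        n_events=(11_406, 2_689, 2_493, 7_901),
    )


class WeightedEventCost(NamedTuple):
    acute: float
    followup: float
    total: float


def discount_factor(t: float, r: float) -> float:
    """Present-value factor ``(1+r)**(-t)`` for a flow occurring at time ``t``.

    Fractional ``t`` is allowed; the expected event time of 5.75 years is
    discounted with this factor.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if r < 0:
        raise ValueError("r must be non-negative")
    return (1.0 + r) ** (-t)


def annuity_factor(start: float, end: float, r: float) -> float:
    """Discounted sum of unit annual end-of-year payments over ``(start, end]``.

    Payments fall at ``start + 1, start + 2, ...``; a partial final year of
    length ``frac = (end - start) mod 1`` is pro-rated and paid at ``end``.
    ``annuity_factor(0, 10, 0.03)`` is the canonical 10-year factor 8.5302.
    """
    if start < 0 or r < 0:
        raise ValueError("start and r must be non-negative")
    if start > end:
        raise ValueError("start must not exceed end")
    span = end - start
    whole = int(math.floor(span + 1e-12))
    total = sum(discount_factor(start + k, r) for k in range(1, whole + 1))
    frac = span - whole
    if frac > 1e-12:
        total += frac * discount_factor(end, r)
    return total


def weighted_event_cost(table: EventCostTable) -> WeightedEventCost:
    """Event-count-weighted mean acute and follow-up cost of a non-fatal event."""
    n = sum(table.n_events)
    if n <= 0:
        raise ValueError("total event count must be positive")
    acute = sum(c * k for c, k in zip(table.acute_cost, table.n_events)) / n
    followup = sum(c * k for c, k in zip(table.followup_cost, table.n_events)) / n
    return WeightedEventCost(acute=acute, followup=followup, total=acute + followup)


def nmb(qaly: float, cost: float, wtp: float) -> float:
    """Net monetary benefit ``qaly * wtp - cost`` (cost as a positive magnitude)."""
    return qaly * wtp - cost


def endstate_values(params: EconomicParameters) -> EndStateValues:
    """Value end states I-IV under the base valuation conventions.

    Conventions (all flows discounted at ``discount_rate``):

    * Annual flows (QoL-years, statin + monitoring, secondary prevention)
      are end-of-year payments, pro-rated for partial years.
    * One-off event costs and the one-year event disutility are discounted
      at the expected event time ``t_event``.
    * State III mixes the fatal branch (QoL truncated to zero after
      ``t_event``, fatal event cost) and the non-fatal branch (one-year
      disutility and event cost at ``t_event``, then annual secondary
      prevention until the horizon) with ``p_death_given_event``.
    * State IV: treatment averts the event with probability
      ``statin_relative_risk_reduction`` (the state-II path is then
      followed); otherwise the state-III path is followed with primary
      prevention paid, and statin disutility accrued, until ``t_event``.
    """
    p = params
    a_full = annuity_factor(0.0, p.horizon_years, p.discount_rate)
    a_to_event = annuity_factor(0.0, p.t_event, p.discount_rate)
    a_secondary = annuity_factor(p.t_event, p.horizon_years, p.discount_rate)
    d_event = discount_factor(p.t_event, p.discount_rate)

    primary_annual = p.cost_statin_annual + p.cost_monitoring_annual
    p_die = p.p_death_given_event
    p_live = 1.0 - p_die
    rrr = p.statin_relative_risk_reduction

    # I: no event, no treatment
    qaly_i = p.qol_chd_free * a_full
    cost_i = 0.0

    # II: no event, treated for the full horizon
    qaly_ii = (p.qol_chd_free - p.statin_annual_disutility) * a_full
    cost_ii = primary_annual * a_full

    # Untreated event path (state III): fatal / non-fatal mixture
    qaly_fatal = p.qol_chd_free * a_to_event
    qaly_nonfatal = p.qol_chd_free * a_full + p.disutility_event * d_event
    qaly_iii = p_die * qaly_fatal + p_live * qaly_nonfatal
    cost_event = p_die * p.cost_fatal_event * d_event + p_live * (
        p.cost_nonfatal_event * d_event + p.cost_secondary_annual * a_secondary
    )
    cost_iii = cost_event

    # Treated event path (event not averted): primary prevention until t_event
    qaly_fatal_tx = (p.qol_chd_free - p.statin_annual_disutility) * a_to_event
    qaly_nonfatal_tx = qaly_nonfatal - p.statin_annual_disutility * a_to_event
    qaly_event_tx = p_die * qaly_fatal_tx + p_live * qaly_nonfatal_tx
    cost_event_tx = primary_annual * a_to_event + cost_event

    # IV: averted with probability rrr, otherwise the treated event path
    qaly_iv = rrr * qaly_ii + (1.0 - rrr) * qaly_event_tx
    cost_iv = rrr * cost_ii + (1.0 - rrr) * cost_event_tx

    def _state(cost: float, qaly: float) -> StateValue:
        return StateValue(cost=-cost, qaly=qaly, nmb=nmb(qaly, cost, p.wtp))

    return EndStateValues(
        no_chd_untreated=_state(cost_i, qaly_i),
        no_chd_treated=_state(cost_ii, qaly_ii),
        chd_untreated=_state(cost_iii, qaly_iii),
        chd_treated=_state(cost_iv, qaly_iv),
        wtp=p.wtp,
    )


def treatment_threshold(endstates: EndStateValues) -> float:
    """Closed-form risk threshold of the final treat/no-treat decision.

    Treat exactly when the prior event risk ``p`` satisfies ``p >= p*`` with

        p* = (NMB_I - NMB_II) / ((NMB_I - NMB_II) + (NMB_IV - NMB_III)),

    clipped to [0, 1] when one action dominates at every risk level.
    Raises ``ValueError`` if both differences vanish (indifference at all
    risk levels).
    """
    harm = endstates.no_chd_untreated.nmb - endstates.no_chd_treated.nmb
    benefit = endstates.chd_treated.nmb - endstates.chd_untreated.nmb
    denom = harm + benefit
    if denom == 0.0:
        raise ValueError("treat and no-treat are value-equivalent at every risk")
    p_star = harm / denom
    return min(1.0, max(0.0, p_star))
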