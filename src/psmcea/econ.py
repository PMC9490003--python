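"""Direct medical cost accrual and incremental cost-effectiveness results.

Costs accrue over the occupancy trace from the Chinese healthcare-system
perspective: first-line drug acquisition while progression-free (immune
checkpoint inhibitors capped at 24 months of use), follow-up and
hospital-service management while alive, subsequent-line treatment for a
fixed proportion of progressed patients (best supportive care for the rest),
one-time adverse-event management at treatment start, and terminal care on
death. All amounts are US$ at the January-2022 exchange rate (6.3746 RMB/$),
which is carried as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import OccupancyTrace

__all__ = [
    "DrugComponent",
    "ArmDefinition",
    "CostBreakdown",
    "CEResult",
    "cycle_drug_cost",
    "accrue_costs",
    "compute_icer",
    "net_monetary_benefit",
]

DEFAULT_WTP = 38024.0               # 3x 2021 Chinese GDP per capita, US$/QALY
RMB_PER_USD = 6.3746


@dataclass(frozen=True)
class DrugComponent:
    """One drug within a regimen: priced units consumed per 42-day cycle.

    ``units_per_cycle`` already encodes the dosing schedule and the pricing
    convention (whole-vial / whole-tablet versus exact per-mg billing);
    ``max_duration_months`` caps immune checkpoint inhibitors at 2 years.
    ``price_group`` names the multiplier target for price scenarios.
    """

    name: str
    unit_cost: float
    units_per_cycle: float
    max_duration_months: float | None = None
    price_group: str | None = None

    def __post_init__(self):
        if self.unit_cost < 0:
            raise ValueError(f"{self.name}: unit cost must be >= 0")
        if self.units_per_cycle < 0:
            raise ValueError(f"{self.name}: units per cycle must be >= 0")

    @property
    def cycle_cost(self) -> float:
        return self.unit_cost * self.units_per_cycle


@dataclass(frozen=True)
class ArmDefinition:
    """Everything needed to cost one treatment strategy."""

    name: str
    first_line: tuple[DrugComponent, ...]
    subsequent_mix: tuple[tuple[DrugComponent, float], ...]   # (drug, weight)
    subsequent_proportion: float
    followup_per_cycle: float
    management_per_cycle: float
    supportive_per_cycle: float
    terminal_care: float
    ae_costs: tuple[float, ...]
    ae_risk: float
    u_pfs: float
    u_pd: float
    ae_disutility: float
    patient_weight_kg: float = 65.0
    patient_bsa_m2: float = 1.72
    # conventions (config switches)
    ae_cost_mode: str = "sum"            # "sum" | "mean" of per-event costs
    followup_in_pd: bool = True
    ae_timing: str = "one_time"

    def __post_init__(self):
        if not (0.0 <= self.subsequent_proportion <= 1.0):
            raise ValueError("subsequent_proportion must lie in [0, 1]")
        if not (0.0 <= self.ae_risk <= 1.0):
            raise ValueError("ae_risk must lie in [0, 1]")
        for c in (self.followup_per_cycle, self.management_per_cycle,
                  self.supportive_per_cycle, self.terminal_care):
            if c < 0:
                raise ValueError("per-cycle costs must be >= 0")
        w = sum(w for _, w in self.subsequent_mix)
        if self.subsequent_mix and abs(w - 1.0) > 1e-9:
            raise ValueError("subsequent mix weights must sum to 1")
        if self.ae_cost_mode not in ("sum", "mean"):
            raise ValueError("ae_cost_mode must be sum or mean")

    @property
    def ae_management_cost(self) -> float:
        if not self.ae_costs:
            return 0.0
        total = float(np.sum(self.ae_costs))
        return total if self.ae_cost_mode == "sum" else total / len(self.ae_costs)


def _multiplier_for(drug: DrugComponent, price_multiplier: float,
                    targets: frozenset[str]) -> float:
    group = drug.price_group or drug.name
    return price_multiplier if group in targets else 1.0


def cycle_drug_cost(regimen: Sequence[DrugComponent], time_months: float,
                    price_multiplier: float = 1.0,
                    multiplier_targets: Sequence[str] = ("nivolumab", "cabozantinib"),
                    ) -> float:
    """Acquisition cost of one regimen for the cycle evaluated at
    ``time_months``; components past their maximum duration contribute 0."""
    if time_months < 0:
        raise ValueError("time_months must be >= 0")
    if price_multiplier <= 0:
        raise ValueError("price multiplier must be > 0")
    targets = frozenset(multiplier_targets)
    total = 0.0
    for drug in regimen:
        if drug.max_duration_months is not None and time_months > drug.max_duration_months:
            continue
        total += drug.cycle_cost * _multiplier_for(drug, price_multiplier, targets)
    return total


@dataclass(frozen=True)
class CostBreakdown:
    """Per-category discounted cost totals for one arm (audit table)."""

    first_line: float
    subsequent: float
    supportive: float
    followup_management: float
    adverse_events: float
    terminal: float

    @property
    def total(self) -> float:
        return (self.first_line + self.subsequent + self.supportive
                + self.followup_management + self.adverse_events + self.terminal)

    def to_frame(self) -> pd.DataFrame:
        rows = [("first_line", self.first_line), ("subsequent", self.subsequent),
                ("supportive", self.supportive),
                ("followup_management", self.followup_management),
                ("adverse_events", self.adverse_events),
                ("terminal", self.terminal), ("total", self.total)]
        return pd.DataFrame(rows, columns=["category", "discounted_cost_usd"])


def accrue_costs(arm: ArmDefinition, trace: OccupancyTrace,
                 price_multiplier: float = 1.0,
                 multiplier_targets: Sequence[str] = ("nivolumab", "cabozantinib"),
                 ) -> CostBreakdown:
    """Accrue all direct medical costs over the occupancy trace (discounted)."""
    tau = trace.time_months
    df_event = trace.discount                      # one-time costs
    df = trace.discount * trace.cycle_fraction     # recurring per-cycle costs
    targets = frozenset(multiplier_targets)

    def scheduled(drugs_with_weights):
        cost = np.zeros_like(tau)
        for drug, w in drugs_with_weights:
            m = _multiplier_for(drug, price_multiplier, targets)
            per_cycle = drug.cycle_cost * m * w
            if drug.max_duration_months is None:
                cost += per_cycle
            else:
                cost += per_cycle * (tau <= drug.max_duration_months)
        return cost

    first_line = float(np.sum(
        scheduled([(d, 1.0) for d in arm.first_line]) * trace.p_pfs * df))

    sub_cycle = scheduled(arm.subsequent_mix)
    subsequent = float(np.sum(
        arm.subsequent_proportion * sub_cycle * trace.p_pd * df))
    supportive = float(np.sum(
        (1.0 - arm.subsequent_proportion) * arm.supportive_per_cycle
        * trace.p_pd * df))

    alive = trace.p_pfs + (trace.p_pd if arm.followup_in_pd else 0.0)
    followup = float(np.sum(
        (arm.followup_per_cycle + arm.management_per_cycle) * alive * df))

    adverse = arm.ae_risk * arm.ae_management_cost * float(df_event[0])
    terminal = arm.terminal_care * float(
        np.sum(trace.incremental_deaths() * df_event))

    return CostBreakdown(first_line=first_line, subsequent=subsequent,
                         supportive=supportive, followup_management=followup,
                         adverse_events=adverse, terminal=terminal)


# ---------------------------------------------------------------------------
# Incremental results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmResult:
    name: str
    total_cost: float
    life_years: float
    qalys: float
    breakdown: CostBreakdown | None = None


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of two strategies (comparator vs reference)."""

    reference: ArmResult
    comparator: ArmResult
    wtp_threshold: float = DEFAULT_WTP
    exchange_rate_rmb_per_usd: float = RMB_PER_USD

    @property
    def incremental_cost(self) -> float:
        return self.comparator.total_cost - self.reference.total_cost

    @property
    def incremental_effect(self) -> float:
        return self.comparator.qalys - self.reference.qalys

    @property
    def verdict(self) -> str:
        dc, de = self.incremental_cost, self.incremental_effect
        if de == 0.0:
            return "equivalent" if dc == 0.0 else ("dominated" if dc > 0 else "dominant")
        if de > 0:
            if dc <= 0:
                return "dominant"
            return ("cost_effective" if dc / de <= self.wtp_threshold
                    else "not_cost_effective")
        return "dominated" if dc >= 0 else "not_cost_effective"

    @property
    def icer(self) -> float:
        """Incremental cost per QALY from unrounded increments; NaN when the
        incremental effect is zero (flagged through ``verdict``)."""
        de = self.incremental_effect
        if de == 0.0:
            return float("nan")
        return self.incremental_cost / de

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm, incr in ((self.reference, False), (self.comparator, True)):
            rows.append({
                "strategy": arm.name,
                "total_cost_usd": arm.total_cost,
                "incr_cost_usd": self.incremental_cost if incr else np.nan,
                "life_years": arm.life_years,
                "qalys": arm.qalys,
                "incr_effect": self.incremental_effect if incr else np.nan,
                "icer_usd_per_qaly": self.icer if incr else np.nan,
            })
        return pd.DataFrame(rows)


def compute_icer(reference: ArmResult, comparator: ArmResult,
                 wtp: float = DEFAULT_WTP) -> CEResult:
    """Incremental cost, effect and ICER of comparator vs reference."""
    return CEResult(reference=reference, comparator=comparator, wtp_threshold=wtp)


def net_monetary_benefit(result: CEResult, wtp: float | None = None) -> float:
    """wtp * incremental QALYs - incremental cost (positive = cost-effective)."""
    w = result.wtp_threshold if wtp is None else wtp
    if w < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return w * result.incremental_effect - result.incremental_cost
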