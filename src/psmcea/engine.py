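"""Three-state partitioned survival engine.

State membership is read directly off the survival curves at each cycle:
progression-free = min(S_PFS, S_OS) (the clamp enforces PFS <= OS when
digitized/extrapolated curves cross), dead = 1 - S_OS, progressed = the
remainder. Life-years and QALYs are the discounted sums of state occupancy
over 6-week cycles.

Two evaluation conventions are exposed because the source model's choice is
unknowable from the publication: where within the cycle occupancy is read
(`eval_point`: start / mid / end; 'mid' is the classic half-cycle
correction), and whether discounting is continuous-in-time or applied in
discrete end-of-year steps (`discounting`: 'continuous' / 'annual').
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import SurvivalSpec

__all__ = [
    "DAYS_PER_MONTH",
    "ModelSettings",
    "OccupancyTrace",
    "compute_occupancy",
    "discounted_life_years",
    "discounted_qalys",
]

DAYS_PER_MONTH = 30.4375    # 365.25 / 12
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ModelSettings:
    """Cycle structure, horizon, and discounting conventions."""

    cycle_days: float = 42.0
    horizon_years: float = 20.0
    annual_discount: float = 0.05
    eval_point: str = "end"          # "start" | "mid" | "end"
    discounting: str = "annual"      # "annual" (end-of-year steps) | "continuous"

    def __post_init__(self):
        if self.cycle_days <= 0:
            raise ValueError("cycle_days must be positive")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        if not (0.0 <= self.annual_discount <= 0.08):
            raise ValueError("annual_discount must lie in [0, 0.08]")
        if self.eval_point not in ("start", "mid", "end"):
            raise ValueError("eval_point must be start, mid or end")
        if self.discounting not in ("annual", "continuous"):
            raise ValueError("discounting must be annual or continuous")

    @property
    def half_cycle_correction(self) -> bool:
        return self.eval_point == "mid"

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / DAYS_PER_YEAR

    @property
    def n_cycles(self) -> int:
        return int(np.ceil(self.horizon_years * DAYS_PER_YEAR / self.cycle_days
                           - 1e-9))

    def cycle_durations_years(self) -> np.ndarray:
        """Per-cycle duration in years; the final cycle is truncated at the
        horizon so short horizons are not over-credited."""
        d = np.full(self.n_cycles, self.cycle_years)
        remainder = self.horizon_years - (self.n_cycles - 1) * self.cycle_years
        d[-1] = min(remainder, self.cycle_years)
        return d

    def eval_times_months(self) -> np.ndarray:
        """Time at which state membership is read, per cycle, in months."""
        k = np.arange(self.n_cycles, dtype=float)
        offset = {"start": 0.0, "mid": 0.5, "end": 1.0}[self.eval_point]
        tau = (k + offset) * self.cycle_months
        return np.minimum(tau, self.horizon_years * 12.0)

    def discount_factors(self, annual_discount: float | None = None) -> np.ndarray:
        r = self.annual_discount if annual_discount is None else annual_discount
        ty = self.eval_times_months() / 12.0
        if self.discounting == "continuous":
            return (1.0 + r) ** (-ty)
        return (1.0 + r) ** (-np.ceil(ty - 1e-12))


@dataclass
class OccupancyTrace:
    """Per-cycle state occupancy with discount factors attached."""

    settings: ModelSettings
    time_months: np.ndarray
    p_pfs: np.ndarray
    p_pd: np.ndarray
    p_dead: np.ndarray
    discount: np.ndarray

    def __post_init__(self):
        total = self.p_pfs + self.p_pd + self.p_dead
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("occupancy rows must sum to 1")

    @property
    def n_cycles(self) -> int:
        return int(self.time_months.size)

    @property
    def cycle_years(self) -> np.ndarray:
        """Per-cycle time credit (final cycle truncated at the horizon)."""
        return self.settings.cycle_durations_years()

    @property
    def cycle_fraction(self) -> np.ndarray:
        """Fraction of a full cycle each row represents (1 except the tail)."""
        return self.cycle_years / self.settings.cycle_years

    @property
    def p_alive(self) -> np.ndarray:
        return self.p_pfs + self.p_pd

    def incremental_deaths(self) -> np.ndarray:
        """New death probability mass per cycle (first cycle from baseline 0)."""
        return np.diff(np.concatenate([[0.0], self.p_dead]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": np.arange(self.n_cycles),
            "time_months": self.time_months,
            "p_pfs": self.p_pfs,
            "p_pd": self.p_pd,
            "p_dead": self.p_dead,
            "discount": self.discount,
        })


def compute_occupancy(pfs: SurvivalSpec, os: SurvivalSpec,
                      settings: ModelSettings,
                      annual_discount: float | None = None) -> OccupancyTrace:
    """Partition the cohort across the three states at each cycle."""
    tau = settings.eval_times_months()
    s_pfs = pfs.survival(tau)
    s_os = os.survival(tau)
    p_pfs = np.minimum(s_pfs, s_os)
    p_dead = 1.0 - s_os
    p_pd = np.clip(1.0 - p_pfs - p_dead, 0.0, None)
    return OccupancyTrace(
        settings=settings, time_months=tau,
        p_pfs=p_pfs, p_pd=p_pd, p_dead=p_dead,
        discount=settings.discount_factors(annual_discount),
    )


def discounted_life_years(trace: OccupancyTrace) -> float:
    """Sum of discounted alive-state occupancy, in years."""
    return float(np.sum(trace.p_alive * trace.discount * trace.cycle_years))


def discounted_qalys(trace: OccupancyTrace, u_pfs: float, u_pd: float,
                     ae_risk: float = 0.0, ae_disutility: float = 0.0,
                     ae_timing: str = "one_time") -> float:
    """Utility-weighted discounted occupancy minus the adverse-event penalty.

    The grade >=3 AE disutility is applied once, at treatment start
    (``ae_timing='one_time'``), or scaled to one cycle's duration
    (``'first_cycle'``) -- the source publication states neither duration nor
    timing, so both are available.
    """
    for name, u in (("u_pfs", u_pfs), ("u_pd", u_pd)):
        if not (0.0 <= u <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    if not (0.0 <= ae_risk <= 1.0):
        raise ValueError("ae_risk must lie in [0, 1]")
    if ae_timing not in ("one_time", "first_cycle"):
        raise ValueError("ae_timing must be one_time or first_cycle")
    q = float(np.sum((u_pfs * trace.p_pfs + u_pd * trace.p_pd) * trace.discount
                     * trace.cycle_years))
    penalty = ae_risk * ae_disutility * float(trace.discount[0])
    if ae_timing == "first_cycle":
        penalty *= trace.settings.cycle_years
    return q - penalty
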