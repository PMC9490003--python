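"""Scenario analyses: time horizon, price reductions, alternative OS models.

Three scenario families mirror the published analysis: (1) shortened model
horizons (5/10/15/20 years); (2) nivolumab+cabozantinib price multipliers
(0.25/0.50/0.75/1.00) applied in both arms and both treatment lines; and
(3) replacement of the overall-survival extrapolation by mixture-cure,
non-mixture-cure, or Royston-Parmar spline fits. The cure/spline fits need
patient-level data (their published parameters were never printed), so the
third family runs on reconstructed or simulated pseudo-IPD only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .model import CEModel
from .reconstruct import PseudoIPD
from .survival import FitResult, fit_mle

__all__ = ["ScenarioGrid", "ScenarioDataError", "run_scenarios", "fit_os_scenario"]


class ScenarioDataError(RuntimeError):
    """A cure/spline scenario was requested without reconstructed data."""


@dataclass(frozen=True)
class ScenarioGrid:
    horizons_years: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
    price_multipliers: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00)
    os_families: tuple[str, ...] = ("mixture_cure", "nonmixture_cure",
                                    "royston_parmar")

    def __post_init__(self):
        if any(not (0.0 < m <= 1.0) for m in self.price_multipliers):
            raise ValueError("price multipliers must lie in (0, 1]")
        if any(h <= 0 for h in self.horizons_years):
            raise ValueError("horizons must be positive")

    @classmethod
    def from_config(cls, config) -> "ScenarioGrid":
        s = config.raw.get("scenarios", {})
        return cls(
            horizons_years=tuple(s.get("horizons_years", (5., 10., 15., 20.))),
            price_multipliers=tuple(s.get("price_multipliers",
                                          (0.25, 0.5, 0.75, 1.0))),
            os_families=tuple(s.get("os_families",
                                    ("mixture_cure", "nonmixture_cure",
                                     "royston_parmar"))),
        )


def fit_os_scenario(os_ipd: Mapping[str, PseudoIPD],
                    family: str) -> dict[str, FitResult]:
    """Refit each arm's OS with a cure or spline family on pseudo-IPD."""
    return {arm: fit_mle(ipd, family) for arm, ipd in os_ipd.items()}


def run_scenarios(model: CEModel, grid: ScenarioGrid | None = None,
                  os_ipd: Mapping[str, PseudoIPD] | None = None,
                  ) -> pd.DataFrame:
    """One result row per scenario cell; the base case appears as the
    horizon-20y / multiplier-1.0 cells."""
    if grid is None:
        grid = ScenarioGrid.from_config(model.config)
    rows = []

    def add(family_label: str, label: str, res):
        rows.append({
            "scenario": family_label, "label": label,
            "ref_cost_usd": res.reference.total_cost,
            "ref_ly": res.reference.life_years,
            "ref_qalys": res.reference.qalys,
            "cmp_cost_usd": res.comparator.total_cost,
            "cmp_ly": res.comparator.life_years,
            "cmp_qalys": res.comparator.qalys,
            "incr_cost_usd": res.incremental_cost,
            "incr_qalys": res.incremental_effect,
            "icer_usd_per_qaly": res.icer,
        })

    add("base_case", "base", model.base_case())
    for h in grid.horizons_years:
        add("horizon", f"{h:g}y", model.evaluate(horizon_years=h))
    for m in grid.price_multipliers:
        add("price", f"x{m:g}", model.evaluate(price_multiplier=m))
    for fam in grid.os_families:
        if os_ipd is None:
            raise ScenarioDataError(
                f"OS scenario {fam!r} requires reconstructed patient-level "
                "data; run the reconstruction or simulation stage first")
        fits = fit_os_scenario(os_ipd, fam)
        os_specs = {arm: fr.spec for arm, fr in fits.items()}
        add("os_model", fam, model.evaluate(os_specs=os_specs))
    return pd.DataFrame(rows)
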