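"""End-to-end cost-effectiveness model built from a run configuration.

``CEModel`` evaluates both strategies under the base case or under any
combination of parameter overrides (one-way sensitivity analysis,
probabilistic draws), price multipliers, alternative horizons, or
substituted overall-survival curves (scenario analysis). Occupancy traces
are cached because survival parameters are held fixed across cost/utility
draws.
"""

from __future__ import annotations

from typing import Mapping

from .config import RunConfig
from .econ import (ArmResult, CEResult, accrue_costs, compute_icer)
from .engine import compute_occupancy, discounted_life_years, discounted_qalys
from .survival import SurvivalSpec

__all__ = ["CEModel"]


class CEModel:
    """Two-strategy partitioned-survival cost-effectiveness model.

    The first arm in the configuration is the reference strategy (sunitinib),
    the second the comparator (nivolumab+cabozantinib).
    """

    def __init__(self, config: RunConfig):
        self.config = config
        names = config.arm_names
        if len(names) != 2:
            raise ValueError("CEModel expects exactly two arms")
        self.reference_name, self.comparator_name = names
        self._trace_cache: dict = {}

    # -- internals ----------------------------------------------------------

    def _trace(self, arm: str, horizon_years: float, discount: float,
               os_spec: SurvivalSpec | None):
        os_used = os_spec if os_spec is not None else \
            self.config.survival_spec(arm, "os")
        key = (arm, horizon_years, discount, id(os_spec) if os_spec is not None else None)
        if key not in self._trace_cache:
            settings = self.config.settings(horizon_years=horizon_years,
                                            annual_discount=discount)
            pfs = self.config.survival_spec(arm, "pfs")
            self._trace_cache[key] = compute_occupancy(pfs, os_used, settings)
        return self._trace_cache[key]

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, overrides: Mapping[str, float] | None = None,
                 price_multiplier: float = 1.0,
                 horizon_years: float | None = None,
                 os_specs: Mapping[str, SurvivalSpec] | None = None,
                 ) -> CEResult:
        """One full model evaluation.

        Parameters
        ----------
        overrides
            Parameter name -> value (names as in ``config.parameter_specs()``,
            e.g. ``"cost.cabozantinib"`` or ``"utility.pfs_nivo_cabo"``;
            ``"rate.discount"`` rebuilds the traces).
        price_multiplier
            Scales the acquisition price of the multiplier-target drugs
            (nivolumab and cabozantinib) in both arms and both lines.
        horizon_years
            Scenario horizon; defaults to the configured horizon.
        os_specs
            Optional per-arm replacement overall-survival curves
            (scenario 3 style robustness analysis).
        """
        v = dict(overrides or {})
        cfg = self.config
        settings = cfg.settings()
        horizon = horizon_years if horizon_years is not None else settings.horizon_years
        discount = float(v.get("rate.discount", settings.annual_discount))

        arm_results = []
        for arm in (self.reference_name, self.comparator_name):
            os_spec = (os_specs or {}).get(arm)
            trace = self._trace(arm, horizon, discount, os_spec)
            arm_def = cfg.arm_definition(arm, v)
            breakdown = accrue_costs(arm_def, trace, price_multiplier,
                                     cfg.multiplier_targets)
            ly = discounted_life_years(trace)
            q = discounted_qalys(trace, arm_def.u_pfs, arm_def.u_pd,
                                 arm_def.ae_risk, arm_def.ae_disutility,
                                 arm_def.ae_timing)
            arm_results.append(ArmResult(name=arm, total_cost=breakdown.total,
                                         life_years=ly, qalys=q,
                                         breakdown=breakdown))
        return compute_icer(arm_results[0], arm_results[1], wtp=cfg.wtp)

    def base_case(self) -> CEResult:
        return self.evaluate()
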