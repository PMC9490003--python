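"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-evaluates the ICER at each parameter's published low and
high bound (tornado rows sorted by spread). The probabilistic analysis draws
all parameters jointly and independently -- gamma for costs, beta for
utilities and probabilities, the discount rate fixed -- with distribution
moments set from mean = base value and SD = (high - low) / (2 * 1.96),
treating the published range as a 95% interval (an ``sd_rule`` switch offers
SD = 20% of the mean instead). The cost-effectiveness acceptability curve is
the fraction of draws with positive net monetary benefit across a
willingness-to-pay grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CEModel

__all__ = [
    "ParameterSpec",
    "TornadoRow",
    "PSAOutput",
    "one_way_sa",
    "sample_parameters",
    "run_psa",
]


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain input: base value, range, and sampling family."""

    name: str
    base: float
    low: float
    high: float
    family: str = "gamma"        # gamma | beta | fixed
    role: str = "cost"           # cost | utility | probability | discount

    def __post_init__(self):
        lo, hi = self.low, self.high
        if lo > hi:  # normalize printed range inversions
            object.__setattr__(self, "low", hi)
            object.__setattr__(self, "high", lo)
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"{self.name}: base {self.base} outside "
                             f"[{self.low}, {self.high}]")
        if self.family not in ("gamma", "beta", "fixed"):
            raise ValueError(f"{self.name}: unknown family {self.family!r}")

    def sd(self, rule: str = "interval95") -> float:
        if rule == "interval95":
            return (self.high - self.low) / (2.0 * 1.96)
        if rule == "fraction20":
            return 0.2 * self.base
        raise ValueError(f"unknown sd rule {rule!r}")


@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float
    flagged: bool = False

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def one_way_sa(model: CEModel, params: list[ParameterSpec]) -> list[TornadoRow]:
    """Tornado analysis: ICER at each parameter's bounds, all else at base."""
    rows = []
    for p in params:
        icers = []
        flagged = False
        for bound in (p.low, p.high):
            try:
                icers.append(model.evaluate({p.name: bound}).icer)
            except (ValueError, FloatingPointError):
                icers.append(float("nan"))
                flagged = True
        rows.append(TornadoRow(parameter=p.name, low_value=p.low,
                               high_value=p.high, icer_at_low=icers[0],
                               icer_at_high=icers[1], flagged=flagged))
    rows.sort(key=lambda r: (-(r.spread if np.isfinite(r.spread) else np.inf),
                             r.parameter))
    return rows


def tornado_frame(rows: list[TornadoRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": r.parameter, "low": r.low_value, "high": r.high_value,
        "icer_at_low": r.icer_at_low, "icer_at_high": r.icer_at_high,
        "spread": r.spread, "flagged": r.flagged} for r in rows])


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def sample_parameters(params: list[ParameterSpec], rng: np.random.Generator,
                      sd_rule: str = "interval95") -> dict[str, float]:
    """One joint, independent draw of all parameters."""
    draw = {}
    for p in params:
        if p.family == "fixed" or p.high == p.low:
            draw[p.name] = p.base
            continue
        sd = p.sd(sd_rule)
        m = p.base
        if p.family == "gamma":
            shape = (m / sd) ** 2
            scale = sd * sd / m
            draw[p.name] = float(rng.gamma(shape, scale))
        else:  # beta, confined to [0, 1]
            max_sd = np.sqrt(m * (1.0 - m)) * 0.999
            if sd >= max_sd:
                warnings.warn(f"{p.name}: SD {sd:.4g} infeasible for beta mean "
                              f"{m:.4g}; clamped", stacklevel=2)
                sd = max_sd
            nu = m * (1.0 - m) / (sd * sd) - 1.0
            a, b = m * nu, (1.0 - m) * nu
            draw[p.name] = float(rng.beta(a, b))
    return draw


@dataclass
class PSAOutput:
    """Monte-Carlo draws of incremental cost/effect plus the CEAC."""

    delta_cost: np.ndarray
    delta_effect: np.ndarray
    wtp_grid: np.ndarray
    ceac: np.ndarray
    seed: int
    n_iterations: int
    n_failed: int = 0

    def probability_cost_effective(self, wtp: float) -> float:
        nmb = wtp * self.delta_effect - self.delta_cost
        return float(np.mean(nmb > 0.0))

    def draws_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_cost_usd": self.delta_cost,
                             "delta_qalys": self.delta_effect})

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp_usd_per_qaly": self.wtp_grid,
                             "p_cost_effective": self.ceac})


def run_psa(model: CEModel, params: list[ParameterSpec] | None = None,
            n: int = 5000, seed: int = 0,
            wtp_grid: np.ndarray | None = None,
            sd_rule: str | None = None) -> PSAOutput:
    """Monte-Carlo PSA: n full model evaluations on joint parameter draws."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if params is None:
        params = model.config.parameter_specs()
    if sd_rule is None:
        sd_rule = str(model.config.conventions.get("psa_sd_rule", "interval95"))
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 600_001.0, 10_000.0)
    rng = np.random.default_rng(seed)

    dc = np.empty(n)
    de = np.empty(n)
    failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # beta clamp warning, once is enough
        for i in range(n):
            draw = sample_parameters(params, rng, sd_rule)
            try:
                res = model.evaluate(draw)
                dc[i], de[i] = res.incremental_cost, res.incremental_effect
            except (ValueError, FloatingPointError):
                dc[i] = de[i] = np.nan
                failed += 1
    ok = np.isfinite(dc) & np.isfinite(de)
    dc, de = dc[ok], de[ok]
    nmb = wtp_grid[:, None] * de[None, :] - dc[None, :]
    ceac = np.mean(nmb > 0.0, axis=1)
    return PSAOutput(delta_cost=dc, delta_effect=de, wtp_grid=wtp_grid,
                     ceac=ceac, seed=seed, n_iterations=n, n_failed=failed)
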