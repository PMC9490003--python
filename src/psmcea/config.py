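"""Run configuration: load, validate, serialize, and build model objects.

The packaged default (``data/base_case.yaml``) carries every published input
of the analysis -- survival parameters, unit costs, utilities, adverse-event
profiles, subsequent-treatment rules, sensitivity ranges and distribution
families -- so the full pipeline runs with no downloads.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .econ import ArmDefinition, DrugComponent
from .engine import ModelSettings
from .survival import SurvivalSpec

__all__ = ["RunConfig", "ConfigError", "load_config", "default_config"]


class ConfigError(ValueError):
    """Field-level configuration validation failure."""


_REQUIRED_TOP = ("settings", "drugs", "costs", "adverse_event_costs",
                 "utilities", "probabilities", "survival", "arms")


@dataclass
class RunConfig:
    """Validated run configuration wrapping the raw mapping."""

    raw: dict[str, Any]

    def __post_init__(self):
        missing = [k for k in _REQUIRED_TOP if k not in self.raw]
        if missing:
            raise ConfigError(f"missing configuration sections: {missing}")
        for arm_name, arm in self.raw["arms"].items():
            for d in arm["first_line"]:
                if d not in self.raw["drugs"]:
                    raise ConfigError(f"arm {arm_name}: unknown first-line drug {d!r}")
            for d in arm["subsequent_mix"]:
                if d not in self.raw["drugs"]:
                    raise ConfigError(f"arm {arm_name}: unknown subsequent drug {d!r}")
            for key, section in (("utility", "utilities"),
                                 ("ae_risk", "probabilities"),
                                 ("subsequent_proportion", "probabilities")):
                if arm[key] not in self.raw[section]:
                    raise ConfigError(f"arm {arm_name}: {key} -> {arm[key]!r} "
                                      f"not found in {section}")
            if arm_name not in self.raw["survival"]:
                raise ConfigError(f"no survival curves for arm {arm_name}")
        mode = self.pricing_mode
        for name, drug in self.raw["drugs"].items():
            if mode not in drug["units_per_cycle"]:
                raise ConfigError(f"drug {name}: no units_per_cycle for mode {mode!r}")
        self.settings()  # validates ranges via ModelSettings

    # -- accessors ----------------------------------------------------------

    @property
    def pricing_mode(self) -> str:
        return self.raw.get("pricing", {}).get("mode", "whole_unit")

    @property
    def multiplier_targets(self) -> tuple[str, ...]:
        return tuple(self.raw.get("pricing", {}).get(
            "multiplier_targets", ["nivolumab", "cabozantinib"]))

    @property
    def wtp(self) -> float:
        return float(self.raw.get("wtp_threshold_usd_per_qaly", 38024.0))

    @property
    def arm_names(self) -> tuple[str, ...]:
        return tuple(self.raw["arms"])

    @property
    def conventions(self) -> dict[str, Any]:
        return self.raw.get("conventions", {})

    def settings(self, **overrides) -> ModelSettings:
        s = dict(self.raw["settings"])
        s.update(overrides)
        return ModelSettings(
            cycle_days=float(s.get("cycle_days", 42.0)),
            horizon_years=float(s.get("horizon_years", 20.0)),
            annual_discount=float(s.get("annual_discount", 0.05)),
            eval_point=str(s.get("eval_point", "end")),
            discounting=str(s.get("discounting", "annual")),
        )

    def survival_spec(self, arm: str, endpoint: str) -> SurvivalSpec:
        entry = self.raw["survival"][arm][endpoint]
        return SurvivalSpec.from_dict(entry)

    def drug_component(self, name: str, values: dict[str, float] | None = None,
                       ) -> DrugComponent:
        drug = self.raw["drugs"][name]
        unit_cost = (values or {}).get(f"cost.{name}", drug["unit_cost"]["base"])
        cap = (float(self.conventions.get("ici_max_months", 24.0))
               if drug.get("ici") else None)
        return DrugComponent(
            name=name, unit_cost=float(unit_cost),
            units_per_cycle=float(drug["units_per_cycle"][self.pricing_mode]),
            max_duration_months=cap, price_group=name,
        )

    def arm_definition(self, arm: str,
                       values: dict[str, float] | None = None) -> ArmDefinition:
        """Build an :class:`ArmDefinition`, optionally overriding any named
        parameter (see :meth:`parameter_specs`) via ``values``."""
        v = values or {}
        a = self.raw["arms"][arm]
        conv = self.conventions

        def cost(name):
            return float(v.get(f"cost.{name}", self.raw["costs"][name]["base"]))

        def util(key):
            return float(v.get(f"utility.{key}", self.raw["utilities"][key]["base"]))

        def prob(key):
            return float(v.get(f"prob.{key}", self.raw["probabilities"][key]["base"]))

        ae_costs = tuple(
            float(v.get(f"cost.ae.{name}", spec["base"]))
            for name, spec in self.raw["adverse_event_costs"].items())
        patient = self.raw.get("patient", {})
        return ArmDefinition(
            name=arm,
            first_line=tuple(self.drug_component(d, v) for d in a["first_line"]),
            subsequent_mix=tuple(
                (self.drug_component(d, v), float(w))
                for d, w in a["subsequent_mix"].items()),
            subsequent_proportion=prob(a["subsequent_proportion"]),
            followup_per_cycle=cost("followup_per_cycle"),
            management_per_cycle=cost("management_per_cycle"),
            supportive_per_cycle=cost("supportive_per_cycle"),
            terminal_care=cost("terminal_care"),
            ae_costs=ae_costs,
            ae_risk=prob(a["ae_risk"]),
            u_pfs=util(a["utility"]),
            u_pd=util("pd"),
            ae_disutility=util("ae_disutility"),
            patient_weight_kg=float(patient.get("weight_kg", 65.0)),
            patient_bsa_m2=float(patient.get("bsa_m2", 1.72)),
            ae_cost_mode=str(conv.get("ae_cost_mode", "sum")),
            followup_in_pd=bool(conv.get("followup_in_pd", True)),
            ae_timing=str(conv.get("ae_timing", "one_time")),
        )

    def parameter_specs(self) -> "list":
        """Every sampleable/variable parameter as uncertainty specs."""
        from .uncertainty import ParameterSpec

        out = []
        for name, drug in self.raw["drugs"].items():
            u = drug["unit_cost"]
            out.append(ParameterSpec(f"cost.{name}", u["base"], u["low"], u["high"],
                                     u.get("distribution", "gamma"), "cost"))
        for name, c in self.raw["costs"].items():
            out.append(ParameterSpec(f"cost.{name}", c["base"], c["low"], c["high"],
                                     c.get("distribution", "gamma"), "cost"))
        for name, c in self.raw["adverse_event_costs"].items():
            out.append(ParameterSpec(f"cost.ae.{name}", c["base"], c["low"], c["high"],
                                     c.get("distribution", "gamma"), "cost"))
        for name, u in self.raw["utilities"].items():
            out.append(ParameterSpec(f"utility.{name}", u["base"], u["low"], u["high"],
                                     u.get("distribution", "beta"), "utility"))
        for name, p in self.raw["probabilities"].items():
            out.append(ParameterSpec(f"prob.{name}", p["base"], p["low"], p["high"],
                                     p.get("distribution", "beta"), "probability"))
        d = self.raw.get("discount_rate",
                         {"base": 0.05, "low": 0.0, "high": 0.08})
        out.append(ParameterSpec("rate.discount", d["base"], d["low"], d["high"],
                                 "fixed", "discount"))
        return out

    # -- (de)serialization --------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.raw, sort_keys=False, default_flow_style=None))

    def copy(self) -> "RunConfig":
        return RunConfig(copy.deepcopy(self.raw))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: not a mapping")
    return RunConfig(raw)


def default_config() -> RunConfig:
    """The packaged base-case configuration."""
    ref = importlib.resources.files("psmcea.data") / "base_case.yaml"
    raw = yaml.safe_load(ref.read_text())
    return RunConfig(raw)
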