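"""Model configuration: schema, validation, (de)serialization, fixture.

A :class:`ModelConfiguration` bundles everything one cost-effectiveness
run needs: two arm blocks (clinical medians + per-cycle economics, and
optionally the published transition-probability table with its
deterministic-sensitivity limits), a global block (utilities, discount
rate, horizon, WTP, accrual and precision flags) and a sensitivity block
(PSA iteration count, cost dispersion, CEAC grid).

Configurations load from YAML or JSON and round-trip losslessly.  A
packaged fixture carries the progressive-glioblastoma BEV+LOM vs LOM
parameter set this package was built around.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .engine import EconomicInputs
from .params import ArmClinicalInputs, InvalidInputError, ParamRange

ARM_KEYS = ("intervention", "comparator")

#: transition names that may appear in an arm's printed-probability table
_PRINTED_KEYS = ("p_pfs_pfs", "p_pfs_pd", "p_pfs_death", "p_pd_pd", "p_pd_death")


class ConfigError(InvalidInputError):
    """A configuration file violates the schema."""


@dataclass
class ArmConfig:
    """One treatment arm: clinical medians and per-cycle costs (USD)."""

    label: str
    median_pfs: float
    median_os: float
    cost_pfs_per_cycle: float
    cost_pd_per_cycle: float
    cost_death: float = 0.0
    #: optional published monthly probabilities with DSA limits, keyed by
    #: transition name; used by precision mode "fixture" and for DSA ranges
    printed_probabilities: dict[str, ParamRange] | None = None

    def clinical_inputs(self) -> ArmClinicalInputs:
        return ArmClinicalInputs(
            arm_label=self.label, median_pfs=self.median_pfs, median_os=self.median_os
        )


@dataclass
class WTPGrid:
    """An inclusive arithmetic willingness-to-pay grid in USD/QALY."""

    start: float = 0.0
    stop: float = 150_000.0
    step: float = 1_500.0

    def values(self) -> list[float]:
        if self.step <= 0 or self.stop < self.start:
            raise ConfigError(
                f"wtp_grid: need step > 0 and stop >= start, got {self!r}"
            )
        n = int(math.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        return [self.start + i * self.step for i in range(n)]


@dataclass
class SensitivityConfig:
    """Settings for probabilistic and deterministic sensitivity analysis."""

    n_iter: int = 1000
    cost_sd_fraction: float = 0.25
    wtp_grid: WTPGrid = field(default_factory=WTPGrid)


@dataclass
class ModelConfiguration:
    """Complete, validated parameterization of a two-arm comparison."""

    intervention: ArmConfig
    comparator: ArmConfig
    utility_pfs: float = 0.89
    utility_pd: float = 0.74
    utility_death: float = 0.0
    discount_rate: float = 0.05
    horizon_cycles: int = 120
    wtp: float = 35_906.0
    half_cycle: bool = False
    precision: str = "derived"
    sensitivity: SensitivityConfig = field(default_factory=SensitivityConfig)
    #: loader warnings (normalized rows, unknown keys); not serialized
    warnings: list[str] = field(default_factory=list, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("utility_pfs", "utility_pd", "utility_death"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must be in [0, 1], got {v!r}")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ConfigError(f"discount_rate: must be in [0, 1), got {self.discount_rate!r}")
        if int(self.horizon_cycles) != self.horizon_cycles or self.horizon_cycles < 1:
            raise ConfigError(f"horizon_cycles: must be a positive integer, got {self.horizon_cycles!r}")
        if self.wtp <= 0:
            raise ConfigError(f"wtp: must be > 0, got {self.wtp!r}")
        if self.precision not in ("derived", "fixture"):
            raise ConfigError(f"precision: must be 'derived' or 'fixture', got {self.precision!r}")
        for key in ARM_KEYS:
            arm: ArmConfig = getattr(self, key)
            for name in ("cost_pfs_per_cycle", "cost_pd_per_cycle", "cost_death"):
                v = getattr(arm, name)
                if v < 0:
                    raise ConfigError(f"{key}.{name}: must be >= 0, got {v!r}")
            arm.clinical_inputs()  # raises on invalid medians
            if self.precision == "fixture" and not arm.printed_probabilities:
                raise ConfigError(
                    f"{key}.printed_probabilities: required when precision='fixture'"
                )
        if self.sensitivity.n_iter < 1:
            raise ConfigError(f"sensitivity.n_iter: must be >= 1, got {self.sensitivity.n_iter!r}")
        if self.sensitivity.cost_sd_fraction < 0:
            raise ConfigError(
                f"sensitivity.cost_sd_fraction: must be >= 0, got {self.sensitivity.cost_sd_fraction!r}"
            )
        self.sensitivity.wtp_grid.values()

    def economic_inputs(self, arm_key: str) -> EconomicInputs:
        arm: ArmConfig = getattr(self, arm_key)
        return EconomicInputs(
            cost_pfs_per_cycle=arm.cost_pfs_per_cycle,
            cost_pd_per_cycle=arm.cost_pd_per_cycle,
            cost_death=arm.cost_death,
            utility_pfs=self.utility_pfs,
            utility_pd=self.utility_pd,
            utility_death=self.utility_death,
            annual_discount_rate=self.discount_rate,
            wtp=self.wtp,
        )


# ---------------------------------------------------------------------------
# (de)serialization


def _arm_to_dict(arm: ArmConfig) -> dict[str, Any]:
    d: dict[str, Any] = {
        "label": arm.label,
        "median_pfs": arm.median_pfs,
        "median_os": arm.median_os,
        "cost_pfs_per_cycle": arm.cost_pfs_per_cycle,
        "cost_pd_per_cycle": arm.cost_pd_per_cycle,
        "cost_death": arm.cost_death,
    }
    if arm.printed_probabilities:
        d["printed_probabilities"] = {
            name: {"base": r.base, "low": r.low, "high": r.high}
            for name, r in arm.printed_probabilities.items()
        }
    return d


def to_dict(config: ModelConfiguration) -> dict[str, Any]:
    """Serialize a configuration to the plain-dict schema (YAML/JSON-ready)."""
    return {
        "arms": {key: _arm_to_dict(getattr(config, key)) for key in ARM_KEYS},
        "global": {
            "utility_pfs": config.utility_pfs,
            "utility_pd": config.utility_pd,
            "utility_death": config.utility_death,
            "discount_rate": config.discount_rate,
            "horizon_cycles": config.horizon_cycles,
            "wtp": config.wtp,
            "half_cycle": config.half_cycle,
            "precision": config.precision,
        },
        "sensitivity": {
            "n_iter": config.sensitivity.n_iter,
            "cost_sd_fraction": config.sensitivity.cost_sd_fraction,
            "wtp_grid": {
                "start": config.sensitivity.wtp_grid.start,
                "stop": config.sensitivity.wtp_grid.stop,
                "step": config.sensitivity.wtp_grid.step,
            },
        },
    }


def _require(mapping: dict[str, Any], key: str, context: str) -> Any:
    if key not in mapping:
        raise ConfigError(f"{context}.{key}: required field is missing")
    return mapping[key]


def _warn_unknown(mapping: dict[str, Any], known: tuple[str, ...], context: str,
                  warnings: list[str]) -> None:
    for key in mapping:
        if key not in known:
            warnings.append(f"{context}.{key}: unknown key ignored")


def _arm_from_dict(d: dict[str, Any], context: str, warnings: list[str]) -> ArmConfig:
    if not isinstance(d, dict):
        raise ConfigError(f"{context}: must be a mapping")
    known = ("label", "median_pfs", "median_os", "cost_pfs_per_cycle",
             "cost_pd_per_cycle", "cost_death", "printed_probabilities")
    _warn_unknown(d, known, context, warnings)
    printed = None
    if d.get("printed_probabilities"):
        printed = {}
        table = d["printed_probabilities"]
        for name, entry in table.items():
            if name not in _PRINTED_KEYS:
                warnings.append(f"{context}.printed_probabilities.{name}: unknown transition ignored")
                continue
            try:
                printed[name] = ParamRange(
                    name=name,
                    base=float(entry["base"]),
                    low=float(entry.get("low", entry["base"])),
                    high=float(entry.get("high", entry["base"])),
                )
            except (KeyError, TypeError) as exc:
                raise ConfigError(
                    f"{context}.printed_probabilities.{name}: needs base/low/high numbers"
                ) from exc
            for bound in ("base", "low", "high"):
                v = getattr(printed[name], bound)
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(
                        f"{context}.printed_probabilities.{name}.{bound}: must be in [0, 1], got {v!r}"
                    )
        # warn once per row whose printed probabilities do not sum to 1
        rows = {
            "PFS": ("p_pfs_pfs", "p_pfs_pd", "p_pfs_death"),
            "PD": ("p_pd_pd", "p_pd_death"),
        }
        for row, names in rows.items():
            if all(n in printed for n in names):
                total = sum(printed[n].base for n in names)
                if abs(total - 1.0) > 1e-6:
                    warnings.append(
                        f"{context}: printed {row} row sums to {total:.6g}, not 1; the "
                        "stay probability will be renormalized by complement when used"
                    )
    return ArmConfig(
        label=str(_require(d, "label", context)),
        median_pfs=float(_require(d, "median_pfs", context)),
        median_os=float(_require(d, "median_os", context)),
        cost_pfs_per_cycle=float(_require(d, "cost_pfs_per_cycle", context)),
        cost_pd_per_cycle=float(_require(d, "cost_pd_per_cycle", context)),
        cost_death=float(d.get("cost_death", 0.0)),
        printed_probabilities=printed,
    )


def from_dict(data: dict[str, Any]) -> ModelConfiguration:
    """Build and validate a configuration from the plain-dict schema.

    Unknown keys produce warnings (collected on ``config.warnings``), not
    errors; missing optional fields are filled with documented defaults
    (horizon 120 cycles, discount 0.05, WTP 35,906, utilities 0.89/0.74).
    """
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    warnings: list[str] = []
    _warn_unknown(data, ("arms", "global", "sensitivity"), "config", warnings)
    arms = _require(data, "arms", "config")
    if not isinstance(arms, dict):
        raise ConfigError("config.arms: must be a mapping")
    _warn_unknown(arms, ARM_KEYS, "config.arms", warnings)
    for key in ARM_KEYS:
        _require(arms, key, "config.arms")

    g = data.get("global", {}) or {}
    known_global = ("utility_pfs", "utility_pd", "utility_death", "discount_rate",
                    "horizon_cycles", "wtp", "half_cycle", "precision")
    _warn_unknown(g, known_global, "config.global", warnings)
    s = data.get("sensitivity", {}) or {}
    _warn_unknown(s, ("n_iter", "cost_sd_fraction", "wtp_grid"), "config.sensitivity", warnings)
    grid = s.get("wtp_grid", {}) or {}
    _warn_unknown(grid, ("start", "stop", "step"), "config.sensitivity.wtp_grid", warnings)

    config = ModelConfiguration(
        intervention=_arm_from_dict(arms["intervention"], "config.arms.intervention", warnings),
        comparator=_arm_from_dict(arms["comparator"], "config.arms.comparator", warnings),
        utility_pfs=float(g.get("utility_pfs", 0.89)),
        utility_pd=float(g.get("utility_pd", 0.74)),
        utility_death=float(g.get("utility_death", 0.0)),
        discount_rate=float(g.get("discount_rate", 0.05)),
        horizon_cycles=int(g.get("horizon_cycles", 120)),
        wtp=float(g.get("wtp", 35_906.0)),
        half_cycle=bool(g.get("half_cycle", False)),
        precision=str(g.get("precision", "derived")),
        sensitivity=SensitivityConfig(
            n_iter=int(s.get("n_iter", 1000)),
            cost_sd_fraction=float(s.get("cost_sd_fraction", 0.25)),
            wtp_grid=WTPGrid(
                start=float(grid.get("start", 0.0)),
                stop=float(grid.get("stop", 150_000.0)),
                step=float(grid.get("step", 1_500.0)),
            ),
        ),
    )
    config.warnings = warnings
    return config


def load_config(path: str | Path) -> ModelConfiguration:
    """Load and validate a YAML or JSON configuration file.

    The format is chosen by suffix (``.json`` vs anything else = YAML;
    YAML is a JSON superset, so either parses).  Loader warnings are
    available on the returned object's ``warnings`` attribute.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return from_dict(data)


def save_config(config: ModelConfiguration, path: str | Path) -> None:
    """Write a configuration to YAML (or JSON when the suffix is .json)."""
    path = Path(path)
    data = to_dict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# packaged glioblastoma fixture

FIXTURE_RESOURCE = "glioblastoma_bev_lom.yaml"

#: documented default dosing assumptions behind the fixture's drug costs
DOSING_DEFAULTS: dict[str, float] = {
    "body_weight_kg": 65.0,
    "body_surface_area_m2": 1.72,
    "bev_dose_mg_per_kg": 10.0,
    "bev_administrations_per_trial_cycle": 3.0,  # q2w within a 6-week cycle
    "bev_vial_mg": 100.0,
    "bev_vial_usd": 209.50,
    "lom_dose_mg_per_m2_combination": 90.0,
    "lom_dose_mg_per_m2_mono": 110.0,
    "lom_max_dose_mg": 200.0,
    "lom_capsule_mg": 40.0,
    "lom_capsule_usd": 3.25,
    "trial_cycle_days": 42.0,
    "model_cycle_days": 365.25 / 12.0,
}


def drug_cost_per_model_cycle(
    unit_price_usd: float,
    unit_size_mg: float,
    dose_mg: float,
    administrations_per_trial_cycle: float = 1.0,
    trial_cycle_days: float = 42.0,
    model_cycle_days: float = 365.25 / 12.0,
) -> float:
    """Drug acquisition cost per monthly model cycle.

    Whole units (vials/capsules) are billed per administration
    (``ceil(dose/unit)``); the per-trial-cycle cost is rescaled to the
    model cycle by the day-length ratio.
    """
    units = math.ceil(dose_mg / unit_size_mg - 1e-9)
    per_trial_cycle = unit_price_usd * units * administrations_per_trial_cycle
    return per_trial_cycle * model_cycle_days / trial_cycle_days


def fixture_drug_costs(dosing: dict[str, float] | None = None) -> dict[str, float]:
    """Monthly drug costs implied by the fixture's dosing defaults.

    Returns ``{"bev_monthly": ..., "lom_monthly_combination": ...,
    "lom_monthly_mono": ...}`` in USD per model cycle.
    """
    d = dict(DOSING_DEFAULTS)
    if dosing:
        d.update(dosing)
    bev = drug_cost_per_model_cycle(
        d["bev_vial_usd"], d["bev_vial_mg"],
        d["bev_dose_mg_per_kg"] * d["body_weight_kg"],
        d["bev_administrations_per_trial_cycle"],
        d["trial_cycle_days"], d["model_cycle_days"],
    )
    lom_comb = drug_cost_per_model_cycle(
        d["lom_capsule_usd"], d["lom_capsule_mg"],
        min(d["lom_dose_mg_per_m2_combination"] * d["body_surface_area_m2"], d["lom_max_dose_mg"]),
        1.0, d["trial_cycle_days"], d["model_cycle_days"],
    )
    lom_mono = drug_cost_per_model_cycle(
        d["lom_capsule_usd"], d["lom_capsule_mg"],
        min(d["lom_dose_mg_per_m2_mono"] * d["body_surface_area_m2"], d["lom_max_dose_mg"]),
        1.0, d["trial_cycle_days"], d["model_cycle_days"],
    )
    return {
        "bev_monthly": bev,
        "lom_monthly_combination": lom_comb,
        "lom_monthly_mono": lom_mono,
    }


def fixture_path() -> Path:
    """Filesystem path of the packaged glioblastoma configuration."""
    return Path(str(resources.files("markovcea").joinpath("data", FIXTURE_RESOURCE)))


def load_fixture() -> ModelConfiguration:
    """Load the packaged progressive-glioblastoma BEV+LOM vs LOM fixture."""
    return load_config(fixture_path())
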