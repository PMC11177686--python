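"""Synthetic trial data and random model configurations.

The cohort model assumes constant hazards, so individual-level event
times consistent with it are exponential: PFS times with rate
``ln(2)/median_pfs`` and post-progression survival with rate
``ln(2)/(median_os - median_pfs)``, overall survival being their sum.
Generating such arms and re-estimating medians closes the loop
data -> medians -> transition probabilities for end-to-end recovery
tests.  Random structurally-valid configurations support fuzzing the
whole pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ArmConfig, ModelConfiguration, SensitivityConfig, WTPGrid
from .params import ArmClinicalInputs, InvalidInputError


@dataclass
class SyntheticTrialArm:
    """Individual-level event times for one simulated trial arm."""

    arm_label: str
    n_patients: int
    true_median_pfs: float
    true_median_os: float
    pfs_times: np.ndarray
    os_times: np.ndarray

    def __post_init__(self) -> None:
        self.pfs_times = np.asarray(self.pfs_times, dtype=float)
        self.os_times = np.asarray(self.os_times, dtype=float)
        if self.n_patients < 1 or len(self.pfs_times) != self.n_patients:
            raise InvalidInputError("arm must contain n_patients >= 1 event-time pairs")
        if np.any(self.pfs_times <= 0) or np.any(self.os_times < self.pfs_times):
            raise InvalidInputError("event times must be positive with os_time >= pfs_time")


def generate_trial_arm(
    rng_seed: int | np.random.Generator,
    n: int,
    median_pfs: float,
    median_os: float,
    arm_label: str = "arm",
) -> SyntheticTrialArm:
    """Simulate one trial arm of exponential progression and survival times.

    PFS times are exponential with median ``median_pfs``; post-progression
    survival is exponential with median ``median_os - median_pfs`` and is
    added to the progression time, so every patient's OS exceeds their PFS.
    """
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    if median_pfs <= 0 or median_os <= median_pfs:
        raise InvalidInputError(
            f"need 0 < median_pfs < median_os, got ({median_pfs}, {median_os})"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    ln2 = math.log(2.0)
    pfs = rng.exponential(scale=median_pfs / ln2, size=n)
    post = rng.exponential(scale=(median_os - median_pfs) / ln2, size=n)
    return SyntheticTrialArm(
        arm_label=arm_label,
        n_patients=n,
        true_median_pfs=median_pfs,
        true_median_os=median_os,
        pfs_times=pfs,
        os_times=pfs + post,
    )


def estimate_medians(arm: SyntheticTrialArm) -> ArmClinicalInputs:
    """Median-based clinical inputs from patient-level times (no censoring).

    ``median_pfs`` is the sample median of the progression times.  The
    transition derivation consumes the *post-progression* median
    (``median_os - median_pfs``), and the median of a sum of exponentials
    exceeds the sum of their medians, so the raw sample median of the OS
    times would bias the PD->Death hazard downward.  The post-progression
    median is therefore estimated directly from ``os - pfs`` and
    ``median_os`` reconstructed additively, which makes the
    data -> medians -> probabilities chain consistent with the model's
    constant-hazard decomposition.
    """
    if arm.n_patients < 1:
        raise InvalidInputError("cannot estimate medians from an empty arm")
    median_pfs = float(np.median(arm.pfs_times))
    median_post = float(np.median(arm.os_times - arm.pfs_times))
    return ArmClinicalInputs(
        arm_label=arm.arm_label,
        median_pfs=median_pfs,
        median_os=median_pfs + median_post,
    )


def trial_to_frame(*arms: SyntheticTrialArm) -> pd.DataFrame:
    """Patient-level table (patient_id, pfs_months, os_months, arm)."""
    frames = []
    offset = 0
    for arm in arms:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.arange(offset, offset + arm.n_patients),
                    "pfs_months": arm.pfs_times,
                    "os_months": arm.os_times,
                    "arm": arm.arm_label,
                }
            )
        )
        offset += arm.n_patients
    return pd.concat(frames, ignore_index=True)


@dataclass
class ConfigConstraints:
    """Uniform sampling bounds for :func:`generate_random_config`.

    Each field is an inclusive ``(low, high)`` interval; pin a value by
    setting ``low == high``.  Default bounds keep every draw structurally
    valid: with ``median_pfs >= 1`` and a post-progression gap ``>= 0.5``
    month the derived PFS exit probabilities can never sum above 1.
    """

    median_pfs: tuple[float, float] = (1.0, 12.0)
    os_minus_pfs: tuple[float, float] = (0.5, 12.0)
    cost_pfs_per_cycle: tuple[float, float] = (100.0, 5000.0)
    cost_pd_per_cycle: tuple[float, float] = (50.0, 1000.0)
    utility_pfs: tuple[float, float] = (0.6, 0.95)
    utility_pd: tuple[float, float] = (0.4, 0.9)
    discount_rate: tuple[float, float] = (0.0, 0.08)
    wtp: tuple[float, float] = (10_000.0, 150_000.0)
    horizon_cycles: tuple[int, int] = (120, 120)
    labels: tuple[str, str] = ("intervention", "comparator")
    #: optional per-arm interval overrides for the arm-level fields, keyed
    #: by "intervention"/"comparator" (e.g. to pin the two arms differently)
    per_arm: dict[str, dict[str, tuple[float, float]]] | None = None

    _ARM_FIELDS = ("median_pfs", "os_minus_pfs", "cost_pfs_per_cycle", "cost_pd_per_cycle")

    def arm_interval(self, arm_key: str, name: str) -> tuple[float, float]:
        if self.per_arm and name in self.per_arm.get(arm_key, {}):
            return self.per_arm[arm_key][name]
        return getattr(self, name)

    def __post_init__(self) -> None:
        for name in (
            "median_pfs", "os_minus_pfs", "cost_pfs_per_cycle", "cost_pd_per_cycle",
            "utility_pfs", "utility_pd", "discount_rate", "wtp", "horizon_cycles",
        ):
            low, high = getattr(self, name)
            if low > high:
                raise InvalidInputError(f"constraints.{name}: low {low} > high {high}")
        for arm_key, fields in (self.per_arm or {}).items():
            for name, (low, high) in fields.items():
                if name not in self._ARM_FIELDS:
                    raise InvalidInputError(f"constraints.per_arm.{arm_key}.{name}: unknown field")
                if low > high:
                    raise InvalidInputError(
                        f"constraints.per_arm.{arm_key}.{name}: low {low} > high {high}"
                    )


def _draw(rng: np.random.Generator, interval: tuple[float, float]) -> float:
    low, high = interval
    return low if low == high else float(rng.uniform(low, high))


def generate_random_config(
    rng_seed: int | np.random.Generator,
    constraints: ConfigConstraints | None = None,
) -> ModelConfiguration:
    """Draw a structurally valid two-arm configuration within constraints.

    Arm medians, per-cycle costs, utilities, discount rate and WTP are
    drawn uniformly and independently within the constraint intervals
    (utility_pd is additionally capped at the drawn utility_pfs so the
    progressed state is never preferred).  The result always loads and
    evaluates without error.
    """
    c = constraints or ConfigConstraints()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    arms = {}
    for key, label in zip(("intervention", "comparator"), c.labels):
        median_pfs = _draw(rng, c.arm_interval(key, "median_pfs"))
        median_os = median_pfs + _draw(rng, c.arm_interval(key, "os_minus_pfs"))
        arms[key] = ArmConfig(
            label=label,
            median_pfs=median_pfs,
            median_os=median_os,
            cost_pfs_per_cycle=_draw(rng, c.arm_interval(key, "cost_pfs_per_cycle")),
            cost_pd_per_cycle=_draw(rng, c.arm_interval(key, "cost_pd_per_cycle")),
        )
    utility_pfs = _draw(rng, c.utility_pfs)
    utility_pd = min(_draw(rng, c.utility_pd), utility_pfs)
    return ModelConfiguration(
        intervention=arms["intervention"],
        comparator=arms["comparator"],
        utility_pfs=utility_pfs,
        utility_pd=utility_pd,
        discount_rate=_draw(rng, c.discount_rate),
        horizon_cycles=int(_draw(rng, c.horizon_cycles)),
        wtp=_draw(rng, c.wtp),
        sensitivity=SensitivityConfig(wtp_grid=WTPGrid()),
    )


def fixture_constraints() -> ConfigConstraints:
    """Constraints pinned to the packaged glioblastoma fixture's values."""
    return ConfigConstraints(
        utility_pfs=(0.89, 0.89),
        utility_pd=(0.74, 0.74),
        discount_rate=(0.05, 0.05),
        wtp=(35_906.0, 35_906.0),
        labels=("BEV+LOM", "LOM"),
        per_arm={
            "intervention": {
                "median_pfs": (4.2, 4.2),
                "os_minus_pfs": (4.9, 4.9),
                "cost_pfs_per_cycle": (3665.95, 3665.95),
                "cost_pd_per_cycle": (227.03, 227.03),
            },
            "comparator": {
                "median_pfs": (1.5, 1.5),
                "os_minus_pfs": (7.1, 7.1),
                "cost_pfs_per_cycle": (470.85, 470.85),
                "cost_pd_per_cycle": (227.03, 227.03),
            },
        },
    )
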