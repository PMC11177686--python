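"""End-to-end evaluation of a model configuration.

Glue between the configuration schema and the numerical modules: derive
(or load) each arm's transition probabilities, build matrices, run the
cohort trace, accrue discounted costs/QALYs, and compare the arms.
Sensitivity analyses re-enter through the ``overrides`` mapping, which
replaces named parameters (dotted names such as
``"intervention.p_pfs_pd"`` or ``"utility_pd"``) without mutating the
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

from .config import ARM_KEYS, ModelConfiguration
from .economics import CEAComparison, compare
from .engine import ArmResult, CohortTrace, accrue, run_cohort
from .params import (
    InvalidInputError,
    TransitionMatrix,
    TransitionProbabilities,
    build_matrix,
    derive_arm_transitions,
)

#: probability parameters recognised per arm in overrides/sensitivity
PROB_PARAMS = ("p_pfs_pd", "p_pfs_death", "p_pd_death")
#: cost parameters recognised per arm
COST_PARAMS = ("cost_pfs_per_cycle", "cost_pd_per_cycle")
#: global utility parameters
UTILITY_PARAMS = ("utility_pfs", "utility_pd")


def parameter_names(config: ModelConfiguration) -> list[str]:
    """All override-able parameter names for this configuration."""
    names = [f"{arm}.{p}" for arm in ARM_KEYS for p in PROB_PARAMS]
    names += [f"{arm}.{c}" for arm in ARM_KEYS for c in COST_PARAMS]
    names += list(UTILITY_PARAMS)
    return names


def base_parameter_values(config: ModelConfiguration) -> dict[str, float]:
    """Base value of every override-able parameter (respects precision mode)."""
    values: dict[str, float] = {}
    for arm_key in ARM_KEYS:
        tp = base_exit_probs(config, arm_key)
        for p in PROB_PARAMS:
            values[f"{arm_key}.{p}"] = tp[p]
        arm = getattr(config, arm_key)
        for c in COST_PARAMS:
            values[f"{arm_key}.{c}"] = getattr(arm, c)
    for u in UTILITY_PARAMS:
        values[u] = getattr(config, u)
    return values


def base_exit_probs(config: ModelConfiguration, arm_key: str) -> dict[str, float]:
    """The arm's three exit probabilities under the configured precision mode."""
    arm = getattr(config, arm_key)
    if config.precision == "fixture":
        printed = arm.printed_probabilities or {}
        missing = [p for p in PROB_PARAMS if p not in printed]
        if missing:
            raise InvalidInputError(
                f"{arm_key}: precision='fixture' needs printed probabilities {missing}"
            )
        return {p: printed[p].base for p in PROB_PARAMS}
    tp = derive_arm_transitions(arm.clinical_inputs())
    return {p: getattr(tp, p) for p in PROB_PARAMS}


@dataclass
class ArmEvaluation:
    """Intermediate products of evaluating one arm."""

    label: str
    transitions: TransitionProbabilities
    matrix: TransitionMatrix
    trace: CohortTrace
    result: ArmResult


@dataclass
class PipelineResult:
    """Everything one configuration evaluation produced."""

    intervention: ArmEvaluation
    comparator: ArmEvaluation
    comparison: CEAComparison
    notes: list[str]

    def arm(self, key: str) -> ArmEvaluation:
        return getattr(self, key)


def evaluate(
    config: ModelConfiguration,
    overrides: Mapping[str, float] | None = None,
    clamp: bool = False,
) -> PipelineResult:
    """Run the full pipeline: transitions -> trace -> accrual -> comparison.

    Parameters
    ----------
    config
        Validated model configuration.
    overrides
        Optional replacement values for named parameters (see
        :func:`parameter_names`); unknown names raise.
    clamp
        When True, a PFS row whose overridden exit probabilities exceed 1
        is rescaled proportionally to sum to 1 (stay probability 0) and
        flagged in the result's notes instead of raising; used by
        deterministic sensitivity analysis.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - set(parameter_names(config))
    if unknown:
        raise InvalidInputError(f"unknown override parameter(s): {sorted(unknown)}")

    notes: list[str] = []
    arm_evals: dict[str, ArmEvaluation] = {}
    for arm_key in ARM_KEYS:
        exits = base_exit_probs(config, arm_key)
        for p in PROB_PARAMS:
            key = f"{arm_key}.{p}"
            if key in overrides:
                v = float(overrides[key])
                if not 0.0 <= v <= 1.0:
                    raise InvalidInputError(f"{key}: probability override must be in [0, 1], got {v!r}")
                exits[p] = v
        exit_pfs = exits["p_pfs_pd"] + exits["p_pfs_death"]
        if exit_pfs > 1.0 and clamp:
            scale = 1.0 / exit_pfs
            notes.append(
                f"{arm_key}: PFS exit probabilities summed to {exit_pfs:.6g} > 1; "
                f"rescaled proportionally to sum to 1"
            )
            exits["p_pfs_pd"] *= scale
            exits["p_pfs_death"] *= scale
        if config.precision == "fixture":
            # keep the printed stay probabilities so build_matrix's
            # complement policy records any renormalization (e.g. a
            # published row summing to 0.99) as a provenance note
            printed = getattr(config, arm_key).printed_probabilities
            tp = TransitionProbabilities(
                p_pfs_pd=exits["p_pfs_pd"],
                p_pfs_death=exits["p_pfs_death"],
                p_pd_death=exits["p_pd_death"],
                p_pfs_pfs=printed["p_pfs_pfs"].base,
                p_pd_pd=printed["p_pd_pd"].base,
            )
        else:
            tp = TransitionProbabilities.from_exit_probs(
                exits["p_pfs_pd"], exits["p_pfs_death"], exits["p_pd_death"]
            )
        matrix = build_matrix(tp)
        notes.extend(f"{arm_key}: {n}" for n in matrix.notes)

        econ = config.economic_inputs(arm_key)
        econ_kwargs = {}
        for c in COST_PARAMS:
            key = f"{arm_key}.{c}"
            if key in overrides:
                econ_kwargs[c] = float(overrides[key])
        for u in UTILITY_PARAMS:
            if u in overrides:
                econ_kwargs[u] = float(overrides[u])
        if econ_kwargs:
            econ = replace(econ, **econ_kwargs)

        trace = run_cohort(matrix, n_cycles=config.horizon_cycles)
        result = accrue(trace, econ, half_cycle=config.half_cycle)
        arm_evals[arm_key] = ArmEvaluation(
            label=getattr(config, arm_key).label,
            transitions=tp,
            matrix=matrix,
            trace=trace,
            result=result,
        )

    comparison = compare(
        arm_evals["intervention"].result, arm_evals["comparator"].result, wtp=config.wtp
    )
    return PipelineResult(
        intervention=arm_evals["intervention"],
        comparator=arm_evals["comparator"],
        comparison=comparison,
        notes=notes,
    )
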