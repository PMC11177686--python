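"""Deterministic (tornado) and probabilistic (Monte-Carlo) sensitivity analysis.

One-way DSA re-runs the full pipeline at each parameter's low and high
bound, holding everything else at base.  PSA draws every parameter from
its distribution — Beta for probabilities and utilities (moments matched
to the base value with the low/high range read as a 95% interval), Gamma
for costs (mean = base, SD = a configurable fraction of the mean) — and
re-evaluates the pipeline per draw.  CEACs report, per willingness-to-pay
value, the fraction of draws in which the intervention has positive
incremental net monetary benefit.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelConfiguration
from .params import InvalidInputError, ParamRange
from .pipeline import (
    COST_PARAMS,
    PROB_PARAMS,
    UTILITY_PARAMS,
    base_parameter_values,
    evaluate,
    parameter_names,
)


def _param_kind(name: str) -> str:
    leaf = name.rsplit(".", 1)[-1]
    if leaf in PROB_PARAMS:
        return "probability"
    if leaf in COST_PARAMS:
        return "cost"
    if leaf in UTILITY_PARAMS:
        return "utility"
    raise InvalidInputError(f"unknown parameter {name!r}")


def default_ranges(
    config: ModelConfiguration, relative_spread: float = 0.20
) -> list[ParamRange]:
    """DSA ranges for every parameter of the configuration.

    Probability parameters take the published lower/upper limits from the
    arm's printed-probability table when available (widened minimally if
    the model's base value falls outside them); parameters without
    published limits get ±``relative_spread`` around base, clamped to the
    valid domain ([0, 1] for probabilities and utilities, >= 0 for costs).
    """
    base = base_parameter_values(config)
    ranges = []
    for name in parameter_names(config):
        b = base[name]
        kind = _param_kind(name)
        low = high = None
        if kind == "probability":
            arm_key, leaf = name.split(".", 1)
            printed = getattr(config, arm_key).printed_probabilities or {}
            if leaf in printed:
                low, high = printed[leaf].low, printed[leaf].high
        if low is None:
            low, high = b * (1 - relative_spread), b * (1 + relative_spread)
            if kind in ("probability", "utility"):
                high = min(high, 1.0)
        low, high = min(low, b), max(high, b)
        ranges.append(ParamRange(name=name, base=b, low=low, high=high))
    return ranges


@dataclass(frozen=True)
class DSARow:
    """One tornado row: the pipeline re-run at a parameter's bounds.

    ``icer_at_low``/``icer_at_high`` are signed ICERs; because the ICER is
    unstable around delta_qalys = 0 (and sign-flips under dominance), the
    rows also carry the incremental net monetary benefit at the
    configured WTP, whose span is the tornado's ranking metric.
    """

    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float
    nmb_at_low: float
    nmb_at_high: float
    notes: tuple[str, ...] = ()

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)

    @property
    def nmb_span(self) -> float:
        return abs(self.nmb_at_high - self.nmb_at_low)


def one_way_dsa(
    config: ModelConfiguration, ranges: list[ParamRange] | None = None
) -> list[DSARow]:
    """One-way deterministic sensitivity analysis over parameter ranges.

    Each parameter is set to its low and high bound in turn (all else at
    base) and the full pipeline re-run.  Bounds that push a transition
    row's exit mass above 1 are clamped to validity and flagged on the
    row, never dropped.  Rows are sorted by incremental-NMB span,
    descending.
    """
    if ranges is None:
        ranges = default_ranges(config)
    rows = []
    for r in ranges:
        results = {}
        row_notes: list[str] = []
        for bound, value in (("low", r.low), ("high", r.high)):
            res = evaluate(config, overrides={r.name: value}, clamp=True)
            results[bound] = res.comparison
            row_notes.extend(f"{bound}: {n}" for n in res.notes if "rescaled" in n)
        rows.append(
            DSARow(
                parameter=r.name,
                low=r.low,
                high=r.high,
                icer_at_low=results["low"].icer,
                icer_at_high=results["high"].icer,
                nmb_at_low=results["low"].incremental_nmb,
                nmb_at_high=results["high"].incremental_nmb,
                notes=tuple(row_notes),
            )
        )
    rows.sort(key=lambda row: row.nmb_span, reverse=True)
    return rows


def dsa_to_frame(rows: list[DSARow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "low": r.low,
                "high": r.high,
                "icer_low": r.icer_at_low,
                "icer_high": r.icer_at_high,
                "icer_span": r.span,
                "inmb_low": r.nmb_at_low,
                "inmb_high": r.nmb_at_high,
                "inmb_span": r.nmb_span,
                "notes": "; ".join(r.notes),
            }
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


def _beta_params(mean: float, sd: float) -> tuple[float, float] | None:
    """Method-of-moments Beta(a, b); None when infeasible (variance too large)."""
    if not 0.0 < mean < 1.0:
        return None
    v = sd * sd
    if v <= 0 or v >= mean * (1.0 - mean):
        return None
    common = mean * (1.0 - mean) / v - 1.0
    return mean * common, (1.0 - mean) * common


def sample_params(
    config: ModelConfiguration,
    rng: np.random.Generator,
    dist_policy: str = "default",
    ranges: list[ParamRange] | None = None,
) -> dict[str, float]:
    """Draw one PSA parameter set, as an overrides mapping.

    ``dist_policy="default"``: Beta for probabilities/utilities with
    moments matched to base and SD = (high - low)/3.92 (the low/high
    range read as a 95% interval; infeasible matches fall back to
    uniform(low, high) with a warning), Gamma for costs with mean = base
    and SD = ``sensitivity.cost_sd_fraction`` * mean.
    ``dist_policy="degenerate"``: every parameter at its base value.
    """
    if dist_policy not in ("default", "degenerate"):
        raise InvalidInputError(f"unknown dist_policy {dist_policy!r}")
    if ranges is None:
        ranges = default_ranges(config)
    base = base_parameter_values(config)
    draw: dict[str, float] = {}
    for r in ranges:
        b = base[r.name]
        if dist_policy == "degenerate":
            draw[r.name] = b
            continue
        kind = _param_kind(r.name)
        if kind == "cost":
            sd_frac = config.sensitivity.cost_sd_fraction
            if b <= 0 or sd_frac == 0:
                draw[r.name] = b
            else:
                shape = 1.0 / (sd_frac * sd_frac)
                draw[r.name] = float(rng.gamma(shape, b / shape))
        else:
            sd = (r.high - r.low) / 3.92
            if sd == 0:
                draw[r.name] = b
                continue
            ab = _beta_params(b, sd)
            if ab is None:
                _warnings.warn(
                    f"{r.name}: Beta moment matching infeasible (mean {b:.4g}, "
                    f"sd {sd:.4g}); falling back to uniform({r.low:.4g}, {r.high:.4g})",
                    stacklevel=2,
                )
                draw[r.name] = float(rng.uniform(r.low, r.high))
            else:
                draw[r.name] = float(rng.beta(*ab))
    return draw


@dataclass(frozen=True)
class PSADraw:
    """One Monte-Carlo iteration: the sampled parameters and its increments."""

    draw_index: int
    sampled_params: dict[str, float]
    delta_cost: float
    delta_qalys: float
    icer: float
    decision: str


@dataclass
class PSAResult:
    """All PSA draws plus bookkeeping (resampling of invalid rows, failures)."""

    draws: list[PSADraw]
    n_rejected: int = 0
    failures: list[str] = field(default_factory=list)


def run_psa(
    config: ModelConfiguration,
    n_iter: int | None = None,
    rng_seed: int | None = None,
    dist_policy: str = "default",
    ranges: list[ParamRange] | None = None,
) -> PSAResult:
    """Probabilistic sensitivity analysis: ``n_iter`` full pipeline runs.

    Draws whose sampled PFS exit probabilities sum above 1 are rejected
    and resampled (count reported); draws that fail evaluation for any
    other reason are recorded as failures and never abort the batch.
    Reproducible given ``rng_seed``.
    """
    if n_iter is None:
        n_iter = config.sensitivity.n_iter
    if rng_seed is None:
        raise InvalidInputError("rng_seed is required for probabilistic analysis")
    if ranges is None:
        ranges = default_ranges(config)
    rng = np.random.default_rng(rng_seed)
    result = PSAResult(draws=[])
    for i in range(n_iter):
        for _attempt in range(1000):
            sampled = sample_params(config, rng, dist_policy=dist_policy, ranges=ranges)
            exit_ok = all(
                sampled.get(f"{arm}.p_pfs_pd", 0.0) + sampled.get(f"{arm}.p_pfs_death", 0.0)
                <= 1.0
                for arm in ("intervention", "comparator")
            )
            if exit_ok:
                break
            result.n_rejected += 1
        else:
            result.failures.append(f"draw {i}: could not sample a valid parameter set")
            continue
        try:
            res = evaluate(config, overrides=sampled)
        except InvalidInputError as exc:
            result.failures.append(f"draw {i}: {exc}")
            continue
        c = res.comparison
        result.draws.append(
            PSADraw(
                draw_index=i,
                sampled_params=sampled,
                delta_cost=c.delta_cost,
                delta_qalys=c.delta_qalys,
                icer=c.icer,
                decision=c.decision,
            )
        )
    return result


def psa_to_frame(result: PSAResult) -> pd.DataFrame:
    """Tabulate PSA draws (CE-plane scatter data plus sampled parameters)."""
    records = []
    for d in result.draws:
        rec = {
            "draw": d.draw_index,
            "delta_cost": d.delta_cost,
            "delta_qalys": d.delta_qalys,
            "icer": d.icer,
            "decision": d.decision,
        }
        rec.update(d.sampled_params)
        records.append(rec)
    return pd.DataFrame(records)


@dataclass(frozen=True)
class CEACPoint:
    """Probability the intervention is cost-effective at one WTP value."""

    wtp: float
    prob_cost_effective: float


def ceac(draws: list[PSADraw], wtp_grid: list[float]) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over a WTP grid.

    Per grid value lambda, the fraction of draws with positive
    incremental net monetary benefit, ``lambda * dE - dC > 0``.
    """
    if not draws:
        raise InvalidInputError("ceac requires at least one PSA draw")
    if not len(wtp_grid):
        raise InvalidInputError("ceac requires a non-empty WTP grid")
    de = np.array([d.delta_qalys for d in draws])
    dc = np.array([d.delta_cost for d in draws])
    return [
        CEACPoint(wtp=float(w), prob_cost_effective=float(np.mean(w * de - dc > 0)))
        for w in wtp_grid
    ]


def ceac_to_frame(points: list[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {"wtp": [p.wtp for p in points],
         "prob_cost_effective": [p.prob_cost_effective for p in points]}
    )


def not_cost_effective_fraction(draws: list[PSADraw], wtp: float) -> float:
    """Fraction of draws in which the intervention is *not* cost-effective.

    A draw counts when its incremental NMB at ``wtp`` is non-positive —
    equivalently ICER above the threshold whenever delta_qalys > 0, and
    always for draws where the intervention is dominated.
    """
    if not draws:
        raise InvalidInputError("requires at least one PSA draw")
    return float(
        np.mean([wtp * d.delta_qalys - d.delta_cost <= 0 for d in draws])
    )


def icer_percentile_positive_effect(draws: list[PSADraw], q: float) -> float:
    """Percentile ``q`` (0-100) of the ICER among draws with delta_qalys > 0."""
    icers = [d.icer for d in draws if d.delta_qalys > 0 and math.isfinite(d.icer)]
    if not icers:
        raise InvalidInputError("no draws with positive incremental effectiveness")
    return float(np.percentile(icers, q))
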