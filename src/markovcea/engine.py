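"""Monthly-cycle Markov cohort simulation with discounted cost/QALY accrual.

A cohort starts fully in the PFS state and is propagated through a
row-stochastic transition matrix once per monthly cycle over a fixed
horizon (120 cycles = 10 years by default).  Costs accrue per state per
cycle; utilities are per-year weights converted to per-cycle weights by
division by 12.  Both are discounted at an annual rate ``r`` with the
continuous-equivalent monthly factor ``d(t) = (1 + r)**(-t/12)``.

Accrual convention: by default, cycle ``t`` (t = 1..N) accrues the state
membership *at* cycle t; cycle 0 — the decision point — accrues nothing.
The optional half-cycle correction instead accrues the average of the
entry (t-1) and exit (t) occupancy of each cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .params import STATES, InvalidInputError, TransitionMatrix


class UnsupportedStructureError(ValueError):
    """The matrix does not have the PFS/PD/Death topology the closed forms assume."""


@dataclass(frozen=True)
class EconomicInputs:
    """Per-state costs, utilities, discounting and the decision threshold.

    Costs are USD per monthly cycle of state membership; utilities are
    QALY weights per *year* of state membership (divided by 12 per cycle).
    """

    cost_pfs_per_cycle: float
    cost_pd_per_cycle: float
    cost_death: float = 0.0
    utility_pfs: float = 0.89
    utility_pd: float = 0.74
    utility_death: float = 0.0
    annual_discount_rate: float = 0.05
    wtp: float = 35906.0

    def __post_init__(self) -> None:
        for name in ("utility_pfs", "utility_pd", "utility_death"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name}: must be in [0, 1], got {v!r}")
        for name in ("cost_pfs_per_cycle", "cost_pd_per_cycle", "cost_death"):
            v = getattr(self, name)
            if v < 0 or math.isnan(v):
                raise InvalidInputError(f"{name}: must be >= 0, got {v!r}")
        if not 0.0 <= self.annual_discount_rate < 1.0:
            raise InvalidInputError(
                f"annual_discount_rate: must be in [0, 1), got {self.annual_discount_rate!r}"
            )

    @property
    def state_costs(self) -> np.ndarray:
        return np.array([self.cost_pfs_per_cycle, self.cost_pd_per_cycle, self.cost_death])

    @property
    def state_utilities(self) -> np.ndarray:
        return np.array([self.utility_pfs, self.utility_pd, self.utility_death])


@dataclass
class CohortTrace:
    """State occupancy fractions per cycle, rows 0..n_cycles."""

    occupancy: np.ndarray
    states: tuple[str, str, str] = STATES

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.ndim != 2 or self.occupancy.shape[1] != 3:
            raise InvalidInputError(
                f"occupancy must be (n_cycles+1, 3), got shape {self.occupancy.shape}"
            )

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def pfs(self) -> np.ndarray:
        return self.occupancy[:, 0]

    @property
    def pd(self) -> np.ndarray:
        return self.occupancy[:, 1]

    @property
    def death(self) -> np.ndarray:
        return self.occupancy[:, 2]


def discount_factors(n_cycles: int, annual_rate: float) -> np.ndarray:
    """Monthly discount factors d(t) = (1+r)^(-t/12) for t = 1..n_cycles."""
    t = np.arange(1, n_cycles + 1, dtype=float)
    return (1.0 + annual_rate) ** (-t / 12.0)


def run_cohort(
    matrix: TransitionMatrix,
    n_cycles: int = 120,
    init: Sequence[float] | None = None,
) -> CohortTrace:
    """Propagate the cohort occupancy vector through the transition matrix.

    Parameters
    ----------
    matrix
        Validated monthly transition matrix.
    n_cycles
        Number of monthly cycles; the trace includes cycle 0, so it has
        ``n_cycles + 1`` rows.
    init
        Initial occupancy over (PFS, PD, Death); defaults to ``[1, 0, 0]``
        (the whole cohort progression-free at the decision point).
    """
    matrix.validate()
    if n_cycles < 1:
        raise InvalidInputError(f"n_cycles must be >= 1, got {n_cycles}")
    v = np.array([1.0, 0.0, 0.0]) if init is None else np.asarray(init, dtype=float)
    if v.shape != (3,) or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
        raise InvalidInputError(f"init must be a non-negative 3-vector summing to 1, got {v!r}")
    occ = np.empty((n_cycles + 1, 3))
    occ[0] = v
    m = matrix.entries
    for t in range(n_cycles):
        occ[t + 1] = occ[t] @ m
    return CohortTrace(occupancy=occ)


@dataclass(frozen=True)
class ArmResult:
    """Discounted totals and per-state decomposition for one arm."""

    total_cost: float
    total_qalys: float
    cost_by_state: dict[str, float]
    qalys_by_state: dict[str, float]

    def __post_init__(self) -> None:
        if abs(self.total_cost - sum(self.cost_by_state.values())) > 1e-9:
            raise InvalidInputError("total_cost does not equal the sum of cost_by_state")
        if abs(self.total_qalys - sum(self.qalys_by_state.values())) > 1e-9:
            raise InvalidInputError("total_qalys does not equal the sum of qalys_by_state")


def accrue(trace: CohortTrace, econ: EconomicInputs, half_cycle: bool = False) -> ArmResult:
    """Accrue discounted costs and QALYs over a cohort trace.

    Cycle ``t`` in 1..N contributes ``occupancy · state_cost · d(t)`` to
    costs and ``occupancy · (state_utility/12) · d(t)`` to QALYs, where
    the occupancy is the membership at cycle t (default) or the average of
    cycles t-1 and t (``half_cycle=True``).
    """
    n = trace.n_cycles
    d = discount_factors(n, econ.annual_discount_rate)
    occ = trace.occupancy
    w = 0.5 * (occ[:-1] + occ[1:]) if half_cycle else occ[1:]
    weighted = w * d[:, None]  # (N, 3) discounted person-cycles
    person_cycles = weighted.sum(axis=0)
    costs = person_cycles * econ.state_costs
    qalys = person_cycles * econ.state_utilities / 12.0
    return ArmResult(
        total_cost=float(costs.sum()),
        total_qalys=float(qalys.sum()),
        cost_by_state={s: float(c) for s, c in zip(trace.states, costs)},
        qalys_by_state={s: float(q) for s, q in zip(trace.states, qalys)},
    )


def _chain_params(matrix: TransitionMatrix) -> tuple[float, float, float]:
    """Extract (stay_pfs, stay_pd, p_pfs_pd), checking the assumed topology."""
    m = matrix.entries
    if abs(m[1, 0]) > 1e-12 or not np.allclose(m[2], [0, 0, 1], atol=1e-12):
        raise UnsupportedStructureError(
            "closed forms require PD->PFS = 0 and an absorbing Death state"
        )
    return float(m[0, 0]), float(m[1, 1]), float(m[0, 1])


def expected_state_time_closed_form(
    matrix: TransitionMatrix,
    state: str,
    monthly_discount: float = 1.0,
    n_cycles: int | None = None,
) -> float:
    """Discounted expected months in a state, by analytic occupancy formulas.

    Independent of :func:`run_cohort`: occupancy at cycle t is written in
    closed form for a cohort starting in PFS —

    * ``PFS(t) = p**t`` (geometric), with ``p`` the PFS stay probability,
    * ``PD(t)  = f * (q**t - p**t) / (q - p)`` (convolution of geometric
      sojourns; ``f * t * p**(t-1)`` when ``q == p``), with ``q`` the PD
      stay probability and ``f`` the PFS->PD probability,
    * ``Death(t) = 1 - PFS(t) - PD(t)``,

    and summed with weight ``delta**t`` for t = 1..N (the default accrual
    convention).  ``n_cycles=None`` sums the infinite series in closed
    form (PFS and PD only).
    """
    p, q, f = _chain_params(matrix)
    delta = float(monthly_discount)
    if not 0.0 < delta <= 1.0:
        raise InvalidInputError(f"monthly_discount must be in (0, 1], got {delta!r}")
    if state not in STATES:
        raise InvalidInputError(f"unknown state {state!r}; expected one of {STATES}")

    if n_cycles is None:
        if state == "PFS":
            x = p * delta
            return x / (1.0 - x) if x < 1.0 else math.inf
        if state == "PD":
            if p * delta >= 1.0 or q * delta >= 1.0:
                return math.inf
            return f * delta / ((1.0 - delta * p) * (1.0 - delta * q))
        # Death: infinite occupancy sum unless discounted.
        if delta == 1.0:
            raise UnsupportedStructureError(
                "expected time in the absorbing Death state diverges without "
                "discounting; pass a finite n_cycles"
            )
        g = delta / (1.0 - delta)
        pfs = expected_state_time_closed_form(matrix, "PFS", delta)
        pd_ = expected_state_time_closed_form(matrix, "PD", delta)
        return g - pfs - pd_

    t = np.arange(1, n_cycles + 1, dtype=float)
    disc = delta**t
    pfs_t = p**t
    if abs(q - p) > 1e-12:
        pd_t = f * (q**t - p**t) / (q - p)
    else:
        pd_t = f * t * p ** (t - 1)
    if state == "PFS":
        series = pfs_t
    elif state == "PD":
        series = pd_t
    else:
        series = 1.0 - pfs_t - pd_t
    return float(np.dot(series, disc))


def trace_to_frame(trace: CohortTrace, annual_discount_rate: float) -> pd.DataFrame:
    """Tabulate a trace with its per-cycle discount factor."""
    n = trace.n_cycles
    d = np.concatenate([[1.0], discount_factors(n, annual_discount_rate)])
    return pd.DataFrame(
        {
            "cycle": np.arange(n + 1),
            "pfs": trace.pfs,
            "pd": trace.pd,
            "death": trace.death,
            "discount_factor": d,
        }
    )


def arm_result_to_frame(result: ArmResult, arm_label: str) -> pd.DataFrame:
    """Tabulate an ArmResult: by-state and total discounted cost and QALYs."""
    rows = [
        {
            "arm": arm_label,
            "component": s,
            "cost_usd": result.cost_by_state[s],
            "qalys": result.qalys_by_state[s],
        }
        for s in result.cost_by_state
    ]
    rows.append(
        {
            "arm": arm_label,
            "component": "total",
            "cost_usd": result.total_cost,
            "qalys": result.total_qalys,
        }
    )
    return pd.DataFrame(rows, columns=["arm", "component", "cost_usd", "qalys"])
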