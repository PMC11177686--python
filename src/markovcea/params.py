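"""Transition-probability derivation for a three-state oncology Markov model.

The model has states PFS (progression-free survival), PD (progressed
disease) and Death.  Monthly transition probabilities are derived from
median time-to-event estimates under a constant-hazard assumption:

    P(event within one cycle) = 1 - 0.5**(1/m) = 1 - exp(-ln(2)/m)

where ``m`` is the median time to event in cycles (months).  The three
hazards are mapped as

* PFS -> PD     from the median progression-free survival,
* PFS -> Death  from the median overall survival,
* PD  -> Death  from the post-progression median (median OS - median PFS),

and the stay probabilities are the complements of the exit probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

STATES: tuple[str, str, str] = ("PFS", "PD", "Death")

#: Names of the five per-arm monthly transition probabilities.
TRANSITION_NAMES: tuple[str, ...] = (
    "p_pfs_pfs",
    "p_pfs_pd",
    "p_pfs_death",
    "p_pd_pd",
    "p_pd_death",
)


class InvalidInputError(ValueError):
    """A clinical or economic input violates its domain constraints."""


def _check_median(value: float, fieldname: str) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise InvalidInputError(f"{fieldname}: must be a number, got {value!r}") from None
    if math.isnan(value) or value <= 0:
        raise InvalidInputError(f"{fieldname}: must be > 0 months, got {value!r}")
    return value


def monthly_prob_from_median(median: float, fieldname: str = "median") -> float:
    """Monthly event probability from a median time-to-event in months.

    Evaluates ``1 - 0.5**(1/median)``, the per-cycle event probability of
    an exponential time-to-event distribution with the given median
    (equivalently ``1 - exp(-R)`` with rate ``R = ln(2)/median``).

    Parameters
    ----------
    median
        Median time to event in months; must be > 0.  ``inf`` is allowed
        and encodes "the event never occurs" (probability 0).
    fieldname
        Name used in the error message when the input is invalid.
    """
    median = _check_median(median, fieldname)
    if math.isinf(median):
        return 0.0
    return 1.0 - 0.5 ** (1.0 / median)


@dataclass(frozen=True)
class ArmClinicalInputs:
    """Per-arm clinical efficacy inputs: median PFS and OS in months."""

    arm_label: str
    median_pfs: float
    median_os: float

    def __post_init__(self) -> None:
        _check_median(self.median_pfs, "median_pfs")
        _check_median(self.median_os, "median_os")
        if self.median_os < self.median_pfs:
            raise InvalidInputError(
                f"median_os ({self.median_os}) must be >= median_pfs ({self.median_pfs})"
            )


@dataclass(frozen=True)
class TransitionProbabilities:
    """The five monthly transition probabilities of one treatment arm.

    Stay probabilities are normally the complements of the exit
    probabilities; externally supplied (e.g. printed, rounded) values may
    violate that identity, which :func:`build_matrix` repairs under its
    normalization policy.
    """

    p_pfs_pd: float
    p_pfs_death: float
    p_pd_death: float
    p_pfs_pfs: float
    p_pd_pd: float

    def __post_init__(self) -> None:
        for name in TRANSITION_NAMES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or math.isnan(v):
                raise InvalidInputError(f"{name}: probability must be in [0, 1], got {v!r}")

    @classmethod
    def from_exit_probs(
        cls, p_pfs_pd: float, p_pfs_death: float, p_pd_death: float
    ) -> "TransitionProbabilities":
        """Build a consistent set from exit probabilities (stays = complements)."""
        if p_pfs_pd + p_pfs_death > 1.0 + 1e-12:
            raise InvalidInputError(
                "PFS exit probabilities sum to "
                f"{p_pfs_pd + p_pfs_death:.6f} > 1; cannot form a valid row"
            )
        return cls(
            p_pfs_pd=p_pfs_pd,
            p_pfs_death=p_pfs_death,
            p_pd_death=p_pd_death,
            p_pfs_pfs=max(0.0, 1.0 - p_pfs_pd - p_pfs_death),
            p_pd_pd=1.0 - p_pd_death,
        )

    def is_consistent(self, tol: float = 1e-9) -> bool:
        """True when the stay probabilities equal the exit complements."""
        return (
            abs(self.p_pfs_pfs - (1.0 - self.p_pfs_pd - self.p_pfs_death)) <= tol
            and abs(self.p_pd_pd - (1.0 - self.p_pd_death)) <= tol
        )


def derive_arm_transitions(arm: ArmClinicalInputs) -> TransitionProbabilities:
    """Derive the five monthly transition probabilities from arm medians.

    PFS->PD uses the median PFS, PFS->Death the median OS, and PD->Death
    the post-progression median ``median_os - median_pfs``.  Stay
    probabilities are complements, computed at full floating-point
    precision.

    Raises
    ------
    InvalidInputError
        If finite ``median_os <= median_pfs`` (the post-progression hazard
        is undefined), or if the two PFS exit probabilities exceed 1.
    """
    p_pfs_pd = monthly_prob_from_median(arm.median_pfs, "median_pfs")
    p_pfs_death = monthly_prob_from_median(arm.median_os, "median_os")
    if math.isinf(arm.median_os):
        p_pd_death = 0.0
    else:
        post_progression = arm.median_os - arm.median_pfs
        if post_progression <= 0:
            raise InvalidInputError(
                f"median_os ({arm.median_os}) must exceed median_pfs "
                f"({arm.median_pfs}): PD->Death hazard undefined"
            )
        p_pd_death = monthly_prob_from_median(post_progression, "median_os - median_pfs")
    return TransitionProbabilities.from_exit_probs(p_pfs_pd, p_pfs_death, p_pd_death)


@dataclass
class TransitionMatrix:
    """A validated 3x3 row-stochastic monthly transition matrix.

    Row/column order is ``(PFS, PD, Death)``.  Death is absorbing and
    PD->PFS is structurally zero (progression is irreversible).  ``notes``
    records any normalization applied to externally supplied rows.
    """

    entries: np.ndarray
    states: tuple[str, str, str] = STATES
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        self.validate()

    def validate(self, tol: float = 1e-12) -> None:
        m = self.entries
        if m.shape != (3, 3):
            raise InvalidInputError(f"transition matrix must be 3x3, got shape {m.shape}")
        if np.any(m < -tol) or np.any(m > 1 + tol):
            raise InvalidInputError("transition matrix entries must be in [0, 1]")
        rowsums = m.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-12):
            raise InvalidInputError(f"transition matrix rows must sum to 1, got {rowsums}")
        if not np.allclose(m[2], [0.0, 0.0, 1.0], atol=tol):
            raise InvalidInputError("Death row must be [0, 0, 1] (absorbing)")
        if abs(m[1, 0]) > tol:
            raise InvalidInputError("PD->PFS must be 0 (progression is irreversible)")


def build_matrix(
    tp: TransitionProbabilities, policy: str = "complement"
) -> TransitionMatrix:
    """Assemble a validated transition matrix from per-arm probabilities.

    Parameters
    ----------
    tp
        The five monthly probabilities; exit probabilities carry the
        clinical signal, stay probabilities may be inconsistent (e.g. a
        printed, rounded row that sums to 0.99).
    policy
        ``"complement"`` (default) recomputes each stay probability as the
        complement of the row's exit probabilities, recording a provenance
        note when this changes a supplied value by more than 1e-12.
        ``"strict"`` raises instead of repairing.

    Raises
    ------
    InvalidInputError
        If a row's exit probabilities sum to more than 1 (no complement
        exists), or if ``policy="strict"`` and a row is inconsistent.
    """
    if policy not in ("complement", "strict"):
        raise InvalidInputError(f"unknown normalization policy {policy!r}")
    exit_pfs = tp.p_pfs_pd + tp.p_pfs_death
    if exit_pfs > 1.0 + 1e-12:
        raise InvalidInputError(
            f"PFS exit probabilities sum to {exit_pfs:.6f} > 1; cannot normalize by complement"
        )
    notes: list[str] = []
    stay_pfs = max(0.0, 1.0 - exit_pfs)
    stay_pd = 1.0 - tp.p_pd_death
    if abs(stay_pfs - tp.p_pfs_pfs) > 1e-12:
        msg = (
            f"PFS row sums to {tp.p_pfs_pfs + exit_pfs:.6g}; stay probability "
            f"p_pfs_pfs recomputed as complement: {tp.p_pfs_pfs:.6g} -> {stay_pfs:.6g}"
        )
        if policy == "strict":
            raise InvalidInputError(msg)
        notes.append(msg)
    if abs(stay_pd - tp.p_pd_pd) > 1e-12:
        msg = (
            f"PD row sums to {tp.p_pd_pd + tp.p_pd_death:.6g}; stay probability "
            f"p_pd_pd recomputed as complement: {tp.p_pd_pd:.6g} -> {stay_pd:.6g}"
        )
        if policy == "strict":
            raise InvalidInputError(msg)
        notes.append(msg)
    entries = np.array(
        [
            [stay_pfs, tp.p_pfs_pd, tp.p_pfs_death],
            [0.0, stay_pd, tp.p_pd_death],
            [0.0, 0.0, 1.0],
        ]
    )
    return TransitionMatrix(entries=entries, notes=notes)


@dataclass(frozen=True)
class ParamRange:
    """A parameter with its base value and deterministic sensitivity range."""

    name: str
    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise InvalidInputError(
                f"{self.name}: range must satisfy low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )


def transitions_to_frame(
    transitions: Mapping[str, TransitionProbabilities],
    source: str = "derived",
) -> pd.DataFrame:
    """Tabulate per-arm transition probabilities (arm, transition, value, source)."""
    rows = [
        {"arm": arm, "transition": name, "value": getattr(tp, name), "source": source}
        for arm, tp in transitions.items()
        for name in TRANSITION_NAMES
    ]
    return pd.DataFrame(rows, columns=["arm", "transition", "value", "source"])
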