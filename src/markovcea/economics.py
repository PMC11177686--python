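"""Incremental cost-effectiveness comparison of two treatment arms.

Computes incremental cost and effectiveness (intervention minus
comparator), the ICER, per-arm cost-effectiveness ratios and net monetary
benefit (NMB = WTP * QALYs - cost), and the decision against a
willingness-to-pay threshold.  Dominance replaces the ICER when the
increments have opposite favourable signs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .engine import ArmResult
from .params import InvalidInputError

_EPS = 1e-12


@dataclass(frozen=True)
class CEAComparison:
    """Result of comparing an intervention against a comparator arm.

    ``icer`` is the signed ratio delta_cost/delta_qalys (``inf``/``-inf``
    when delta_qalys is 0 with nonzero delta_cost, ``nan`` when both are
    0); ``dominance`` flags the quadrants where the ICER is not a
    meaningful decision statistic.
    """

    delta_cost: float
    delta_qalys: float
    icer: float
    dominance: str | None
    decision: str
    wtp: float
    nmb_intervention: float
    nmb_comparator: float
    ce_ratio_intervention: float
    ce_ratio_comparator: float

    @property
    def incremental_nmb(self) -> float:
        """NMB of the intervention minus NMB of the comparator."""
        return self.nmb_intervention - self.nmb_comparator


def net_monetary_benefit(result: ArmResult, wtp: float) -> float:
    """NMB = WTP * QALYs - cost for one arm."""
    return wtp * result.total_qalys - result.total_cost


def signed_icer(delta_cost: float, delta_qalys: float) -> float:
    """delta_cost / delta_qalys with signed-infinity conventions at zero."""
    if abs(delta_qalys) > _EPS:
        return delta_cost / delta_qalys
    if abs(delta_cost) <= _EPS:
        return math.nan
    return math.copysign(math.inf, delta_cost)


def compare(intervention: ArmResult, comparator: ArmResult, wtp: float) -> CEAComparison:
    """Compare two arm results at a willingness-to-pay threshold.

    The intervention is *dominant* when it is at least as cheap and more
    effective (or cheaper and at least as effective), *dominated* in the
    mirror case, and *equivalent* when both increments are zero.  It is
    judged cost-effective when it dominates or when delta_qalys > 0 and
    ICER < WTP.
    """
    if wtp <= 0:
        raise InvalidInputError(f"wtp must be > 0, got {wtp!r}")
    dc = intervention.total_cost - comparator.total_cost
    de = intervention.total_qalys - comparator.total_qalys
    icer = signed_icer(dc, de)

    dominance: str | None = None
    if abs(dc) <= _EPS and abs(de) <= _EPS:
        decision = "equivalent"
    elif de >= -_EPS and dc <= _EPS:
        dominance, decision = "dominant", "dominant"
    elif de <= _EPS and dc >= -_EPS:
        dominance, decision = "dominated", "dominated"
    elif de > 0:
        decision = "cost-effective" if icer < wtp else "not-cost-effective"
    else:
        # Southwest quadrant: cheaper but less effective; by convention the
        # intervention is not adopted on effectiveness grounds.
        decision = "not-cost-effective"

    return CEAComparison(
        delta_cost=dc,
        delta_qalys=de,
        icer=icer,
        dominance=dominance,
        decision=decision,
        wtp=wtp,
        nmb_intervention=net_monetary_benefit(intervention, wtp),
        nmb_comparator=net_monetary_benefit(comparator, wtp),
        ce_ratio_intervention=signed_icer(intervention.total_cost, intervention.total_qalys),
        ce_ratio_comparator=signed_icer(comparator.total_cost, comparator.total_qalys),
    )


def comparison_to_frame(
    intervention: ArmResult,
    comparator: ArmResult,
    comparison: CEAComparison,
    labels: tuple[str, str] = ("intervention", "comparator"),
) -> pd.DataFrame:
    """Tabulate the comparison in the conventional CEA report layout."""
    int_label, comp_label = labels
    rows = [
        ("costs_pfs_usd", intervention.cost_by_state["PFS"], comparator.cost_by_state["PFS"]),
        ("costs_pd_usd", intervention.cost_by_state["PD"], comparator.cost_by_state["PD"]),
        ("qalys_pfs", intervention.qalys_by_state["PFS"], comparator.qalys_by_state["PFS"]),
        ("qalys_pd", intervention.qalys_by_state["PD"], comparator.qalys_by_state["PD"]),
        ("total_costs_usd", intervention.total_cost, comparator.total_cost),
        ("total_qalys", intervention.total_qalys, comparator.total_qalys),
        ("incremental_costs_usd", comparison.delta_cost, None),
        ("incremental_qalys", comparison.delta_qalys, None),
        ("ce_ratio_usd_per_qaly", comparison.ce_ratio_intervention, comparison.ce_ratio_comparator),
        ("icer_usd_per_qaly", comparison.icer, None),
        ("nmb_usd", comparison.nmb_intervention, comparison.nmb_comparator),
        ("decision", comparison.decision, None),
    ]
    return pd.DataFrame(rows, columns=["quantity", int_label, comp_label])
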