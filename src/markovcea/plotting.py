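"""Static figure export: CEAC, tornado diagram, CE-plane scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .sensitivity import CEACPoint, DSARow, PSADraw


def plot_ceac(points: list[CEACPoint], path: str | Path, wtp: float | None = None) -> None:
    """Cost-effectiveness acceptability curve."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot([p.wtp for p in points], [p.prob_cost_effective for p in points], lw=1.5)
    if wtp is not None:
        ax.axvline(wtp, color="grey", ls="--", lw=1, label=f"WTP = ${wtp:,.0f}/QALY")
        ax.legend(frameon=False)
    ax.set_xlabel("Willingness to pay (USD/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(rows: list[DSARow], path: str | Path, max_rows: int = 15) -> None:
    """Tornado diagram of incremental NMB at the low/high parameter bounds."""
    rows = rows[:max_rows][::-1]  # widest at the top
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(rows) + 1.5))
    for i, r in enumerate(rows):
        lo, hi = sorted((r.nmb_at_low, r.nmb_at_high))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878d0")
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels([r.parameter for r in rows], fontsize=8)
    ax.set_xlabel("Incremental net monetary benefit (USD)")
    ax.axvline(0, color="k", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_psa_scatter(draws: list[PSADraw], path: str | Path, wtp: float | None = None) -> None:
    """Incremental cost-effectiveness plane scatter of PSA draws."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(
        [d.delta_qalys for d in draws],
        [d.delta_cost for d in draws],
        s=6,
        alpha=0.4,
        edgecolors="none",
    )
    if wtp is not None:
        xs = sorted(d.delta_qalys for d in draws)
        ax.plot(xs, [wtp * x for x in xs], "--", color="grey", lw=1,
                label=f"WTP = ${wtp:,.0f}/QALY")
        ax.legend(frameon=False)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("Incremental effectiveness (QALYs)")
    ax.set_ylabel("Incremental cost (USD)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
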