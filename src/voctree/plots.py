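"""Optional matplotlib figures: acceptability curves and tornado diagrams."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .uncertainty import CEACPoint, TornadoReport

__all__ = ["plot_ceac", "plot_tornado"]


def plot_ceac(points: Sequence[CEACPoint], path: str | Path, title: str = "") -> None:
    """Probability cost-effective (and dominant) against willingness to pay."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    wtp = [p.wtp for p in points]
    ax.plot(wtp, [p.probability_cost_effective for p in points], label="cost-effective")
    ax.plot(wtp, [p.probability_dominant for p in points], "--", label="dominant")
    ax.set_xlabel("willingness to pay (QAR per pain crisis averted)")
    ax.set_ylabel("probability")
    ax.set_ylim(-0.02, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(report: TornadoReport, path: str | Path, top: int = 15) -> None:
    """Horizontal bars of standardized regression coefficients, largest first."""
    entries = report.entries[:top][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * max(len(entries), 4) + 1.5))
    ax.barh(
        [e.parameter for e in entries],
        [e.standardized_coefficient for e in entries],
        color=["tab:red" if e.standardized_coefficient < 0 else "tab:blue" for e in entries],
    )
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel(f"standardized coefficient on {report.output} ({report.comparison})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
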