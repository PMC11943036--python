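"""Figure helpers: cumulative-incidence curves and their difference."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["risk_curve_figure"]


def risk_curve_figure(curves: pd.DataFrame, risk_difference: pd.DataFrame | None = None,
                      reference: str = ""):
    """Two-panel figure: per-strategy CI(t) (A) and their difference (B).

    ``curves`` needs columns strategy/day/cumulative_incidence and optionally
    lo/hi bands; ``risk_difference`` needs day/rd and optionally lo/hi.
    """
    n_panels = 2 if risk_difference is not None else 1
    fig, axes = plt.subplots(1, n_panels, figsize=(6 * n_panels, 4.5), squeeze=False)
    ax = axes[0][0]
    for s, grp in curves.groupby("strategy", sort=False):
        line, = ax.plot(grp["day"], grp["cumulative_incidence"], label=s)
        if {"lo", "hi"}.issubset(grp.columns):
            ax.fill_between(grp["day"], grp["lo"], grp["hi"], alpha=0.2,
                            color=line.get_color())
    ax.set_xlabel("days since referral")
    ax.set_ylabel("cumulative incidence of successful extubation")
    ax.set_ylim(0, 1)
    ax.legend()
    ax.set_title("A")

    if risk_difference is not None:
        ax = axes[0][1]
        ax.plot(risk_difference["day"], risk_difference["rd"], color="k")
        if {"lo", "hi"}.issubset(risk_difference.columns):
            ax.fill_between(risk_difference["day"], risk_difference["lo"],
                            risk_difference["hi"], alpha=0.2, color="k")
        ax.axhline(0.0, lw=0.8, ls="--", color="grey")
        ax.set_xlabel("days since referral")
        label = f"risk difference (ref. {reference})" if reference else "risk difference"
        ax.set_ylabel(label)
        ax.set_title("B")
    fig.tight_layout()
    return fig
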