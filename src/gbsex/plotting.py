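"""Static rendering of the sex-assignment plot (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .containers import FEMALE, MALE

__all__ = ["render_gender_plot"]

_COLOURS = {MALE: "tab:blue", FEMALE: "tab:red", "U": "0.5"}


def render_gender_plot(
    points: pd.DataFrame, curves: pd.DataFrame, path: str | Path, colour_by: str = "recorded"
) -> None:
    """Scatter M_y*P_Y against H with the two decision boundaries.

    ``colour_by`` selects the label column used for colours ('recorded'
    or 'predicted').
    """
    fig, ax = plt.subplots(figsize=(6, 5))
    for label, sub in points.groupby(colour_by, sort=True):
        ax.scatter(
            sub["H"],
            sub["y"],
            s=14,
            alpha=0.7,
            color=_COLOURS.get(label, "0.5"),
            label={MALE: "male", FEMALE: "female"}.get(label, "unknown/unassigned"),
        )
    ax.plot(curves["H"], curves["male_boundary_y"], "b--", lw=1, label="male boundary")
    ax.plot(curves["H"], curves["female_boundary_y"], "r--", lw=1, label="female boundary")
    if len(points):
        ymax = max(float(points["y"].max()) * 1.05, 1.0)
        ax.set_ylim(-0.5, ymax)
    ax.set_xlabel("adjusted X heterozygosity $H$")
    ax.set_ylabel("non-missing Y SNPs $M_y P_Y$")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
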