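"""Line-plot panels of class means versus population size."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .core import EASY, HARD
from .metrics import MEASURE_NEIGHBOUR, MEASURE_SHARED, MEASURE_SUCCESSFUL

__all__ = ["plot_summary"]

_CLASS_COLOURS = {EASY: "tab:blue", HARD: "tab:red"}
_MODE_STYLES = {"horizontal": "--", "vertical": "-"}


def plot_summary(summary, out_path=None):
    """Five panels: measures (i) and (ii) absolute/relative, plus (iii).

    Easy in blue, Hard in red; dashed lines horizontal transmission, solid
    vertical; one line per (mode, p) condition.  ``summary`` is the
    per-condition mean table from :func:`iapsim.experiment.run_grid`.
    """
    panels = [
        (MEASURE_SUCCESSFUL, "absolute", "historical", "successful / agent"),
        (MEASURE_SUCCESSFUL, "relative", "historical", "successful (relative)"),
        (MEASURE_SHARED, "absolute", "-", "shared by ≥ 10%"),
        (MEASURE_SHARED, "relative", "-", "shared (relative)"),
        (MEASURE_NEIGHBOUR, "absolute", "-", "neighbour sharing"),
    ]
    fig, axes = plt.subplots(3, 2, figsize=(9, 10))
    axes = axes.ravel()
    for ax, (measure, norm, basis, title) in zip(axes, panels):
        sub = summary[
            (summary["measure"] == measure)
            & (summary["normalization"] == norm)
            & (summary["knowledge_basis"] == basis)
        ]
        for (cls, mode, p), grp in sub.groupby(["convention_class", "mode", "p"]):
            grp = grp.sort_values("n")
            ax.plot(
                grp["n"],
                grp["mean"],
                linestyle=_MODE_STYLES.get(mode, "-"),
                marker="o" if p < 1 / 300 else "s",
                color=_CLASS_COLOURS[cls],
                label=f"{cls} {mode} p={p:g}",
                alpha=0.8,
            )
        ax.set_xscale("log")
        ax.set_xlabel("population size n")
        ax.set_title(title)
    axes[0].legend(fontsize=6)
    axes[-1].axis("off")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
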