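"""Plot writers: power-curve panels and PVCA stacked bars.

Matplotlib is imported lazily so headless pipelines that never plot do not
pay for it.
"""

from __future__ import annotations

from .power import PowerCurve
from .pvca import VarianceDecomposition

__all__ = ["plot_power_panel", "plot_pvca_bars"]

_REPLICATE_COLORS = {2: "tab:blue", 4: "tab:red", 8: "tab:green", 16: "tab:brown"}


def plot_power_panel(curves: list[PowerCurve], ax=None, title: str | None = None):
    """Power vs effect size, one curve per replicate level.

    Mirrors the usual presentation of screening power studies: y axis in
    percent, x axis in sdu, 80% reliability threshold dashed.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    for curve in sorted(curves, key=lambda c: c.replicates):
        color = _REPLICATE_COLORS.get(curve.replicates)
        ax.plot(
            curve.effects,
            100 * curve.power,
            marker="o",
            ms=3,
            color=color,
            label=f"{curve.replicates} replicates",
        )
    ax.axhline(80, ls="--", lw=0.8, color="grey")
    ax.set_xlabel("effect size (sdu)")
    ax.set_ylabel("power (%)")
    ax.set_ylim(0, 100)
    if title is None and curves:
        title = f"{curves[0].scenario} (alpha={curves[0].alpha})"
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax


def plot_pvca_bars(decomp: VarianceDecomposition, ax=None):
    """Stacked horizontal bar of variance proportions per factor."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 1.8))
    left = 0.0
    items = sorted(decomp.proportions.items(), key=lambda kv: -kv[1])
    for name, frac in items:
        ax.barh([0], [100 * frac], left=left, label=f"{name} ({100 * frac:.1f}%)")
        left += 100 * frac
    ax.set_xlim(0, 100)
    ax.set_yticks([])
    ax.set_xlabel(
        f"% of variance in first {decomp.n_pcs_used} PCs "
        f"({100 * decomp.pc_variance_captured:.1f}% of total)"
    )
    ax.legend(fontsize=7, ncol=2, loc="upper center", bbox_to_anchor=(0.5, -0.4))
    return ax
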