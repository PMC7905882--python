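"""Publication-style plots: mean density curves with CI bands and
significance bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .stats import MeanCurveWithCI

_XLABEL = {
    "density_peaks": "density-peak intensity (clusters / kernel)",
    "nn_distance": "nearest-neighbor distance (nm)",
    "fwhm": "cluster FWHM (nm)",
}


def plot_mean_curves(
    curves: dict[str, MeanCurveWithCI],
    comparisons: list[tuple[tuple[str, str], list[tuple[float, float]]]],
    analysis: str,
    path: str | Path,
) -> None:
    """Mean curve + shaded CI band per condition; bars mark regions of
    significant difference (non-overlapping bands) per pairwise
    comparison below the curves."""
    fig, ax = plt.subplots(figsize=(5, 3.4))
    for cond, mc in sorted(curves.items()):
        (line,) = ax.plot(mc.grid, mc.mean, label=f"{cond} (n={mc.n_cells})")
        ax.fill_between(mc.grid, mc.ci_low, mc.ci_high, alpha=0.25, color=line.get_color())
    ymax = max(float(mc.ci_high.max()) for mc in curves.values()) or 1.0
    for i, (pair, intervals) in enumerate(comparisons):
        y = -0.05 * ymax * (i + 1)
        for lo, hi in intervals:
            ax.plot([lo, hi], [y, y], lw=3, solid_capstyle="butt")
        if intervals:
            ax.annotate(f"{pair[0]} vs {pair[1]}", (intervals[0][0], y),
                        fontsize=6, va="bottom")
    ax.set_xlabel(_XLABEL.get(analysis, analysis))
    ax.set_ylabel("mean probability density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
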