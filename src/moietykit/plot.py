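"""Plot utilities for optimization analyses.

Qualitative views of a repetition ensemble: histograms of optimized
moiety-state parameter values and observed-vs-calculated isotopologue
intensity bars.  Figures are written to file (SVG/PNG); no interactive
backend is assumed.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis import ModelAnalysis
from .modeling import OptimizationResult
from .profile import IsotopologueProfile

__all__ = ["plot_moiety_distribution", "plot_isotopologue_intensity"]


def plot_moiety_distribution(
    result: OptimizationResult,
    parameter_names: Sequence[str],
    path,
    block: Optional[str] = None,
    bins: int = 20,
) -> None:
    """Histogram each fitted parameter's values across repetitions."""
    block = block or next(iter(result.blocks))
    arr = np.array([r.params for r in result.blocks[block]])
    n = arr.shape[1]
    ncols = min(4, n)
    nrows = math.ceil(n / ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.4 * nrows), squeeze=False)
    for i in range(nrows * ncols):
        ax = axes[i // ncols][i % ncols]
        if i >= n:
            ax.axis("off")
            continue
        ax.hist(arr[:, i], bins=bins, range=(0, 1), color="steelblue")
        name = parameter_names[i % len(parameter_names)] if parameter_names else f"p{i}"
        ax.set_title(name, fontsize=8)
        ax.set_xlim(0, 1)
    fig.suptitle(f"{result.model_name} [{block}]: parameter distributions")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_isotopologue_intensity(
    observed: IsotopologueProfile,
    analysis: ModelAnalysis,
    dataset_name: str,
    path,
) -> None:
    """Observed vs mean calculated intensities with repetition spread."""
    stats = analysis.intensity_stats[dataset_name]
    x = np.arange(len(observed.contents))
    fig, ax = plt.subplots(figsize=(max(6, 0.25 * len(x)), 3.5))
    ax.bar(x - 0.2, observed.intensities, width=0.4, label="observed", color="gray")
    ax.bar(
        x + 0.2,
        stats["mean"],
        width=0.4,
        yerr=stats["sd"],
        label="calculated (mean ± sd)",
        color="steelblue",
    )
    labels = [
        ".".join(str(c) for c in content) if len(content) > 1 else str(content[0])
        for content in observed.contents
    ]
    step = max(1, len(x) // 30)
    ax.set_xticks(x[::step])
    ax.set_xticklabels(labels[::step], rotation=90, fontsize=6)
    ax.set_xlabel("isotope content")
    ax.set_ylabel("relative intensity")
    ax.set_title(f"{analysis.model_name} vs {dataset_name}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
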