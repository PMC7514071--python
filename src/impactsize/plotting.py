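"""Density-pair visualization (headless-safe, optional)."""

from __future__ import annotations

import numpy as np

from .core import LabeledSample
from .density import DensityPair


def plot_density_pair(pair: DensityPair, sample: LabeledSample | None = None,
                      path=None, names=("X1", "X2")):
    """Plot both group densities with vertical median markers.

    Saves to ``path`` if given, otherwise returns the figure.  Uses the
    Agg backend so it works without a display.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(pair.grid, pair.pdf1, color="tab:red", label=str(names[0]))
    ax.plot(pair.grid, pair.pdf2, color="tab:blue", label=str(names[1]))
    if sample is not None:
        ax.axvline(float(np.median(sample.x1)), color="green", linestyle="-", linewidth=1)
        ax.axvline(float(np.median(sample.x2)), color="green", linestyle="--", linewidth=1)
    ax.set_xlabel("value")
    ax.set_ylabel(f"PDF ({pair.method.upper()})")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
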