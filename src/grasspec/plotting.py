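"""Minimal diagnostic plotting."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_observed_vs_predicted(
    y: np.ndarray,
    yhat: np.ndarray,
    path: str | Path,
    xlabel: str = "observed",
    ylabel: str = "predicted",
    title: str | None = None,
) -> None:
    """Scatter of cross-validated predictions against observations.

    Draws the one-to-one line; no further styling.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(y, yhat, s=18)
    lo = min(y.min(), yhat.min())
    hi = max(y.max(), yhat.max())
    pad = 0.05 * (hi - lo if hi > lo else 1.0)
    ax.plot([lo - pad, hi + pad], [lo - pad, hi + pad], "k--", linewidth=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
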