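"""QC figures: population gate plots and per-class event galleries."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import EventImage

__all__ = ["population_scatter", "event_gallery"]


def population_scatter(gated: pd.DataFrame, path: str | Path,
                       x_field: str = "calcein_intensity",
                       y_field: str = "draq5_intensity") -> None:
    """Log10 intensity scatter of double positives, coloured by population."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dp = gated[gated["double_positive"]]
    fig, ax = plt.subplots(figsize=(5, 5))
    for pop, sub in dp.groupby("population", dropna=False):
        x = np.log10(np.clip(sub[x_field].to_numpy(float), 1e-9, None))
        y = np.log10(np.clip(sub[y_field].to_numpy(float), 1e-9, None))
        ax.scatter(x, y, s=4, alpha=0.5, label=str(pop))
    ax.set_xlabel(f"log10 {x_field}")
    ax.set_ylabel(f"log10 {y_field}")
    ax.legend(markerscale=3, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def event_gallery(images: Sequence[EventImage], path: str | Path,
                  channels: Optional[Iterable[str]] = None,
                  max_events: int = 8) -> None:
    """Contact sheet: one row per event, one column per channel."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    images = list(images)[:max_events]
    if not images:
        raise ValueError("no images to plot")
    channels = list(channels or images[0].channel_map)
    fig, axes = plt.subplots(len(images), len(channels),
                             figsize=(1.6 * len(channels), 1.6 * len(images)),
                             squeeze=False)
    for i, img in enumerate(images):
        for j, ch in enumerate(channels):
            ax = axes[i][j]
            ax.imshow(img.channel(ch), cmap="gray")
            ax.set_xticks([])
            ax.set_yticks([])
            if i == 0:
                ax.set_title(ch, fontsize=8)
        axes[i][0].set_ylabel(img.event_id, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
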