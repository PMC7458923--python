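"""Figure writers: ordination scatterplots and importance-frequency bars."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .profile_io import SampleMetadata

_SPECIES_COLORS = {"marthae": "#d81b60", "subcristatus": "#fdd835"}
_SEX_MARKERS = {"F": "o", "M": "^"}


def plot_ordination(
    coordinates: np.ndarray,
    meta: SampleMetadata,
    path: Union[str, Path],
    axis_labels: tuple[str, str] = ("axis 1", "axis 2"),
    title: str = "",
) -> None:
    """Scatter the first two ordination axes, colored by species and with
    marker shape by sex."""
    fig, ax = plt.subplots(figsize=(6, 5))
    species = meta["species"].to_numpy()
    sex = meta["sex"].to_numpy()
    for sp, color in _SPECIES_COLORS.items():
        for sx, marker in _SEX_MARKERS.items():
            mask = (species == sp) & (sex == sx)
            if mask.any():
                ax.scatter(
                    coordinates[mask, 0], coordinates[mask, 1],
                    c=color, marker=marker, edgecolors="k", linewidths=0.3,
                    alpha=0.8, label=f"{sp} {sx}",
                )
    ax.set_xlabel(axis_labels[0])
    ax.set_ylabel(axis_labels[1])
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_importance_frequency(
    frequency: dict[str, int], path: Union[str, Path], title: str = ""
) -> None:
    """Bar chart of how often each compound was the top Gini-importance
    variable across protocol runs."""
    items = sorted(frequency.items(), key=lambda kv: (-kv[1], kv[0]))
    names = [k for k, _ in items]
    counts = [v for _, v in items]
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(names)), 4))
    ax.bar(range(len(names)), counts, color="#455a64")
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("runs ranked top by Gini importance")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
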