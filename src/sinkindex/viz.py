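"""Rendering: sink-map heatmaps, scalp topomaps, FT/CPO boxplots.

Topomaps use the standard 10–20 2-D electrode layout (via mne's montage
definitions, with the older temporal-chain names T3/T4/T5/T6 mapped to
their modern equivalents for coordinate lookup only).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .exceptions import ValidationError

_MODERN_NAME = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}


def electrode_positions(labels) -> np.ndarray:
    """2-D scalp positions (head-frame x, y) for 10–20 electrode labels."""
    import mne

    try:
        montage = mne.channels.make_standard_montage("colin27_1020")
    except ValueError:  # older montage naming
        montage = mne.channels.make_standard_montage("standard_1020")
    pos3d = montage.get_positions()["ch_pos"]
    out = []
    for lab in labels:
        key = _MODERN_NAME.get(lab, lab)
        if key not in pos3d:
            raise ValidationError(f"no montage position for channel {lab!r}")
        out.append(pos3d[key][:2])
    return np.asarray(out)


def plot_sink_heatmap(si: np.ndarray, channel_labels, window_duration_ms: float,
                      path=None, title: str = ""):
    """Channel × window sink-index heatmap."""
    fig, ax = plt.subplots(figsize=(10, 4))
    n_win = si.shape[1]
    extent = [0, n_win * window_duration_ms / 1000.0, si.shape[0], 0]
    im = ax.imshow(si, aspect="auto", extent=extent, cmap="viridis")
    ax.set_yticks(np.arange(len(channel_labels)) + 0.5, channel_labels, fontsize=6)
    ax.set_xlabel("time (s)")
    ax.set_title(title or "sink index")
    fig.colorbar(im, ax=ax, label="SI")
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig


def plot_topomap(values: np.ndarray, channel_labels, path=None, title: str = ""):
    """Scalp topomap of per-channel values on the 10–20 layout."""
    import mne

    pos = electrode_positions(channel_labels)
    fig, ax = plt.subplots(figsize=(4, 4))
    im, _ = mne.viz.plot_topomap(values, pos, axes=ax, show=False, cmap="viridis")
    ax.set_title(title)
    fig.colorbar(im, ax=ax)
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig


def plot_region_boxplots(markers: pd.DataFrame, path=None):
    """FT vs CPO mean-SI boxplots per cohort."""
    fig, ax = plt.subplots(figsize=(6, 4))
    groups = sorted(markers["group"].unique())
    data, labels = [], []
    for g in groups:
        sub = markers[markers["group"] == g]
        data += [sub["si_ft"].to_numpy(), sub["si_cpo"].to_numpy()]
        labels += [f"{g}\nFT", f"{g}\nCPO"]
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("mean sink index")
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig


def render_outputs(run_dir) -> list[Path]:
    """Render heatmaps, topomaps and boxplots for a completed run."""
    run_dir = Path(run_dir)
    markers_path = run_dir / "markers.csv"
    sinkmap_dir = run_dir / "sinkmaps"
    if not markers_path.exists() or not sinkmap_dir.exists():
        raise ValidationError(f"{run_dir} is not a completed run directory")
    fig_dir = run_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    written: list[Path] = []

    markers = pd.read_csv(markers_path)
    for tsv in sorted(sinkmap_dir.glob("*.tsv")):
        table = pd.read_csv(tsv, sep="\t", index_col=0)
        si = table.to_numpy()
        labels = list(table.index)
        win_ms = 1000.0 * float(table.columns[1]) if len(table.columns) > 1 else 125.0
        hm = fig_dir / f"{tsv.stem}_heatmap.png"
        plot_sink_heatmap(si, labels, win_ms, hm, title=tsv.stem)
        written.append(hm)
        tm = fig_dir / f"{tsv.stem}_topomap.png"
        plot_topomap(si.mean(axis=1), labels, tm, title=tsv.stem)
        written.append(tm)
    bx = fig_dir / "region_boxplots.png"
    plot_region_boxplots(markers, bx)
    written.append(bx)
    return written
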