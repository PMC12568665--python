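"""Heatmap renderings of the structure features (recurrence, chroma, tempogram)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .complexity import PITCH_CLASSES, ChromaMatrix, RecurrenceMatrix, Tempogram

__all__ = ["plot_recurrence", "plot_chroma", "plot_tempogram", "save_structure_plots"]


def plot_recurrence(rm: RecurrenceMatrix, ax=None, frame_times=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    extent = None
    if frame_times is not None:
        t = np.asarray(frame_times)[rm.kept_frames] / 60.0
        extent = [t[0], t[-1], t[-1], t[0]]
    ax.imshow(rm.similarity, cmap="magma", vmin=0, vmax=1, extent=extent)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("time (min)")
    ax.set_title(f"recurrence similarity ({rm.feature_used})")
    return ax


def plot_chroma(cm: ChromaMatrix, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    t = cm.times_s / 60.0
    ax.imshow(
        cm.energy, aspect="auto", origin="lower", cmap="viridis",
        extent=[t[0], t[-1], -0.5, 11.5],
    )
    ax.set_yticks(range(12), PITCH_CLASSES)
    ax.set_xlabel("time (min)")
    ax.set_title("chroma (constant-Q)")
    return ax


def plot_tempogram(tg: Tempogram, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    t = tg.times_s / 60.0
    extent = None
    if t.size > 1 and t[-1] > t[0]:
        extent = [t[0], t[-1], float(tg.bpm_axis[-1]), float(tg.bpm_axis[0])]
    ax.imshow(
        tg.autocorr, aspect="auto", origin="lower", cmap="coolwarm",
        vmin=-1, vmax=1, extent=extent,
    )
    ax.set_xlabel("time (min)")
    ax.set_ylabel("tempo (BPM)")
    ax.set_title("tempogram (onset autocorrelation)")
    return ax


def save_structure_plots(out_dir, label, rm=None, cm=None, tg=None, frame_times=None):
    """Write PNG heatmaps for whichever features are provided."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for obj, plot, name in (
        (rm, plot_recurrence, "recurrence"),
        (cm, plot_chroma, "chroma"),
        (tg, plot_tempogram, "tempogram"),
    ):
        if obj is None:
            continue
        if name == "recurrence":
            ax = plot(obj, frame_times=frame_times)
        else:
            ax = plot(obj)
        path = out / f"{label}_{name}.png"
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(path)
    return written
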