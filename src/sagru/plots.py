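"""Clarke error grid scatter and CGM trace plots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def clarke_grid_plot(pred, ref, path=None, title="Clarke Error Grid"):
    """Scatter predictions vs reference over the zone boundary lines."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(ref, pred, s=4, alpha=0.4, color="tab:blue")

    # canonical zone boundary segments (x = reference, y = prediction)
    segs = [
        ([0, 400], [0, 400]),            # diagonal
        ([0, 175 / 3], [70, 70]),
        ([175 / 3, 400 / 1.2], [70, 400]),   # y = 1.2 x upper A
        ([70, 400], [56, 320]),          # y = 0.8 x lower A
        ([70, 70], [84, 400]),
        ([0, 70], [180, 180]),
        ([70, 290], [180, 400]),         # y = x + 110
        ([180, 180], [0, 70]),
        ([180, 400], [70, 70]),
        ([240, 240], [70, 180]),
        ([240, 400], [180, 180]),
        ([130, 180], [0, 70]),           # y = (7/5)x - 182
    ]
    for xs, ys in segs:
        ax.plot(xs, ys, color="black", lw=0.8)
    for x, y, z in [(30, 15, "A"), (370, 260, "B"), (280, 370, "C"),
                    (160, 25, "C"), (30, 140, "D"), (370, 120, "D"),
                    (30, 370, "E"), (370, 30, "E")]:
        ax.text(x, y, z, fontsize=12)
    ax.set_xlim(0, 400)
    ax.set_ylim(0, 400)
    ax.set_xlabel("Reference glucose (mg/dL)")
    ax.set_ylabel("Predicted glucose (mg/dL)")
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def trace_plot(series, predictions=None, pred_times=None, path=None):
    """Plot one patient's glucose trace (and optional forecasts) over time."""
    fig, ax = plt.subplots(figsize=(10, 3.5))
    ax.plot(series.timestamps, series.glucose_values, lw=1.0, label="CGM")
    if predictions is not None:
        ax.plot(pred_times, predictions, lw=1.0, ls="--", label="forecast")
    ax.axhline(70, color="tab:red", lw=0.6, ls=":")
    ax.axhline(180, color="tab:orange", lw=0.6, ls=":")
    ax.set_ylabel("glucose (mg/dL)")
    ax.set_title(f"patient {series.patient_id}")
    ax.legend(loc="upper right")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
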