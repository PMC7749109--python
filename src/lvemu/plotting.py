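"""Quick-look plots for traces, stress fields and training histories."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_trace", "plot_pv_loop", "plot_history", "plot_stress_field"]


def _axes(ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    return ax


def plot_trace(trace, ax=None):
    """LV pressure and volume against time on twin axes."""
    ax = _axes(ax)
    ax.plot(trace.time, trace.volume, color="tab:blue", label="volume (ml)")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("volume (ml)", color="tab:blue")
    ax2 = ax.twinx()
    ax2.plot(trace.time, trace.pressure, color="tab:red",
             label="pressure (mmHg)")
    ax2.set_ylabel("pressure (mmHg)", color="tab:red")
    ax.set_title(trace.model_id)
    return ax


def plot_pv_loop(trace, ax=None):
    ax = _axes(ax)
    ax.plot(trace.volume, trace.pressure)
    ax.set_xlabel("volume (ml)")
    ax.set_ylabel("pressure (mmHg)")
    return ax


def plot_history(history, ax=None):
    """Training (and validation, if present) loss curves with the best
    epoch marked."""
    ax = _axes(ax)
    ax.plot(history.train_loss, label="training loss")
    if history.val_loss is not None:
        ax.plot(history.val_loss, label="validation loss")
    ax.axvline(history.best_epoch, ls="--", color="gray",
               label=f"best epoch {history.best_epoch}")
    ax.set_xlabel("epoch")
    ax.set_ylabel("MAE (scaled)")
    ax.legend()
    return ax


def plot_stress_field(field, component: str = "ff", ax=None):
    """Scatter of one stress component over the endocardial centroids,
    colored by magnitude (z against azimuth)."""
    ax = _axes(ax)
    c = field.centroids
    vals = getattr(field, f"sigma_{component}")
    theta = np.arctan2(c[:, 1], c[:, 0])
    sc = ax.scatter(theta, c[:, 2], c=vals, s=12, cmap="viridis")
    ax.set_xlabel("azimuth (rad)")
    ax.set_ylabel("z (mm)")
    ax.figure.colorbar(sc, ax=ax, label=f"sigma_{component} (kPa)")
    return ax
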