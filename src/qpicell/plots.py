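"""Optional figures: rose plots of horizon directions and growth curves."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from qpicell.dirstats import DirectionalSample
from qpicell.segment import CellTrack


def rose_plot(sample: DirectionalSample, n_bins: int = 16, ax=None):
    """Angular histogram of horizon-crossing directions."""
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(sample.angles_rad, bins=edges)
    ax.bar((edges[:-1] + edges[1:]) / 2, counts, width=np.diff(edges),
           edgecolor="k", alpha=0.7)
    ax.set_title(f"horizon {sample.horizon_um:g} um, "
                 f"{sample.n_reaching}/{sample.n_total_cells} cells")
    return ax


def growth_curves(tracks: list[CellTrack], ax=None):
    """Dry-mass growth curves, one line per track."""
    if ax is None:
        _, ax = plt.subplots()
    for t in tracks:
        ax.plot(t.times_min / 60.0, t.masses_pg, label=f"track {t.track_id}")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("dry mass (pg)")
    return ax
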