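"""Figure-style exports: gridded accessibility / angle maps over the entry
region and the exposed-area curve.  All plots use the Agg backend so runs
stay headless."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_access_map(amap, value: str = "accessible", path=None, ax=None):
    """Scatter an access map in entry-region (u, v) coordinates.

    ``value``: 'accessible' (flag), 'margin' (mm) or 'angle' (degrees).
    u grows posteriorly, v superiorly; the plot is flipped so anterior is
    left, superior up (the surgeon's lateral view of a right ear).
    """
    created = ax is None
    if created:
        _, ax = plt.subplots(figsize=(5, 4.5))
    if value == "accessible":
        c = amap.accessible.astype(float)
        label = f"accessible (margin > {amap.threshold} mm, angle < {amap.max_angle} deg)"
        cmap, vmin, vmax = "RdYlGn", 0, 1
    elif value == "margin":
        c, label, cmap = amap.margins, "safety margin (mm)", "viridis"
        vmin, vmax = -1, np.percentile(amap.margins, 95)
    else:
        c, label, cmap = amap.angles, "canal entry angle (deg)", "magma"
        vmin, vmax = 0, 180
    sc = ax.scatter(amap.uv[:, 0], amap.uv[:, 1], c=c, s=6, cmap=cmap, vmin=vmin, vmax=vmax)
    ax.invert_xaxis()
    ax.set_xlabel("posterior of EAC (mm)")
    ax.set_ylabel("superior of EAC centre (mm)")
    ax.set_title(f"{amap.canal} canal")
    ax.set_aspect("equal")
    plt.colorbar(sc, ax=ax, label=label)
    if path is not None:
        plt.savefig(path, dpi=150, bbox_inches="tight")
        plt.close()
    return ax


def plot_exposure_curve(angles_deg, areas_mm2, ideal_angle: float = 30.0, path=None):
    """Exposed canal-wall area as a function of the canal entry angle."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(angles_deg, areas_mm2, "-o", ms=3)
    i = int(np.argmin(np.abs(np.asarray(angles_deg) - ideal_angle)))
    ax.plot(angles_deg[i], areas_mm2[i], "k*", ms=12)
    ax.set_xlabel("canal entry angle (deg)")
    ax.set_ylabel("exposed area (mm$^2$)")
    ax.set_title("Exposed canal lumen vs entry angle")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
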