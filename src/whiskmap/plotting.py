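"""Optional rendering of motor maps and sensory overlays (matplotlib)."""

from __future__ import annotations

import numpy as np

from .maps import AverageMap, MotorMap
from .sensory import SensoryContour

__all__ = ["plot_map", "plot_overlay"]


def _extent(grid):
    # imshow extent in mm; half-pitch margins so cell centers sit on coords
    dml = grid.ml_extent_mm / (grid.n_cols - 1)
    dap = grid.ap_extent_mm / (grid.n_rows - 1)
    return (
        -dml / 2,
        grid.ml_extent_mm + dml / 2,
        grid.ap_origin_mm - grid.ap_extent_mm - dap / 2,
        grid.ap_origin_mm + dap / 2,
    )


def plot_map(m: MotorMap | AverageMap, ax=None, *, cmap="RdBu_r", symmetric=True,
             title: str | None = None):
    """Heat map of one motor map with a Bregma cross marker. Returns the Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 4))
    vals = m.values
    if symmetric and np.isfinite(vals).any():
        lim = np.nanmax(np.abs(vals))
        kw = {"vmin": -lim, "vmax": lim}
    else:
        kw = {}
    im = ax.imshow(vals, origin="upper", extent=_extent(m.grid), cmap=cmap, **kw)
    ax.plot(0, 0, "k+", markersize=12, markeredgewidth=2)  # Bregma
    ax.set_xlabel("ML (mm, lateral +)")
    ax.set_ylabel("AP (mm, anterior +)")
    who = "average" if isinstance(m, AverageMap) else m.mouse_id
    ax.set_title(title or f"{m.metric} / {m.whisker} / {who} / {m.power}")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax


def plot_overlay(contours: list[SensoryContour], motor_map: AverageMap, ax=None):
    """Sensory contours over the motor map, shared mm coordinates."""
    ax = plot_map(motor_map, ax=ax, title="sensory-motor overlay")
    for c in contours:
        ax.plot(c.polygon_mm[:, 0], c.polygon_mm[:, 1], lw=1.5, label=c.label)
    ax.legend(fontsize=7, loc="lower right")
    return ax
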