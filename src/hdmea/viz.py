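"""Heat-map plotting of activity maps and single-unit footprints."""

from __future__ import annotations

import numpy as np

from .detect import ActivityMap
from .layout import ElectrodeLayout
from .merge import GlobalFootprint

__all__ = ["plot_activity_map", "plot_footprint"]


def _grid(layout: ElectrodeLayout, values: dict[int, float]) -> np.ndarray:
    img = np.full((layout.n_rows, layout.n_cols), np.nan)
    for e, v in values.items():
        r, c = layout.rowcol(e)
        img[int(r), int(c)] = v
    return img


def plot_activity_map(amap: ActivityMap, layout: ElectrodeLayout, path=None, ax=None):
    """Array heat map of the largest negative spike amplitude per electrode;
    unrecorded electrodes render blank (missing is not zero)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    img = _grid(layout, amap.values)
    extent = (0, layout.n_cols * layout.pitch, layout.n_rows * layout.pitch, 0)
    im = ax.imshow(img, cmap="hot", extent=extent, interpolation="nearest")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    plt.colorbar(im, ax=ax, label="max |negative amplitude| (μV)")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_footprint(fp: GlobalFootprint, layout: ElectrodeLayout, path=None, ax=None):
    """Negative-peak amplitude heat map of one footprint."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    values = {
        e: float(max(0.0, -m)) for e, m in zip(fp.electrode_ids, fp.template.min(axis=1))
    }
    img = _grid(layout, values)
    extent = (0, layout.n_cols * layout.pitch, layout.n_rows * layout.pitch, 0)
    im = ax.imshow(img, cmap="viridis", extent=extent, interpolation="nearest")
    ax.set_title(f"unit {fp.unit_id}" + (f", day {fp.day_index}" if fp.day_index is not None else ""))
    plt.colorbar(im, ax=ax, label="|negative peak| (μV)")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
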