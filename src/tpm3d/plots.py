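"""Bullseye (polar map) rendering of per-slice, per-segment values."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .datamodel import SegmentModel  # noqa: E402

__all__ = ["bullseye"]


def bullseye(values: np.ndarray, model: SegmentModel, title: str = "",
             path=None, cmap: str = "RdYlBu_r", vmin=None, vmax=None):
    """Polar bullseye of ``values`` with shape (n_slices, n_seg).

    The apex maps to the center ring and the base to the outer ring.
    Orientation: the septal wall at the top, the inferior wall on the
    right, the lateral wall at the bottom and the anterior wall on the
    left (angles run clockwise from the image top).
    """
    n_sl, n_seg = values.shape
    if n_seg != model.n_seg:
        raise ValueError("values shape does not match the segment model")
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)          # clockwise, matching the segment order
    th = np.deg2rad(model.boundaries_deg + model.angular_origin_deg)
    r = np.arange(n_sl + 1)
    TH, R = np.meshgrid(th, r)
    pc = ax.pcolormesh(TH, R, values, cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_yticks([])
    ax.set_xticks(np.deg2rad([0, 90, 180, 270]))
    ax.set_xticklabels(["septal", "inferior", "lateral", "anterior"])
    ax.set_title(title)
    fig.colorbar(pc, ax=ax, shrink=0.75)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
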