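"""Bullseye infographics.

A bullseye plot shows the 36 regions as annular wedges: 4 concentric
rings (layers; innermost = most periventricular) crossed with 9 equal
angular sectors (zones). The default angular order runs clockwise from
the top — Front-L, Front-R, Par-R, Occ-R, Temp-R, BGIT, Temp-L, Occ-L,
Par-L — so left and right lobes mirror each other across the vertical
axis; the order is configurable.

Value semantics are tagged: lesion loads in [0, 1] use a sequential
colormap, correlations in [-1, 1] a sequential map over the observed
range, and tau differences in [-2, 2] a diverging pink/blue map centred
at zero (pink = numerically stronger association for the highlighted
rater, blue = weaker).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
import numpy as np

matplotlib.use("Agg")  # noqa: E402 — headless rendering
import matplotlib.pyplot as plt
from matplotlib import colors as mcolors
from matplotlib.cm import ScalarMappable
from matplotlib.patches import Wedge

from .loads import RegionalLoadTable
from .zones import N_ZONES, ZONE_NAMES, region_id

__all__ = [
    "BullseyeValues",
    "DEFAULT_ANGULAR_ORDER",
    "render_bullseye",
    "render_difference",
    "cohort_summary",
]

#: zone indices clockwise from 12 o'clock (mirror-symmetric layout)
DEFAULT_ANGULAR_ORDER: tuple[int, ...] = (1, 2, 4, 6, 8, 9, 7, 5, 3)

_SEMANTIC_RANGE = {
    "load": (0.0, 1.0),
    "correlation": (-1.0, 1.0),
    "difference": (-2.0, 2.0),
}


@dataclass
class BullseyeValues:
    """A 9 zones x 4 layers matrix of values with semantics and mask."""

    values: np.ndarray              # shape (9, n_layers)
    semantics: str = "load"         # load | correlation | difference
    mask: np.ndarray | None = None  # True = masked (drawn hatched)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != N_ZONES:
            raise ValueError(f"expected {N_ZONES} zone rows, got "
                             f"{self.values.shape[0]}")
        if self.semantics not in _SEMANTIC_RANGE:
            raise ValueError(f"unknown semantics {self.semantics!r}")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool) | ~np.isfinite(self.values)
        lo, hi = _SEMANTIC_RANGE[self.semantics]
        vis = self.values[~self.mask]
        if vis.size and (vis.min() < lo or vis.max() > hi):
            raise ValueError(
                f"{self.semantics} values outside [{lo}, {hi}]: "
                f"range [{vis.min():.3g}, {vis.max():.3g}]"
            )

    @property
    def n_layers(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_vector(cls, vec: np.ndarray, semantics: str = "load",
                    n_layers: int = 4) -> "BullseyeValues":
        """Build from a flat 36-vector indexed by region id - 1."""
        vec = np.asarray(vec, dtype=float)
        mat = np.empty((N_ZONES, n_layers))
        for z in range(1, N_ZONES + 1):
            for l in range(1, n_layers + 1):
                mat[z - 1, l - 1] = vec[region_id(z, l, n_layers) - 1]
        return cls(values=mat, semantics=semantics)

    @classmethod
    def from_loads(cls, loads: RegionalLoadTable) -> "BullseyeValues":
        return cls.from_vector(loads.load, "load", loads.n_layers)


def _wedge_geometry(n_layers: int, angular_order: tuple[int, ...],
                    inner_hole: float = 0.12):
    """Yield (zone, layer, theta1, theta2, r_in, r_out) for every wedge.

    Angles are matplotlib-convention (counterclockwise from east); the
    first zone sector is centred at 12 o'clock and the order proceeds
    clockwise.
    """
    sector = 360.0 / len(angular_order)
    ring = (1.0 - inner_hole) / n_layers
    for pos, zone in enumerate(angular_order):
        # clockwise from the top; sector centred on its mid-angle
        mid = 90.0 - pos * sector
        t1, t2 = mid - sector / 2.0, mid + sector / 2.0
        for layer in range(1, n_layers + 1):
            r_in = inner_hole + (layer - 1) * ring
            yield zone, layer, t1, t2, r_in, r_in + ring


def _make_norm_cmap(bv: BullseyeValues, cmap=None, vmin=None, vmax=None):
    if bv.semantics == "difference":
        data = bv.values[~bv.mask]
        lim = max(np.abs(data).max() if data.size else 0.0, 1e-6)
        vmin = -lim if vmin is None else vmin
        vmax = lim if vmax is None else vmax
        cmap = cmap or "RdBu_r"  # pink/red = stronger, blue = weaker
    elif bv.semantics == "correlation":
        vmin = -1.0 if vmin is None else vmin
        vmax = 1.0 if vmax is None else vmax
        cmap = cmap or "viridis"
    else:
        vmin = 0.0 if vmin is None else vmin
        if vmax is None:
            data = bv.values[~bv.mask]
            vmax = max(float(data.max()) if data.size else 1.0, 1e-6)
        cmap = cmap or "YlOrRd"
    return mcolors.Normalize(vmin=vmin, vmax=vmax), plt.get_cmap(cmap)


def render_bullseye(bv: BullseyeValues, path=None, *, cmap=None,
                    vmin=None, vmax=None, title: str | None = None,
                    angular_order: tuple[int, ...] = DEFAULT_ANGULAR_ORDER,
                    ax=None):
    """Draw the 36-wedge bullseye; returns the matplotlib Axes.

    Masked cells are drawn hatched. Output is deterministic for a fixed
    input: saving twice produces byte-identical SVG.
    """
    norm, cm = _make_norm_cmap(bv, cmap, vmin, vmax)
    own_fig = ax is None
    if own_fig:
        with plt.rc_context({"svg.hashsalt": "bullseye"}):
            fig, ax = plt.subplots(figsize=(5.2, 4.6))
    else:
        fig = ax.figure
    ax.set_aspect("equal")
    ax.set_xlim(-1.28, 1.28)
    ax.set_ylim(-1.28, 1.28)
    ax.axis("off")
    for zone, layer, t1, t2, r_in, r_out in _wedge_geometry(
            bv.n_layers, angular_order):
        val = bv.values[zone - 1, layer - 1]
        masked = bv.mask[zone - 1, layer - 1]
        wedge = Wedge((0, 0), r_out, t1, t2, width=r_out - r_in,
                      facecolor="white" if masked else cm(norm(val)),
                      edgecolor="0.3", linewidth=0.6,
                      hatch="///" if masked else None)
        wedge.set_gid(f"region-z{zone}-l{layer}")
        ax.add_patch(wedge)
    # sector labels just outside the outer ring
    sector = 360.0 / len(angular_order)
    for pos, zone in enumerate(angular_order):
        mid = np.deg2rad(90.0 - pos * sector)
        ax.text(1.13 * np.cos(mid), 1.13 * np.sin(mid), ZONE_NAMES[zone],
                ha="center", va="center", fontsize=8)
    if title:
        ax.set_title(title, fontsize=10)
    fig.colorbar(ScalarMappable(norm=norm, cmap=cm), ax=ax, shrink=0.8)
    if path is not None:
        with plt.rc_context({"svg.hashsalt": "bullseye"}):
            fig.savefig(path, metadata=_no_date_metadata(path), dpi=150,
                        bbox_inches="tight")
        plt.close(fig)
    return ax


def _no_date_metadata(path) -> dict | None:
    # SVG embeds a creation date by default, which breaks byte-identical output
    return {"Date": None} if str(path).endswith(".svg") else None


def render_difference(bv: BullseyeValues, path=None, **kwargs):
    """Diverging pink/blue bullseye of tau differences, centred at 0."""
    if bv.semantics != "difference":
        raise ValueError("render_difference requires difference semantics")
    kwargs.setdefault("cmap", "RdBu_r")
    return render_bullseye(bv, path, **kwargs)


def cohort_summary(cohort: list[RegionalLoadTable],
                   ) -> tuple[BullseyeValues, BullseyeValues]:
    """Per-region median and IQR of loads across subjects."""
    if len(cohort) < 2:
        raise ValueError("cohort summary needs >= 2 subjects")
    stack = np.stack([t.load for t in cohort], axis=0)
    med = np.median(stack, axis=0)
    q1, q3 = np.percentile(stack, [25, 75], axis=0)
    n_layers = cohort[0].n_layers
    return (BullseyeValues.from_vector(med, "load", n_layers),
            BullseyeValues.from_vector(q3 - q1, "load", n_layers))
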