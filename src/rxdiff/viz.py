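"""Views, colormap rendering and integrals.

A view maps the current state to a scalar field via an arbitrary expression
(any nonlinear combination of species, coordinates, time and derivative
tokens).  Rendering is a pure function of (field, view): adaptive scaling
maps the frame minimum to 0 and maximum to 1 (a flat field maps to the
midpoint), fixed scaling clamps to [vmin, vmax].  Nodes outside the domain
mask, and non-finite values, are drawn in a sentinel colour instead of
raising.

Colormap set: perceptually-uniform ``viridis`` (default), the diverging
``diverging`` (RdBu), and ``flame``, a multi-hue dark-to-bright map in the
house style of interactive PDE art.  Colormap choice matters for
accessibility; the perceptually-uniform default is deliberate.
"""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps as _mpl_colormaps
from matplotlib.colors import LinearSegmentedColormap

from .grid import Grid, DomainMask
from .model import ViewSpec
from .operators import System

__all__ = [
    "COLORMAPS",
    "SENTINEL_RGB",
    "evaluate_view",
    "render_frame",
    "compute_integral",
    "render_line_plot",
]

_flame = LinearSegmentedColormap.from_list(
    "flame",
    ["#140b34", "#84206b", "#e55c30", "#f6d746", "#ffffff"],
)

COLORMAPS = {
    "viridis": _mpl_colormaps["viridis"],
    "diverging": _mpl_colormaps["RdBu_r"],
    "flame": _flame,
}

SENTINEL_RGB = np.array([255, 0, 255], dtype=np.uint8)  # non-finite / no-data


def evaluate_view(state, view: ViewSpec, system: System) -> np.ma.MaskedArray:
    """Evaluate a view expression on the current state.

    Returns a masked array: masked-out domain nodes are flagged as no-data.
    """
    from .expr import parse
    from .model import _kinetics_symbols

    ctx = system.context(state.fields, state.t)
    e = parse(view.expression, _kinetics_symbols(system.cfg))
    vals = np.empty(system.grid.shape)
    vals[...] = np.asarray(_safe_eval(e, ctx), dtype=float)
    return np.ma.masked_array(vals, mask=~system.mask.inside)


def _safe_eval(e, ctx):
    from .expr import evaluate

    return evaluate(e, ctx)


def _normalise(field: np.ndarray, scaling) -> tuple[np.ndarray, np.ndarray]:
    """Map to [0, 1]; returns (normalised, bad-pixel mask)."""
    vals = np.ma.filled(np.ma.masked_invalid(field), np.nan)
    bad = ~np.isfinite(vals)
    if isinstance(field, np.ma.MaskedArray):
        bad = bad | np.ma.getmaskarray(field)
    finite = vals[~bad]
    if scaling == "adaptive":
        if finite.size == 0:
            return np.full(vals.shape, 0.5), bad
        lo, hi = float(finite.min()), float(finite.max())
        if hi == lo:  # degenerate flat field -> midpoint
            return np.full(vals.shape, 0.5), bad
    else:
        lo, hi = float(scaling[0]), float(scaling[1])
        if hi == lo:
            return np.full(vals.shape, 0.5), bad
    with np.errstate(invalid="ignore"):
        norm = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    norm[bad] = 0.0
    return norm, bad


def render_frame(field, view: ViewSpec) -> np.ndarray:
    """Render a scalar field to a deterministic uint8 RGB raster (ny, nx, 3)."""
    cmap = COLORMAPS.get(view.colormap)
    if cmap is None:
        raise KeyError(
            f"unknown colormap {view.colormap!r}; available: {sorted(COLORMAPS)}"
        )
    norm, bad = _normalise(np.asanyarray(field), view.scaling)
    rgba = cmap(norm)
    rgb = (rgba[..., :3] * 255).round().astype(np.uint8)
    rgb[bad] = SENTINEL_RGB
    # image row 0 is the top of the picture; grid row 0 is y = 0
    return rgb[::-1, :, :]


def render_line_plot(grid: Grid, field, view: ViewSpec, path) -> None:
    """1D runs render as x-vs-value line plots (PNG via matplotlib Agg)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(grid.X[0], np.asarray(field)[0], lw=1.5)
    ax.set_xlabel("x")
    ax.set_ylabel(view.name)
    if view.scaling != "adaptive":
        ax.set_ylim(view.scaling[0], view.scaling[1])
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def compute_integral(field, grid: Grid, mask: DomainMask | None = None) -> float:
    """Midpoint quadrature of the field over the simulated nodes:
    sum(field) * dx_eff * dy_eff (dy_eff = 1 on 1D grids)."""
    vals = np.asarray(field, dtype=float)
    if mask is not None and not mask.all_inside:
        total = float(vals[mask.inside].sum())
    else:
        total = float(vals.sum())
    w = grid.dx * (grid.dy if grid.dimension == 2 else 1.0)
    return total * w
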