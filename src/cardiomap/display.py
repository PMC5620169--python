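"""Display scaling, scattered interpolation and map rendering.

This is the imaging half of the method: per-location fold changes are mapped
to a 0-100 display scale (mimicking the voltage scale of an electroanatomical
mapping console, which cannot show negative values), interpolated over the
bulls-eye disk by inverse-distance weighting, and rendered as colour-coded 2D
polar maps or 3D ventricular surfaces.

Colour semantics follow the mapping console: strong down-regulation (display
0) in red, yellow below baseline, green at the baseline/reference value
(display 20 by default), blue and finally pink for up-regulated values
(display 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
from matplotlib import colors as mcolors
from matplotlib.cm import ScalarMappable
from matplotlib.colors import LinearSegmentedColormap, Normalize
from scipy.spatial.distance import cdist

from .errors import DegenerateScaleWarning, DomainError
from .geometry import LVGeometry, SegmentScheme, DEFAULT_SCHEME, polar_to_cartesian

DEFAULT_ANCHOR_TARGET = 20.0

#: Display-value -> colour stops of the default map.
DEFAULT_COLOR_STOPS: tuple[tuple[float, str], ...] = (
    (0.0, "#d7191c"),    # red: maximal down-regulation
    (10.0, "#ffd300"),   # yellow
    (20.0, "#1a9641"),   # green: baseline / reference value
    (60.0, "#2c7bb6"),   # blue
    (100.0, "#f06eaa"),  # pink: maximal up-regulation
)


@dataclass(frozen=True)
class DisplayScale:
    """Monotone map from fold-change units to the [0, 100] display scale.

    Without an anchor this is the linear min-max map.  With an anchor the map
    is piecewise linear: [min, anchor] -> [0, anchor_target] and
    [anchor, max] -> [anchor_target, 100], pinning the reference location to
    exactly ``anchor_target`` display units.
    """

    source_min: float
    source_max: float
    anchor_value: float | None = None
    anchor_target: float = DEFAULT_ANCHOR_TARGET
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if not self.source_min < self.source_max:
                raise DomainError("source_min must be < source_max for a non-degenerate scale")
            if self.anchor_value is not None and not (
                self.source_min < self.anchor_value < self.source_max
            ):
                raise DomainError("anchor_value must lie strictly inside (min, max)")

    def apply(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.degenerate:
            return np.full(v.shape, self.anchor_target)
        lo, hi = self.source_min, self.source_max
        if self.anchor_value is None:
            out = 100.0 * (v - lo) / (hi - lo)
        else:
            anc, tgt = self.anchor_value, self.anchor_target
            out = np.where(
                v <= anc,
                tgt * (v - lo) / (anc - lo),
                tgt + (100.0 - tgt) * (v - anc) / (hi - anc),
            )
        return np.clip(out, 0.0, 100.0)


def rescale_display(
    values,
    anchor_value: float | None = None,
    anchor_target: float = DEFAULT_ANCHOR_TARGET,
) -> tuple[np.ndarray, DisplayScale]:
    """Build a DisplayScale from fold changes and apply it.

    Constant input yields a degenerate scale: everything maps to
    ``anchor_target`` and a :class:`DegenerateScaleWarning` is emitted.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise DomainError("need at least one value to rescale")
    if np.any(v <= 0) or np.any(~np.isfinite(v)):
        raise DomainError("fold changes must be positive and finite")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        warnings.warn(
            "constant fold changes: degenerate display scale, mapping all "
            f"values to {anchor_target}",
            DegenerateScaleWarning,
            stacklevel=2,
        )
        scale = DisplayScale(lo, hi, None, anchor_target, degenerate=True)
        return scale.apply(v), scale
    scale = DisplayScale(lo, hi, anchor_value, anchor_target)
    return scale.apply(v), scale


@dataclass(frozen=True)
class ColorScale:
    """Piecewise-linear colour map over display values."""

    stops: tuple[tuple[float, str], ...] = DEFAULT_COLOR_STOPS

    def __post_init__(self) -> None:
        vals = [s[0] for s in self.stops]
        if len(vals) < 2 or any(b <= a for a, b in zip(vals, vals[1:])):
            raise DomainError("colour stops must be strictly increasing in display value")

    @property
    def vmin(self) -> float:
        return self.stops[0][0]

    @property
    def vmax(self) -> float:
        return self.stops[-1][0]

    def colormap(self) -> LinearSegmentedColormap:
        span = self.vmax - self.vmin
        anchors = [((v - self.vmin) / span, c) for v, c in self.stops]
        return LinearSegmentedColormap.from_list("cardiomap", anchors)

    def norm(self) -> Normalize:
        return Normalize(self.vmin, self.vmax)

    def rgba(self, values) -> np.ndarray:
        return self.colormap()(self.norm()(np.asarray(values, dtype=float)))


@dataclass(frozen=True)
class PolarGrid:
    """Raster of display values over the unit disk (NaN outside)."""

    u: np.ndarray            # 1-D axis, length n
    v: np.ndarray            # 1-D axis, length n
    values: np.ndarray       # (n, n), NaN where mask is False
    mask: np.ndarray         # (n, n) boolean, True inside the disk

    @property
    def resolution(self) -> int:
        return self.u.size


def idw_interpolate(
    points,
    values,
    resolution: int = 201,
    power: float = 2.0,
    exact_tol: float = 1e-12,
) -> PolarGrid:
    """Inverse-distance-weighted interpolation onto a square disk raster.

    Grid nodes closer than ``exact_tol`` to a sample take that sample's value
    exactly; interpolated values are convex combinations of the inputs and
    therefore bounded by the input range.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vals = np.asarray(values, dtype=float).ravel()
    if pts.size == 0 or vals.size == 0:
        raise DomainError("need at least one sample point to interpolate")
    if pts.shape[0] != vals.size or pts.shape[1] != 2:
        raise DomainError("points must be (n, 2) and values length n")
    if np.any(np.hypot(pts[:, 0], pts[:, 1]) > 1 + 1e-9):
        raise DomainError("sample points must lie inside the unit disk")

    axis = np.linspace(-1.0, 1.0, resolution)
    uu, vv = np.meshgrid(axis, axis, indexing="xy")
    mask = uu**2 + vv**2 <= 1.0
    nodes = np.column_stack([uu[mask], vv[mask]])

    d = cdist(nodes, pts)
    nearest = d.argmin(axis=1)
    exact = d[np.arange(d.shape[0]), nearest] < exact_tol
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[exact] = 0.0  # avoid inf rows; filled from the coincident sample below
    interp = (w @ vals) / np.where(exact, 1.0, w.sum(axis=1))
    interp[exact] = vals[nearest[exact]]

    grid = np.full(uu.shape, np.nan)
    grid[mask] = interp
    return PolarGrid(u=axis, v=axis, values=grid, mask=mask)


def grid_to_rgba(grid: PolarGrid, colors: ColorScale | None = None) -> np.ndarray:
    """Colour a PolarGrid; outside-disk pixels are fully transparent."""
    colors = colors or ColorScale()
    rgba = colors.rgba(np.nan_to_num(grid.values, nan=colors.vmin))
    rgba[..., 3] = np.where(grid.mask, 1.0, 0.0)
    return rgba


def _draw_scheme(ax, scheme: SegmentScheme) -> None:
    for r in (*scheme.ring_bounds, 1.0):
        ax.add_patch(plt.Circle((0, 0), r, fill=False, color="k", lw=0.6))
    edges = (0.0, *scheme.ring_bounds, 1.0)
    for i, (start, labels) in enumerate(scheme.rings):
        if len(labels) < 2:
            continue
        width = 360.0 / len(labels)
        for k in range(len(labels)):
            ang = np.radians(start + k * width)
            r0, r1 = edges[i], edges[i + 1]
            ax.plot(
                [r0 * np.cos(ang), r1 * np.cos(ang)],
                [r0 * np.sin(ang), r1 * np.sin(ang)],
                color="k",
                lw=0.6,
            )


def render_bullseye(
    grid: PolarGrid,
    colors: ColorScale | None = None,
    scheme: SegmentScheme | None = None,
    samples=None,
    zones=(),
    title: str | None = None,
    colorbar: bool = True,
    ax=None,
    path=None,
):
    """Render a bulls-eye polar map with optional overlays.

    ``samples`` is an optional (n, 2) array of (u, v) marker positions;
    ``zones`` an iterable of zone polygons (outlined in black).  Saving
    format follows the ``path`` suffix (.png or .svg).
    """
    if grid.values is None or not np.any(grid.mask):
        raise DomainError("cannot render an unpopulated grid")
    colors = colors or ColorScale()
    if ax is None:
        fig, ax = plt.subplots(figsize=(4.6, 4.2))
    else:
        fig = ax.figure
    rgba = grid_to_rgba(grid, colors)
    ax.imshow(rgba, origin="lower", extent=(-1, 1, -1, 1), interpolation="nearest")
    ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, color="k", lw=1.0))
    if scheme is not None:
        _draw_scheme(ax, scheme)
    if samples is not None:
        pts = np.atleast_2d(np.asarray(samples, dtype=float))
        ax.plot(pts[:, 0], pts[:, 1], "k.", ms=3)
    for zone in zones:
        verts = np.vstack([zone.vertices, zone.vertices[:1]])
        ax.plot(verts[:, 0], verts[:, 1], "k-", lw=1.2)
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    if colorbar:
        sm = ScalarMappable(norm=colors.norm(), cmap=colors.colormap())
        fig.colorbar(sm, ax=ax, fraction=0.046, pad=0.04, label="display value")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def lv_surface_mesh(
    geometry: LVGeometry | None = None,
    n_meridional: int = 48,
    n_circumferential: int = 96,
):
    """Triangulate the parametric LV surface.

    Returns ``(vertices, faces, rho, theta)`` with one apex vertex plus an
    ``n_meridional x n_circumferential`` grid; the mesh is watertight except
    for the open basal rim.
    """
    geom = geometry or LVGeometry()
    rho_rings = np.linspace(0.0, 1.0, n_meridional + 1)[1:]
    thetas = np.arange(n_circumferential) * 360.0 / n_circumferential
    rr, tt = np.meshgrid(rho_rings, thetas, indexing="ij")
    ring_xyz = polar_to_cartesian(rr.ravel(), tt.ravel(), geom)
    apex = polar_to_cartesian(0.0, 0.0, geom)
    vertices = np.vstack([apex, ring_xyz])
    rho_all = np.concatenate([[0.0], rr.ravel()])
    theta_all = np.concatenate([[0.0], tt.ravel()])

    faces = []
    nc = n_circumferential
    for j in range(nc):
        faces.append([0, 1 + j, 1 + (j + 1) % nc])
    for i in range(n_meridional - 1):
        base0, base1 = 1 + i * nc, 1 + (i + 1) * nc
        for j in range(nc):
            a, b = base0 + j, base0 + (j + 1) % nc
            c, d = base1 + j, base1 + (j + 1) % nc
            faces.append([a, c, b])
            faces.append([b, c, d])
    return vertices, np.asarray(faces, dtype=int), rho_all, theta_all


def render_3d_surface(
    points,
    values,
    geometry: LVGeometry | None = None,
    colors: ColorScale | None = None,
    n_meridional: int = 48,
    n_circumferential: int = 96,
    power: float = 2.0,
    path=None,
):
    """Colour the 3D LV surface by IDW of per-location display values.

    ``points`` are sample (u, v) disk coordinates matching ``values``.
    Returns a ``trimesh.Trimesh`` with per-vertex colours; pass ``path``
    ending in .ply/.obj/.vtk-compatible suffixes supported by trimesh to
    export.
    """
    import trimesh

    vals = np.asarray(values, dtype=float).ravel()
    if vals.size < 1:
        raise DomainError("need at least one value to colour the surface")
    colors = colors or ColorScale()
    vertices, faces, rho, theta = lv_surface_mesh(geometry, n_meridional, n_circumferential)
    uv = np.column_stack([rho * np.cos(np.radians(theta)), rho * np.sin(np.radians(theta))])

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = cdist(uv, pts)
    nearest = d.argmin(axis=1)
    exact = d[np.arange(d.shape[0]), nearest] < 1e-12
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[exact] = 0.0
    vertex_values = (w @ vals) / np.where(exact, 1.0, w.sum(axis=1))
    vertex_values[exact] = vals[nearest[exact]]

    rgba = (colors.rgba(vertex_values) * 255).astype(np.uint8)
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, vertex_colors=rgba, process=False)
    mesh.vertex_attributes["display_value"] = vertex_values
    if path is not None:
        mesh.export(path)
    return mesh
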