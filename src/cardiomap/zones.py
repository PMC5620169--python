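"""Ischemic/remote zone delineation, transposition and group statistics.

The analysis workflow delineates the ischemic area as a polygon on the 5-h
bulls-eye map of each gene, transposes the identical polygon onto the control
and 24-h maps (all groups share the same biopsy coordinates), averages fold
changes inside (ischemic) and outside (remote) the polygon per animal, and
compares the three groups by one-way ANOVA with Holm-Sidak-adjusted pairwise
post-hoc tests.

The unit of analysis defaults to the animal (per-animal zone means), which
avoids treating the 52 within-heart biopsies as independent replicates;
``unit="sample"`` pools biopsies instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import Polygon
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, ZoneError

GROUP_ORDER = ("control", "ir5h", "ir24h")
ZONE_LABELS = ("ischemic", "remote")


@dataclass(frozen=True)
class ZonePolygon:
    """Simple polygon on the bulls-eye plane delineating a zone."""

    label: str
    vertices: np.ndarray  # (n, 2) of (u, v), implicitly closed
    source_group: str | None = None

    def __post_init__(self) -> None:
        verts = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if verts.shape[0] < 3 or verts.shape[1] != 2:
            raise ZoneError("a zone polygon needs at least 3 (u, v) vertices")
        if np.any(np.hypot(verts[:, 0], verts[:, 1]) > 1 + 1e-9):
            raise ZoneError("zone vertices must lie within the unit disk")
        poly = Polygon(verts)
        if not poly.is_valid or poly.area <= 0:
            raise ZoneError("zone polygon is degenerate or self-intersecting")
        object.__setattr__(self, "vertices", verts)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


def point_in_zone(points, zone: ZonePolygon):
    """Classify point(s) (u, v) against a zone polygon.

    Points exactly on an edge or vertex count as inside (boundary-inclusive
    even-odd rule; for a simple polygon shapely's ``covers`` coincides with
    it).  Returns a bool, or a boolean array for multiple points.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 2:
        raise DomainError("points must have two coordinates (u, v)")
    if np.any(np.hypot(pts[:, 0], pts[:, 1]) > 1 + 1e-9):
        raise DomainError("points must lie within the unit disk")
    inside = shapely.covers(zone.polygon, shapely.points(pts))
    if single:
        return bool(inside[0])
    return np.asarray(inside, dtype=bool)


def _locations_uv(locations: pd.DataFrame) -> pd.DataFrame:
    df = locations.copy()
    if "u" not in df.columns or "v" not in df.columns:
        if not {"rho", "theta_deg"} <= set(df.columns):
            raise ZoneError("locations need u/v or rho/theta_deg columns")
        df["u"] = df["rho"] * np.cos(np.radians(df["theta_deg"]))
        df["v"] = df["rho"] * np.sin(np.radians(df["theta_deg"]))
    return df


def transpose_zone(zone: ZonePolygon, locations_by_group: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Apply one polygon verbatim to every group's location set.

    All maps must share the same location ids and coordinates (that is what
    makes the transposition exact); mismatches raise ``ZoneError``.  Returns
    a tidy frame with columns ``group, location_id, inside``.
    """
    frames = {g: _locations_uv(df).sort_values("location_id") for g, df in locations_by_group.items()}
    if not frames:
        raise ZoneError("no location sets supplied")
    ref_group = next(iter(frames))
    ref = frames[ref_group]
    for g, df in frames.items():
        if list(df["location_id"]) != list(ref["location_id"]):
            raise ZoneError(f"location ids of group {g!r} differ from {ref_group!r}")
        if not np.allclose(df[["u", "v"]].to_numpy(), ref[["u", "v"]].to_numpy(), atol=1e-9):
            raise ZoneError(f"coordinates of group {g!r} differ from {ref_group!r}")
    inside = point_in_zone(ref[["u", "v"]].to_numpy(), zone)
    out = []
    for g in frames:
        out.append(
            pd.DataFrame(
                {"group": g, "location_id": ref["location_id"].to_numpy(), "inside": inside}
            )
        )
    return pd.concat(out, ignore_index=True)


def zone_summaries(
    expression: pd.DataFrame,
    classification,
    zone_label: str = "ischemic",
) -> pd.DataFrame:
    """Per animal x gene mean fold change inside and outside the zone.

    ``classification`` maps location id -> inside flag (a Mapping, or a frame
    with ``location_id``/``inside`` columns).  Means are taken on fold
    changes, never on display values.  Returns tidy rows with ``zone`` in
    {"ischemic", "remote"}.
    """
    if isinstance(classification, pd.DataFrame):
        cls = classification.drop_duplicates("location_id").set_index("location_id")["inside"]
    else:
        cls = pd.Series(dict(classification))
    expr = expression.copy()
    unknown = set(expr["sample_id"]) - set(cls.index)
    if unknown:
        raise ZoneError(f"locations without a zone classification: {sorted(unknown)[:5]}")
    if not cls.any():
        raise ZoneError(f"zone {zone_label!r} contains no sampling locations")
    expr["zone"] = np.where(
        expr["sample_id"].map(cls).astype(bool), zone_label, "remote"
    )
    keys = [c for c in ("gene", "group", "animal_id", "zone") if c in expr.columns]
    out = (
        expr.groupby(keys, sort=False, observed=True)["fold_change"]
        .agg(n="size", mean_fold_change="mean")
        .reset_index()
    )
    return out


def anova_groups(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across >= 2 groups of >= 2 values.

    Degenerate-data policy: zero between- and within-group variance gives
    (F, p) = (0, 1); zero within-group variance with distinct means gives
    (inf, 0).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise DomainError("ANOVA needs at least two groups with two values each")
    grand = np.concatenate(arrs).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    if ssw == 0.0:
        return (0.0, 1.0) if ssb == 0.0 else (float("inf"), 0.0)
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p)


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjustment, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p values must lie in [0, 1]")
    return multipletests(p, method="holm-sidak")[1]


def compare_zone_groups(
    summaries: pd.DataFrame,
    group_order: Sequence[str] = GROUP_ORDER,
    unit: str = "animal",
) -> pd.DataFrame:
    """ANOVA + Holm-Sidak pairwise contrasts per gene x zone.

    ``summaries`` is the output of :func:`zone_summaries`.  With
    ``unit="animal"`` each animal contributes its zone mean; ``"sample"``
    would require per-sample rows instead (pass raw expression through
    :func:`zone_summaries` with animal_id removed).
    """
    del unit  # the unit choice is made upstream, in what `summaries` holds
    rows = []
    for (gene, zone), sub in summaries.groupby(["gene", "zone"], sort=False, observed=True):
        series = [
            sub.loc[sub["group"] == g, "mean_fold_change"].to_numpy() for g in group_order
        ]
        f, p = anova_groups(series)
        contrasts = [
            (group_order[i], group_order[j])
            for i in range(len(group_order))
            for j in range(i + 1, len(group_order))
        ]
        raw = []
        for a, b in contrasts:
            ga = series[group_order.index(a)]
            gb = series[group_order.index(b)]
            t = stats.ttest_ind(ga, gb, equal_var=True)
            raw.append(1.0 if np.isnan(t.pvalue) else float(t.pvalue))
        adj = holm_sidak_adjust(raw)
        row = {
            "gene": gene,
            "zone": zone,
            "f_statistic": f,
            "anova_p": p,
        }
        for g, s in zip(group_order, series):
            row[f"n_{g}"] = s.size
            row[f"mean_{g}"] = s.mean()
        for (a, b), pr, pa in zip(contrasts, raw, adj):
            row[f"p_{a}_vs_{b}"] = pr
            row[f"p_adj_{a}_vs_{b}"] = pa
        rows.append(row)
    return pd.DataFrame(rows)


def threshold_zone(
    grid,
    level: float,
    label: str = "ischemic",
    source_group: str | None = "ir5h",
    max_vertices: int = 64,
) -> ZonePolygon:
    """Convenience helper: contour the display raster at ``level``.

    Returns the longest closed contour of ``display >= level`` as a zone
    polygon.  Intended as a starting point only — the reference workflow uses
    a manually delineated polygon.
    """
    from skimage import measure

    filled = np.where(grid.mask, grid.values, -np.inf)
    contours = measure.find_contours(filled, level)
    if not contours:
        raise ZoneError(f"no contour found at display level {level}")
    contour = max(contours, key=len)
    # image rows index v, columns index u
    vs = np.interp(contour[:, 0], np.arange(grid.v.size), grid.v)
    us = np.interp(contour[:, 1], np.arange(grid.u.size), grid.u)
    verts = np.column_stack([us, vs])
    if len(verts) > max_vertices:
        step = max(1, len(verts) // max_vertices)
        verts = verts[::step]
    r = np.hypot(verts[:, 0], verts[:, 1])
    over = r > 1.0
    verts[over] /= r[over, None]
    return ZonePolygon(label=label, vertices=verts, source_group=source_group)
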