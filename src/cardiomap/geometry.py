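"""Left-ventricular surface model and bulls-eye (polar-map) projection.

The left ventricle is modelled as a truncated prolate hemiellipsoid with the
apex pointing down: in Cartesian coordinates (mm) the surface is

    x = a * sin(phi) * cos(theta)
    y = a * sin(phi) * sin(theta)
    z = -L * cos(phi),        phi in [0, phi_max],

where ``a`` is the basal radius, ``L`` the apex-to-base length and ``phi`` the
meridional parameter (0 at the apex).  ``phi_max = truncation * pi/2``; a
truncation of 1 keeps the full hemiellipsoid up to the equatorial base plane.

The bulls-eye projection maps this surface onto the unit disk: ``rho`` is the
arc-length position along the meridian, normalised so that the apex sits at
the centre (rho = 0) and the basal rim on the boundary (rho = 1), and
``theta`` (degrees, counter-clockwise) is the circumferential angle.  The
anterior wall is displayed at 12 o'clock, i.e. theta = 90 deg, with the
septum at 9 o'clock (theta = 180 deg) — the conventional orientation of the
AHA polar display.

Arc-length rho uses the incomplete elliptic integral of the second kind; the
inverse mapping solves the one-dimensional arc-length equation by bisection
(Brent), which keeps the polar<->Cartesian round trip accurate to ~1e-12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import ellipeinc

from .errors import CoordinateError, DomainError

#: theta (degrees) of the centre of the anterior wall on the displayed map.
ANTERIOR_THETA = 90.0

#: AHA segment names, 1-17.
SEGMENT_NAMES = {
    1: "basal anterior",
    2: "basal anteroseptal",
    3: "basal inferoseptal",
    4: "basal inferior",
    5: "basal inferolateral",
    6: "basal anterolateral",
    7: "mid anterior",
    8: "mid anteroseptal",
    9: "mid inferoseptal",
    10: "mid inferior",
    11: "mid inferolateral",
    12: "mid anterolateral",
    13: "apical anterior",
    14: "apical septal",
    15: "apical inferior",
    16: "apical lateral",
    17: "apex",
}


@dataclass(frozen=True)
class LVGeometry:
    """Truncated prolate hemiellipsoid standing in for the explanted LV.

    Parameters
    ----------
    apex_base_length
        Apex-to-base semi-axis ``L`` in mm (default 60, a pig-heart scale).
    basal_radius
        Equatorial semi-axis ``a`` in mm (default 30).
    base_truncation
        Fraction of the hemiellipsoid kept, measured from the apex, in
        ``(0, 1]``.  1 keeps everything up to the base plane.
    """

    apex_base_length: float = 60.0
    basal_radius: float = 30.0
    base_truncation: float = 1.0

    def __post_init__(self) -> None:
        if not (self.apex_base_length > 0 and self.basal_radius > 0):
            raise DomainError("apex_base_length and basal_radius must be > 0")
        if not 0 < self.base_truncation <= 1:
            raise DomainError("base_truncation must lie in (0, 1]")

    @property
    def phi_max(self) -> float:
        """Meridional parameter of the basal rim (radians)."""
        return self.base_truncation * math.pi / 2.0

    def meridian_arc(self, phi):
        """Arc length (mm) along a meridian from the apex to parameter phi.

        The integrand sqrt(a^2 cos^2 phi + L^2 sin^2 phi) is an elliptic
        integral of the second kind with parameter m = 1 - (L/a)^2.
        """
        m = 1.0 - (self.apex_base_length / self.basal_radius) ** 2
        return self.basal_radius * ellipeinc(phi, m)

    @property
    def meridian_length(self) -> float:
        """Total apex-to-rim meridian arc length (mm)."""
        return float(self.meridian_arc(self.phi_max))


def _as_points(point) -> tuple[np.ndarray, bool]:
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 3:
        raise DomainError("expected point(s) with three Cartesian components")
    return pts, single


def cartesian_to_polar(point, geometry: LVGeometry | None = None, *, tol: float = 1e-6):
    """Project on-surface Cartesian point(s) to bulls-eye (rho, theta).

    Parameters
    ----------
    point
        Shape ``(3,)`` or ``(n, 3)`` array of x/y/z in mm.
    geometry
        Surface model; defaults to :class:`LVGeometry`.
    tol
        Relative off-surface tolerance (fraction of the larger semi-axis).

    Returns
    -------
    (rho, theta)
        rho in [0, 1]; theta in degrees [0, 360).  Scalars for a single
        point, arrays otherwise.  The apex returns theta = 0 by convention.
    """
    geom = geometry or LVGeometry()
    pts, single = _as_points(point)
    a, big_l = geom.basal_radius, geom.apex_base_length
    x, y, z = pts.T
    r = np.hypot(x, y)
    # atan2 recovers phi from (sin phi, cos phi) without the conditioning
    # loss of arccos near the apex.
    phi = np.arctan2(r / a, -z / big_l)
    resid = np.hypot(r - a * np.sin(phi), z + big_l * np.cos(phi))
    scale = max(a, big_l)
    if np.any(resid > tol * scale):
        worst = float(np.max(resid))
        raise CoordinateError(
            f"point(s) off the LV surface by up to {worst:.3g} mm "
            f"(tolerance {tol * scale:.3g} mm)"
        )
    if np.any(phi > geom.phi_max * (1 + 1e-9) + tol):
        raise CoordinateError("point(s) beyond the basal truncation plane")
    phi = np.minimum(phi, geom.phi_max)
    rho = np.clip(geom.meridian_arc(phi) / geom.meridian_length, 0.0, 1.0)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    theta = np.where(r <= 1e-12 * a, 0.0, theta)  # apex: theta is arbitrary, report 0
    if single:
        return float(rho[0]), float(theta[0])
    return rho, theta


def polar_to_cartesian(rho, theta, geometry: LVGeometry | None = None):
    """Map bulls-eye coordinates back onto the 3D surface.

    rho must lie in [0, 1] and theta (degrees) in [0, 360); anything else
    raises :class:`~cardiomap.errors.DomainError`.  Returns an ``(n, 3)``
    array, or shape ``(3,)`` for scalar input.
    """
    geom = geometry or LVGeometry()
    rho_arr = np.asarray(rho, dtype=float)
    theta_arr = np.asarray(theta, dtype=float)
    single = rho_arr.ndim == 0 and theta_arr.ndim == 0
    rho_arr, theta_arr = np.broadcast_arrays(np.atleast_1d(rho_arr), np.atleast_1d(theta_arr))
    if np.any(~np.isfinite(rho_arr)) or np.any((rho_arr < 0) | (rho_arr > 1)):
        raise DomainError("rho must lie in [0, 1]")
    if np.any(~np.isfinite(theta_arr)) or np.any((theta_arr < 0) | (theta_arr >= 360)):
        raise DomainError("theta must lie in [0, 360) degrees")

    s_total = geom.meridian_length
    phi_max = geom.phi_max

    def invert(rho_i: float) -> float:
        if rho_i <= 0.0:
            return 0.0
        if rho_i >= 1.0:
            return phi_max
        target = rho_i * s_total
        return brentq(
            lambda p: geom.meridian_arc(p) - target,
            0.0,
            phi_max,
            xtol=1e-14,
            rtol=8.9e-16,
        )

    phi = np.array([invert(r) for r in rho_arr.ravel()]).reshape(rho_arr.shape)
    t = np.radians(theta_arr)
    out = np.stack(
        [
            geom.basal_radius * np.sin(phi) * np.cos(t),
            geom.basal_radius * np.sin(phi) * np.sin(t),
            -geom.apex_base_length * np.cos(phi),
        ],
        axis=-1,
    )
    if single:
        return out[0]
    return out


@dataclass(frozen=True)
class SegmentScheme:
    """AHA 17-segment partition of the unit disk.

    Rings (half-open in rho, rho = 1 belongs to the basal ring):

    ======================  ==========  ================================
    rho range               segments    sectors
    ======================  ==========  ================================
    [0.00, 0.25)            17          apex cap (full circle)
    [0.25, 0.50)            13-16       4 x 90 deg, anterior at 90 deg
    [0.50, 0.75)            7-12        6 x 60 deg, anterior at 90 deg
    [0.75, 1.00]            1-6         6 x 60 deg, anterior at 90 deg
    ======================  ==========  ================================

    Sectors are half-open in theta and ordered counter-clockwise starting at
    the stored start angle, so every (rho, theta) has exactly one owner.
    """

    ring_bounds: tuple[float, ...] = (0.25, 0.5, 0.75)
    # per ring from the apex: (start angle of the first sector, CCW labels)
    rings: tuple[tuple[float, tuple[int, ...]], ...] = (
        (0.0, (17,)),
        (45.0, (13, 14, 15, 16)),
        (60.0, (7, 8, 9, 10, 11, 12)),
        (60.0, (1, 2, 3, 4, 5, 6)),
    )

    def assign(self, rho, theta):
        rho_arr = np.atleast_1d(np.asarray(rho, dtype=float))
        theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
        rho_arr, theta_arr = np.broadcast_arrays(rho_arr, theta_arr)
        if np.any((rho_arr < 0) | (rho_arr > 1)):
            raise DomainError("rho must lie in [0, 1]")
        if np.any((theta_arr < 0) | (theta_arr >= 360)):
            raise DomainError("theta must lie in [0, 360) degrees")
        ring = np.searchsorted(np.asarray(self.ring_bounds), rho_arr, side="right")
        seg = np.empty(rho_arr.shape, dtype=int)
        for i, (start, labels) in enumerate(self.rings):
            sel = ring == i
            if not np.any(sel):
                continue
            width = 360.0 / len(labels)
            idx = np.floor(((theta_arr[sel] - start) % 360.0) / width).astype(int)
            seg[sel] = np.asarray(labels)[np.minimum(idx, len(labels) - 1)]
        if np.isscalar(rho) and np.isscalar(theta):
            return int(seg.ravel()[0])
        return seg

    def area_fraction(self, segment: int) -> float:
        """Analytic area fraction of a segment on the unit disk."""
        edges = (0.0, *self.ring_bounds, 1.0)
        for i, (_, labels) in enumerate(self.rings):
            if segment in labels:
                ring_area = edges[i + 1] ** 2 - edges[i] ** 2
                return ring_area / len(labels)
        raise DomainError(f"unknown segment {segment}")


DEFAULT_SCHEME = SegmentScheme()


def assign_segment(rho, theta, scheme: SegmentScheme | None = None):
    """Assign AHA segment id(s) 1-17 to bulls-eye coordinate(s)."""
    return (scheme or DEFAULT_SCHEME).assign(rho, theta)


@dataclass(frozen=True)
class SamplingLocation:
    """One biopsy site, with both coordinate systems and its segment label."""

    location_id: str
    x: float
    y: float
    z: float
    rho: float
    theta: float
    segment: int


#: Deterministic default layout: concentric rings from apex to base.
RING_RHO = (0.125, 0.375, 0.625, 0.875)
RING_WEIGHTS = (4, 12, 16, 20)


def _ring_counts(n: int) -> list[int]:
    total = sum(RING_WEIGHTS)
    quotas = [n * w / total for w in RING_WEIGHTS]
    counts = [int(math.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(quotas)), key=lambda i: (counts[i] - quotas[i], -i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_sampling_scheme(
    n: int = 52,
    geometry: LVGeometry | None = None,
    seed: int | None = None,
    scheme: SegmentScheme | None = None,
) -> list[SamplingLocation]:
    """Generate a quasi-uniform biopsy layout over the LV surface.

    The default layout is deterministic: four concentric rings at rho =
    0.125/0.375/0.625/0.875 holding 4/12/16/20 sites (52 in total), each ring
    rotated by half a site spacing so no site falls on a sector boundary.
    Supplying ``seed`` adds a small reproducible jitter in rho and theta.

    ``n = 1`` returns a single apex location.
    """
    if n < 1:
        raise DomainError("need at least one sampling location")
    geom = geometry or LVGeometry()
    seg_scheme = scheme or DEFAULT_SCHEME

    if n == 1:
        xyz = polar_to_cartesian(0.0, 0.0, geom)
        return [
            SamplingLocation("r1p01", *map(float, xyz), 0.0, 0.0, seg_scheme.assign(0.0, 0.0))
        ]

    rng = np.random.default_rng(seed) if seed is not None else None
    edges = (0.0, 0.25, 0.5, 0.75, 1.0)
    locations: list[SamplingLocation] = []
    for ring, (rho0, count) in enumerate(zip(RING_RHO, _ring_counts(n))):
        if count == 0:
            continue
        spacing = 360.0 / count
        for k in range(count):
            theta = (spacing * (k + 0.5)) % 360.0
            rho = rho0
            if rng is not None:
                theta = (theta + rng.uniform(-0.3, 0.3) * spacing) % 360.0
                rho = float(
                    np.clip(
                        rho + rng.uniform(-0.04, 0.04),
                        edges[ring] + 0.02,
                        edges[ring + 1] - 0.02,
                    )
                )
            xyz = polar_to_cartesian(rho, theta, geom)
            locations.append(
                SamplingLocation(
                    f"r{ring + 1}p{k + 1:02d}",
                    float(xyz[0]),
                    float(xyz[1]),
                    float(xyz[2]),
                    rho,
                    theta,
                    int(seg_scheme.assign(rho, theta)),
                )
            )
    return locations


def locations_frame(locations) -> "pd.DataFrame":
    """Tabulate SamplingLocations (adds flattened disk coordinates u, v)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "location_id": [l.location_id for l in locations],
            "x_mm": [l.x for l in locations],
            "y_mm": [l.y for l in locations],
            "z_mm": [l.z for l in locations],
            "rho": [l.rho for l in locations],
            "theta_deg": [l.theta for l in locations],
            "segment": [l.segment for l in locations],
        }
    )
    df["u"] = df["rho"] * np.cos(np.radians(df["theta_deg"]))
    df["v"] = df["rho"] * np.sin(np.radians(df["theta_deg"]))
    return df
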