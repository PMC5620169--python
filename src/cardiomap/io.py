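"""Reading/writing the pipeline's CSV/JSON/YAML interchange formats.

All tables are UTF-8 CSV with a header row, '.' decimal separator, angles in
degrees and fold changes at full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import CoordinateError, ValidationError
from .geometry import LVGeometry, cartesian_to_polar, polar_to_cartesian
from .zones import ZonePolygon

LOCATION_COLUMNS = ("location_id", "x_mm", "y_mm", "z_mm", "rho", "theta_deg")
CT_COLUMNS = ("sample_id", "animal_id", "group", "gene", "replicate", "ct")


def write_locations(locations: pd.DataFrame, path) -> Path:
    path = Path(path)
    cols = [c for c in (*LOCATION_COLUMNS, "segment") if c in locations.columns]
    locations[cols].to_csv(path, index=False)
    return path


def read_locations(path, geometry: LVGeometry | None = None, tol: float = 1e-6) -> pd.DataFrame:
    """Read a sampling-location table and reconcile its coordinate systems.

    Accepts Cartesian columns, polar columns, or both; whichever is missing
    is computed from the other, and when both are present the polar pair is
    recomputed from x/y/z and cross-checked.
    """
    geom = geometry or LVGeometry()
    df = pd.read_csv(path)
    if "location_id" not in df.columns:
        raise ValidationError(f"{path}: missing column 'location_id'")
    have_xyz = {"x_mm", "y_mm", "z_mm"} <= set(df.columns)
    have_polar = {"rho", "theta_deg"} <= set(df.columns)
    if not have_xyz and not have_polar:
        raise ValidationError(f"{path}: need x_mm/y_mm/z_mm and/or rho/theta_deg columns")
    if df["location_id"].duplicated().any():
        dup = df.loc[df["location_id"].duplicated(), "location_id"].iloc[0]
        raise ValidationError(f"{path}: duplicated location_id {dup!r}")
    if have_xyz:
        rho, theta = cartesian_to_polar(df[["x_mm", "y_mm", "z_mm"]].to_numpy(), geom)
        if have_polar:
            if not (
                np.allclose(rho, df["rho"].to_numpy(), atol=1e-6)
                and np.allclose(
                    np.exp(1j * np.radians(theta)),
                    np.exp(1j * np.radians(df["theta_deg"].to_numpy())),
                    atol=1e-6,
                )
            ):
                raise CoordinateError(
                    f"{path}: stored rho/theta_deg disagree with x/y/z coordinates"
                )
        df["rho"], df["theta_deg"] = rho, theta
    else:
        bad = df.index[(df["rho"] < 0) | (df["rho"] > 1)]
        if len(bad):
            raise ValidationError(f"{path}: rho out of [0, 1] at row {bad[0]}")
        df["theta_deg"] = df["theta_deg"] % 360.0
        xyz = polar_to_cartesian(df["rho"].to_numpy(), df["theta_deg"].to_numpy(), geom)
        df["x_mm"], df["y_mm"], df["z_mm"] = xyz.T
    df["u"] = df["rho"] * np.cos(np.radians(df["theta_deg"]))
    df["v"] = df["rho"] * np.sin(np.radians(df["theta_deg"]))
    return df


def write_ct(ct: pd.DataFrame, path) -> Path:
    path = Path(path)
    ct[list(CT_COLUMNS)].to_csv(path, index=False)
    return path


def read_ct(path) -> pd.DataFrame:
    """Read and validate a long-format raw Ct table."""
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    ct = pd.to_numeric(df["ct"], errors="coerce")
    bad = df.index[ct.isna() | (ct <= 0) | (ct > 45)]
    if len(bad):
        raise ValidationError(
            f"{path}: column 'ct' out of range (0, 45] at row {int(bad[0]) + 2}"
        )
    df["ct"] = ct
    dup = df.duplicated(subset=["animal_id", "sample_id", "gene", "replicate"])
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate (animal_id, sample_id, gene, replicate) at row "
            f"{int(df.index[dup][0]) + 2}"
        )
    return df


def write_zone(zone: ZonePolygon, path) -> Path:
    path = Path(path)
    payload = {
        "label": zone.label,
        "source_group": zone.source_group,
        "vertices": [[float(u), float(v)] for u, v in zone.vertices],
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_zone(path) -> ZonePolygon:
    payload = json.loads(Path(path).read_text())
    for key in ("label", "vertices"):
        if key not in payload:
            raise ValidationError(f"{path}: zone JSON missing key {key!r}")
    return ZonePolygon(
        label=payload["label"],
        vertices=np.asarray(payload["vertices"], dtype=float),
        source_group=payload.get("source_group"),
    )


def write_yaml(data: dict, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


def read_yaml(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a YAML mapping")
    return data


def geometry_from_config(data: dict) -> LVGeometry:
    return LVGeometry(
        apex_base_length=float(data.get("apex_base_length_mm", 60.0)),
        basal_radius=float(data.get("basal_radius_mm", 30.0)),
        base_truncation=float(data.get("base_truncation", 1.0)),
    )
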