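"""Synthetic porcine LV expression studies with known ground truth.

The generator reproduces the statistical structure the analysis assumes: a
three-group study (sham controls n=8, ischemia/reperfusion at 5 h n=6 and at
24 h n=6), 52 quasi-uniform biopsy locations per heart, a panel of seven
target and three reference genes, a spatially localised ischemic-core
expression effect, and replicate-level Ct measurement noise on top of an
animal-level offset.

Spatial model.  On the bulls-eye plane the true log2 fold change of a target
gene blends a core and a remote amplitude through a Gaussian kernel centred
on the ischemic core (default rho=0.35, theta=90 deg: the apical-anterior
mid-LAD territory):

    w(d)        = exp(-d^2 / (2 sigma^2)),   d = disk distance to the core
    log2FC(d)   = core * w(d) + remote * (1 - w(d))

Ground-truth zone membership is w >= 1/2, i.e. d <= sigma*sqrt(2 ln 2), so
zone tests have an exact truth set.

Noise model.  Measured Ct values are

    Ct = baseline(gene) - log2FC + animal_effect + N(0, ct_noise_sd)

per technical replicate; reference genes carry no group effect.  The animal
effect (shared by all genes of an animal, default SD 0.15 cycles) mimics
loading/RNA-quality variation and cancels exactly in dCt.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import (
    DEFAULT_SCHEME,
    LVGeometry,
    SegmentScheme,
    generate_sampling_scheme,
    locations_frame,
)
from .qpcr import DEFAULT_REFERENCES, DEFAULT_TARGETS
from .zones import ZonePolygon

GROUPS = ("control", "ir5h", "ir24h")

#: Typical baseline Ct per gene at the 500 ng cDNA input of the protocol.
DEFAULT_BASELINE_CT: dict[str, float] = {
    "CASP3": 26.0,
    "CLU": 24.0,
    "ERCC4": 28.0,
    "GATA4": 25.0,
    "HK2": 24.0,
    "MEF2C": 27.0,
    "HIF1A": 23.0,
    "GAPDH": 18.0,
    "HPRT1": 25.0,
    "PPIA": 21.0,
}

# Qualitative spatiotemporal profile of each target gene, encoded as
# (core, remote) log2 fold-change amplitudes per post-ischemia time point:
#   CASP3  strong core up-regulation at 5 h, back to baseline by 24 h
#   HIF1A  core + partial remote up at 5 h; remote-only up at 24 h
#   GATA4  core up at 5 h, stronger at 24 h
#   MEF2C  essentially unchanged throughout
#   HK2    core up with remote down at 5 h; globally down at 24 h
#   CLU    apical-core up, remote down at 5 h; mixed mild up at 24 h
#   ERCC4  moderate core up at both time points
_PROFILE: dict[str, dict[str, tuple[float, float]]] = {
    "HIF1A": {"ir5h": (1.5, 0.5), "ir24h": (0.0, 1.0)},
    "CASP3": {"ir5h": (2.0, 0.3), "ir24h": (0.0, 0.0)},
    "GATA4": {"ir5h": (1.0, 0.0), "ir24h": (1.5, 0.0)},
    "MEF2C": {"ir5h": (0.0, 0.0), "ir24h": (0.0, 0.0)},
    "HK2": {"ir5h": (2.0, -1.0), "ir24h": (-1.5, -1.5)},
    "CLU": {"ir5h": (1.0, -0.5), "ir24h": (0.5, 0.5)},
    "ERCC4": {"ir5h": (1.0, 0.0), "ir24h": (1.0, 0.0)},
}


def default_profiles() -> pd.DataFrame:
    """Per-gene x group amplitude table (control amplitudes are zero)."""
    rows = []
    for gene in DEFAULT_TARGETS:
        for group in GROUPS:
            core, remote = (0.0, 0.0) if group == "control" else _PROFILE[gene][group]
            rows.append(
                {"gene": gene, "group": group, "core_log2fc": core, "remote_log2fc": remote}
            )
    return pd.DataFrame(rows)


def null_profiles() -> pd.DataFrame:
    """Amplitude table with every effect set to zero (null simulation)."""
    prof = default_profiles()
    prof[["core_log2fc", "remote_log2fc"]] = 0.0
    return prof


@dataclass
class StudyConfig:
    """Everything the generator needs; defaults encode the study design."""

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"control": 8, "ir5h": 6, "ir24h": 6}
    )
    n_locations: int = 52
    target_genes: tuple[str, ...] = DEFAULT_TARGETS
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCES
    core_rho: float = 0.35
    core_theta: float = 90.0
    core_sigma: float = 0.25
    amplitudes: pd.DataFrame | None = None  # defaults to default_profiles()
    baseline_ct: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE_CT))
    replicates: int = 2
    ct_noise_sd: float = 0.25
    animal_sd: float = 0.15
    geometry: LVGeometry = field(default_factory=LVGeometry)
    jitter_locations: bool = False

    def validate(self) -> None:
        problems = []
        if any(v < 1 for v in self.group_sizes.values()):
            problems.append("group_sizes must all be >= 1")
        if self.n_locations < 1:
            problems.append("n_locations must be >= 1")
        if self.ct_noise_sd < 0 or self.animal_sd < 0:
            problems.append("noise SDs must be >= 0")
        if self.core_sigma <= 0:
            problems.append("core_sigma must be > 0")
        if not 0 <= self.core_rho <= 1 or not 0 <= self.core_theta < 360:
            problems.append("core centre must satisfy rho in [0,1], theta in [0,360)")
        if self.replicates < 1:
            problems.append("replicates must be >= 1")
        amp = self.resolved_amplitudes()
        if not np.all(np.isfinite(amp[["core_log2fc", "remote_log2fc"]].to_numpy())):
            problems.append("amplitudes must be finite")
        missing_baseline = [
            g
            for g in (*self.target_genes, *self.reference_genes)
            if g not in self.baseline_ct
        ]
        if missing_baseline:
            problems.append(f"baseline_ct missing genes: {missing_baseline}")
        if problems:
            raise ValidationError("invalid study config: " + "; ".join(problems))

    def resolved_amplitudes(self) -> pd.DataFrame:
        return self.amplitudes if self.amplitudes is not None else default_profiles()

    @property
    def core_uv(self) -> tuple[float, float]:
        t = np.radians(self.core_theta)
        return self.core_rho * float(np.cos(t)), self.core_rho * float(np.sin(t))

    @property
    def zone_radius(self) -> float:
        """Disk radius of the ground-truth ischemic zone (kernel weight 1/2)."""
        return self.core_sigma * float(np.sqrt(2.0 * np.log(2.0)))

    def kernel_weight(self, u, v) -> np.ndarray:
        u0, v0 = self.core_uv
        d2 = (np.asarray(u) - u0) ** 2 + (np.asarray(v) - v0) ** 2
        return np.exp(-d2 / (2.0 * self.core_sigma**2))


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free truth the generator committed to."""

    expression: pd.DataFrame   # gene, group, location_id, true_log2fc
    zone: pd.DataFrame         # location_id, u, v, kernel_weight, in_zone
    core_segments: tuple[int, ...]  # segments whose every location is in the zone


@dataclass(frozen=True)
class SimulatedStudy:
    locations: pd.DataFrame
    ct: pd.DataFrame
    truth: GroundTruth
    config: StudyConfig
    seed: int


def ischemic_zone_polygon(config: StudyConfig, n_vertices: int = 96) -> ZonePolygon:
    """Polygon circumscribing the ground-truth zone circle.

    Circumscribed (not inscribed) so the polygon covers the full w >= 1/2
    disk region and the truth set membership of any location strictly inside
    or outside the circle is preserved.
    """
    u0, v0 = config.core_uv
    r = config.zone_radius / np.cos(np.pi / n_vertices)
    ang = 2 * np.pi * np.arange(n_vertices) / n_vertices
    verts = np.column_stack([u0 + r * np.cos(ang), v0 + r * np.sin(ang)])
    norm = np.hypot(verts[:, 0], verts[:, 1])
    over = norm > 1.0
    verts[over] /= norm[over, None]
    return ZonePolygon(label="ischemic", vertices=verts, source_group="ir5h")


def simulate_study(
    config: StudyConfig | None = None,
    seed: int = 0,
    scheme: SegmentScheme | None = None,
) -> SimulatedStudy:
    """Generate locations, a raw Ct table and the ground truth.

    Deterministic given (config, seed).  The Ct table is long format with
    columns ``sample_id, animal_id, group, gene, replicate, ct``; sample ids
    are the location ids (unique within an animal).
    """
    config = config or StudyConfig()
    config.validate()
    scheme = scheme or DEFAULT_SCHEME
    rng = np.random.default_rng(seed)

    locs = generate_sampling_scheme(
        config.n_locations,
        config.geometry,
        seed=seed if config.jitter_locations else None,
        scheme=scheme,
    )
    loc_df = locations_frame(locs)
    w = config.kernel_weight(loc_df["u"].to_numpy(), loc_df["v"].to_numpy())
    in_zone = w >= 0.5

    amp = config.resolved_amplitudes().set_index(["gene", "group"])
    genes = [*config.target_genes, *config.reference_genes]
    n_targets = len(config.target_genes)
    n_locs = len(loc_df)

    # true log2 fold change per (gene, group, location); references are zero
    truth_rows = []
    log2fc = {}
    for group in GROUPS:
        mat = np.zeros((len(genes), n_locs))
        for gi, gene in enumerate(config.target_genes):
            core, remote = amp.loc[(gene, group), ["core_log2fc", "remote_log2fc"]]
            mat[gi] = core * w + remote * (1.0 - w)
            truth_rows.append(
                pd.DataFrame(
                    {
                        "gene": gene,
                        "group": group,
                        "location_id": loc_df["location_id"],
                        "true_log2fc": mat[gi],
                    }
                )
            )
        log2fc[group] = mat

    baseline = np.array([config.baseline_ct[g] for g in genes])
    n_rep = config.replicates
    ct_blocks: list[np.ndarray] = []
    animal_ids: list[str] = []
    animal_groups: list[str] = []
    for group in GROUPS:
        for a in range(int(config.group_sizes.get(group, 0))):
            animal_effect = rng.normal(0.0, config.animal_sd)
            # (genes, locations, replicates)
            noise = rng.normal(0.0, config.ct_noise_sd, (len(genes), n_locs, n_rep))
            ct_blocks.append(
                (baseline[:, None, None] - log2fc[group][:, :, None] + animal_effect + noise).ravel()
            )
            animal_ids.append(f"{group}_{a + 1:02d}")
            animal_groups.append(group)

    rows_per_animal = len(genes) * n_locs * n_rep
    sample_block = np.tile(np.repeat(loc_df["location_id"].to_numpy(), n_rep), len(genes))
    gene_block = np.repeat(genes, n_locs * n_rep)
    rep_block = np.tile(np.arange(1, n_rep + 1), len(genes) * n_locs)
    n_animals = len(animal_ids)
    ct_df = pd.DataFrame(
        {
            "sample_id": np.tile(sample_block, n_animals),
            "animal_id": np.repeat(np.asarray(animal_ids, dtype=object), rows_per_animal),
            "group": np.repeat(np.asarray(animal_groups, dtype=object), rows_per_animal),
            "gene": np.tile(gene_block, n_animals),
            "replicate": np.tile(rep_block, n_animals),
            "ct": np.concatenate(ct_blocks),
        }
    )

    zone_df = loc_df[["location_id", "u", "v"]].copy()
    zone_df["kernel_weight"] = w
    zone_df["in_zone"] = in_zone
    seg_of = loc_df.set_index("location_id")["segment"]
    core_segments = tuple(
        int(s)
        for s in sorted(loc_df["segment"].unique())
        if bool(zone_df.set_index("location_id").loc[seg_of.index[seg_of == s], "in_zone"].all())
    )
    truth = GroundTruth(
        expression=pd.concat(truth_rows, ignore_index=True),
        zone=zone_df,
        core_segments=core_segments,
    )
    return SimulatedStudy(locations=loc_df, ct=ct_df, truth=truth, config=config, seed=seed)


def null_config(**overrides) -> StudyConfig:
    """StudyConfig with all expression effects removed (for calibration)."""
    cfg = StudyConfig(amplitudes=null_profiles(), **overrides)
    return cfg
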