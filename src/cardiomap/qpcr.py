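"""Relative qPCR quantification: replicate handling, calibration, ddCt.

The quantification model is the classical comparative-Ct (ddCt) scheme with
multi-reference normalisation:

    dCt(s, g)   = Ct(s, g) - mean_r Ct(s, r)         r over reference genes
    ddCt(s, g)  = dCt(s, g) - dCt(calibrator, g)
    fold change = E ** (-ddCt)

The arithmetic mean of reference-gene Ct values is exactly the geometric mean
of the reference quantities on the linear scale (Ct is a log2 quantity), so
"normalisation to the geometric mean of the reference genes" is implemented
as a plain mean in Ct space.  The amplification efficiency E defaults to 2
(perfect doubling per cycle) and can be replaced by the efficiency fitted
from a dilution calibration curve, applied run-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, FitError, ValidationError

#: Default target panel (seven genes of interest).
DEFAULT_TARGETS = ("CASP3", "CLU", "ERCC4", "GATA4", "HK2", "MEF2C", "HIF1A")
#: Default reference (housekeeping) panel.
DEFAULT_REFERENCES = ("GAPDH", "HPRT1", "PPIA")

#: Primer metadata for the default porcine panel:
#: gene -> (forward primer, reverse primer, amplicon length in bp).
#: No primer pair is available for HIF1A.
PRIMERS: dict[str, tuple[str, str, int]] = {
    "CASP3": ("GGGATTGAGACGGACAGTGG", "TGAACCAGGATCCGTCCTTTG", 136),
    "CLU": ("CATGAAGTTCTACGCGCGTG", "AGTAGAAGGGGGAGCTCTGG", 92),
    "ERCC4": ("ATGGGAAGCACTGACCGAAG", "GAACACGTCCTGTCGTCACT", 114),
    "GATA4": ("AGAAAACGGAAGCCCAAGAAC", "CCACACTGCTGGAGTTGCTG", 109),
    "HK2": ("CAGCAGAACAGCCTGGATGA", "GGATGGCTTCCTTCAGCAGT", 106),
    "MEF2C": ("TAACATGCCGCCATCCGCCC", "ATCCTCTCGGTCGCTGCCGT", 151),
    "GAPDH": ("TCCACCCACGGCAAGTTCCAC", "ATGTTGGCGGGATCTCGCTCCT", 104),
    "HPRT1": ("CCCAGCGTCGTGATTAGTGA", "ATCTCGAGCAAGCCGTTCAG", 131),
    "PPIA": ("GTCTTCTTCGACATCGCCGT", "TCCTTTCTCCCCAGTGCTCA", 120),
}


@dataclass(frozen=True)
class PanelConfig:
    """Gene panel: targets, references and the calibrator rule.

    ``calibrator = None`` means "gene-wise mean dCt over all control-group
    samples"; a string selects every row with that sample id (e.g. a named
    biopsy location, averaged across animals); an ``(animal_id, sample_id)``
    pair selects one physical sample.
    """

    target_genes: tuple[str, ...] = DEFAULT_TARGETS
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCES
    calibrator: object = None
    primers: Mapping[str, tuple[str, str, int]] = field(default_factory=lambda: dict(PRIMERS))

    def __post_init__(self) -> None:
        overlap = set(self.target_genes) & set(self.reference_genes)
        if overlap:
            raise ValidationError(f"genes cannot be both target and reference: {sorted(overlap)}")
        if not self.reference_genes:
            raise ValidationError("at least one reference gene is required")


@dataclass(frozen=True)
class CalibrationCurve:
    """Dilution-series regression of Ct on log10(relative quantity)."""

    quantities: tuple[float, ...]
    mean_ct: tuple[float, ...]
    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    valid: bool
    plausible: bool


def collapse_replicates(records: pd.DataFrame, qc_threshold: float = 0.5) -> pd.DataFrame:
    """Average technical replicates per sample x gene.

    Returns one row per group key with ``mean_ct``, the replicate standard
    deviation (0 for a single replicate), replicate count and a QC flag set
    when the replicate SD exceeds ``qc_threshold`` cycles.
    """
    if records.empty:
        raise DomainError("no Ct records supplied")
    keys = [c for c in ("animal_id", "group", "sample_id", "gene") if c in records.columns]
    if not keys:
        raise ValidationError("records need at least a sample_id or gene column")
    agg = records.groupby(keys, sort=False, observed=True)["ct"].agg(
        mean_ct="mean", replicate_sd="std", n_replicates="size"
    )
    agg["replicate_sd"] = agg["replicate_sd"].fillna(0.0)
    agg["qc_flag"] = agg["replicate_sd"] > qc_threshold
    return agg.reset_index()


def fit_calibration_curve(quantities, cts) -> CalibrationCurve:
    """Fit a standard curve from a dilution series.

    Ordinary least squares of Ct on log10(relative quantity); the fitted
    slope gives the amplification efficiency E = 10**(-1/slope) (slope
    -3.3219 corresponds to perfect doubling, E = 2).  A non-negative slope
    is returned with ``valid=False``; E outside (1, 2.5] clears the
    ``plausible`` flag.
    """
    q = np.asarray(quantities, dtype=float)
    ct = np.asarray(cts, dtype=float)
    if q.shape != ct.shape or q.ndim != 1:
        raise FitError("quantities and cts must be matching 1-D sequences")
    if np.unique(q).size < 3:
        raise FitError("a calibration curve needs at least 3 distinct quantities")
    if np.any(q <= 0):
        raise DomainError("relative quantities must be positive")
    x = np.log10(q)
    if np.ptp(x) == 0:
        raise FitError("zero variance in log10(quantity)")
    fit = stats.linregress(x, ct)
    slope = float(fit.slope)
    valid = slope < 0
    efficiency = float(10.0 ** (-1.0 / slope)) if slope != 0 else float("nan")
    plausible = valid and 1.0 < efficiency <= 2.5
    return CalibrationCurve(
        quantities=tuple(q),
        mean_ct=tuple(ct),
        slope=slope,
        intercept=float(fit.intercept),
        efficiency=efficiency,
        r_squared=float(fit.rvalue**2),
        valid=valid,
        plausible=plausible,
    )


def _resolve_efficiency(efficiency) -> float:
    if isinstance(efficiency, CalibrationCurve):
        if not efficiency.valid:
            raise DomainError("calibration curve has a non-negative slope; no usable efficiency")
        efficiency = efficiency.efficiency
    e = float(efficiency)
    if e <= 0 or not np.isfinite(e):
        raise DomainError(f"amplification efficiency must be positive, got {e}")
    return e


def delta_delta_ct(
    ct: pd.DataFrame,
    panel: PanelConfig | None = None,
    calibrator=None,
    efficiency=2.0,
) -> pd.DataFrame:
    """Compute dCt / ddCt / fold change for every sample x target gene.

    Parameters
    ----------
    ct
        Long-format table with columns ``sample_id, gene, ct`` plus optional
        ``animal_id, group, replicate``.  Replicates are averaged first.
    panel
        Target/reference panel; defaults to :class:`PanelConfig`.
    calibrator
        Overrides the panel's calibrator rule (see :class:`PanelConfig`).
    efficiency
        Scalar amplification efficiency or a fitted
        :class:`CalibrationCurve` applied run-wide.

    Returns
    -------
    DataFrame with one row per sample x target gene carrying ``delta_ct``,
    ``delta_delta_ct`` and ``fold_change``.
    """
    panel = panel or PanelConfig()
    if calibrator is None:
        calibrator = panel.calibrator
    e = _resolve_efficiency(efficiency)

    collapsed = collapse_replicates(ct)
    index_cols = [c for c in ("animal_id", "sample_id") if c in collapsed.columns]
    if "sample_id" not in index_cols:
        raise ValidationError("Ct table must carry a sample_id column")
    meta_cols = [c for c in ("group",) if c in collapsed.columns]
    wide = collapsed.pivot_table(index=index_cols, columns="gene", values="mean_ct")

    refs = list(panel.reference_genes)
    missing_ref_cols = [g for g in refs if g not in wide.columns]
    if missing_ref_cols:
        raise ValidationError(f"reference gene(s) absent from the table: {missing_ref_cols}")
    bad = wide.index[wide[refs].isna().any(axis=1)]
    if len(bad):
        raise ValidationError(
            f"samples missing a reference-gene Ct: {[str(b) for b in bad.tolist()]}"
        )

    targets = [g for g in panel.target_genes if g in wide.columns]
    if not targets:
        raise ValidationError("no target-gene Ct values found")
    ref_mean = wide[refs].mean(axis=1)
    dct = wide[targets].sub(ref_mean, axis=0)

    meta = (
        collapsed[index_cols + meta_cols].drop_duplicates().set_index(index_cols)
        if meta_cols
        else None
    )

    if calibrator is None:
        if meta is None or "group" not in meta.columns:
            raise ValidationError(
                "default calibrator needs a 'group' column with control samples"
            )
        mask = meta.reindex(dct.index)["group"].eq("control").to_numpy()
        if not mask.any():
            raise ValidationError("no control-group samples available as calibrator")
        cal = dct.loc[mask].mean(axis=0)
    elif isinstance(calibrator, str):
        sel = dct.index.get_level_values("sample_id") == calibrator \
            if isinstance(dct.index, pd.MultiIndex) else dct.index == calibrator
        if not np.any(sel):
            raise ValidationError(f"calibrator sample {calibrator!r} not in the table")
        cal = dct.loc[sel].mean(axis=0)
    else:
        try:
            cal = dct.loc[tuple(calibrator)]
        except KeyError as exc:
            raise ValidationError(f"calibrator sample {calibrator!r} not in the table") from exc

    ddct = dct - cal
    fc = np.power(e, -ddct)

    out = dct.stack().rename("delta_ct").reset_index()
    out["delta_delta_ct"] = ddct.stack().to_numpy()
    out["fold_change"] = fc.stack().to_numpy()
    if meta is not None:
        out = out.merge(meta.reset_index(), on=index_cols, how="left")
    order = [c for c in ("animal_id", "sample_id", "group", "gene") if c in out.columns]
    return out[order + ["delta_ct", "delta_delta_ct", "fold_change"]]
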