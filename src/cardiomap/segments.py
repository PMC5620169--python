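"""AHA 17-segment quantification and the 2xSD biological-relevance rule.

With ~3 biopsies per segment a formal segment-level test is not justified;
instead a segment difference between control and a treated group is called
biologically relevant — and painted red on the segmental polar display —
when the absolute difference of the segment means exceeds twice the pooled
SD of the two segments' location values.  The wording "2xSD of the mean
values of both segments" admits other readings; they are selectable via
``rule`` (see :func:`relevance_flags`) with pooled SD as the default.
"""

from __future__ import annotations

from typing import Mapping

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Wedge

from .errors import DomainError, ValidationError
from .geometry import DEFAULT_SCHEME, SEGMENT_NAMES, SegmentScheme

RULES = ("pooled", "sd_of_means", "sum_sd")


def segment_summaries(
    expression: pd.DataFrame,
    segments,
    scheme: SegmentScheme | None = None,
) -> pd.DataFrame:
    """Mean and SD of fold changes per gene x group x segment.

    ``segments`` maps location id -> segment (Mapping or frame with
    ``location_id``/``segment``).  Values pool across animals within a
    group.  Every segment appears for every gene x group; empty segments get
    n = 0 and missing mean/SD, segments with one value get SD = missing.
    """
    scheme = scheme or DEFAULT_SCHEME
    if isinstance(segments, pd.DataFrame):
        seg = segments.drop_duplicates("location_id").set_index("location_id")["segment"]
    else:
        seg = pd.Series(dict(segments))
    expr = expression.copy()
    unmapped = set(expr["sample_id"]) - set(seg.index)
    if unmapped:
        raise ValidationError(f"locations without a segment id: {sorted(unmapped)[:5]}")
    expr["segment"] = expr["sample_id"].map(seg).astype(int)
    keys = [c for c in ("gene", "group") if c in expr.columns]
    agg = (
        expr.groupby(keys + ["segment"], sort=False, observed=True)["fold_change"]
        .agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    agg.loc[agg["n"] < 2, "sd"] = np.nan
    all_segments = sorted({s for _, labels in scheme.rings for s in labels})
    full = (
        agg.set_index(keys + ["segment"])
        .reindex(
            pd.MultiIndex.from_product(
                [agg[k].unique() for k in keys] + [all_segments], names=keys + ["segment"]
            )
        )
        .reset_index()
    )
    full["n"] = full["n"].fillna(0).astype(int)
    return full


def relevance_flags(
    summaries_a: pd.DataFrame,
    summaries_b: pd.DataFrame,
    rule: str = "pooled",
) -> pd.DataFrame:
    """Flag segments whose mean difference exceeds 2 x SD.

    ``rule`` picks the SD reading:

    - ``"pooled"``: pooled sample SD of the two segments' values
      (sqrt of the df-weighted average of the variances) — the default;
    - ``"sd_of_means"``: sample SD of the two segment means;
    - ``"sum_sd"``: sum of the two segment SDs.

    Flags are strict (difference must *exceed* the threshold) and symmetric
    in the two inputs.  Segments with fewer than two values on either side
    are marked ``undetermined`` (rendered grey, never red).
    """
    if rule not in RULES:
        raise DomainError(f"unknown rule {rule!r}; expected one of {RULES}")
    key = ["gene", "segment"]
    a = summaries_a.set_index(key).sort_index()
    b = summaries_b.set_index(key).sort_index()
    if not a.index.equals(b.index):
        raise ValidationError("segment summaries do not cover matching gene/segment sets")
    groups = (
        str(a["group"].iloc[0]) if "group" in a.columns else "a",
        str(b["group"].iloc[0]) if "group" in b.columns else "b",
    )
    na, nb = a["n"].to_numpy(), b["n"].to_numpy()
    ma, mb = a["mean"].to_numpy(), b["mean"].to_numpy()
    sa, sb = a["sd"].to_numpy(), b["sd"].to_numpy()
    undetermined = (na < 2) | (nb < 2) | np.isnan(sa) | np.isnan(sb)
    diff = np.abs(ma - mb)
    with np.errstate(invalid="ignore"):
        if rule == "pooled":
            sd = np.sqrt(((na - 1) * sa**2 + (nb - 1) * sb**2) / (na + nb - 2))
        elif rule == "sd_of_means":
            sd = np.abs(ma - mb) / np.sqrt(2.0)
        else:
            sd = sa + sb
    threshold = 2.0 * sd
    flagged = ~undetermined & (diff > threshold)
    out = a.reset_index()[key].copy()
    out["comparison"] = f"{groups[0]} vs {groups[1]}"
    out["diff"] = diff
    out["threshold"] = threshold
    out["flagged"] = flagged
    out["undetermined"] = undetermined
    return out


def _segment_patches(scheme: SegmentScheme):
    edges = (0.0, *scheme.ring_bounds, 1.0)
    patches = {}
    for i, (start, labels) in enumerate(scheme.rings):
        r0, r1 = edges[i], edges[i + 1]
        width = 360.0 / len(labels)
        for k, seg in enumerate(labels):
            t0 = start + k * width
            patches[seg] = (r0, r1, t0, t0 + width)
    return patches


def render_segment_polar(
    data,
    scheme: SegmentScheme | None = None,
    value_column: str | None = None,
    title: str | None = None,
    ax=None,
    path=None,
):
    """Draw the 17-segment schematic polar display.

    ``data`` is either a flags frame (from :func:`relevance_flags`; flagged
    segments red, undetermined grey, the rest white) or a mapping/frame of
    per-segment values coloured on a sequential scale via ``value_column``.
    All 17 segments must be present.
    """
    scheme = scheme or DEFAULT_SCHEME
    patches = _segment_patches(scheme)
    if isinstance(data, pd.DataFrame) and "flagged" in data.columns:
        sub = data.drop_duplicates("segment").set_index("segment")
        missing = set(patches) - set(sub.index)
        if missing:
            raise ValidationError(f"missing segments: {sorted(missing)}")
        def facecolor(seg):
            if bool(sub.loc[seg, "undetermined"]):
                return "0.75"
            return "#d7191c" if bool(sub.loc[seg, "flagged"]) else "white"
        colors = {seg: facecolor(seg) for seg in patches}
    else:
        if isinstance(data, pd.DataFrame):
            col = value_column or "mean"
            series = data.drop_duplicates("segment").set_index("segment")[col]
        else:
            series = pd.Series(dict(data))
        missing = set(patches) - set(series.index)
        if missing:
            raise ValidationError(f"missing segments: {sorted(missing)}")
        vals = series.astype(float)
        lo, hi = vals.min(), vals.max()
        span = (hi - lo) or 1.0
        cmap = plt.get_cmap("viridis")
        colors = {seg: cmap((vals[seg] - lo) / span) for seg in patches}

    if ax is None:
        fig, ax = plt.subplots(figsize=(4.2, 4.2))
    else:
        fig = ax.figure
    for seg, (r0, r1, t0, t1) in patches.items():
        ax.add_patch(
            Wedge((0, 0), r1, t0, t1, width=r1 - r0, facecolor=colors[seg],
                  edgecolor="k", lw=0.8)
        )
        rc = (r0 + r1) / 2 if r0 > 0 else 0.0
        tc = np.radians((t0 + t1) / 2)
        ax.text(rc * np.cos(tc), rc * np.sin(tc), str(seg),
                ha="center", va="center", fontsize=7)
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
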