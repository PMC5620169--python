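"""Zone delineation, transposition and the ANOVA + Holm-Sidak workflow."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cardiomap import (
    ZonePolygon,
    anova_groups,
    compare_zone_groups,
    holm_sidak_adjust,
    ischemic_zone_polygon,
    point_in_zone,
    transpose_zone,
    zone_summaries,
)
from cardiomap.errors import DomainError, ZoneError

SQUARE = ZonePolygon("ischemic", [[-0.3, -0.3], [0.3, -0.3], [0.3, 0.3], [-0.3, 0.3]])


def test_zone_polygon_validation():
    with pytest.raises(ZoneError):
        ZonePolygon("z", [[0, 0], [0.1, 0.1]])  # too few vertices
    with pytest.raises(ZoneError):
        ZonePolygon("z", [[0, 0], [0.2, 0.2], [0.2, 0.0], [0.0, 0.2]])  # bow-tie
    with pytest.raises(ZoneError):
        ZonePolygon("z", [[0, 0], [1.5, 0], [0, 0.5]])  # vertex outside the disk


def test_point_in_zone_basics():
    assert point_in_zone([0.0, 0.0], SQUARE)
    assert not point_in_zone([0.9, 0.0], SQUARE)
    assert point_in_zone([0.3, 0.0], SQUARE)  # on an edge: counts as inside
    assert point_in_zone([0.3, 0.3], SQUARE)  # on a vertex
    with pytest.raises(DomainError):
        point_in_zone([1.2, 0.2], SQUARE)


def ray_casting_oracle(point, vertices):
    """Independent even-odd crossing-number classification (interior only)."""
    x, y = point
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x_cross > x:
                inside = not inside
    return inside


def test_point_in_zone_matches_ray_casting_oracle():
    rng = np.random.default_rng(17)
    # star-shaped polygon
    angles = np.linspace(0, 2 * np.pi, 10, endpoint=False)
    radii = np.where(np.arange(10) % 2 == 0, 0.8, 0.35)
    star = ZonePolygon("star", np.column_stack([radii * np.cos(angles), radii * np.sin(angles)]))
    r = np.sqrt(rng.uniform(0, 1, 200)) * 0.99
    t = rng.uniform(0, 2 * np.pi, 200)
    pts = np.column_stack([r * np.cos(t), r * np.sin(t)])
    fast = point_in_zone(pts, star)
    slow = np.array([ray_casting_oracle(p, star.vertices) for p in pts])
    assert np.array_equal(fast, slow)


def test_transpose_zone_is_an_exact_set_identity(study):
    zone = ischemic_zone_polygon(study.config)
    maps = {g: study.locations for g in ("control", "ir5h", "ir24h")}
    cls = transpose_zone(zone, maps)
    by_group = {g: set(sub.loc[sub["inside"], "location_id"]) for g, sub in cls.groupby("group")}
    assert by_group["control"] == by_group["ir5h"] == by_group["ir24h"]
    truth = set(study.truth.zone.loc[study.truth.zone["in_zone"], "location_id"])
    assert by_group["ir5h"] == truth


def test_transpose_zone_rejects_mismatched_location_sets(study):
    other = study.locations.iloc[:-1]
    with pytest.raises(ZoneError):
        transpose_zone(SQUARE, {"control": study.locations, "ir5h": other})


def test_empty_zone_classifies_nothing(study):
    tiny = ZonePolygon("tiny", [[0.01, 0.21], [0.02, 0.21], [0.02, 0.22], [0.01, 0.22]])
    cls = transpose_zone(tiny, {"control": study.locations})
    assert cls["inside"].sum() == 0


def test_zone_summaries_arithmetic():
    expr = pd.DataFrame(
        {
            "gene": "g",
            "group": "control",
            "animal_id": "a1",
            "sample_id": ["l1", "l2", "l3", "l4", "l5"],
            "fold_change": [2.0, 4.0, 1.0, 1.0, 1.0],
        }
    )
    cls = {"l1": True, "l2": True, "l3": False, "l4": False, "l5": False}
    out = zone_summaries(expr, cls).set_index("zone")
    assert out.loc["ischemic", "mean_fold_change"] == pytest.approx(3.0)
    assert out.loc["remote", "mean_fold_change"] == pytest.approx(1.0)
    assert int(out.loc["ischemic", "n"]) + int(out.loc["remote", "n"]) == 5

    with pytest.raises(ZoneError):
        zone_summaries(expr, {k: False for k in cls})


# ---------------------------------------------------------------------------
# ANOVA

def test_anova_equal_group_means_give_zero_f():
    f, p = anova_groups([(1, 2, 3), (1, 2, 3), (1, 2, 3)])
    assert f == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_anova_constant_data_policy():
    assert anova_groups([(1.0, 1.0), (1.0, 1.0)]) == (0.0, 1.0)
    f, p = anova_groups([(1.0, 1.0), (2.0, 2.0)])
    assert np.isinf(f) and p == 0.0


def test_two_group_anova_is_squared_t():
    rng = np.random.default_rng(4)
    a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
    f, p = anova_groups([a, b])
    t = stats.ttest_ind(a, b, equal_var=True)
    assert f == pytest.approx(t.statistic**2, rel=1e-12)
    assert p == pytest.approx(t.pvalue, rel=1e-12)


def test_anova_matches_sums_of_squares_oracle():
    groups = [(1.0, 2.0), (3.0, 4.0), (5.0, 6.0)]
    f, p = anova_groups(groups)
    # from-scratch sums of squares
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, allv.size - len(groups)
    f_oracle = (ssb / dfb) / (ssw / dfw)
    assert f == pytest.approx(f_oracle, rel=1e-12)
    assert p == pytest.approx(stats.f.sf(f_oracle, dfb, dfw), rel=1e-12)


def test_anova_requires_two_groups_of_two():
    with pytest.raises(DomainError):
        anova_groups([(1, 2, 3)])
    with pytest.raises(DomainError):
        anova_groups([(1, 2), (3,)])


# ---------------------------------------------------------------------------
# Holm-Sidak

def holm_sidak_oracle(p):
    """Closed-form step-down formula, evaluated independently."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, val)
        adj[idx] = min(1.0, running)
    return adj


def test_holm_sidak_printed_example():
    adj = holm_sidak_adjust([0.01, 0.02, 0.04])
    assert np.allclose(adj, [0.029701, 0.039600, 0.040000], atol=5e-7)
    assert np.allclose(adj, holm_sidak_oracle([0.01, 0.02, 0.04]), atol=1e-12)


def test_holm_sidak_identities():
    assert np.allclose(holm_sidak_adjust([1.0, 1.0]), [1.0, 1.0])
    assert holm_sidak_adjust([0.03])[0] == pytest.approx(0.03)
    with pytest.raises(DomainError):
        holm_sidak_adjust([0.1, 1.2])


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
def test_holm_sidak_dominates_holm_bonferroni(p):
    adj = holm_sidak_adjust(p)
    p_arr = np.asarray(p)
    # Holm-Bonferroni oracle
    order = np.argsort(p_arr, kind="stable")
    m = p_arr.size
    hb = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p_arr[idx]))
        hb[idx] = running
    assert np.all(adj <= hb + 1e-12)
    assert np.all(adj >= p_arr - 1e-12)  # adjusted >= raw
    assert np.allclose(adj, holm_sidak_oracle(p_arr), atol=1e-9)
    # step-down monotonicity
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_compare_zone_groups_structure(study, expression):
    zone = ischemic_zone_polygon(study.config)
    cls = transpose_zone(zone, {"control": study.locations}).drop_duplicates("location_id")
    stats_df = compare_zone_groups(zone_summaries(expression, cls[["location_id", "inside"]]))
    assert set(stats_df["zone"]) == {"ischemic", "remote"}
    assert len(stats_df) == expression["gene"].nunique() * 2
    adj_cols = [c for c in stats_df.columns if c.startswith("p_adj_")]
    raw_cols = [c.replace("p_adj_", "p_") for c in adj_cols]
    assert np.all(stats_df[adj_cols].to_numpy() >= stats_df[raw_cols].to_numpy() - 1e-12)
    assert np.all(stats_df["f_statistic"] >= 0)
    # a strong configured 5h core effect must be detected for CASP3 ischemic
    row = stats_df.query("gene == 'CASP3' and zone == 'ischemic'").iloc[0]
    assert row["p_adj_control_vs_ir5h"] < 0.001
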