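import numpy as np
import pandas as pd
import pytest

from woodgen import renewal
from woodgen.landscape import NestboxMap


def line_map(n=20, spacing=200.0):
    return NestboxMap(box_ids=np.arange(n),
                      xy=np.column_stack([np.arange(n) * spacing,
                                          np.zeros(n)]))


def test_select_areas_on_a_line():
    m = line_map(20)
    sel = renewal.select_areas(m, k=3)
    assert sel.anchor_box_a == 0 and sel.anchor_box_b == 19
    np.testing.assert_array_equal(sel.member_boxes_a, [0, 1, 2])
    np.testing.assert_array_equal(sel.member_boxes_b, [17, 18, 19])


def test_select_areas_tie_is_deterministic():
    # a square: the two diagonals tie; the lexicographically smallest
    # anchor pair (0, 3) must win every time
    xy = np.array([[0, 0], [100, 0], [0, 100], [100, 100.0]])
    m = NestboxMap(box_ids=np.arange(4), xy=xy)
    sel = renewal.select_areas(m, k=1)
    assert (sel.anchor_box_a, sel.anchor_box_b) == (0, 3)


def test_select_areas_overlap_raises():
    # two far endpoints with everything else clustered in the middle:
    # both anchors reach into the same central boxes
    xy = np.vstack([[[0, 0.0]], [[4000, 0.0]],
                    np.column_stack([np.full(12, 2000.0), np.zeros(12)])])
    m = NestboxMap(box_ids=np.arange(14), xy=xy)
    with pytest.raises(ValueError, match="overlap"):
        renewal.select_areas(m, k=6)


def test_generated_layout_areas_are_separated():
    from woodgen.config import SimulationConfig
    from woodgen.landscape import build_landscape
    m = build_landscape(SimulationConfig(n_boxes=1019, extent_m=4000, seed=2))
    sel = renewal.select_areas(m, k=50)
    ca = m.coords_of(sel.member_boxes_a).mean(axis=0)
    cb = m.coords_of(sel.member_boxes_b).mean(axis=0)
    assert np.hypot(*(ca - cb)) > 2000
    from shapely.geometry import MultiPoint
    ha = MultiPoint([tuple(p) for p in m.coords_of(sel.member_boxes_a)]).convex_hull
    hb = MultiPoint([tuple(p) for p in m.coords_of(sel.member_boxes_b)]).convex_hull
    assert not ha.intersects(hb)


# --------------------------------------------------------------------------
# hull density

def test_hull_density_square_and_triangle():
    sq = np.array([[0, 0], [100, 0], [100, 100], [0, 100.0]])
    area, dens = renewal.hull_density(sq)
    assert area == pytest.approx(1.0)
    assert dens == pytest.approx(4.0)
    tri = np.array([[0, 0], [100, 0], [0, 100.0]])
    area, _ = renewal.hull_density(tri)
    assert area == pytest.approx(0.5)


def test_hull_density_matches_shoelace_oracle(rng):
    def shoelace(poly):
        x, y = poly[:, 0], poly[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    from scipy.spatial import ConvexHull
    pts = rng.uniform(0, 1000, size=(50, 2))
    hull_pts = pts[ConvexHull(pts).vertices]
    area, dens = renewal.hull_density(pts)
    assert area == pytest.approx(shoelace(hull_pts) / 1e4, rel=1e-9)
    assert dens == pytest.approx(50 / area, rel=1e-9)


def test_hull_density_collinear_raises():
    with pytest.raises(ValueError):
        renewal.hull_density(np.array([[0, 0], [1, 1], [2, 2.0]]))


# --------------------------------------------------------------------------
# lag curves

def _random_mating_pairs(rng, n_per_area=40, n_years=6, base=0.02,
                         noise=0.01):
    """Birth cohorts in two areas with no spatial or temporal structure."""
    m = line_map(30, spacing=150.0)
    sel = renewal.select_areas(m, k=8)
    rows, ids = [], []
    iid = 0
    for area, boxes in (("A", sel.member_boxes_a), ("B", sel.member_boxes_b)):
        for _ in range(n_per_area):
            rows.append(dict(id=iid, natal_box=rng.choice(boxes),
                             birth_year=int(rng.integers(0, n_years)),
                             sex="M", status="local", dam=None, sire=None,
                             social_sire=None))
            iid += 1
    individuals = pd.DataFrame(rows)
    ids = individuals["id"].to_numpy()
    iu, ju = np.triu_indices(len(ids), k=1)
    pairs = pd.DataFrame({"id_a": ids[iu], "id_b": ids[ju],
                          "pi_hat": base + noise * rng.random(len(iu))})
    return pairs, sel, individuals


def test_random_mating_lag_curve_starts_at_baseline(rng):
    pairs, sel, individuals = _random_mating_pairs(rng)
    curves = renewal.lag_curve(pairs, sel, individuals, n_boot=100, seed=4)
    for c in curves.values():
        assert c.crossing_lag == 0.0
        assert c.ci_lo[0] <= c.baseline <= c.ci_hi[0]


def test_baseline_invariant_to_area_swap(rng):
    pairs, sel, individuals = _random_mating_pairs(rng)
    swapped = renewal.AreaSelection(
        anchor_box_a=sel.anchor_box_b, anchor_box_b=sel.anchor_box_a,
        member_boxes_a=sel.member_boxes_b, member_boxes_b=sel.member_boxes_a,
        hull_area_ha=sel.hull_area_ha[::-1],
        density_boxes_per_ha=sel.density_boxes_per_ha[::-1])
    c1 = renewal.lag_curve(pairs, sel, individuals, n_boot=10, seed=0)
    c2 = renewal.lag_curve(pairs, swapped, individuals, n_boot=10, seed=0)
    assert c1["A"].baseline == pytest.approx(c2["B"].baseline)


def test_structured_cohorts_decay_toward_baseline(rng):
    """Same-cohort, same-area pairs are more related; relatedness fades
    with birth-year lag down to the cross-area level."""
    pairs, sel, individuals = _random_mating_pairs(rng, n_per_area=50,
                                                   noise=0.004)
    by = individuals.set_index("id")["birth_year"]
    area = individuals.set_index("id")["natal_box"].isin(
        set(sel.member_boxes_a.tolist()))
    lag = (by.loc[pairs["id_a"]].to_numpy()
           - by.loc[pairs["id_b"]].to_numpy())
    same_area = (area.loc[pairs["id_a"]].to_numpy()
                 == area.loc[pairs["id_b"]].to_numpy())
    bump = np.where(same_area, 0.08 * np.exp(-np.abs(lag) / 0.8), 0.0)
    # individual-level heterogeneity so the cluster bootstrap has
    # genuine between-individual variance to propagate
    eff = pd.Series(rng.normal(0, 0.003, len(individuals)),
                    index=individuals["id"])
    pairs = pairs.assign(pi_hat=pairs["pi_hat"] + bump
                         + eff.loc[pairs["id_a"]].to_numpy()
                         + eff.loc[pairs["id_b"]].to_numpy())
    curves = renewal.lag_curve(pairs, sel, individuals, n_boot=150, seed=5)
    for c in curves.values():
        assert c.mean[0] > c.baseline
        assert c.ci_lo[0] > c.baseline     # clearly above at lag 0
        assert 1 <= c.crossing_lag <= 5


def test_pooled_curve_combines_areas(rng):
    pairs, sel, individuals = _random_mating_pairs(rng)
    curves = renewal.lag_curve(pairs, sel, individuals, n_boot=10, seed=0,
                               include_pooled=True)
    assert curves["pooled"].n_pairs.sum() == (curves["A"].n_pairs.sum()
                                              + curves["B"].n_pairs.sum())
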