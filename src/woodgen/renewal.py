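"""Temporal renewal of spatial genetic structure.

The spatial relatedness pattern is maintained by the continual arrival and
death of close kin rather than by a fixed genetic substrate.  To show this,
two maximally separated areas of the woodland are selected (the two most
distant nest boxes plus the k nearest boxes around each); within each area,
mean identity by descent is tracked for pairs of birds born increasing
numbers of years apart, and compared against a cross-wood baseline -- the
average relatedness of same-cohort birds from opposite areas.  The lag at
which the within-area curve first becomes statistically indistinguishable
from the baseline measures how fast the genetic basis of the pattern turns
over.  Convex-hull nestbox density is reported per area so that density
differences are not mistaken for turnover differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .landscape import NestboxMap

__all__ = ["AreaSelection", "select_areas", "hull_density",
           "LagCurve", "lag_curve"]


@dataclass
class AreaSelection:
    anchor_box_a: int
    anchor_box_b: int
    member_boxes_a: np.ndarray
    member_boxes_b: np.ndarray
    hull_area_ha: tuple[float, float]
    density_boxes_per_ha: tuple[float, float]


def select_areas(nestbox_map: NestboxMap, k: int = 50) -> AreaSelection:
    """Anchor on the two most distant boxes; take the k nearest boxes to
    each anchor (anchor included).  Ties in anchor distance resolve to the
    lexicographically smallest (id_a, id_b); nearest-box ties to the lowest
    box id.  Overlapping member sets raise an error."""
    ids, xy = nestbox_map.box_ids, nestbox_map.xy
    if len(ids) < 2 * k + 2:
        raise ValueError(f"need at least {2 * k + 2} boxes for k={k}")
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    dmax = d2.max()
    cand = np.argwhere(d2 >= dmax - 1e-9)
    cand = cand[cand[:, 0] < cand[:, 1]]
    pairs = sorted((int(ids[i]), int(ids[j])) for i, j in cand)
    ia_id, ib_id = pairs[0]
    ia = int(np.searchsorted(ids, ia_id))
    ib = int(np.searchsorted(ids, ib_id))

    def nearest(anchor_idx: int) -> np.ndarray:
        order = np.lexsort((ids, d2[anchor_idx]))
        return np.sort(ids[order[:k]])

    mem_a, mem_b = nearest(ia), nearest(ib)
    if len(np.intersect1d(mem_a, mem_b)):
        raise ValueError("area member sets overlap; woodland too small "
                         "for the requested k")
    areas, dens = [], []
    for mem in (mem_a, mem_b):
        try:
            ha, de = hull_density(nestbox_map.coords_of(mem))
        except ValueError:   # degenerate (tiny or collinear) member set
            ha = de = float("nan")
        areas.append(ha); dens.append(de)
    return AreaSelection(anchor_box_a=ia_id, anchor_box_b=ib_id,
                         member_boxes_a=mem_a, member_boxes_b=mem_b,
                         hull_area_ha=tuple(areas),
                         density_boxes_per_ha=tuple(dens))


def hull_density(xy: np.ndarray) -> tuple[float, float]:
    """Convex-hull area (hectares) and boxes per hectare for a box set."""
    if len(xy) < 3:
        raise ValueError("need at least 3 boxes for a hull")
    hull = MultiPoint([tuple(p) for p in xy]).convex_hull
    if hull.area <= 0:
        raise ValueError("boxes are collinear; hull has no area")
    area_ha = hull.area / 1e4
    return area_ha, len(xy) / area_ha


@dataclass
class LagCurve:
    area: str
    lags: np.ndarray
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_pairs: np.ndarray
    baseline: float
    baseline_ci: tuple[float, float]
    crossing_lag: float   # smallest lag whose CI contains the baseline

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"area": self.area, "lag_years": self.lags,
                             "mean": self.mean, "ci_lo": self.ci_lo,
                             "ci_hi": self.ci_hi, "n_pairs": self.n_pairs})


def _boot_mean(values, id_a, id_b, n_boot, rng):
    ids = np.unique(np.concatenate([id_a, id_b]))
    pos = {v: i for i, v in enumerate(ids)}
    ai = np.array([pos[v] for v in id_a])
    bi = np.array([pos[v] for v in id_b])
    means = []
    for _ in range(n_boot):
        mult = np.bincount(rng.integers(len(ids), size=len(ids)),
                           minlength=len(ids))
        w = (mult[ai] * mult[bi]).astype(float)
        if w.sum() > 0:
            means.append(float(np.average(values, weights=w)))
    return np.array(means)


def lag_curve(pairs: pd.DataFrame, selection: AreaSelection,
              individuals: pd.DataFrame, value_col: str = "pi_hat",
              max_lag: int | None = None, n_boot: int = 200,
              min_pairs: int = 10, seed: int = 0,
              include_pooled: bool = False) -> dict[str, LagCurve]:
    """Within-area relatedness by birth-year lag, against the cross-wood
    baseline.

    Area membership is by NATAL box (the analysis concerns birth cohorts);
    immigrants, having no natal box, never enter.  The baseline averages
    same-cohort cross-area pairs over every year with at least
    ``min_pairs`` such pairs.  ``crossing_lag`` is the smallest lag whose
    bootstrap CI contains the baseline (0 if already at lag 0; NaN if the
    curve never reaches it)."""
    ind = individuals.set_index("id")
    natal = ind["natal_box"]
    birth = ind["birth_year"]

    def area_of(iid):
        nb = natal.get(iid)
        if nb is None or pd.isna(nb):
            return None
        nb = int(nb)
        if nb in set(selection.member_boxes_a.tolist()):
            return "A"
        if nb in set(selection.member_boxes_b.tolist()):
            return "B"
        return None

    df = pairs.dropna(subset=[value_col]).copy()
    df["area_a"] = [area_of(i) for i in df["id_a"]]
    df["area_b"] = [area_of(i) for i in df["id_b"]]
    df["by_a"] = [birth.get(i) for i in df["id_a"]]
    df["by_b"] = [birth.get(i) for i in df["id_b"]]
    df = df.dropna(subset=["area_a", "area_b", "by_a", "by_b"])
    df["lag"] = (df["by_a"] - df["by_b"]).abs().astype(int)

    rng = np.random.default_rng(seed)

    # cross-wood baseline: same-cohort, opposite-area pairs
    cross = df[(df["area_a"] != df["area_b"]) & (df["lag"] == 0)]
    counts = cross.groupby("by_a").size()
    good_years = counts[counts >= min_pairs].index
    cross = cross[cross["by_a"].isin(good_years)]
    if len(cross) == 0:
        baseline, base_ci = np.nan, (np.nan, np.nan)
    else:
        baseline = float(cross[value_col].mean())
        bb = _boot_mean(cross[value_col].to_numpy(),
                        cross["id_a"].to_numpy(), cross["id_b"].to_numpy(),
                        n_boot, rng)
        base_ci = (tuple(np.percentile(bb, [2.5, 97.5]))
                   if len(bb) else (baseline, baseline))

    out = {}
    labels = ("A", "B", "pooled") if include_pooled else ("A", "B")
    for label in labels:
        if label == "pooled":
            within = df[(df["area_a"] == df["area_b"])
                        & df["area_a"].isin(["A", "B"])]
        else:
            within = df[(df["area_a"] == label) & (df["area_b"] == label)]
        lags = (np.arange(0, max_lag + 1) if max_lag is not None
                else np.arange(0, int(within["lag"].max()) + 1 if len(within)
                               else 1))
        mean = np.full(len(lags), np.nan)
        lo = np.full(len(lags), np.nan)
        hi = np.full(len(lags), np.nan)
        n = np.zeros(len(lags), dtype=int)
        for i, lag in enumerate(lags):
            sub = within[within["lag"] == lag]
            n[i] = len(sub)
            if n[i] == 0:
                continue
            mean[i] = float(sub[value_col].mean())
            bb = _boot_mean(sub[value_col].to_numpy(),
                            sub["id_a"].to_numpy(), sub["id_b"].to_numpy(),
                            n_boot, rng)
            if len(bb):
                lo[i], hi[i] = np.percentile(bb, [2.5, 97.5])
                lo[i], hi[i] = min(lo[i], mean[i]), max(hi[i], mean[i])
        crossing = np.nan
        if np.isfinite(baseline):
            for i, lag in enumerate(lags):
                if n[i] >= min_pairs and np.isfinite(lo[i]) and \
                        lo[i] <= baseline <= hi[i]:
                    crossing = float(lag)
                    break
        out[label] = LagCurve(area=label, lags=lags, mean=mean, ci_lo=lo,
                              ci_hi=hi, n_pairs=n, baseline=baseline,
                              baseline_ci=base_ci, crossing_lag=crossing)
    return out
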