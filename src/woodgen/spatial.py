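"""Population structure and isolation by distance.

Covers: PCA of standardized genotypes; annotation of pairwise records with
breeding/natal distances, pair type and sex pair; progressive kin stripping
(by SNP-estimated kinship degree or by social-pedigree links); binned
relatedness-distance decay curves with individual-level cluster-bootstrap
confidence intervals; and penalized-spline fits of relatedness on distance
per immigration-status stratum, summarised by the average first derivative
of the fitted smooth (reported per km and per SD of distance).

Because every individual appears in many pairs, all uncertainty here
resamples *individuals*, never pairs: a bootstrap replicate keeps the pairs
whose two members are both drawn, with multiplicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix
from .kincalc import DEGREE_CUTOFFS, classify_degree

__all__ = [
    "PcaResult", "pca", "pair_table", "strip_kin",
    "DecayCurve", "decay_curve", "RegressionFit", "stratified_fit",
    "z_relatedness", "chrom_sex_contrast", "chrom_mean_contrast",
    "DEFAULT_BINS",
]

DEFAULT_BINS = np.arange(0.0, 4500.0, 500.0)  # 0-4 km in 500 m bins


# --------------------------------------------------------------------------
# PCA

@dataclass
class PcaResult:
    scores: np.ndarray              # (n_samples, k)
    variance_explained: np.ndarray  # (k,) fractions of total variance
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        ve = self.variance_explained
        if np.any(ve < -1e-12) or np.any(np.diff(ve) > 1e-12) or ve.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must be non-negative, "
                             "non-increasing and sum to at most 1")


def pca(g: GenotypeMatrix, n_components: int = 15) -> PcaResult:
    """PCA of genotypes centred by 2p and scaled by sqrt(2p(1-p)).

    Missing calls are mean-imputed; monomorphic loci are dropped with a
    warning.  Variance fractions are eigenvalues of the sample covariance
    over the total (sum over all components).
    """
    p = g.allele_freq()
    poly = (p > 0) & (p < 1) & np.isfinite(p)
    if not poly.all():
        warnings.warn(f"dropping {int((~poly).sum())} monomorphic loci from PCA")
    x = g.dosage[:, poly].astype(np.float64)
    pj = p[poly]
    x[x < 0] = np.nan
    centred = x - 2.0 * pj
    centred = np.where(np.isnan(centred), 0.0, centred)
    centred /= np.sqrt(2.0 * pj * (1.0 - pj))
    gram = centred @ centred.T / centred.shape[1]
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0, None), vecs[:, order]
    k = min(n_components, len(vals))
    scores = vecs[:, :k] * np.sqrt(vals[:k])
    return PcaResult(scores=scores,
                     variance_explained=vals[:k] / max(vals.sum(), 1e-300),
                     sample_ids=g.samples["id"].to_numpy())


# --------------------------------------------------------------------------
# pair annotation

def _breeding_coords(breeding: pd.DataFrame, nestbox_map) -> dict[int, list]:
    """id -> list of (year, x, y) breeding records."""
    melted = (breeding.melt(id_vars=["year", "box_id"],
                            value_vars=["male_id", "female_id"], value_name="id")
              .dropna(subset=["id"]).astype({"id": int}))
    xy = nestbox_map.coords_of(melted["box_id"].to_numpy())
    melted["x"], melted["y"] = xy[:, 0], xy[:, 1]
    out: dict[int, list] = {}
    for iid, grp in melted.groupby("id"):
        out[iid] = list(zip(grp["year"], grp["x"], grp["y"]))
    return out


def _pair_distance(rec_a, rec_b, max_year_gap: int = 2) -> tuple[float, float]:
    """(breeding distance, year midpoint).

    Same-year co-breeding records take priority (minimum distance over
    co-bred years); otherwise the minimum across record pairs at most
    ``max_year_gap`` years apart; NaN if no such pair of records exists.
    """
    best_same, best_near = np.inf, np.inf
    year = np.nan
    for ya, xa, yya in rec_a:
        for yb, xb, yyb in rec_b:
            gap = abs(ya - yb)
            if gap > max_year_gap:
                continue
            d = np.hypot(xa - xb, yya - yyb)
            if gap == 0:
                if d < best_same:
                    best_same, year = d, ya
            elif d < best_near:
                best_near, year = d, (ya + yb) / 2
    if np.isfinite(best_same):
        return best_same, year
    if np.isfinite(best_near):
        return best_near, year
    return np.nan, np.nan


def pair_table(pairs: pd.DataFrame, individuals: pd.DataFrame,
               breeding: pd.DataFrame, nestbox_map,
               max_year_gap: int = 2) -> pd.DataFrame:
    """Annotate pair records with distances, pair type and sex pair.

    Adds breeding_distance_m (same-year co-breeding boxes, else the closest
    records <= ``max_year_gap`` years apart), natal_distance_m (only when
    both natal boxes are known -- immigrants have none), pair_type
    (local-local / local-immigrant / immigrant-immigrant) and sex_pair
    (MM/MF/FF).  Pairs without any usable coordinate pair keep NaN distance.
    """
    ind = individuals.set_index("id")
    recs = _breeding_coords(breeding, nestbox_map)
    a = pairs["id_a"].to_numpy()
    b = pairs["id_b"].to_numpy()

    bd = np.empty(len(pairs)); yr = np.empty(len(pairs))
    for i, (ia, ib) in enumerate(zip(a, b)):
        ra, rb = recs.get(ia), recs.get(ib)
        if ra is None or rb is None:
            bd[i], yr[i] = np.nan, np.nan
        else:
            bd[i], yr[i] = _pair_distance(ra, rb, max_year_gap)

    natal = ind["natal_box"].to_dict()
    nd = np.full(len(pairs), np.nan)
    has_a = np.array([natal.get(i) is not None and not pd.isna(natal.get(i))
                      for i in a])
    has_b = np.array([natal.get(i) is not None and not pd.isna(natal.get(i))
                      for i in b])
    both = has_a & has_b
    if both.any():
        xa = nestbox_map.coords_of(np.array([int(natal[i]) for i in a[both]]))
        xb = nestbox_map.coords_of(np.array([int(natal[i]) for i in b[both]]))
        nd[both] = np.hypot(*(xa - xb).T)

    status = ind["status"].to_dict()
    sex = ind["sex"].to_dict()
    n_imm = np.array([(status.get(ia) == "immigrant")
                      + (status.get(ib) == "immigrant") for ia, ib in zip(a, b)])
    pair_type = np.array(["local-local", "local-immigrant",
                          "immigrant-immigrant"])[n_imm]
    sexes = [frozenset_str(sex.get(ia, "U"), sex.get(ib, "U")) for ia, ib in zip(a, b)]

    out = pairs.copy()
    out["breeding_distance_m"] = bd
    out["mid_year"] = yr
    out["natal_distance_m"] = nd
    out["pair_type"] = pair_type
    out["sex_pair"] = sexes
    return out


def frozenset_str(sa: str, sb: str) -> str:
    return "".join(sorted([sa, sb]))  # MM / FM -> "FM" sorted, MM, FF


# --------------------------------------------------------------------------
# kin stripping

STRIP_LEVELS = ("none", "no_first", "no_first_second", "distant_only")


def _pedigree_relation(ind: pd.DataFrame) -> dict:
    """Map id -> (dam, sire) for social-pedigree relationship checks."""
    return {row.id: (row.dam, row.sire) for row in ind.itertuples()}


def strip_kin(pairs: pd.DataFrame, level: str = "none",
              source: str = "snp_degree",
              individuals: pd.DataFrame | None = None,
              remove_half_sibs: bool = False) -> pd.DataFrame:
    """Remove close-kin pairs.

    ``snp_degree`` mode thresholds KING phi: ``no_first`` drops phi above
    the first-degree lower bound (and duplicates), ``no_first_second`` also
    drops second degree, ``distant_only`` drops third degree and closer.
    ``social_pedigree`` mode removes parent-offspring and full-sib pairs
    (optionally half-sibs) inferred from dam/sire links.
    """
    if level == "none":
        return pairs.copy()
    if source == "snp_degree":
        if "phi" not in pairs:
            raise ValueError("snp_degree stripping needs a 'phi' column")
        cut = {"no_first": DEGREE_CUTOFFS["first"],
               "no_first_second": DEGREE_CUTOFFS["second"],
               "distant_only": DEGREE_CUTOFFS["third"]}[level]
        return pairs[~(pairs["phi"] > cut)].copy()
    if source == "social_pedigree":
        if individuals is None:
            raise ValueError("social_pedigree stripping needs the pedigree")
        par = {row.id: (row.dam, row.social_sire
                        if "social_sire" in individuals.columns else row.sire)
               for row in individuals.itertuples()}
        drop = np.zeros(len(pairs), dtype=bool)
        for i, (ia, ib) in enumerate(zip(pairs["id_a"], pairs["id_b"])):
            pa, pb = par.get(ia, (None, None)), par.get(ib, (None, None))
            po = ia in pb or ib in pa
            shared = sum(1 for x, y in zip(pa, pb)
                         if x is not None and not pd.isna(x) and x == y)
            fs = shared == 2
            hs = shared == 1
            drop[i] = po or fs or (remove_half_sibs and hs)
        return pairs[~drop].copy()
    raise ValueError(f"unknown source {source!r}")


# --------------------------------------------------------------------------
# decay curves

@dataclass
class DecayCurve:
    bins: np.ndarray        # (k+1,) edges in metres
    mean: np.ndarray        # (k,) mean relatedness per bin (NaN = empty)
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_pairs: np.ndarray
    stratum: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lo_m": self.bins[:-1], "hi_m": self.bins[1:],
            "mean": self.mean, "ci_lo": self.ci_lo, "ci_hi": self.ci_hi,
            "n_pairs": self.n_pairs, "stratum": self.stratum,
        })


def _cluster_bootstrap_means(values, id_a, id_b, bin_idx, n_bins, n_boot, rng):
    """Bootstrap bin means by resampling individuals with replacement."""
    ids = np.unique(np.concatenate([id_a, id_b]))
    pos = {v: i for i, v in enumerate(ids)}
    ai = np.array([pos[v] for v in id_a])
    bi = np.array([pos[v] for v in id_b])
    out = np.full((n_boot, n_bins), np.nan)
    for r in range(n_boot):
        draw = rng.integers(len(ids), size=len(ids))
        mult = np.bincount(draw, minlength=len(ids))
        w = mult[ai] * mult[bi]
        if w.sum() == 0:
            continue
        sums = np.bincount(bin_idx, weights=w * values, minlength=n_bins)
        cnts = np.bincount(bin_idx, weights=w.astype(float), minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[r] = np.where(cnts > 0, sums / cnts, np.nan)
    return out


def decay_curve(pairs: pd.DataFrame, value_col: str = "pi_hat",
                distance_col: str = "breeding_distance_m",
                bins: np.ndarray = DEFAULT_BINS, n_boot: int = 200,
                seed: int = 0, stratum: str = "") -> DecayCurve:
    """Binned mean relatedness vs distance with cluster-bootstrap 95% CI."""
    df = pairs.dropna(subset=[value_col, distance_col])
    d = df[distance_col].to_numpy()
    v = df[value_col].to_numpy()
    inside = (d >= bins[0]) & (d < bins[-1])
    df, d, v = df[inside], d[inside], v[inside]
    bin_idx = np.digitize(d, bins) - 1
    n_bins = len(bins) - 1
    n_pairs = np.bincount(bin_idx, minlength=n_bins)
    sums = np.bincount(bin_idx, weights=v, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_pairs > 0, sums / n_pairs, np.nan)
    rng = np.random.default_rng(seed)
    boots = _cluster_bootstrap_means(v, df["id_a"].to_numpy(),
                                     df["id_b"].to_numpy(), bin_idx,
                                     n_bins, n_boot, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        lo = np.nanpercentile(boots, 2.5, axis=0)
        hi = np.nanpercentile(boots, 97.5, axis=0)
    # a CI must contain its point estimate even at tiny bootstrap counts
    lo = np.fmin(lo, mean)
    hi = np.fmax(hi, mean)
    return DecayCurve(bins=np.asarray(bins, dtype=float), mean=mean,
                      ci_lo=lo, ci_hi=hi, n_pairs=n_pairs, stratum=stratum)


# --------------------------------------------------------------------------
# stratified spline fits

@dataclass
class RegressionFit:
    stratum: str
    beta_std: float          # mean d(relatedness)/d(distance in SD units)
    beta_std_ci: tuple[float, float]
    beta_per_km: float
    beta_per_km_ci: tuple[float, float]
    n_pairs: int
    spline_coefs: np.ndarray | None = None

    def __post_init__(self) -> None:
        for lo, hi in (self.beta_std_ci, self.beta_per_km_ci):
            if lo > hi:
                raise ValueError("CI bounds out of order")


def _spline_mean_derivative(d: np.ndarray, v: np.ndarray, df_spline: int,
                            alpha: float) -> tuple[float, np.ndarray]:
    """Penalized B-spline fit of v on d; returns the average first
    derivative of the smooth over the observed distances (per metre).

    The fit is a ridge-penalized least-squares solve with the curvature
    penalty of the B-spline basis, so a purely linear trend is never
    shrunk (it lies in the penalty null space).  Distance enters in SD
    units internally, which makes the penalty weight scale-free.
    """
    from statsmodels.gam.api import BSplines
    scale = d.std()
    ds = d / scale
    bs = BSplines(ds[:, None], df=[df_spline], degree=[3],
                  include_intercept=False)
    basis = bs.basis
    pen = bs.penalty_matrices[0]
    X = np.column_stack([np.ones(len(ds)), basis])
    P = np.zeros((X.shape[1], X.shape[1]))
    P[1:, 1:] = alpha * pen
    coef = np.linalg.solve(X.T @ X + P, X.T @ v)
    grid = np.linspace(ds.min(), ds.max(), 200)
    bg = bs.transform(grid[:, None])
    pred = coef[0] + bg @ coef[1:]
    deriv = np.gradient(pred, grid)
    # weight the derivative by where the data actually sit
    idx = np.clip(np.searchsorted(grid, ds), 0, len(grid) - 1)
    return float(deriv[idx].mean() / scale), coef


def stratified_fit(pairs: pd.DataFrame, value_col: str = "pi_hat",
                   distance_col: str = "breeding_distance_m",
                   strata_col: str | None = "pair_type",
                   min_pairs: int = 200, df_spline: int = 6,
                   alpha: float = 1.0, n_boot: int = 100,
                   seed: int = 0) -> list[RegressionFit]:
    """Per-stratum penalized-spline fit of relatedness on distance.

    The slope-like summary beta is the average first derivative of the
    fitted smooth over the observed distance range, reported both per SD of
    distance and per km, with 95% CIs from a cluster bootstrap over
    individuals (each replicate resamples individuals and refits).
    """
    df = pairs.dropna(subset=[value_col, distance_col])
    strata = (["all"] if strata_col is None
              else list(pd.unique(df[strata_col])))
    rng = np.random.default_rng(seed)
    fits = []
    for stratum in strata:
        sub = df if strata_col is None else df[df[strata_col] == stratum]
        if len(sub) < min_pairs:
            warnings.warn(f"stratum {stratum}: only {len(sub)} pairs (<"
                          f"{min_pairs}); skipped")
            continue
        d = sub[distance_col].to_numpy()
        v = sub[value_col].to_numpy()
        if np.ptp(d) <= 0:
            raise ValueError(f"stratum {stratum}: degenerate distance range")
        sd = d.std()
        beta_raw, coefs = _spline_mean_derivative(d, v, df_spline, alpha)

        ids = np.unique(np.concatenate([sub["id_a"], sub["id_b"]]))
        pos = {x: i for i, x in enumerate(ids)}
        ai = np.array([pos[x] for x in sub["id_a"]])
        bi = np.array([pos[x] for x in sub["id_b"]])
        boots = []
        for _ in range(n_boot):
            mult = np.bincount(rng.integers(len(ids), size=len(ids)),
                               minlength=len(ids))
            w = mult[ai] * mult[bi]
            sel = np.repeat(np.arange(len(sub)), w)
            if len(sel) < 10 or np.ptp(d[sel]) <= 0:
                continue
            try:
                b, _ = _spline_mean_derivative(d[sel], v[sel], df_spline, alpha)
                boots.append(b)
            except Exception:
                continue
        if boots:
            lo, hi = np.percentile(boots, [2.5, 97.5])
            lo, hi = min(lo, beta_raw), max(hi, beta_raw)
        else:
            lo = hi = beta_raw
        fits.append(RegressionFit(
            stratum=str(stratum),
            beta_std=beta_raw * sd, beta_std_ci=(lo * sd, hi * sd),
            beta_per_km=beta_raw * 1000.0,
            beta_per_km_ci=(lo * 1000.0, hi * 1000.0),
            n_pairs=len(sub), spline_coefs=coefs))
    return fits


# --------------------------------------------------------------------------
# autosome vs Z, by sex pair

def z_relatedness(g_z: GenotypeMatrix) -> pd.DataFrame:
    """Copy-aware dosage-correlation relatedness on the Z chromosome.

    Each call is centred by (copies * p) and scaled by sqrt(copies * p(1-p));
    the pairwise statistic is the mean cross-product over shared loci.  For
    two diploid samples this is the usual GRM-style estimate of pi-hat; for
    pairs involving a hemizygous female it generalises the same covariance
    to one allele copy.  Negative values are clamped to 0 to stay on the
    pi-hat-like scale.
    """
    p = g_z.allele_freq()
    poly = (p > 0) & (p < 1) & np.isfinite(p)
    sub = g_z.select_loci(np.flatnonzero(poly))
    p = sub.allele_freq()
    c = np.where(sub.hemi_mask, 1.0, 2.0)
    x = sub.dosage.astype(np.float64)
    miss = sub.dosage < 0
    centred = (x - c * p) / np.sqrt(c * p * (1 - p))
    centred[miss] = 0.0
    nonmiss = (~miss).astype(np.float64)
    num = centred @ centred.T
    den = nonmiss @ nonmiss.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    ids = sub.samples["id"].to_numpy()
    iu, ju = np.triu_indices(len(ids), k=1)
    return pd.DataFrame({"id_a": ids[iu], "id_b": ids[ju],
                         "pi_z": np.clip(r[iu, ju], 0.0, 1.0)})


def chrom_mean_contrast(g_auto: GenotypeMatrix, g_z: GenotypeMatrix,
                        seed: int = 0) -> tuple[float, float]:
    """Mean pairwise relatedness on the Z vs a matched autosomal set.

    Both chromosome sets are summarised with the same copy-aware
    dosage-correlation estimator, and the autosomal loci are randomly
    subsampled to the Z locus count so the two means carry comparable
    sampling noise.  Returns (mean_auto, mean_z): sex-limited Z
    transmission (brothers share at least their maternal Z) and the Z's
    smaller effective size concentrate sharing, so the Z mean exceeds the
    autosomal mean under sex-biased, dispersal-limited demography.
    """
    rng = np.random.default_rng(seed)
    n_z = g_z.n_loci
    if n_z == 0:
        raise ValueError("no Z loci")
    idx = np.sort(rng.choice(g_auto.n_loci, size=min(n_z, g_auto.n_loci),
                             replace=False))
    r_auto = z_relatedness(g_auto.select_loci(idx))
    r_z = z_relatedness(g_z)
    return (float(np.nanmean(r_auto["pi_z"])), float(np.nanmean(r_z["pi_z"])))


def chrom_sex_contrast(pairs_auto: pd.DataFrame, pairs_z: pd.DataFrame,
                       bins: np.ndarray = DEFAULT_BINS, n_boot: int = 100,
                       seed: int = 0) -> dict[tuple[str, str], DecayCurve]:
    """Decay curves for every (chromosome set x sex pair) combination.

    ``pairs_auto`` must carry pi_hat, ``pairs_z`` pi_z; both need
    breeding_distance_m and sex_pair columns (merge via pair_table)."""
    out = {}
    for label, df, col in (("autosomes", pairs_auto, "pi_hat"),
                           ("Z", pairs_z, "pi_z")):
        for sp in ("MM", "FM", "FF"):
            sub = df[df["sex_pair"] == sp]
            if len(sub) == 0:
                warnings.warn(f"no {sp} pairs for {label}")
                continue
            out[(label, sp)] = decay_curve(
                sub, value_col=col, bins=bins, n_boot=n_boot, seed=seed,
                stratum=f"{label}:{sp}")
    return out
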