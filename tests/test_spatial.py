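import warnings

import numpy as np
import pandas as pd
import pytest

from woodgen import genio, kincalc, spatial
from woodgen.landscape import NestboxMap
from woodgen.simulate import balding_nichols_freqs

from .conftest import hwe_genotypes, make_matrix


# --------------------------------------------------------------------------
# PCA

def test_pca_separates_diverged_pools(rng):
    from sklearn.metrics import silhouette_score
    p = np.clip(rng.beta(2, 2, 2000), 0.05, 0.95)
    pa = balding_nichols_freqs(p, 0.2, rng)
    pb = balding_nichols_freqs(p, 0.2, rng)
    d = np.vstack([hwe_genotypes(pa, 60, rng), hwe_genotypes(pb, 60, rng)])
    res = spatial.pca(make_matrix(d), n_components=5)
    labels = np.array([0] * 60 + [1] * 60)
    assert silhouette_score(res.scores[:, :1], labels) > 0.9
    assert res.variance_explained[0] > 3 * res.variance_explained[1]


def test_pca_panmictic_has_no_dominant_axis(rng):
    p = np.clip(rng.beta(2, 2, 1000), 0.1, 0.9)
    d = hwe_genotypes(p, 80, rng)
    res = spatial.pca(make_matrix(d), n_components=10)
    # permutation null: break genotype-sample linkage per locus
    perm = d.copy()
    for j in range(perm.shape[1]):
        perm[:, j] = rng.permutation(perm[:, j])
    null = spatial.pca(make_matrix(perm), n_components=10)
    assert res.variance_explained[0] < 1.3 * null.variance_explained[0]


def test_pca_duplicated_samples_get_identical_scores(rng):
    p = np.clip(rng.beta(2, 2, 500), 0.1, 0.9)
    d = hwe_genotypes(p, 30, rng)
    d[1] = d[0]
    res = spatial.pca(make_matrix(d), n_components=4)
    np.testing.assert_allclose(res.scores[0], res.scores[1], atol=1e-8)


# --------------------------------------------------------------------------
# pair annotation

@pytest.fixture()
def toy_population():
    nb = NestboxMap(box_ids=np.arange(3),
                    xy=np.array([[0.0, 0], [300, 400], [1000, 0]]))
    individuals = pd.DataFrame({
        "id": [1, 2, 3],
        "sex": ["M", "F", "M"],
        "birth_year": [0, 0, np.nan],
        "natal_box": [0, 1, np.nan],
        "status": ["local", "local", "immigrant"],
        "dam": [None, None, None], "sire": [None, None, None],
        "social_sire": [None, None, None],
    })
    breeding = pd.DataFrame({
        "year": [1, 1, 1],
        "box_id": [0, 1, 2],
        "male_id": [1, 3, None],
        "female_id": [None, 2, None],
    })
    return nb, individuals, breeding


def test_pair_distances_and_types(toy_population):
    nb, individuals, breeding = toy_population
    pairs = pd.DataFrame({"id_a": [1, 1, 2], "id_b": [2, 3, 3]})
    out = spatial.pair_table(pairs, individuals, breeding, nb)
    # ids 1 and 2 breed the same year at boxes 0 and 1: 3-4-5 triangle
    r12 = out[(out.id_a == 1) & (out.id_b == 2)].iloc[0]
    assert r12.breeding_distance_m == pytest.approx(500.0)
    assert r12.natal_distance_m == pytest.approx(500.0)
    assert r12.pair_type == "local-local" and r12.sex_pair == "FM"
    # immigrant pair member: no natal distance
    r13 = out[(out.id_a == 1) & (out.id_b == 3)].iloc[0]
    assert np.isnan(r13.natal_distance_m)
    assert r13.pair_type == "local-immigrant" and r13.sex_pair == "MM"
    # same box, same year
    r23 = out[(out.id_a == 2) & (out.id_b == 3)].iloc[0]
    assert r23.breeding_distance_m == 0.0


def test_cross_year_distance_uses_nearby_years(toy_population):
    nb, individuals, breeding = toy_population
    breeding = pd.DataFrame({
        "year": [1, 2, 1, 5],
        "box_id": [0, 1, 2, 2],
        "male_id": [1, None, 3, 3],
        "female_id": [None, 2, None, None],
    })
    pairs = pd.DataFrame({"id_a": [1, 2], "id_b": [2, 3]})
    out = spatial.pair_table(pairs, individuals, breeding, nb,
                             max_year_gap=2)
    # 1 (year 1, box 0) vs 2 (year 2, box 1): one year apart -> 500 m
    assert out.iloc[0].breeding_distance_m == pytest.approx(500.0)
    # 2 (year 2) vs 3 (years 1 and 5): year 1 within gap, year 5 not
    d23 = np.hypot(1000 - 300, 0 - 400)
    assert out.iloc[1].breeding_distance_m == pytest.approx(d23)


# --------------------------------------------------------------------------
# kin stripping

def test_strip_kin_levels():
    pairs = pd.DataFrame({
        "id_a": [1, 2, 3, 4], "id_b": [5, 6, 7, 8],
        "phi": [0.3, 0.12, 0.06, 0.01],
    })
    assert len(spatial.strip_kin(pairs, "none")) == 4
    assert len(spatial.strip_kin(pairs, "no_first")) == 3
    assert len(spatial.strip_kin(pairs, "no_first_second")) == 2
    stripped = spatial.strip_kin(pairs, "distant_only")
    assert len(stripped) == 1
    assert (stripped["phi"] <= kincalc.DEGREE_CUTOFFS["third"]).all()
    all_first = pairs.assign(phi=0.25)
    assert len(spatial.strip_kin(all_first, "no_first")) == 0


def test_strip_kin_social_pedigree():
    individuals = pd.DataFrame({
        "id": [1, 2, 3, 4, 5],
        "dam": [None, None, 1, 1, 1],
        "sire": [None, None, 2, 2, 9],
        "social_sire": [None, None, 2, 2, 9],
    })
    pairs = pd.DataFrame({"id_a": [1, 3, 3, 1], "id_b": [3, 4, 5, 2]})
    out = spatial.strip_kin(pairs, "no_first", source="social_pedigree",
                            individuals=individuals)
    # parent-offspring (1,3) and full sibs (3,4) removed; half sibs kept
    kept = set(map(tuple, out[["id_a", "id_b"]].to_numpy()))
    assert kept == {(3, 5), (1, 2)}
    out2 = spatial.strip_kin(pairs, "no_first", source="social_pedigree",
                             individuals=individuals, remove_half_sibs=True)
    assert set(map(tuple, out2[["id_a", "id_b"]].to_numpy())) == {(1, 2)}


# --------------------------------------------------------------------------
# decay curves and fits on synthetic pair data

def _synthetic_pairs(rng, n_ind=120, slope_per_m=0.0, noise=0.0,
                     base=0.05):
    ids = np.arange(n_ind)
    xy = rng.uniform(0, 4000, size=(n_ind, 2))
    iu, ju = np.triu_indices(n_ind, k=1)
    d = np.hypot(*(xy[iu] - xy[ju]).T)
    v = base + slope_per_m * d + noise * rng.normal(size=len(d))
    return pd.DataFrame({"id_a": ids[iu], "id_b": ids[ju],
                         "breeding_distance_m": d, "pi_hat": v})


def test_decay_curve_flat_under_random_mating(rng):
    pairs = _synthetic_pairs(rng, slope_per_m=0.0, noise=0.01)
    curve = spatial.decay_curve(pairs, n_boot=100, seed=1)
    ok = ~np.isnan(curve.mean)
    grand = np.nanmean(pairs["pi_hat"])
    assert ((curve.ci_lo[ok] <= grand) & (grand <= curve.ci_hi[ok])).mean() > 0.8
    assert (curve.ci_lo[ok] <= curve.mean[ok]).all()
    assert (curve.mean[ok] <= curve.ci_hi[ok]).all()


def test_decay_curve_detects_decline(rng):
    from scipy.stats import spearmanr
    pairs = _synthetic_pairs(rng, slope_per_m=-1e-5, noise=0.005)
    curve = spatial.decay_curve(pairs, n_boot=50, seed=1)
    ok = ~np.isnan(curve.mean)
    rho, p = spearmanr(np.arange(len(curve.mean))[ok], curve.mean[ok])
    assert rho < 0 and p < 0.01


def test_bootstrap_ci_widens_with_fewer_pairs(rng):
    pairs = _synthetic_pairs(rng, n_ind=150, noise=0.02)
    small = pairs.sample(200, random_state=0)
    c_big = spatial.decay_curve(pairs, n_boot=100, seed=2)
    c_small = spatial.decay_curve(small, n_boot=100, seed=2)
    wide_big = np.nanmean(c_big.ci_hi - c_big.ci_lo)
    wide_small = np.nanmean(c_small.ci_hi - c_small.ci_lo)
    assert wide_small > wide_big


def test_stratified_fit_recovers_linear_slope(rng):
    pairs = _synthetic_pairs(rng, slope_per_m=-1e-5, noise=0.0)
    sd = pairs["breeding_distance_m"].std()
    fit, = spatial.stratified_fit(pairs, strata_col=None, n_boot=0)
    assert fit.beta_std == pytest.approx(-1e-5 * sd, rel=0.05)
    assert fit.beta_per_km == pytest.approx(-0.01, rel=0.05)


def test_stratified_fit_null_ci_covers_zero(rng):
    pairs = _synthetic_pairs(rng, slope_per_m=-1e-5, noise=0.005)
    pairs["breeding_distance_m"] = rng.permutation(
        pairs["breeding_distance_m"].to_numpy())
    fit, = spatial.stratified_fit(pairs, strata_col=None, n_boot=60, seed=3)
    lo, hi = fit.beta_std_ci
    assert lo <= 0.0 <= hi


def test_stratified_fit_degenerate_distance_errors(rng):
    pairs = _synthetic_pairs(rng)
    pairs["breeding_distance_m"] = 100.0
    with pytest.raises(ValueError, match="degenerate"):
        spatial.stratified_fit(pairs, strata_col=None, min_pairs=10)


# --------------------------------------------------------------------------
# kin stripping flattens the curve on a simulated population

@pytest.fixture(scope="module")
def sim_pairs():
    from woodgen.config import SimulationConfig
    from woodgen.simulate import run_simulation
    cfg = SimulationConfig(n_boxes=200, occupancy=0.35, n_years=14,
                           n_autosomal_snps=1200, n_z_snps=300, seed=21)
    sim = run_simulation(cfg)
    g = genio.from_simulation(sim)
    rng = np.random.default_rng(0)
    sel = np.sort(rng.choice(g.n_samples, size=min(350, g.n_samples),
                             replace=False))
    g = g.select_samples(sel)
    ga = genio.split_datasets(g)["autosomal"]
    pairs = kincalc.mom_ibd(ga)
    king = kincalc.king_robust(ga)
    pairs = pairs.merge(king[["id_a", "id_b", "phi"]], on=["id_a", "id_b"])
    pairs = spatial.pair_table(pairs, sim.individuals, sim.breeding,
                               sim.nestbox_map)
    return sim, g, pairs


def _linear_slope(df, col="pi_hat"):
    ok = df.dropna(subset=[col, "breeding_distance_m"])
    return np.polyfit(ok["breeding_distance_m"], ok[col], 1)[0]


def test_kin_stripping_flattens_ibd_distance(sim_pairs):
    _, _, pairs = sim_pairs
    s_all = _linear_slope(pairs)
    s_strip = _linear_slope(spatial.strip_kin(pairs, "no_first"))
    assert s_all < 0
    assert abs(s_strip) < abs(s_all)
    stripped = spatial.strip_kin(pairs, "no_first")
    assert not (stripped["phi"] > kincalc.DEGREE_CUTOFFS["first"]).any()


def test_local_pairs_show_steeper_decline_than_immigrant_pairs(sim_pairs):
    _, _, pairs = sim_pairs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits = spatial.stratified_fit(pairs, n_boot=0, min_pairs=100)
    by = {f.stratum: f.beta_per_km for f in fits}
    assert by["local-local"] < by["immigrant-immigrant"]


def test_mm_pairs_have_steepest_z_decay(sim_pairs):
    sim, g, pairs = sim_pairs
    gz = genio.split_datasets(g)["z_only"]
    zp = spatial.z_relatedness(gz)
    zp = spatial.pair_table(zp, sim.individuals, sim.breeding,
                            sim.nestbox_map)
    s_mm = _linear_slope(zp[zp.sex_pair == "MM"], "pi_z")
    s_ff = _linear_slope(zp[zp.sex_pair == "FF"], "pi_z")
    assert s_mm < s_ff
    curves = spatial.chrom_sex_contrast(pairs, zp, n_boot=20, seed=0)
    assert ("Z", "MM") in curves and ("autosomes", "FF") in curves
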