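import numpy as np
import pandas as pd
import pytest

from woodgen import kincalc
from woodgen.kincalc import RohParams, classify_degree, king_robust, mom_ibd

from .conftest import hwe_genotypes, make_matrix


# --------------------------------------------------------------------------
# KING-robust

def king_oracle(a, b):
    """Direct per-pair KING-robust phi by explicit counting."""
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    n_het_het = int(((a == 1) & (b == 1)).sum())
    n_opp = int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum())
    denom = int((a == 1).sum() + (b == 1).sum())
    if denom == 0:
        return np.nan
    return (n_het_het - 2.0 * n_opp) / denom


def test_king_matches_counting_oracle_on_random_instances(rng):
    for _ in range(100):
        L = rng.integers(10, 60)
        n = rng.integers(2, 6)
        d = rng.integers(-1, 3, size=(n, L)).astype(np.int8)
        g = make_matrix(d)
        res = king_robust(g).set_index(["id_a", "id_b"])
        for i in range(n):
            for j in range(i + 1, n):
                expect = king_oracle(d[i], d[j])
                got = res.loc[(i, j), "phi"]
                if np.isnan(expect):
                    assert bool(res.loc[(i, j), "undefined"])
                else:
                    assert got == pytest.approx(expect, abs=1e-10)


def test_king_hand_counted_table():
    # counts: N_AaAa=2, N_AAaa=1, N_Aa(a)=4, N_Aa(b)=4 -> phi = (2-2)/8 = 0
    a = np.array([1, 1, 1, 1, 0, 0, 0], dtype=np.int8)
    b = np.array([1, 1, 0, 0, 1, 1, 2], dtype=np.int8)
    g = make_matrix(np.vstack([a, b]))
    assert king_robust(g)["phi"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_king_identical_samples_phi_half(rng):
    d = hwe_genotypes([0.3] * 400, 1, rng)
    g = make_matrix(np.vstack([d, d]))
    assert king_robust(g)["phi"].iloc[0] == pytest.approx(0.5, abs=1e-12)


def test_king_negative_between_diverged_pools(rng):
    from woodgen.simulate import balding_nichols_freqs
    p = np.clip(rng.beta(2, 2, 2000), 0.1, 0.9)
    pa = balding_nichols_freqs(p, 0.1, rng)
    pb = balding_nichols_freqs(p, 0.1, rng)
    d = np.vstack([hwe_genotypes(pa, 20, rng), hwe_genotypes(pb, 20, rng)])
    g = make_matrix(d)
    res = king_robust(g)
    cross = res[(res["id_a"] < 20) & (res["id_b"] >= 20)]
    assert cross["phi"].mean() < -0.01


# --------------------------------------------------------------------------
# degree classification

@pytest.mark.parametrize("phi,expected", [
    (0.4, "duplicate"), (0.25, "first"), (0.12, "second"), (0.05, "third"),
    (0.01, "unrelated"), (-0.1, "unrelated"), (np.nan, "unrelated"),
])
def test_degree_thresholds(phi, expected):
    assert classify_degree(phi) == expected


def test_full_sibs_classified_first_degree(rng):
    p = np.clip(rng.beta(2, 2, 5000), 0.1, 0.9)
    hits = 0
    n_pairs = 60
    rows = []
    for _ in range(n_pairs):
        dad = (rng.random((2, len(p))) < p).astype(np.int8)
        mum = (rng.random((2, len(p))) < p).astype(np.int8)
        for _ in range(2):
            pick_d = rng.integers(2, size=len(p))
            pick_m = rng.integers(2, size=len(p))
            rows.append(dad[pick_d, np.arange(len(p))]
                        + mum[pick_m, np.arange(len(p))])
    g = make_matrix(np.array(rows, dtype=np.int8))
    res = king_robust(g)
    sibs = res[(res["id_a"] % 2 == 0) & (res["id_b"] == res["id_a"] + 1)]
    degs = classify_degree(sibs["phi"].to_numpy())
    assert (degs == "first").mean() >= 0.95


# --------------------------------------------------------------------------
# method-of-moments IBD

def test_self_pair_pi_hat_one(rng):
    d = hwe_genotypes([0.4] * 2000, 1, rng)
    g = make_matrix(np.vstack([d, d]))
    assert mom_ibd(g)["pi_hat"].iloc[0] == pytest.approx(1.0, abs=1e-6)


def test_parent_offspring_pi_hat_half(rng):
    p = np.clip(rng.beta(2, 2, 5000), 0.15, 0.85)
    rows = []
    for _ in range(100):
        par = (rng.random((2, len(p))) < p).astype(np.int8)
        other = (rng.random((2, len(p))) < p).astype(np.int8)
        child = (par[rng.integers(2, size=len(p)), np.arange(len(p))]
                 + other[rng.integers(2, size=len(p)), np.arange(len(p))])
        rows += [par.sum(axis=0), child]
    g = make_matrix(np.array(rows, dtype=np.int8))
    res = mom_ibd(g)
    po = res[(res["id_a"] % 2 == 0) & (res["id_b"] == res["id_a"] + 1)]
    assert po["pi_hat"].mean() == pytest.approx(0.5, abs=0.02)


def test_unrelated_mean_pi_hat_near_zero(rng):
    p = np.clip(rng.beta(2, 2, 20_000), 0.1, 0.9)
    g = make_matrix(hwe_genotypes(p, 60, rng))
    res = mom_ibd(g)
    assert abs(res["pi_hat"].mean()) < 0.01


def test_mom_ibd_invariances(rng):
    p = np.clip(rng.beta(2, 2, 800), 0.15, 0.85)
    d = hwe_genotypes(p, 8, rng)
    g = make_matrix(d)
    base = mom_ibd(g)
    # locus-order permutation leaves estimates unchanged
    perm = rng.permutation(d.shape[1])
    g2 = make_matrix(d[:, perm], pos=np.arange(d.shape[1]) * 1000 + 1)
    np.testing.assert_allclose(base["pi_hat"], mom_ibd(g2)["pi_hat"],
                               atol=1e-12)
    # pair symmetry: reversing the sample order flips ids only
    g3 = make_matrix(d[::-1])
    res3 = mom_ibd(g3)
    merged = base.merge(
        res3.assign(id_a=7 - res3["id_b"], id_b=7 - res3["id_a"]),
        on=["id_a", "id_b"], suffixes=("", "_r"))
    np.testing.assert_allclose(merged["pi_hat"], merged["pi_hat_r"],
                               atol=1e-12)


def test_low_confidence_flagged():
    d = np.array([[0, 1, 2], [1, 1, 0]], dtype=np.int8)
    g = make_matrix(np.repeat(d, 1, axis=0))
    res = mom_ibd(g, maf_floor=0.0)
    assert res["low_confidence"].all()


# --------------------------------------------------------------------------
# ROH

def roh_oracle(dosage, pos, p: RohParams):
    """Brute-force scanning-window ROH caller (independent loops)."""
    n = len(pos)
    het = dosage == 1
    miss = dosage < 0
    w = min(p.window_snp, n)
    good = []
    for s in range(n - w + 1):
        good.append(het[s:s + w].sum() <= p.window_het
                    and miss[s:s + w].sum() <= p.window_missing)
    cand = []
    for i in range(n):
        votes = [good[s] for s in range(max(0, i - w + 1),
                                        min(i, n - w) + 1)]
        cand.append(sum(votes) / len(votes) > p.hit_threshold)
    segs = []
    i = 0
    while i < n:
        if not cand[i] or het[i] or miss[i]:
            i += 1
            continue
        j = i
        last_ok = i
        while j + 1 < n and cand[j + 1]:
            if pos[j + 1] - pos[j] > p.max_gap_kb * 1000:
                break
            j += 1
            if not het[j] and not miss[j]:
                last_ok = j
        j = last_ok
        n_snps = j - i + 1
        length_bp = pos[j] - pos[i] + 1
        if (n_snps >= p.min_snp and length_bp / 1000 >= p.min_kb
                and (length_bp / 1000) / n_snps <= p.min_density_kb_per_snp
                and (p.seg_het_max is None
                     or het[i:j + 1].sum() <= p.seg_het_max)):
            segs.append((int(pos[i]), int(pos[j]), n_snps))
        i = j + 1
    return segs


def test_roh_matches_bruteforce_on_random_instances(rng):
    params = RohParams(window_snp=10, window_het=1, window_missing=2,
                       hit_threshold=0.05, min_snp=15, min_kb=50,
                       max_gap_kb=100, min_density_kb_per_snp=50)
    for k in range(100):
        L = int(rng.integers(30, 500))
        pos = np.sort(rng.choice(3_000_000, size=L, replace=False))
        # mosaics of homozygous tracts and noisy stretches
        d = rng.choice([0, 1, 2, -1], size=L,
                       p=[0.35, 0.25, 0.35, 0.05]).astype(np.int8)
        if k % 2 == 0 and L > 60:
            s = int(rng.integers(0, L - 50))
            tract = rng.choice([0, 2], size=50)
            d[s:s + 50] = tract
        g = make_matrix(d[None, :], pos=pos)
        got = kincalc.detect_roh(g, params, allow_filtered=True)
        got_t = [(r.start_bp, r.end_bp, r.n_snps) for r in got.itertuples()]
        assert got_t == roh_oracle(d, pos, params)


def test_fully_heterozygous_sample_has_no_roh():
    g = make_matrix(np.ones((1, 300), dtype=np.int8),
                    pos=np.arange(300) * 10_000 + 1)
    params = RohParams(window_snp=20, min_snp=30, min_kb=100)
    assert len(kincalc.detect_roh(g, params, allow_filtered=True)) == 0


def test_constructed_run_with_embedded_het_detected(rng):
    L = 400
    pos = np.arange(L) * 10_000 + 1
    d = rng.integers(0, 3, L).astype(np.int8)
    d[100:220] = rng.choice([0, 2], size=120)
    d[160] = 1  # single embedded heterozygote, allowed by window_het=1
    g = make_matrix(d[None, :], pos=pos)
    params = RohParams(window_snp=20, window_het=1, window_missing=2,
                       min_snp=100, min_kb=1000, max_gap_kb=200,
                       min_density_kb_per_snp=100)
    segs = kincalc.detect_roh(g, params, allow_filtered=True)
    assert len(segs) == 1
    seg = segs.iloc[0]
    assert seg.start_bp <= pos[100] and seg.end_bp >= pos[219]


def test_full_sib_mating_froh_quarter(rng):
    """Offspring of a full-sib mating carry ~25% of the genome in ROH."""
    from woodgen.config import SimulationConfig
    from woodgen.simulate import _Meiosis, _make_locus_table
    cfg = SimulationConfig(n_autosomal_snps=10_000, n_z_snps=0, seed=3)
    lt = _make_locus_table(cfg, np.random.default_rng(3))
    meio = _Meiosis(lt)
    p = np.clip(rng.beta(2, 2, 10_000), 0.05, 0.95)
    a_idx = lt.autosome_index()
    loci_kw = dict(chrom=lt.chrom[a_idx], pos=lt.pos_bp[a_idx])
    params = RohParams(window_snp=50, min_snp=60, min_kb=1000,
                       max_gap_kb=2000, min_density_kb_per_snp=200)
    genome_kb = cfg.n_autosomes * cfg.autosome_length_bp / 1000
    frohs = []
    for _ in range(12):
        dad = (rng.random((2, 10_000)) < p).astype(np.int8)
        mum = (rng.random((2, 10_000)) < p).astype(np.int8)
        sib = lambda: np.stack([meio.autosomal_gamete(rng, dad),
                                meio.autosomal_gamete(rng, mum)])
        s1, s2 = sib(), sib()
        child = np.stack([meio.autosomal_gamete(rng, s1),
                          meio.autosomal_gamete(rng, s2)])
        g = make_matrix(child.sum(axis=0)[None, :], **loci_kw)
        segs = kincalc.detect_roh(g, params, allow_filtered=True)
        frohs.append(segs["length_kb"].sum() / genome_kb)
    assert np.mean(frohs) == pytest.approx(0.25, abs=0.05)
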