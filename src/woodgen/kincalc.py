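"""Pairwise relatedness and runs of homozygosity.

Two relatedness estimators are provided:

* ``mom_ibd`` -- the method-of-moments genome-wide IBD estimator: observed
  IBS0/IBS1/IBS2 pair counts are combined with allele-frequency-based
  expected IBS-given-IBD proportions to solve P(IBD=0,1,2) by moments;
  pi-hat = P(IBD=2) + P(IBD=1)/2.  Rare variants are excluded (default
  MAF < 0.1) because moments IBD is sensitive to them.
* ``king_robust`` -- the KING-robust kinship coefficient
  phi = (N_AaAa - 2 N_AAaa) / (N_Aa(a) + N_Aa(b)),
  robust to population structure because it never uses allele frequencies.

Kinship degrees use the powers-of-one-half convention: duplicate
phi > 0.354, first degree (0.177, 0.354], second (0.0884, 0.177], third
(0.0442, 0.0884], otherwise unrelated.

ROH detection follows the scanning-window rule used by PLINK --homozyg:
a window of W consecutive SNPs is "homozygous-compatible" if it holds at
most H heterozygous and M missing calls; a SNP is in candidate state when
the fraction of windows spanning it that are compatible exceeds a hit
threshold, and maximal candidate runs meeting length/count/density/gap
conditions are emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

__all__ = [
    "mom_ibd", "king_robust", "classify_degree", "DEGREE_CUTOFFS",
    "RohParams", "detect_roh", "roh_sample_summary",
    "pairwise_frame",
]

DEGREE_CUTOFFS = {
    "duplicate": 0.354,
    "first": 0.177,
    "second": 0.0884,
    "third": 0.0442,
}


# --------------------------------------------------------------------------
# helpers

def _indicator_mats(dosage: np.ndarray):
    """Float32 indicators for genotype 0/1/2 and non-missing."""
    A0 = (dosage == 0).astype(np.float32)
    A1 = (dosage == 1).astype(np.float32)
    A2 = (dosage == 2).astype(np.float32)
    M = (dosage >= 0).astype(np.float32)
    return A0, A1, A2, M


def _upper(ids: np.ndarray, mat: np.ndarray, name: str,
           extra: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    iu, ju = np.triu_indices(len(ids), k=1)
    out = pd.DataFrame({"id_a": ids[iu], "id_b": ids[ju], name: mat[iu, ju]})
    if extra:
        for k, v in extra.items():
            out[k] = v[iu, ju]
    return out


def pairwise_frame(ids_a, ids_b=None) -> pd.DataFrame:
    """All unordered pairs (id_a < id_b) of one or two id collections."""
    ids_a = np.asarray(ids_a)
    if ids_b is None:
        iu, ju = np.triu_indices(len(ids_a), k=1)
        return pd.DataFrame({"id_a": ids_a[iu], "id_b": ids_a[ju]})
    ids_b = np.asarray(ids_b)
    a, b = np.meshgrid(ids_a, ids_b, indexing="ij")
    lo = np.minimum(a, b).ravel()
    hi = np.maximum(a, b).ravel()
    keep = lo != hi
    return pd.DataFrame({"id_a": lo[keep], "id_b": hi[keep]}).drop_duplicates()


# --------------------------------------------------------------------------
# method-of-moments IBD

def mom_ibd(g: GenotypeMatrix, maf_floor: float = 0.1,
            min_informative: int = 50) -> pd.DataFrame:
    """Pairwise pi-hat over autosomal diploid genotypes.

    Expected IBS-class proportions given IBD state are computed from
    sample allele frequencies at the retained loci (MAF >= ``maf_floor``);
    the three IBD-state probabilities are solved sequentially, clamped to
    the simplex and renormalised.  Returns one row per unordered pair with
    columns pi_hat, P(IBD=0/1/2) and a low-confidence flag for pairs with
    fewer than ``min_informative`` shared non-missing loci.
    """
    keep = np.flatnonzero(~g.loci["is_z"].to_numpy() & (g.maf() >= maf_floor))
    sub = g.select_loci(keep)
    p = sub.allele_freq()
    q = 1.0 - p
    A0, A1, A2, M = _indicator_mats(sub.dosage)

    # per-pair IBS counts (shared non-missing loci only)
    n_shared = M @ M.T
    ibs0 = A0 @ A2.T
    ibs0 = ibs0 + ibs0.T
    ibs2 = A0 @ A0.T + A1 @ A1.T + A2 @ A2.T
    ibs1 = n_shared - ibs0 - ibs2

    # expected per-locus IBS-class probabilities, summed over loci
    e0_ibs0 = 2 * p**2 * q**2
    e0_ibs1 = 4 * p**3 * q + 4 * p * q**3
    e0_ibs2 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibs1 = 2 * p * q            # = 2p^2 q + 2p q^2
    e1_ibs2 = p**2 + q**2          # = p^3 + q^3 + p^2 q + p q^2
    L = len(p)
    S0_0, S0_1, S0_2 = e0_ibs0.sum(), e0_ibs1.sum(), e0_ibs2.sum()
    S1_1, S1_2 = e1_ibs1.sum(), e1_ibs2.sum()

    # missing data: scale expectations by the pair's shared-locus fraction
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = n_shared / L
        P0 = ibs0 / (S0_0 * frac)
        P1 = (ibs1 - P0 * S0_1 * frac) / (S1_1 * frac)
        P2 = (ibs2 - P0 * S0_2 * frac - P1 * S1_2 * frac) / n_shared
    # clamp to the simplex, then renormalise
    P0 = np.clip(P0, 0.0, 1.0)
    P1 = np.clip(P1, 0.0, 1.0)
    P2 = np.clip(P2, 0.0, 1.0)
    tot = P0 + P1 + P2
    with np.errstate(divide="ignore", invalid="ignore"):
        P0, P1, P2 = P0 / tot, P1 / tot, P2 / tot
    pi_hat = np.clip(P2 + 0.5 * P1, 0.0, 1.0)

    ids = g.samples["id"].to_numpy()
    out = _upper(ids, pi_hat, "pi_hat",
                 extra={"ibd0": P0, "ibd1": P1, "ibd2": P2,
                        "n_loci": n_shared})
    out["low_confidence"] = out["n_loci"] < min_informative
    return out


# --------------------------------------------------------------------------
# KING-robust kinship

def king_robust(g: GenotypeMatrix) -> pd.DataFrame:
    """KING-robust phi per unordered pair of diploid samples.

    phi = (N_AaAa - 2 N_AAaa) / (N_Aa^(a) + N_Aa^(b)) over loci non-missing
    in both samples.  Pairs with a zero denominator get phi = NaN and an
    ``undefined`` flag.
    """
    A0, A1, A2, M = _indicator_mats(g.dosage)
    het_ab = A1 @ A1.T
    opp = A0 @ A2.T
    opp = opp + opp.T
    het_a = A1 @ M.T       # het in a, non-missing in b
    denom = het_a + het_a.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (het_ab - 2.0 * opp) / denom
    ids = g.samples["id"].to_numpy()
    out = _upper(ids, phi, "phi", extra={"n_het_sum": denom})
    out["undefined"] = out["n_het_sum"] == 0
    return out


def classify_degree(phi: float | np.ndarray):
    """Kinship degree class from phi (KING powers-of-one-half cutoffs)."""
    phi_arr = np.atleast_1d(np.asarray(phi, dtype=float))
    out = np.full(phi_arr.shape, "unrelated", dtype=object)
    out[phi_arr > DEGREE_CUTOFFS["third"]] = "third"
    out[phi_arr > DEGREE_CUTOFFS["second"]] = "second"
    out[phi_arr > DEGREE_CUTOFFS["first"]] = "first"
    out[phi_arr > DEGREE_CUTOFFS["duplicate"]] = "duplicate"
    out[~np.isfinite(phi_arr)] = "unrelated"
    if np.isscalar(phi) or np.asarray(phi).ndim == 0:
        return out.item()
    return out


# --------------------------------------------------------------------------
# runs of homozygosity

@dataclass
class RohParams:
    """Scanning-window ROH parameters (PLINK --homozyg defaults)."""
    window_snp: int = 50
    window_het: int = 1
    window_missing: int = 5
    hit_threshold: float = 0.05
    min_snp: int = 100
    min_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    min_density_kb_per_snp: float = 50.0
    seg_het_max: int | None = None  # max hets inside an emitted segment


def _candidate_snps(het: np.ndarray, miss: np.ndarray, p: RohParams) -> np.ndarray:
    """Per-SNP candidate state from the sliding W-SNP window vote."""
    n = len(het)
    w = min(p.window_snp, n)
    if n == 0:
        return np.zeros(0, dtype=bool)
    het_c = np.concatenate([[0], np.cumsum(het)])
    mis_c = np.concatenate([[0], np.cumsum(miss)])
    starts = np.arange(n - w + 1)
    good = ((het_c[starts + w] - het_c[starts] <= p.window_het)
            & (mis_c[starts + w] - mis_c[starts] <= p.window_missing))
    # windows spanning SNP i start in [max(0, i-w+1), min(i, n-w)]
    good_c = np.concatenate([[0], np.cumsum(good)])
    i = np.arange(n)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, n - w)
    n_span = hi - lo + 1
    n_good = good_c[hi + 1] - good_c[lo]
    return (n_good / n_span) > p.hit_threshold


def _emit_segments(pos: np.ndarray, het: np.ndarray, miss: np.ndarray,
                   cand: np.ndarray, p: RohParams) -> list[tuple[int, int, int]]:
    """Maximal candidate runs passing the segment-level filters.

    Returns (start_idx, end_idx inclusive, n_snps)."""
    segs = []
    n = len(pos)
    i = 0
    while i < n:
        if not cand[i] or het[i] or miss[i]:
            i += 1
            continue
        j = i
        last_ok = i
        while j + 1 < n and cand[j + 1]:
            gap = pos[j + 1] - pos[j]
            if gap > p.max_gap_kb * 1000:
                break
            j += 1
            if not het[j] and not miss[j]:
                last_ok = j
        j = last_ok  # trim trailing het/missing calls
        n_snps = j - i + 1
        length_bp = pos[j] - pos[i] + 1
        dens_ok = (length_bp / 1000.0) / n_snps <= p.min_density_kb_per_snp
        het_ok = (p.seg_het_max is None
                  or int(het[i:j + 1].sum()) <= p.seg_het_max)
        if (n_snps >= p.min_snp and length_bp / 1000.0 >= p.min_kb
                and dens_ok and het_ok):
            segs.append((i, j, n_snps))
        i = j + 1
    return segs


def detect_roh(g: GenotypeMatrix, params: RohParams | None = None,
               allow_filtered: bool = False) -> pd.DataFrame:
    """ROH segments per sample on autosomal data.

    The input should be unfiltered by MAF or LD pruning; pass
    ``allow_filtered=True`` to override the guard (the guard only checks
    that the matrix was not visibly depleted of rare variants).
    """
    if params is None:
        params = RohParams()
    if g.loci["is_z"].any():
        g = g.select_loci(np.flatnonzero(~g.loci["is_z"].to_numpy()))
    if not allow_filtered:
        maf = g.maf()
        if len(maf) and np.nanmin(maf) > 0.01 and g.n_loci > 200:
            warnings.warn("input looks MAF-filtered; ROH should run on "
                          "unfiltered genotypes (allow_filtered=True to "
                          "silence this)")
    rows = []
    chroms = g.loci["chrom"].to_numpy()
    pos_all = g.loci["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = pos_all[idx]
        for i in range(g.n_samples):
            d = g.dosage[i, idx]
            het = (d == 1).astype(np.int8)
            miss = (d < 0).astype(np.int8)
            cand = _candidate_snps(het, miss, params)
            for s, e, n_snps in _emit_segments(pos, het, miss, cand, params):
                rows.append(dict(sample_id=g.samples["id"].iloc[i],
                                 chrom=chrom, start_bp=int(pos[s]),
                                 end_bp=int(pos[e]), n_snps=n_snps,
                                 length_kb=(pos[e] - pos[s] + 1) / 1000.0))
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start_bp",
                                       "end_bp", "n_snps", "length_kb"])


def roh_sample_summary(segments: pd.DataFrame, sample_ids,
                       genome_kb: float | None = None) -> pd.DataFrame:
    """Per-sample ROH count, total and mean length, and genome fraction."""
    rows = []
    by = segments.groupby("sample_id") if len(segments) else None
    for sid in sample_ids:
        if by is not None and sid in by.groups:
            seg = by.get_group(sid)
            n, tot = len(seg), float(seg["length_kb"].sum())
            mean = tot / n
        else:
            n, tot, mean = 0, 0.0, 0.0
        rows.append(dict(sample_id=sid, n_roh=n, total_kb=tot, mean_kb=mean,
                         froh=(tot / genome_kb) if genome_kb else np.nan))
    return pd.DataFrame(rows)
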