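"""Genome-wide differentiation between groups.

Per-SNP Weir & Cockerham (1984) variance components a (among groups),
b (among individuals within groups) and c (within individuals) are kept so
windows and the global value aggregate as ratio-of-sums
F_ST = sum(a) / sum(a + b + c).  Negative per-locus estimates are retained,
as the estimator defines them.  A Hudson-style two-population estimator is
provided as an independent cross-check.  Windows tile chromosomes in
non-overlapping 50 kb blocks by default (configurable step).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

__all__ = ["fst_per_snp", "window_fst", "global_fst", "hudson_fst",
           "extreme_subsets"]


def _group_stats(dosage: np.ndarray):
    """Per-locus sample size, allele frequency and observed het fraction."""
    valid = dosage >= 0
    n = valid.sum(axis=0).astype(float)
    d = np.where(valid, dosage, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = d.sum(axis=0) / (2.0 * n)
        h = np.where(valid, dosage == 1, False).sum(axis=0) / n
    return n, p, h


def fst_per_snp(g: GenotypeMatrix, groups: np.ndarray) -> pd.DataFrame:
    """Weir-Cockerham variance components per autosomal locus (two groups).

    Returns chrom, pos, a, b, c and the per-locus estimate a/(a+b+c)
    (NaN where the locus is monomorphic across both groups or a group has
    fewer than 2 genotyped samples).
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two non-empty groups required")
    d1 = g.dosage[groups == labels[0]]
    d2 = g.dosage[groups == labels[1]]
    if len(d1) == 0 or len(d2) == 0:
        raise ValueError("both groups must be non-empty")
    r = 2.0
    n1, p1, h1 = _group_stats(d1)
    n2, p2, h2 = _group_stats(d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar)
                                   - s2 * (r - 1) / r - h_bar / 4.0) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar)
                                     - s2 * (r - 1) / r
                                     - h_bar * (2 * n_bar - 1) / (4 * n_bar))
        c = h_bar / 2.0
        fst = a / (a + b + c)
    bad = (n1 < 2) | (n2 < 2)
    mono = (p_bar <= 0) | (p_bar >= 1)
    for arr in (a, b, c, fst):
        arr[bad | mono] = np.nan
    return pd.DataFrame({"chrom": g.loci["chrom"], "pos": g.loci["pos"],
                         "a": a, "b": b, "c": c, "fst": fst})


def global_fst(per_snp: pd.DataFrame) -> float:
    """Ratio-of-sums F_ST over every defined locus."""
    ok = per_snp[["a", "b", "c"]].notna().all(axis=1)
    num = per_snp.loc[ok, "a"].sum()
    den = (per_snp.loc[ok, ["a", "b", "c"]].to_numpy()).sum()
    return float(num / den) if den != 0 else np.nan


def window_fst(per_snp: pd.DataFrame, window_bp: int = 50_000,
               step_bp: int | None = None) -> pd.DataFrame:
    """Windowed ratio-of-sums F_ST in half-open [start, end) tiles.

    Non-overlapping by default (step = window); mean of per-locus estimates
    is reported alongside the weighted ratio-of-sums value.
    """
    if step_bp is None:
        step_bp = window_bp
    rows = []
    for chrom, grp in per_snp.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"loci on {chrom} not position-sorted")
        if len(pos) == 0:
            continue
        last = pos.max()
        for start in range(0, int(last) + 1, step_bp):
            end = start + window_bp
            sel = grp[(pos >= start) & (pos < end)]
            ok = sel[["a", "b", "c"]].notna().all(axis=1)
            n_snps = int(ok.sum())
            if n_snps:
                num = sel.loc[ok, "a"].sum()
                den = sel.loc[ok, ["a", "b", "c"]].to_numpy().sum()
                weighted = float(num / den) if den != 0 else np.nan
                mean = float(sel.loc[ok, "fst"].mean())
            else:
                weighted = mean = np.nan
            rows.append(dict(chrom=chrom, start_bp=start, end_bp=end,
                             n_snps=n_snps, fst_mean=mean,
                             fst_weighted=weighted))
    return pd.DataFrame(rows)


def hudson_fst(g: GenotypeMatrix, groups: np.ndarray) -> float:
    """Hudson two-population F_ST (ratio of averages), as a cross-check."""
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    out_num = out_den = 0.0
    n1, p1, _ = _group_stats(g.dosage[groups == labels[0]])
    n2, p2, _ = _group_stats(g.dosage[groups == labels[1]])
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (2 * n1 - 1) \
            - p2 * (1 - p2) / (2 * n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = np.isfinite(num) & np.isfinite(den) & (den > 0)
    return float(num[ok].sum() / den[ok].sum())


def extreme_subsets(mds: np.ndarray, labels: np.ndarray,
                    sample_ids: np.ndarray, k: int = 50,
                    phi_pairs: pd.DataFrame | None = None):
    """Most model-distinct individuals from the classifier's MDS space.

    The k most extreme immigrants along MDS axis 1 and the k most extreme
    locals along MDS axis 2, extremity measured toward each group's own
    centroid side of the axis.  If KING phi pairs are supplied, the maximum
    within-subset kinship is reported as a screen against the subsets being
    families.  Returns (top_immigrants, top_locals, screen_dict).
    """
    labels = np.asarray(labels)
    sample_ids = np.asarray(sample_ids)

    def top(group: str, axis: int) -> np.ndarray:
        mask = labels == group
        if mask.sum() < k:
            raise ValueError(f"k={k} exceeds {group} group size {mask.sum()}")
        coord = mds[:, axis]
        sign = np.sign(coord[mask].mean()) or 1.0
        extremity = sign * coord
        idx = np.flatnonzero(mask)
        order = idx[np.argsort(-extremity[idx], kind="stable")]
        return sample_ids[order[:k]]

    top_imm = top("immigrant", 0)
    top_loc = top("local", 1)
    screen = {}
    if phi_pairs is not None:
        for name, subset in (("immigrant", top_imm), ("local", top_loc)):
            s = set(subset.tolist())
            sel = phi_pairs[phi_pairs["id_a"].isin(s)
                            & phi_pairs["id_b"].isin(s)]
            screen[f"max_phi_{name}"] = (float(sel["phi"].max())
                                         if len(sel) else np.nan)
    return top_imm, top_loc, screen
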