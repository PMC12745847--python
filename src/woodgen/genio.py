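"""Genotype containers, file I/O (VCF / PLINK text), quality control,
Hardy-Weinberg exact testing, LD pruning and autosome/Z dataset splitting.

The container keeps allele *dosages* (0/1/2, -1 for missing).  Z-linked loci
in females are single-copy: their dosage is the allele itself (0/1) and every
frequency computation counts allele copies (two per male, one per female).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeMatrix", "QcParams", "QcReport", "LdPruneParams",
    "from_simulation", "read_genotypes", "write_vcf", "write_plink",
    "hwe_exact_p", "apply_qc", "ld_prune", "split_datasets",
]


# --------------------------------------------------------------------------
# container

@dataclass
class GenotypeMatrix:
    dosage: np.ndarray          # (n_samples, n_loci) int8; -1 = missing
    samples: pd.DataFrame       # id, sex ('M'/'F'), status ('local'/'immigrant')
    loci: pd.DataFrame          # chrom, pos, ref, alt, is_z

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.loci = self.loci.reset_index(drop=True)
        if self.dosage.shape != (len(self.samples), len(self.loci)):
            raise ValueError("dosage shape does not match sample/locus tables")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def hemi_mask(self) -> np.ndarray:
        """True where a call is single-copy (female sample x Z locus)."""
        female = (self.samples["sex"].to_numpy() == "F")
        is_z = self.loci["is_z"].to_numpy()
        return female[:, None] & is_z[None, :]

    def copies(self) -> np.ndarray:
        """Allele copies per call (2, or 1 for female Z), 0 where missing."""
        c = np.where(self.hemi_mask, 1, 2).astype(np.int8)
        c[self.dosage < 0] = 0
        return c

    def allele_freq(self) -> np.ndarray:
        """Copy-aware alternate-allele frequency per locus."""
        d = np.where(self.dosage < 0, 0, self.dosage)
        c = self.copies()
        tot = c.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, d.sum(axis=0) / tot, np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return (self.dosage >= 0).mean(axis=0)

    def select_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.dosage[:, idx].copy(),
                              self.samples.copy(), self.loci.iloc[idx])

    def select_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.dosage[idx].copy(),
                              self.samples.iloc[idx], self.loci.copy())


def from_simulation(sim) -> GenotypeMatrix:
    """Dosage matrix over every genotyped breeder of a simulation."""
    if sim.genome is None:
        raise ValueError("simulation was run with track_genotypes=False")
    ids = sim.breeder_ids().tolist()
    dosage = sim.genome.dosage_matrix(ids)
    ind = sim.individuals.set_index("id")
    samples = pd.DataFrame({
        "id": ids,
        "sex": ind.loc[ids, "sex"].to_numpy(),
        "status": ind.loc[ids, "status"].to_numpy(),
    })
    loci_tab = sim.loci
    a_idx = loci_tab.autosome_index()
    z_idx = loci_tab.z_index()
    order = np.concatenate([a_idx, z_idx])
    loci = pd.DataFrame({
        "chrom": loci_tab.chrom[order],
        "pos": loci_tab.pos_bp[order],
        "ref": "A", "alt": "G",
        "is_z": loci_tab.is_z[order],
    })
    return GenotypeMatrix(dosage=dosage, samples=samples, loci=loci)


# --------------------------------------------------------------------------
# writers

def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """VCF 4.2 with diploid autosomal GTs and true haploid female-Z GTs.

    Sample metadata (sex, status) goes to a ``<path>.samples.csv`` sidecar.
    """
    path = Path(path)
    hemi = g.hemi_mask
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=woodgen\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.loci["chrom"]):
            length = int(g.loci.loc[g.loci["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        names = [str(s) for s in g.samples["id"]]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        dip = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        hap = {0: "0", 1: "1", -1: "."}
        for j in range(g.n_loci):
            row = g.loci.iloc[j]
            gts = [hap[int(d)] if hemi[i, j] else dip[int(d)]
                   for i, d in enumerate(g.dosage[:, j])]
            fh.write(f"{row.chrom}\t{int(row.pos)}\t{row.chrom}:{int(row.pos)}\t"
                     f"{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
    g.samples.to_csv(f"{path}.samples.csv", index=False)


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """PLINK text (.ped/.map).  Female Z calls are duplicated homozygous by
    convention and flagged in a ``<prefix>.zhemi`` sidecar listing Z loci."""
    prefix = Path(prefix)
    loci = g.loci
    with open(f"{prefix}.map", "w") as fh:
        for _, row in loci.iterrows():
            fh.write(f"{row.chrom}\t{row.chrom}:{int(row.pos)}\t0\t{int(row.pos)}\n")
    ref = loci["ref"].to_numpy(); alt = loci["alt"].to_numpy()
    sex_code = {"M": 1, "F": 2}
    with open(f"{prefix}.ped", "w") as fh:
        for i in range(g.n_samples):
            s = g.samples.iloc[i]
            fields = [str(s["id"]), str(s["id"]), "0", "0",
                      str(sex_code.get(s["sex"], 0)), "-9"]
            d = g.dosage[i]
            for j in range(g.n_loci):
                if d[j] < 0:
                    fields += ["0", "0"]
                elif d[j] == 0:
                    fields += [ref[j], ref[j]]
                elif d[j] == 2:
                    fields += [alt[j], alt[j]]
                elif d[j] == 1 and g.hemi_mask[i, j]:
                    fields += [alt[j], alt[j]]   # single-copy alt, duplicated
                else:
                    fields += [ref[j], alt[j]]
            fh.write(" ".join(fields) + "\n")
    with open(f"{prefix}.zhemi", "w") as fh:
        fh.write("# Z-linked loci; female genotypes are duplicated haploid calls\n")
        for _, row in loci[loci["is_z"]].iterrows():
            fh.write(f"{row.chrom}:{int(row.pos)}\n")
    g.samples.to_csv(f"{prefix}.samples.csv", index=False)


# --------------------------------------------------------------------------
# readers

def _sample_table(names: list[str], sidecar: str | Path | None) -> pd.DataFrame:
    df = pd.DataFrame({"id": names, "sex": "U", "status": "unknown"})
    if sidecar is not None and Path(sidecar).exists():
        meta = pd.read_csv(sidecar, dtype={"id": str})
        meta["id"] = meta["id"].astype(str)
        df = df[["id"]].merge(meta, on="id", how="left")
        df["sex"] = df["sex"].fillna("U")
        df["status"] = df["status"].fillna("unknown")
    return df


def read_vcf(path: str | Path, samples_csv: str | Path | None = None,
             z_chroms: tuple[str, ...] = ("Z",)) -> GenotypeMatrix:
    from cyvcf2 import VCF
    path = Path(path)
    if samples_csv is None:
        samples_csv = f"{path}.samples.csv"
    vcf = VCF(str(path))
    names = list(vcf.samples)
    rows, dosages = [], []
    for v in vcf:
        d = np.empty(len(names), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            alleles = [a for a in gt[:-1] if a is not None]
            if not alleles or alleles[0] < 0:
                d[i] = -1
            else:
                d[i] = sum(a for a in alleles if a >= 0)
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0] if v.ALT else "N",
                     v.CHROM in z_chroms))
        dosages.append(d)
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "is_z"])
    dosage = np.array(dosages, dtype=np.int8).T if dosages else \
        np.empty((len(names), 0), dtype=np.int8)
    return GenotypeMatrix(dosage=dosage, samples=_sample_table(names, samples_csv),
                          loci=loci)


def read_plink_text(prefix: str | Path, samples_csv: str | Path | None = None,
                    z_chroms: tuple[str, ...] = ("Z",)) -> GenotypeMatrix:
    prefix = Path(prefix)
    if samples_csv is None:
        samples_csv = f"{prefix}.samples.csv"
    mp = pd.read_csv(f"{prefix}.map", sep=r"\s+", header=None,
                     names=["chrom", "snp_id", "cm", "pos"],
                     dtype={"chrom": str})
    n_loci = len(mp)
    ids, sexes, rows = [], [], []
    with open(f"{prefix}.ped") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_loci:
                raise ValueError(f"{prefix}.ped line {ln}: expected "
                                 f"{6 + 2 * n_loci} fields, got {len(parts)}")
            ids.append(parts[1])
            sexes.append({"1": "M", "2": "F"}.get(parts[4], "U"))
            alleles = np.array(parts[6:]).reshape(n_loci, 2)
            rows.append(alleles)
    samples = _sample_table(ids, samples_csv)
    if (samples["sex"] == "U").all():
        samples["sex"] = sexes
    loci = pd.DataFrame({"chrom": mp["chrom"], "pos": mp["pos"],
                         "ref": "?", "alt": "?",
                         "is_z": mp["chrom"].isin(z_chroms)})
    dosage = np.empty((len(ids), n_loci), dtype=np.int8)
    ref = np.empty(n_loci, dtype=object)
    alt = np.empty(n_loci, dtype=object)
    ref[:] = None; alt[:] = None
    for j in range(n_loci):
        col = np.array([r[j] for r in rows])
        seen = [a for a in pd.unique(col.ravel()) if a != "0"]
        seen.sort()
        if not seen:
            ref[j], alt[j] = "A", "G"
        elif len(seen) == 1:
            ref[j], alt[j] = seen[0], "G" if seen[0] != "G" else "A"
        else:
            ref[j], alt[j] = seen[0], seen[1]
        miss = (col == "0").any(axis=1)
        dosage[:, j] = (col == alt[j]).sum(axis=1)
        dosage[miss, j] = -1
    loci["ref"] = ref; loci["alt"] = alt
    g = GenotypeMatrix(dosage=dosage, samples=samples, loci=loci)
    # undo the duplicated-homozygote convention on female Z calls
    hemi = g.hemi_mask
    g.dosage[hemi & (g.dosage == 2)] = 1
    return g


def read_genotypes(path: str | Path, format: str = "vcf",
                   samples_csv: str | Path | None = None) -> GenotypeMatrix:
    if format == "vcf":
        return read_vcf(path, samples_csv)
    if format == "plink_text":
        return read_plink_text(path, samples_csv)
    raise ValueError(f"unknown format {format!r}")


# --------------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided conditional exact HWE p-value.

    Sums the probabilities of all heterozygote counts (given the observed
    allele counts) that are no more likely than the observed one -- the
    standard SNP exact test without the mid-p correction.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_minor = min(n_Aa + 2 * n_AA, n_Aa + 2 * n_aa)  # minor allele copies
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    homs_minor = (n_minor - hets) // 2
    homs_major = n - hets - homs_minor
    # log P(het = h | allele counts) up to a common constant
    logp = (hets * np.log(2.0)
            - gammaln(homs_minor + 1) - gammaln(hets + 1) - gammaln(homs_major + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = np.flatnonzero(hets == n_Aa)
    if len(obs) == 0:
        raise ValueError("observed heterozygote count inconsistent with alleles")
    p_obs = p[obs[0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


# --------------------------------------------------------------------------
# QC

@dataclass
class QcParams:
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_alpha: float = 0.001
    max_sample_missing: float | None = None  # optional, default off

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")


@dataclass
class QcReport:
    n_loci_in: int
    n_call_rate: int
    n_maf: int
    n_hwe: int
    n_loci_out: int
    n_samples_removed: int = 0

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus HWE exact p: autosomes on all samples, Z on males only."""
    male = (g.samples["sex"].to_numpy() == "M")
    is_z = g.loci["is_z"].to_numpy()
    p = np.ones(g.n_loci)
    for j in range(g.n_loci):
        d = g.dosage[male, j] if is_z[j] else g.dosage[:, j]
        d = d[d >= 0]
        if len(d) == 0:
            continue
        p[j] = hwe_exact_p(int((d == 0).sum()), int((d == 1).sum()),
                           int((d == 2).sum()))
    return p


def apply_qc(g: GenotypeMatrix, params: QcParams | None = None
             ) -> tuple[GenotypeMatrix, QcReport]:
    """Drop loci failing call-rate, MAF or HWE thresholds.

    A locus is removed when call rate <= ``min_call_rate``, MAF <=
    ``min_maf`` (copy-aware on the Z), or HWE exact p <= ``hwe_alpha``
    (autosomes over all samples; Z over male genotypes only).
    """
    if params is None:
        params = QcParams()
    if g.n_samples < 2:
        raise ValueError("QC needs at least 2 samples")
    n_removed_samples = 0
    if params.max_sample_missing is not None:
        miss = (g.dosage < 0).mean(axis=1)
        keep_s = miss <= params.max_sample_missing
        n_removed_samples = int((~keep_s).sum())
        if n_removed_samples:
            g = g.select_samples(np.flatnonzero(keep_s))
    fail_cr = g.call_rate() <= params.min_call_rate
    with np.errstate(invalid="ignore"):
        fail_maf = ~(g.maf() > params.min_maf)  # NaN (no calls) fails too
    fail_hwe = _hwe_pvalues(g) <= params.hwe_alpha
    keep = ~(fail_cr | fail_maf | fail_hwe)
    report = QcReport(
        n_loci_in=g.n_loci,
        n_call_rate=int(fail_cr.sum()),
        n_maf=int(fail_maf.sum()),
        n_hwe=int(fail_hwe.sum()),
        n_loci_out=int(keep.sum()),
        n_samples_removed=n_removed_samples,
    )
    if report.n_loci_out == 0:
        warnings.warn("QC removed every locus")
    return g.select_loci(np.flatnonzero(keep)), report


# --------------------------------------------------------------------------
# LD pruning

@dataclass
class LdPruneParams:
    r2_max: float = 0.2
    window_bp: int = 50_000
    step_snps: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_max <= 1.0:
            raise ValueError("r2_max must lie in (0, 1]")


def ld_prune(g: GenotypeMatrix, params: LdPruneParams | None = None
             ) -> np.ndarray:
    """Indices of loci kept after greedy windowed r^2 pruning.

    Windows of ``window_bp`` advance by ``step_snps`` SNPs within each
    chromosome; of any pair with genotype correlation r^2 > ``r2_max`` the
    later locus is dropped.  Deterministic; loci must be position-sorted.
    """
    if params is None:
        params = LdPruneParams()
    x = g.dosage.astype(np.float64)
    x[g.dosage < 0] = np.nan
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    removed = np.zeros(g.n_loci, dtype=bool)
    chroms = g.loci["chrom"].to_numpy()
    pos = g.loci["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if np.any(np.diff(pos[idx]) < 0):
            raise ValueError(f"loci on {chrom} are not position-sorted")
        start = 0
        while start < len(idx):
            lo = pos[idx[start]]
            end = start
            while end < len(idx) and pos[idx[end]] < lo + params.window_bp:
                end += 1
            win = idx[start:end]
            win = win[~removed[win]]
            for a_i in range(len(win)):
                if removed[win[a_i]]:
                    continue
                for b_i in range(a_i + 1, len(win)):
                    ja, jb = win[a_i], win[b_i]
                    if removed[jb]:
                        continue
                    if sd[ja] == 0 or sd[jb] == 0:
                        continue
                    r = (x[:, ja] @ x[:, jb]) / (len(x) * sd[ja] * sd[jb])
                    if r * r > params.r2_max:
                        removed[jb] = True
            start += params.step_snps
    return np.flatnonzero(~removed)


# --------------------------------------------------------------------------
# dataset splitting

def split_datasets(g: GenotypeMatrix, exclude_chroms: tuple[str, ...] = ()
                   ) -> dict[str, GenotypeMatrix]:
    """Split into an autosomal and a Z-only dataset.

    ``exclude_chroms`` removes whole chromosomes (e.g. one carrying a large
    inversion) from both outputs.
    """
    chroms = g.loci["chrom"].to_numpy()
    is_z = g.loci["is_z"].to_numpy()
    excluded = np.isin(chroms, exclude_chroms)
    auto_idx = np.flatnonzero(~is_z & ~excluded)
    z_idx = np.flatnonzero(is_z & ~excluded)
    if len(z_idx) == 0:
        warnings.warn("no Z loci present; z_only dataset is empty")
    return {"autosomal": g.select_loci(auto_idx), "z_only": g.select_loci(z_idx)}
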