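"""Spatially explicit forward simulator of a nestbox bird population.

Annual cycle
------------
Each simulated spring:

1. every established breeder survives with probability ``adult_survival``;
2. survivors retain their box and slot (one male + one female per box);
3. a fraction ``immigration_fill`` of vacant slots is reserved for
   immigrants drawn from an external pool differentiated from the founders
   by a Balding-Nichols perturbation of allele frequencies; the remaining
   vacancies are open to locally born recruits, which disperse from their
   natal box (distance from a sex-specific kernel, direction uniform) and
   settle at the nearest free box to the target point;
4. each box holding a pair produces a Poisson clutch; every chick recruits
   to the following spring's candidate pool with probability
   ``recruit_prob``;
5. offspring genomes follow Mendelian transmission with recombination on
   the autosomes and ZW rules on the Z: sons receive a recombined paternal
   Z gamete plus the mother's single Z; daughters receive a recombined
   paternal Z only.  With probability ``epp_rate`` the genetic sire is a
   random other male breeding within ``epp_radius_m``; the social sire
   remains the box mate.

Founders and immigrants enter without a natal box and are recorded with
status ``immigrant``; every locally hatched recruit is ``local``.  All
stochastic draws come from a single seeded generator, so runs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .landscape import NestboxMap, build_landscape

__all__ = [
    "LocusTable", "Genome", "SimResult", "run_simulation",
    "draw_immigrant_haplotypes", "dispersal_kernel_draw",
    "neutral_zw_simulation", "zw_copy_fraction_in_males",
]

MALE, FEMALE = "M", "F"


# --------------------------------------------------------------------------
# locus table and genome container

@dataclass(frozen=True)
class LocusTable:
    chrom: np.ndarray      # (L,) str
    pos_bp: np.ndarray     # (L,) int
    is_z: np.ndarray       # (L,) bool
    lengths_bp: dict       # chrom -> length
    morgans: dict          # chrom -> genetic length in Morgans

    @property
    def n_loci(self) -> int:
        return len(self.chrom)

    def autosome_index(self) -> np.ndarray:
        return np.flatnonzero(~self.is_z)

    def z_index(self) -> np.ndarray:
        return np.flatnonzero(self.is_z)


def _make_locus_table(cfg: SimulationConfig, rng: np.random.Generator) -> LocusTable:
    chroms, poss = [], []
    autos = [str(i + 1) for i in range(cfg.n_autosomes)]
    per = np.full(cfg.n_autosomes, cfg.n_autosomal_snps // cfg.n_autosomes)
    per[: cfg.n_autosomal_snps % cfg.n_autosomes] += 1
    for name, k in zip(autos, per):
        pos = np.sort(rng.choice(cfg.autosome_length_bp, size=k, replace=False))
        chroms.append(np.full(k, name)); poss.append(pos)
    if cfg.n_z_snps:
        pos = np.sort(rng.choice(cfg.z_length_bp, size=cfg.n_z_snps, replace=False))
        chroms.append(np.full(cfg.n_z_snps, "Z")); poss.append(pos)
    chrom = np.concatenate(chroms)
    pos_bp = np.concatenate(poss).astype(np.int64)
    morgans = {c: length / 1e6 * cfg.recomb_cm_per_mb / 100.0
               for c, length in cfg.chrom_lengths_bp.items()}
    return LocusTable(chrom=chrom, pos_bp=pos_bp, is_z=(chrom == "Z"),
                      lengths_bp=cfg.chrom_lengths_bp, morgans=morgans)


class Genome:
    """Per-individual haplotypes: diploid autosomes; Z diploid in males,
    single-copy in females (the W carries no analysed loci)."""

    def __init__(self, loci: LocusTable):
        self.loci = loci
        self.auto: dict[int, np.ndarray] = {}  # id -> (2, nA) int8
        self.z: dict[int, np.ndarray] = {}     # id -> (2 or 1, nZ) int8

    def add(self, iid: int, auto_haps: np.ndarray, z_haps: np.ndarray) -> None:
        self.auto[iid] = auto_haps
        self.z[iid] = z_haps

    def dosage_matrix(self, ids: list[int]) -> np.ndarray:
        """Allele-dosage matrix over [autosomal loci, Z loci].

        Female Z dosages are the single-copy allele (0/1)."""
        nA = len(self.loci.autosome_index())
        nZ = len(self.loci.z_index())
        out = np.zeros((len(ids), nA + nZ), dtype=np.int8)
        for i, iid in enumerate(ids):
            out[i, :nA] = self.auto[iid].sum(axis=0)
            out[i, nA:] = self.z[iid].sum(axis=0)
        return out


# --------------------------------------------------------------------------
# kernels and founder/immigrant draws

def dispersal_kernel_draw(rng: np.random.Generator, median_m: float,
                          family: str, log_sigma: float, size: int | None = None):
    """Draw natal dispersal distances with the requested median."""
    if family == "lognormal":
        return rng.lognormal(mean=np.log(median_m), sigma=log_sigma, size=size)
    if family == "weibull":
        shape = 1.8  # right-skewed but thinner tail than lognormal
        scale = median_m / np.log(2.0) ** (1.0 / shape)
        return scale * rng.weibull(shape, size=size)
    raise ValueError(f"unknown kernel family {family!r}")


def _founder_freqs(cfg: SimulationConfig, rng: np.random.Generator,
                   n_loci: int) -> np.ndarray:
    a, b = cfg.founder_maf_beta
    p = rng.beta(a, b, size=n_loci)
    return np.clip(p, 0.05, 0.95)


def balding_nichols_freqs(p: np.ndarray, fst: float,
                          rng: np.random.Generator) -> np.ndarray:
    """External-pool frequencies: Balding-Nichols draw around ``p``.

    ``fst`` is the target two-population Hudson F_ST between the pool and
    the population at frequencies ``p``.  Because a single BN draw with
    mixing parameter theta has E[(p'-p)^2] = theta*p*(1-p) while the
    two-population Hudson denominator is 2p(1-p), the draw uses
    theta = 2*fst so the realized pool-vs-source F_ST matches the target.
    """
    if fst <= 0:
        return p.copy()
    theta = min(2.0 * fst, 0.999)
    c = (1.0 - theta) / theta
    return rng.beta(p * c, (1.0 - p) * c)


def draw_immigrant_haplotypes(pool_auto: np.ndarray, pool_z: np.ndarray,
                              sex: str, rng: np.random.Generator):
    """Haplotypes for one immigrant, sampled independently from the external
    pool's allele frequencies (immigrants are unrelated by construction)."""
    auto = (rng.random((2, len(pool_auto))) < pool_auto).astype(np.int8)
    kz = 2 if sex == MALE else 1
    z = (rng.random((kz, len(pool_z))) < pool_z).astype(np.int8)
    return auto, z


# --------------------------------------------------------------------------
# meiosis

def _gamete(rng: np.random.Generator, haps: np.ndarray, morgans: float,
            pos_frac: np.ndarray) -> np.ndarray:
    """One recombined gamete from a diploid chromosome.

    Crossover count ~ Poisson(genetic length in Morgans), positions uniform,
    no interference; starting haplotype chosen at random."""
    k = rng.poisson(morgans)
    start = rng.integers(2)
    if k == 0:
        return haps[start].copy()
    cx = np.sort(rng.random(k))
    phase = (np.searchsorted(cx, pos_frac) + start) % 2
    return np.where(phase == 0, haps[0], haps[1]).astype(np.int8)


class _Meiosis:
    """Caches per-chromosome locus slices for fast gamete formation."""

    def __init__(self, loci: LocusTable):
        self.loci = loci
        self.auto_slices = []  # (slice into autosomal array, morgans, pos_frac)
        a_idx = loci.autosome_index()
        chrom_a = loci.chrom[a_idx]
        off = 0
        for name in pd.unique(chrom_a):
            sel = np.flatnonzero(chrom_a == name)
            pos = loci.pos_bp[a_idx[sel]]
            frac = pos / loci.lengths_bp[name]
            self.auto_slices.append((slice(off, off + len(sel)),
                                     loci.morgans[name], frac))
            off += len(sel)
        z_idx = loci.z_index()
        self.z_frac = (loci.pos_bp[z_idx] / loci.lengths_bp["Z"]
                       if len(z_idx) else np.empty(0))
        self.z_morgans = loci.morgans.get("Z", 0.0)
        self.nA, self.nZ = off, len(z_idx)

    def autosomal_gamete(self, rng, haps: np.ndarray) -> np.ndarray:
        g = np.empty(self.nA, dtype=np.int8)
        for sl, morgans, frac in self.auto_slices:
            g[sl] = _gamete(rng, haps[:, sl], morgans, frac)
        return g

    def z_gamete_from_male(self, rng, z_haps: np.ndarray) -> np.ndarray:
        return _gamete(rng, z_haps, self.z_morgans, self.z_frac)


# --------------------------------------------------------------------------
# simulation result

@dataclass
class SimResult:
    config: SimulationConfig
    nestbox_map: NestboxMap
    individuals: pd.DataFrame   # id, sex, birth_year, natal_box, status, dam, sire, social_sire
    breeding: pd.DataFrame      # year, box_id, male_id, female_id
    genome: Genome | None
    loci: LocusTable
    extinct_year: int | None = None

    @property
    def extinct(self) -> bool:
        return self.extinct_year is not None

    def breeder_ids(self) -> np.ndarray:
        ids = np.union1d(self.breeding["male_id"].dropna().astype(int).to_numpy(),
                         self.breeding["female_id"].dropna().astype(int).to_numpy())
        return ids

    def immigrant_fraction_by_year(self, burn_in: int = 0) -> pd.Series:
        """Per-year fraction of breeding adults recorded as immigrants."""
        status = self.individuals.set_index("id")["status"]
        rows = []
        for year, grp in self.breeding.groupby("year"):
            if year < burn_in:
                continue
            ids = pd.concat([grp["male_id"], grp["female_id"]]).dropna().astype(int)
            if len(ids) == 0:
                continue
            rows.append((year, float((status.loc[ids] == "immigrant").mean())))
        return pd.Series(dict(rows), name="immigrant_fraction")

    def natal_dispersal(self) -> pd.DataFrame:
        """Natal-box to first-breeding-box distance for locally born breeders."""
        ind = self.individuals.set_index("id")
        first = (self.breeding.melt(id_vars=["year", "box_id"],
                                    value_vars=["male_id", "female_id"],
                                    value_name="id")
                 .dropna(subset=["id"]).astype({"id": int})
                 .sort_values("year").groupby("id").first())
        local = ind[ind["status"] == "local"]
        joined = local.join(first, how="inner", rsuffix="_breed")
        a = self.nestbox_map.coords_of(joined["natal_box"].astype(int).to_numpy())
        b = self.nestbox_map.coords_of(joined["box_id"].astype(int).to_numpy())
        d = np.hypot(*(a - b).T)
        return pd.DataFrame({"id": joined.index, "sex": joined["sex"].to_numpy(),
                             "distance_m": d}).reset_index(drop=True)


# --------------------------------------------------------------------------
# the simulator

@dataclass
class _Chick:
    iid: int
    sex: str
    birth_year: int
    natal_box: int
    dam: int
    sire: int          # genetic
    social_sire: int


def run_simulation(config: SimulationConfig,
                   nestbox_map: NestboxMap | None = None) -> SimResult:
    """Run the annual-cycle simulation; see the module docstring."""
    rng = np.random.default_rng(config.seed)
    if nestbox_map is None:
        nestbox_map = build_landscape(config, rng)
    loci = _make_locus_table(config, rng)
    meio = _Meiosis(loci)
    track = config.track_genotypes
    genome = Genome(loci) if track else None

    a_idx = loci.autosome_index()
    founder_p_auto = _founder_freqs(config, rng, len(a_idx))
    founder_p_z = _founder_freqs(config, rng, loci.n_loci - len(a_idx))
    pool_auto = balding_nichols_freqs(founder_p_auto,
                                      config.immigrant_divergence_fst, rng)
    pool_z = balding_nichols_freqs(founder_p_z,
                                   config.immigrant_divergence_fst, rng)

    xy = nestbox_map.xy
    n_pairs_target = max(1, int(round(config.occupancy * config.n_boxes)))

    next_id = 0
    ind_rows: list[dict] = []
    breeding_rows: list[dict] = []

    def new_individual(sex, birth_year, natal_box, status, dam, sire, social_sire):
        nonlocal next_id
        iid = next_id
        next_id += 1
        ind_rows.append(dict(id=iid, sex=sex, birth_year=birth_year,
                             natal_box=natal_box, status=status,
                             dam=dam, sire=sire, social_sire=social_sire))
        return iid

    def add_immigrant(sex):
        iid = new_individual(sex, None, None, "immigrant", None, None, None)
        if track:
            auto, z = draw_immigrant_haplotypes(pool_auto, pool_z, sex, rng)
            genome.add(iid, auto, z)
        return iid

    def add_recruit(c: _Chick):
        iid = new_individual(c.sex, c.birth_year, c.natal_box, "local",
                             c.dam, c.sire, c.social_sire)
        if track:
            auto = np.stack([
                meio.autosomal_gamete(rng, genome.auto[c.dam]),
                meio.autosomal_gamete(rng, genome.auto[c.sire])])
            paternal_z = meio.z_gamete_from_male(rng, genome.z[c.sire])
            if c.sex == MALE:
                z = np.stack([genome.z[c.dam][0], paternal_z])
            else:
                z = paternal_z[None, :]
            genome.add(iid, auto, z)
        return iid

    def kernel_target(natal_box: int, sex: str) -> np.ndarray:
        median = (config.disp_median_male_m if sex == MALE
                  else config.disp_median_female_m)
        d = dispersal_kernel_draw(rng, median, config.kernel_family,
                                  config.disp_log_sigma)
        theta = rng.uniform(0, 2 * np.pi)
        return xy[natal_box] + d * np.array([np.cos(theta), np.sin(theta)])

    def nearest_box(target: np.ndarray, candidates: set[int]) -> int:
        cb = np.fromiter(candidates, dtype=np.int64)
        # ties broken by lowest box id
        return int(cb[np.lexsort((cb, np.hypot(*(xy[cb] - target).T)))[0]])

    # territory state: box -> occupant id (males hold territories; females
    # reside at a box, pairing with the male there if present)
    male_at: dict[int, int] = {}
    female_at: dict[int, int] = {}

    # founders (year-0 arrivals from outside): males on random boxes,
    # females joining them
    start_boxes = rng.choice(config.n_boxes, size=n_pairs_target,
                             replace=False)
    for b in start_boxes:
        male_at[int(b)] = add_immigrant(MALE)
        female_at[int(b)] = add_immigrant(FEMALE)

    chick_pool: list[_Chick] = []
    extinct_year = None
    all_boxes = set(range(config.n_boxes))

    for year in range(config.n_years):
        if year > 0:
            # 1. adult survival; survivors retain their box
            for occ in (male_at, female_at):
                for b in list(occ):
                    if rng.random() >= config.adult_survival:
                        del occ[b]
            # recruits surviving from last year's chicks
            recruits = [c for c in chick_pool
                        if rng.random() < config.recruit_prob]
            chick_pool = []
            rng.shuffle(recruits)
            rec_m = [c for c in recruits if c.sex == MALE]
            rec_f = [c for c in recruits if c.sex == FEMALE]

            # 2. male settlement: territories are any male-free box
            n_new_m = max(0, n_pairs_target - len(male_at))
            free_m = all_boxes - set(male_at)
            for _ in range(n_new_m):
                if not free_m:
                    break
                # a vacancy goes to an immigrant with probability
                # immigration_fill, otherwise to a local recruit if any
                # remain; an unfillable vacancy stays open this year
                if rng.random() < config.immigration_fill:
                    iid = add_immigrant(MALE)
                    b = int(rng.choice(np.fromiter(free_m, dtype=np.int64)))
                elif rec_m:
                    c = rec_m.pop()
                    iid = add_recruit(c)
                    b = nearest_box(kernel_target(c.natal_box, c.sex), free_m)
                else:
                    continue
                male_at[b] = iid
                free_m.discard(b)

            # 3. female settlement: boxes holding an unpaired male
            n_new_f = max(0, n_pairs_target - len(female_at))
            open_f = {b for b in male_at if b not in female_at}
            for _ in range(n_new_f):
                if not open_f:
                    break
                if rng.random() < config.immigration_fill:
                    iid = add_immigrant(FEMALE)
                    b = int(rng.choice(np.fromiter(open_f, dtype=np.int64)))
                elif rec_f:
                    c = rec_f.pop()
                    iid = add_recruit(c)
                    b = nearest_box(kernel_target(c.natal_box, c.sex), open_f)
                else:
                    continue
                female_at[b] = iid
                open_f.discard(b)

            # widowed females relocate to the nearest unpaired male
            # (within-population breeding dispersal)
            widowed = [b for b in list(female_at) if b not in male_at]
            open_f = {b for b in male_at if b not in female_at}
            for b in widowed:
                if not open_f:
                    break
                j = nearest_box(xy[b], open_f)
                female_at[j] = female_at.pop(b)
                open_f.discard(j)

        # 4. pairing and census: a box with both a male and a female breeds
        paired = [(b, male_at[b], female_at[b])
                  for b in sorted(set(male_at) & set(female_at))]
        for b, m, f in paired:
            breeding_rows.append(dict(year=year, box_id=int(b),
                                      male_id=m, female_id=f))
        if not paired:
            extinct_year = year
            break

        # 5. reproduction (chicks hatched this year recruit next year)
        if year < config.n_years - 1:
            pair_boxes = np.array([b for b, _, _ in paired])
            pair_males = np.array([m for _, m, _ in paired])
            for b, m, f in paired:
                n_chicks = rng.poisson(config.clutch_size_mean)
                for _ in range(n_chicks):
                    sire = m
                    if config.epp_rate > 0 and rng.random() < config.epp_rate:
                        d = np.hypot(*(xy[pair_boxes] - xy[b]).T)
                        near = np.flatnonzero((d <= config.epp_radius_m)
                                              & (pair_males != m))
                        if len(near):
                            sire = int(pair_males[rng.choice(near)])
                    chick_pool.append(_Chick(
                        iid=-1, sex=MALE if rng.random() < 0.5 else FEMALE,
                        birth_year=year, natal_box=int(b), dam=f, sire=sire,
                        social_sire=m))

    individuals = pd.DataFrame(ind_rows)
    breeding = pd.DataFrame(breeding_rows,
                            columns=["year", "box_id", "male_id", "female_id"])
    return SimResult(config=config, nestbox_map=nestbox_map,
                     individuals=individuals, breeding=breeding,
                     genome=genome, loci=loci, extinct_year=extinct_year)


# --------------------------------------------------------------------------
# ZW bookkeeping and a neutral-diversity reference simulation

def zw_copy_fraction_in_males(sexes) -> float:
    """Fraction of Z copies carried by males (2 per male, 1 per female)."""
    sexes = np.asarray(sexes)
    n_m = int((sexes == MALE).sum())
    n_f = int((sexes == FEMALE).sum())
    if n_m + n_f == 0:
        raise ValueError("no individuals")
    return 2.0 * n_m / (2.0 * n_m + n_f)


def neutral_zw_simulation(n_individuals: int, n_auto_loci: int, n_z_loci: int,
                          n_generations: int, mu: float,
                          seed: int) -> tuple[float, float]:
    """Neutral Wright-Fisher run with ZW transmission at unlinked loci.

    Equal sex ratio, random mating, constant population size, symmetric
    biallelic mutation at rate ``mu`` per locus per transmission.  Returns
    mean nucleotide diversity (expected heterozygosity 2p(1-p)) over the
    final generation for autosomal and Z loci.  At mutation-drift
    equilibrium the Z/autosome ratio approaches 3/4, the effective-size
    ratio of a Z chromosome that spends two-thirds of its history in males.
    """
    rng = np.random.default_rng(seed)
    n_m = n_f = n_individuals // 2
    # initial frequencies at 0.5 everywhere; long run reaches equilibrium
    auto = (rng.random((n_m + n_f, 2, n_auto_loci)) < 0.5).astype(np.int8)
    z_m = (rng.random((n_m, 2, n_z_loci)) < 0.5).astype(np.int8)
    z_f = (rng.random((n_f, 1, n_z_loci)) < 0.5).astype(np.int8)

    def mutate(x):
        flip = rng.random(x.shape) < mu
        np.bitwise_xor(x, flip.astype(np.int8), out=x)

    for _ in range(n_generations):
        fathers = rng.integers(n_m, size=n_m + n_f)
        mothers = rng.integers(n_f, size=n_m + n_f)
        # autosomes: one random allele per parent per locus (unlinked)
        pick_p = rng.integers(2, size=(n_m + n_f, n_auto_loci))
        pick_m = rng.integers(2, size=(n_m + n_f, n_auto_loci))
        cols = np.arange(n_auto_loci)
        pat = auto[fathers[:, None], pick_p, cols[None, :]]
        mat = auto[(mothers + n_m)[:, None], pick_m, cols[None, :]]
        new_auto = np.stack([pat, mat], axis=1)
        mutate(new_auto)
        # Z: sons = paternal pick + mother's single Z; daughters = paternal pick
        zcols = np.arange(n_z_loci)
        pick_z = rng.integers(2, size=(n_m + n_f, n_z_loci))
        pat_z = z_m[fathers[:, None], pick_z, zcols[None, :]]
        new_z_m = np.stack([pat_z[:n_m], z_f[mothers[:n_m], 0]], axis=1)
        new_z_f = pat_z[n_m:][:, None, :]
        mutate(new_z_m)
        mutate(new_z_f)
        auto, z_m, z_f = new_auto, new_z_m, new_z_f

    def het(freq):
        return float(np.mean(2.0 * freq * (1.0 - freq)))

    p_auto = auto.mean(axis=(0, 1))
    z_copies = np.concatenate([z_m.reshape(-1, n_z_loci),
                               z_f.reshape(-1, n_z_loci)])
    p_z = z_copies.mean(axis=0)
    return het(p_auto), het(p_z)
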