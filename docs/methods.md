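# Methods

## The system being modelled

`woodgen` studies how limited natal dispersal, annual population turnover
and heavy immigration shape fine-scale genetic structure in a continuously
monitored nestbox population of a short-lived woodland songbird.  The
monitored wood spans roughly 4 km and holds on the order of a thousand
usable nestboxes, a quarter to a half of which hold a breeding pair each
spring.  Locally hatched recruits disperse a median of just under 1 km
from their natal box, females about 1.5× (≈300 m) further than males, and
roughly half of each year's breeders are unringed adults assumed born
outside the wood ("immigrants").  Birds are male-homogametic (ZZ males,
ZW females), so the Z chromosome spends two-thirds of its transmission
history in males and has an effective population size about ¾ that of the
autosomes.

Because the analyses here are verified on simulated data, every claim a
test makes is a claim about parameter recovery or estimator correctness
under the simulator's assumptions — not about any particular wild
population.

## The forward simulator (`simwood` → `woodgen.simulate`)

**Annual cycle.** Each year: (1) every breeder survives with probability
`adult_survival` (default 0.5/yr, typical for a small passerine; with
recruitment at age 1 this gives a generation time near 2 years);
(2) survivors retain their box; (3) males claim territories first — a new
male takes any male-free box, immigrants at random, recruits at the box
nearest their dispersal target (kernel distance × uniform direction from
the natal box); (4) new females settle at the box with an unpaired male
nearest their target (immigrant females at a random such box), and
widowed females relocate to the nearest unpaired male; (5) each paired box
produces a Poisson(`clutch_size_mean`=7) clutch, and each chick enters
the next spring's recruit pool with probability `recruit_prob`=0.12.
Each vacancy is reserved for an immigrant with probability
`immigration_fill`; the default 0.5 calibrates the realized immigrant
share of breeders to ≈50%.  The male-first/female-joins asymmetry is the
standard territorial-songbird settlement model; it keeps the settlement
option set dense for both sexes, which is what lets the realized
dispersal medians track the configured kernels after discretisation.

**Dispersal kernels.** Log-normal by default (right-skewed, the usual
choice for passerine natal dispersal), parameterised by the median
(`disp_median_male_m`=700, `disp_median_female_m`=1050, ratio 1.5,
difference ≈300 m) with log-SD 0.6; Weibull (shape 1.8) as an option.
Realized distances are shortened relative to the kernel by boundary
truncation (targets beyond the wood settle at the rim): ~5–10% for males,
~15% for females at the default medians.  The female:male *ratio* is much
less affected (realized ≈1.43–1.46 against the configured 1.5).

**Genetics.** Biallelic SNPs on 10 autosomes of 60 Mb plus a 75 Mb Z.
Founder frequencies are Beta(2,2) clipped to [0.05, 0.95].  Recombination
is Poisson crossovers (1 cM/Mb, no interference, positions uniform).
ZW rules: sons receive a recombined paternal Z gamete plus the mother's
single Z; daughters receive the paternal gamete only; the W carries no
loci.  With probability `epp_rate` (default 0 — every estimator here is
genetic, so extra-pair paternity only relabels the social sire) the
genetic sire is a random other male breeding within `epp_radius_m`.

**Immigrants** are unrelated draws from an external pool whose allele
frequencies are a Balding–Nichols perturbation of the founder
frequencies.  `immigrant_divergence_fst` is the *realized two-population
Hudson F_ST* between pool and founders; since a BN draw with parameter θ
yields ancestor-vs-pool F_ST of θ/2, the draw uses θ = 2×F.  The default
F = 0.001 represents a weakly differentiated surrounding landscape;
even at this level the classifier separates immigrants from locals above
chance, mostly through kin structure rather than allele-frequency
displacement — the same phenomenon the real study reports at
F_ST ≈ 3.6×10⁻⁴.

**What the simulator does not emulate:** habitat heterogeneity,
phenotype-dependent dispersal, mate choice, selection, genotyping error,
and the deep coalescent history of a real population.  The last point
matters for one analysis: a population-wide elevation of Z-chromosome IBD
reflects thousands of generations at reduced N_e, which an ~9-generation
forward run cannot create from founder pools with identical diversity on
Z and autosomes.  Tests therefore target the transmission-level
consequence of ZW inheritance (first-degree male pairs share more of the
Z: brothers carry the same maternal Z with certainty, so E[π̂_Z] = 0.75
vs 0.5 autosomal), and the sex-pair contrast of Z decay slopes, both of
which the forward model genuinely produces.

**Neutral ZW reference run.** `neutral_zw_simulation` is a Wright–Fisher
model with ZW transmission at unlinked loci and symmetric biallelic
mutation, used to check that Z nucleotide diversity equilibrates near ¾
of autosomal diversity.  The check uses N=40 (20+20), μ=1e-4 (θ≈0.016 —
small, because the biallelic-equilibrium ratio is
0.75·(2θ_A+1)/(2θ_Z+1), which approaches 0.75 only for small θ), 800
generations (≥10·N_e, fully equilibrated from any start), 2,000 loci per
compartment and 20 replicates.  Diversities are pooled across replicates
*before* the ratio is taken: the per-replicate ratio is biased low
(≈0.70) because Z diversity has the larger drift variance and shares the
pedigree with the autosomal estimate.

## Estimators (`kincalc`, `divscan`, `genio`)

* **Method-of-moments IBD.** IBS0/1/2 counts per pair are combined with
  HWE-expected IBS-class probabilities at the sample allele frequencies
  (loci with MAF < 0.1 excluded; moments IBD is fragile to rare
  variants); P(IBD=0,1,2) solved sequentially, clamped to the simplex and
  renormalised; π̂ = P2 + P1/2.  No finite-sample frequency correction is
  applied (bias is O(1/n) at the sample sizes used).  Clamping makes the
  mean π̂ of unrelated pairs slightly positive (≈ +0.015 at 1.5k loci,
  ≈ +0.006 at 20k loci); tests of the "unrelated ⇒ π̂ ≈ 0" property use
  20k loci for this reason.
* **KING-robust kinship.** φ = (N_AaAa − 2N_AAaa)/(N_Aa(a)+N_Aa(b)) over
  jointly non-missing loci; frequency-free and hence robust to structure.
  Degree classes use the powers-of-½ cutoffs (0.354/0.177/0.0884/0.0442).
* **HWE exact test.** Two-sided conditional exact test (sum of
  heterozygote-count probabilities no larger than the observed one, no
  mid-p), computed with log-gamma weights and a 1e-12 relative tie
  tolerance; verified against exact rational enumeration for all tables
  with n ≤ 30.
* **ROH.** PLINK-style scanning window: a W-SNP window is compatible with
  homozygosity if it has ≤H hets and ≤M missing; a SNP is a candidate if
  the fraction of spanning windows that are compatible exceeds 5%;
  maximal candidate runs must pass SNP-count, length, density and gap
  filters, and are trimmed to homozygous endpoints.  Defaults mirror
  PLINK (W=50, H=1, M=5, ≥100 SNPs, ≥1 Mb, ≤50 kb/SNP, gap ≤1 Mb) but
  every parameter is exposed because simulated marker densities
  (~120 kb/SNP at desk scale) need looser density settings.  The caller
  matches a brute-force reimplementation exactly on random instances.
* **F_ST.** Weir–Cockerham (1984) per-locus components a, b, c retained
  so windows and the global value aggregate by ratio-of-sums; negative
  per-locus values kept.  Windows tile chromosomes half-open,
  non-overlapping 50 kb by default.  Hudson's estimator is the
  independent cross-check.
* **QC / LD pruning.** Call rate > 0.95, MAF > 0.05 (allele-copy-aware on
  the Z: 2 copies per male, 1 per female), HWE p > 0.001 (autosomes on
  all samples, Z on males only).  Greedy r² pruning in 50 kb windows
  advanced by 50 SNPs, dropping the later locus of any pair with
  r² > 0.2.

## Spatial analyses (`spatial`)

PCA standardises dosages by 2p̂ and √(2p̂(1−p̂)) with mean imputation.
Pairwise records are annotated with Euclidean breeding distance
(same-year co-breeding boxes preferred; otherwise the minimum over record
pairs ≤2 years apart), natal distance (absent when either bird is an
immigrant), pair type and sex pair.  Kin stripping removes pairs above a
KING-degree cutoff, or parent–offspring/full-sib (optionally half-sib)
links from the social pedigree.

Decay curves are binned means (default 0–4 km in 500 m bins) with 95%
CIs from a cluster bootstrap that resamples *individuals* (each replicate
keeps pairs whose two members are drawn, with multiplicity) — every bird
appears in many pairs, so pair-level resampling would be anticonservative.
The stratified fit is a curvature-penalized B-spline regression of π̂ on
distance per immigration-status stratum, solved as a ridge least-squares
problem (distance internally in SD units so the penalty weight is
scale-free; a linear trend lies in the penalty null space and is never
shrunk).  The slope summary β is the average first derivative of the
smooth over the observed distances, reported per SD of distance and per
km, with cluster-bootstrap CIs.  This replaces a Bayesian GAMM with a
multi-membership random effect: same estimand (the stratum smooth),
frequentist uncertainty.

The Z-vs-autosome contrast uses a copy-aware dosage-correlation
relatedness (each call centred by c·p̂ and scaled by √(c·p̂(1−p̂)) with
c the copy number) so female hemizygous Z calls enter coherently; for
matched comparisons the autosomal loci are subsampled to the Z locus
count so clamping noise is comparable.

## Temporal renewal (`renewal`)

The two most distant boxes anchor two areas of the k=50 nearest boxes
each (ties: lexicographic smallest anchor pair, lowest box id).  Area
membership of a bird is by natal box.  Within-area pairs are grouped by
birth-year lag; the baseline is the mean relatedness of same-cohort
cross-area pairs, averaged over years with ≥10 such pairs.  The crossing
lag is the smallest lag whose bootstrap CI contains the baseline.  For
replicate-level checks the two areas' within-area pairs are pooled,
which stabilises the crossing lag estimate.  Convex-hull nestbox density
(shapely hull, shoelace-verified) is reported per area.

## Immigrant classification (`migclass`)

Majority-class undersampling to balance, 70/30 stratified splits, first
15 PC scores into a 500-tree Random Forest; accuracy distributions over
repeated splits; a 50-forest ensemble on one split averages tree
proximity matrices (fraction of trees in which two samples share a leaf),
visualised by classical (Torgerson) MDS of 1 − proximity; per-individual
confidence is the ensemble immigrant-vote fraction (ties break toward
"local").  The chance baseline permutes labels per repeat and reruns the
identical pipeline.  PCA is fitted on the full balanced sample before
splitting — deliberately mirroring the original analysis order even
though it leaks test information into the features; the accuracy numbers
should be read accordingly.

## Problem sizes and numerical choices

Desk-scale defaults (250 boxes, 20 years, 5,000+500 SNPs, ≈1,300
genotyped breeders) keep a full `replay` under a minute on one core.
Replicate-based checks use 1,019 boxes, 18 years, 3,000+600 SNPs with
400-breeder subsamples for pairwise stages — large enough that every
qualitative ordering is stable across 20 replicates, small enough that
the whole suite runs in minutes.  Bootstrap counts default to 100–200
and are arguments everywhere.  Degenerate inputs are explicit: extinction
returns a result (not an exception), empty bins are reported as gaps,
monomorphic loci are dropped from PCA with a warning, zero KING
denominators are flagged undefined, and collinear hulls raise.

## Known limitations

Realized dispersal medians are boundary-deflated at kernel scales
comparable to the wood (the ratio is robust; absolute medians are not).
The MoM clamping bias makes small mean-π̂ comparisons estimator-dependent;
matched locus counts are used wherever two chromosome sets are compared.
The classifier's leakage-prone PCA ordering is kept for fidelity to the
replicated design, with a leakage-safe variant available by fitting PCA
on training data only.  No attempt is made to reproduce dataset-specific
numbers (PC variance fractions, β magnitudes, the 0.0016 baseline, the
64.8% accuracy), which depend on unreleased genotype data; the package's
claims are the estimator identities, calibrations and orderings its
tests compute.
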