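# woodgen

Spatial population genetics of a continuously monitored nestbox songbird
population: who breeds near their relatives, how fast the genetic basis of
that structure turns over, and whether immigrants are genetically
distinguishable from locally born birds.

## The problem

In a large, continuous woodland population of a short-lived, vagile
songbird, relatedness declines with distance (isolation by distance) even
though dispersal is easy.  Three linked questions arise:

1. **Is the spatial structure just close kin settling near each other?**
   If so, the decline of identity by descent (π̂) with breeding distance
   should flatten as first- and second-degree relatives are removed, and
   should differ between the sexes (females disperse ~1.5× further) and
   between autosomes and the Z chromosome (the Z travels mostly through
   the philopatric sex and has N_e ≈ ¾ of the autosomes).
2. **How persistent is the pattern's genetic basis?**  With ~50% annual
   breeder turnover, same-area birds born a few years apart should be no
   more related than birds from opposite ends of the wood born the same
   year.
3. **Are immigrants a distinct genetic pool?**  F_ST between immigrants
   and locals is tiny, yet a Random-Forest classifier on genomic PCs can
   beat chance — quantified against a label-permutation null.

The package provides a spatially explicit forward simulator
(sex-biased log-normal dispersal kernels, nearest-box settlement, ~50%
immigrant vacancy fill, ZW inheritance with recombination, optional
extra-pair paternity) in place of restricted real genotype data, so every
stage is verifiable by parameter recovery and estimator oracles, plus the
full analysis stack:

| module | contents |
|---|---|
| `woodgen.simulate` | annual-cycle forward simulator, neutral ZW reference model |
| `woodgen.genio` | VCF / PLINK-text I/O, QC (call rate, MAF, HWE exact test), LD pruning, autosome/Z splits |
| `woodgen.kincalc` | method-of-moments IBD (π̂), KING-robust kinship (φ), degree classes, runs of homozygosity |
| `woodgen.spatial` | PCA, pair distance/type annotation, kin stripping, decay curves, penalized-spline IBD–distance fits |
| `woodgen.renewal` | most-distant-area selection, birth-cohort lag curves, cross-wood baseline, hull density |
| `woodgen.migclass` | balanced Random-Forest ensemble, averaged proximity + MDS, permutation null |
| `woodgen.divscan` | per-SNP and 50 kb-window Weir–Cockerham F_ST, MDS-extreme subset comparison |
| `woodgen.pipeline` | end-to-end `replay` with manifest and presets |

Key estimators, in standard notation: π̂ = P(IBD=2) + ½P(IBD=1) from
IBS-class moments; φ = (N_AaAa − 2N_AAaa)/(N_Aa^(a)+N_Aa^(b));
Weir–Cockerham F_ST = Σa / Σ(a+b+c) by ratio of sums.

## Worked example

```python
import numpy as np
from woodgen.config import desk_preset
from woodgen.simulate import run_simulation
from woodgen import genio, kincalc, spatial

sim = run_simulation(desk_preset(seed=0, n_years=25))
print(f"breeders genotyped: {len(sim.breeder_ids())}")
print(f"immigrant fraction: {sim.immigrant_fraction_by_year(burn_in=5).mean():.3f}")
med = sim.natal_dispersal().groupby('sex')['distance_m'].median()
print(f"median natal dispersal  M: {med['M']:.0f} m  F: {med['F']:.0f} m  "
      f"ratio: {med['F']/med['M']:.2f}")

g = genio.split_datasets(genio.from_simulation(sim))["autosomal"]
sub = g.select_samples(np.sort(np.random.default_rng(0)
                               .choice(g.n_samples, 300, replace=False)))
pairs = kincalc.mom_ibd(sub)
pairs = pairs.merge(kincalc.king_robust(sub)[["id_a", "id_b", "phi"]],
                    on=["id_a", "id_b"])
pairs = spatial.pair_table(pairs, sim.individuals, sim.breeding,
                           sim.nestbox_map)
for level in ("none", "no_first"):
    ok = spatial.strip_kin(pairs, level).dropna(subset=["breeding_distance_m"])
    slope = np.polyfit(ok["breeding_distance_m"], ok["pi_hat"], 1)[0] * 1000
    print(f"IBD~distance slope ({level}): {slope:.5f} per km")
```

Output:

```
breeders genotyped: 1592
immigrant fraction: 0.531
median natal dispersal  M: 634 m  F: 925 m  ratio: 1.46
IBD~distance slope (none): -0.00360 per km
IBD~distance slope (no_first): -0.00130 per km
```

The simulated wood realizes the configured ~50% immigrant breeder share
and the 1.5× female dispersal bias (the ratio is slightly deflated by the
wood's boundary), and removing first-degree kin flattens the
IBD–distance slope roughly three-fold — the kin-clustering signature the
analyses are designed to detect.

The same pipeline runs from the shell:

```bash
woodgen replay --preset desk --seed 0 --out results/
woodgen simulate --preset desk --seed 0 --out sim/   # VCF + PLINK + CSVs
woodgen qc sim/genotypes.vcf --out sim/clean
```

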