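# Methods

`admixscan` analyses admixed populations whose genomes are mosaics of
three divergent ancestral pools — IND (*Bos indicus*), AFT (African *Bos
taurus*) and EUT (European *Bos taurus* dairy breeds), the situation of
East African crossbred dairy cattle.  It couples a genome-wide association
model that separates *where an allele came from* (ancestral origin) from
*what the allele is* (residual SNP effect) with haplotype-homozygosity
selection scans (iHS within the admixed population, Rsb against an
indigenous reference), and bundles a forward simulator so that every stage
is testable without access to restricted data.

## The synthetic cohort

**Ancestral pools.**  Pool allele frequencies follow the Balding–Nichols
drift model: given a shared base frequency *p* and a pool differentiation
*F*, the drifted frequency is Beta-distributed with mean *p* and variance
*p(1−p)F*.  Defaults: base frequencies uniform on (0.05, 0.95) and
*F* = 0.25 per pool, matching strongly diverged cattle pools.  Founder
haplotypes are drawn per SNP from the drifted frequencies; optionally each
pool's haplotypes are Li–Stephens-style mosaics of a few prototype
haplotypes (default 6 prototypes per pool, prototype switches at
5 /Morgan, 1% emission error), which reproduces the long shared haplotype
blocks of real breeds with small effective size.  SNP-independent founders
are the default for the library primitives because they keep every
downstream oracle tractable; the pipeline's study cohort enables the
prototype model because the contrast between recently admixed and deep
inter-se animals (below) only exists when founder haplotypes are long and
shared.

**Admixture.**  A breeding population of 200 individuals (pure founders in
the target pool proportions, deterministically composed) evolves by
discrete generations of random mating; meiosis places Poisson(*L*)
crossovers uniformly per chromosome (Haldane model, 1 Morgan = 100 Mbp
throughout).  A cohort animal of admixture age *g* is an offspring of two
distinct generation *g−1* individuals: age-1 animals are F1s with intact
single-ancestry haplotypes; ages 12–24 (the default range, consistent with
some 60 years of crossing at 2.5–5 years per generation) give deeply
recombined animals.  The simulator records the exact tract structure, so
the returned ancestry matrix is truth, and it separately records, per
haplotype and chromosome, the number of EUT↔non-EUT tract junctions
visible at SNP resolution (a junction between two SNPs that bracket an odd
number of class boundaries).  This is the oracle the crossover-counting
code is validated against.

The per-chromosome gamete lineages of one animal are simulated
independently, so between-chromosome correlation of an animal's ancestry
proportions is weaker than in a single-pedigree simulation; genome-wide
expectations are unaffected.

**Sweeps.**  `inject_sweep` manufactures the haplotype signature of
positive selection directly: a donor haplotype's alleles are copied over a
flank (half-width in bp) onto random recipients until the carrier
frequency of the donor's flank haplotype reaches the target.  This
produces the extended block of identical haplotypes that iHS and Rsb are
designed to detect, with an exactly known core SNP.  The study conditions
use target 0.6 with a 1 Mbp half-width for the within-population
(partial-sweep) setting and target 0.9 with a 3 Mbp half-width for the
divergent near-fixation setting that Rsb is designed for — haplotype
signatures of strong recent selection in cattle span multiple Mbp
(extent of order 1/(2 t r) for a sweep ~20 generations old).

**Phenotypes.**  Repeated records per animal follow
*y = μ + Σ(origin effect × EUT dosage) + Σ(allele effect × allele dosage)
+ u + pe + e*, with *u* ~ N(0, σg²G) for a supplied GRM,
*pe* ~ N(0, σpe²I) per animal and *e* ~ N(0, σe²I) per record.  Defaults
(σg², σpe², σe²) = (1, 0.5, 1) with 3 records per animal mimic milk-yield
deviations with repeatability ≈ 0.6.

## Ancestry summaries and the recency filter

A *recent crossover* is an adjacent-SNP transition between EUT and a
non-EUT label on one haplotype; IND↔AFT switches are internal to the
indigenous component and never count.  Counts are standardized per Morgan
using the position of the chromosome's last SNP as its length (the only
definition reproducible from the data alone).  Per chromosome the lower of
an animal's two haplotype rates is taken; the unweighted mean over
chromosomes is the animal's recency score, and animals scoring below 3
crossovers/Morgan are removed before the selection scans.  The rationale:
a recently admixed animal carries long intact exotic haplotypes on which
selection has not had time to act, and their extended homozygosity swamps
genuine sweep signals.

## GWA: dual-effect mixed model

Per SNP, the ancestral-origin effect (per EUT-origin allele copy, dosage
0/1/2 from the local-ancestry labels) and the residual allele effect (per
alternate-allele copy) are estimated jointly in

y = 1μ + Xβ + Wu + Wpe + e,

with u ~ N(0, σg²G) under a leave-one-chromosome-out VanRaden GRM
(method 1, sample allele frequencies for centering, monomorphic SNPs
dropped), pe ~ N(0, σpe²I), e ~ N(0, σe²I), and W the record→animal
incidence shared by u and pe.  Both effects are Wald-tested against χ²₁.

Fitting is two-stage (EMMAX style): variance components are REML-estimated
once per LOCO GRM under the intercept-only null, then each SNP is tested
by GLS at fixed variance structure.  The restricted likelihood is
evaluated on an exact collapse of the repeated-records model —
within-animal contrasts contribute (N−m)·log σe² + SSW/σe², animal means
follow N(Xβ, σg²G + σpe²I + σe²D⁻¹) — which is verified against a dense
record-level evaluation in the test suite.  Optimization is L-BFGS-B on
log-variances (lower bound 1e-8 of the phenotypic variance; estimates
pinned there are reported clipped with a warning) polished by Nelder–Mead,
convergence 1e-8 on the objective.  A full per-SNP REML refit
(`fit_reml` with the SNP columns in X) is available as the exact path.

Two properties of this design matter for interpretation:

* The two-stage approximation differs from a full per-SNP refit by the
  REML degrees-of-freedom/projection change from adding the SNP columns,
  of order t²·p/m for m animals — about 10⁻² on −log₁₀p at m = 50.  This
  is a property of the approximation, not of the implementation; the
  implementation's algebra is validated independently.
* In an admixed cohort, p values across SNPs within one scan are strongly
  dependent: every origin dosage loads on the animal's global ancestry,
  so a single polygenic realization tilts thousands of tests jointly, and
  the origin scan is additionally conservative because REML's genomic
  variance absorbs ancestry-correlated signal.  Calibration is therefore
  demonstrated *marginally* — a null SNP's p values across phenotype
  replicates are uniform when the analysis GRM matches the generating
  model — rather than by within-scan uniformity, which is not a property
  a correct estimator has under these conditions.

Simulated GWA truth draws the polygenic background from the
non-focal-chromosome GRM, so the background is exactly what the LOCO
analysis models; drawing it from the full GRM makes every tested SNP
infinitesimally causal, which is a different (power, not calibration)
experiment.

## Selection scans

**EHH / iHS.**  For a core allele, EHH at extension SNP *t* is the
identical-pair fraction Σₖ nₖ(nₖ−1) / (n_a(n_a−1)) over the carriers'
core-to-*t* haplotypes.  iHH integrates EHH (trapezoid, map distance at
1 cM/Mbp) outward to the point where EHH first drops below 0.05, with
linear interpolation to the crossing; curves that reach the chromosome end
above the threshold are flagged edge-truncated and integrated in full (a
configuration switch can drop them).  Raw iHS = ln(iHH_ancestral /
iHH_derived), computed at SNPs with MAF > 0.05; the ancestral allele is
the pooled-sample majority (exact ties resolve to the reference allele
with a warning).  Raw scores are standardized to mean 0, population SD 1
within derived-allele-frequency bins of width 0.025; bins with fewer than
10 SNPs or zero spread are merged with their nearest neighbor.  Two-sided
p values use −log₁₀(2Φ̄(|z|)).

**EHHS / iES / Rsb.**  The site-level statistic uses sample-size-corrected
heterozygosities over *all* haplotypes: EHHS = (1−h_st)/(1−h_s) with h_st
the haplotype heterozygosity from core to extension and h_s the allele
heterozygosity at the core; it is 1 at the core by construction and is
integrated exactly like iHH.  Rsb = ln(iES_admixed / iES_reference) per
SNP computable in both populations, standardized by the genome-wide median
and SD, with the same p transform.  No MAF filter is applied to Rsb.

The partition-refinement inner loops are numba-compiled; they are verified
exactly against brute-force pair counting on random panels.

**Sensitivity to marker density.**  The ratio of a sweep's integrated
homozygosity to the neutral background scales with SNP spacing, because
neutral EHH decays over a roughly constant number of SNP steps while the
sweep's extent is fixed in bp.  The bundled study conditions use 25 kb
spacing over 4 × 25 Mbp chromosomes (the real analysis this emulates had
~5 kb spacing genome-wide); sparser grids than ~50 kb make desk-scale
sweep detection unreliable.  Small filtered cohorts are the other failure
mode: below ~100 retained animals the minor-allele iHH is dominated by
integration noise.

## Multiple testing and regions

Storey–Tibshirani q values: π₀ from the natural-cubic-spline smoother of
π₀(λ) over λ = 0.05…0.95 evaluated at λ = 0.95 (clipped to (1/m, 1]), and
q as the step-up minimum of π₀·m·p/rank; π₀ = 1 reproduces
Benjamini–Hochberg exactly.  FDR threshold lines report −log₁₀ of the
largest p whose q passes the level.

Candidate regions are seeded by SNPs with q < 0.1 and grown stepwise: any
SNP with q below the suggestive threshold (0.5 for iHS, 0.25 for Rsb)
within 500 Kbp of the last identified SNP becomes the new boundary, until
a step finds none; boundaries are the outermost identified SNP positions
(1-based closed; BED exports convert to 0-based half-open); regions grown
from different seeds that touch are merged.  GWA regions use one
suggestive threshold (p < 10⁻³) for both seeding and extension.  Overlap
lengths between closed intervals are reported as end − start of the shared
interval.  Each selection region is labeled with its dominant ancestry:
the pool with the highest mean local-ancestry fraction over the region's
SNPs among the retained animals, ties resolved in IND, AFT, EUT order with
a logged warning.

## What the simulations do and do not show

The generator reproduces the statistical structure the analyses assume:
exact ancestry tracts, Poisson recombination, controllable pool
differentiation, optional long founder haplotypes, verbatim-copy sweep
blocks, and phenotypes generated under the fitted model.  It does not
model mutation, genotyping or phasing error, ancestry-call error (labels
are truth, while real local-ancestry calls carry HMM uncertainty),
pedigree overlap between cohort animals' chromosomes, gene conversion, or
crossover interference.  Passing tests therefore demonstrate correctness
and power of the *machinery* under clean inputs, not robustness of the
scans to call error or array artifacts.

## Numerical conventions

Seeds are explicit everywhere; no global RNG state.  Coordinates are
1-based bp; 1 Morgan = 100 Mbp everywhere.  The GRM may carry a small
configurable diagonal ridge (default 0, logged when applied).  Degenerate
design columns (constant or collinear dosages) mark the affected effect
not-estimable and keep the other; for an exactly collinear origin/allele
pair the origin effect is kept, matching the model's reading of the
allele effect as residual to origin.
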