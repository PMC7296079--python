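# admixscan

Local-ancestry-aware GWAS and haplotype-based selection scans for admixed
populations, with a forward simulator of admixed cohorts.

## The problem

Crossbred dairy cattle in East Africa descend from decades of crossing
European dairy breeds (EUT) onto indigenous zebu populations that are
themselves ancient admixtures of *Bos indicus* (IND) and African *Bos
taurus* (AFT).  Their genomes are ancestry mosaics, which both complicates
and enriches mapping: an allele's effect can be split into the part
explained by *which ancestral population contributed it* and the residual
effect of the allele itself, and the length distribution of shared
haplotypes records recent selection.  `admixscan` implements the full
analysis chain for such cohorts:

* **synthpop** — forward simulation of admixed cohorts from three
  Balding–Nichols-differentiated ancestral pools, with exact ancestry
  tracts, optional long shared founder haplotypes, injectable selective
  sweeps and repeated-record phenotypes;
* **ancestry** — per-allele EUT dosages, recent-crossover counting
  (EUT↔non-EUT transitions per Morgan at 1 Morgan = 100 Mbp), and the
  recency filter that removes recently admixed animals (score < 3
  crossovers/Morgan) before selection scans;
* **relatedness** — VanRaden genomic relationship matrices, whole-genome
  and leave-one-chromosome-out (LOCO), and PCA;
* **assoc** — the dual-effect mixed model
  `y = 1μ + Xβ + Wu + Wpe + e`, with `β` holding the ancestral-origin
  effect and the residual SNP effect jointly, `u ~ N(0, σg²G)` under the
  LOCO GRM, repeated records through a shared incidence `W`, REML variance
  components and per-SNP generalized-least-squares Wald tests;
* **ehh** — EHH, iHH and iHS (`iHS = ln(iHH_a/iHH_d)`, standardized
  within derived-allele-frequency bins of 0.025) and the between-population
  EHHS/iES/Rsb statistics (`Rsb = ln(iES_A/iES_B)`, standardized by the
  genome median and SD), with two-sided Gaussian p values;
* **mtc** — Storey–Tibshirani q values and FDR threshold lines;
* **regions** — seed-and-extend candidate-region calling (seed q < 0.1,
  500-Kbp steps, suggestive q < 0.5 for iHS and < 0.25 for Rsb; p < 10⁻³
  for GWA), dominant-ancestry labels and interval intersection.

`docs/methods.md` describes the models, defaults and limitations.

## Worked example

Run the whole pipeline on a simulated cohort with a strong divergent sweep
on chromosome 2:

```python
from admixscan.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    out_dir="demo", seed=7,
    n_admixed=400, n_recent=100,          # 300 deep inter-se + 100 F1 animals
    sweep_chrom=2, sweep_target_freq=0.9, sweep_half_width_bp=3_000_000,
)
results = run_pipeline(config)
```

This simulates 400 admixed animals on 4 × 25 Mbp chromosomes (4,000 SNPs),
injects the sweep, and writes haplotypes, ancestry, phenotypes, scan
tables, regions and a manifest under `demo/`.  With seed 7 the manifest
reports:

```
retained: 205  removed: 195
cohort_mean: {'IND': 0.239, 'AFT': 0.017, 'EUT': 0.744}
ihs regions: 1   rsb regions: 1   gwa regions: 38
```

The cohort's mean ancestry lands on the configured 0.24/0.03/0.73
IND/AFT/EUT mix; the recency filter removes the 100 F1 animals plus the
deep animals with fewer than 3 recent crossovers per Morgan.  The top of
`demo/regions.tsv`:

```
chrom  start_mbp   end_mbp  n_snps  top_stat dominant_ancestry  source
    2  15.132069 15.132069       1  0.000059               EUT     ihs
    2   9.503094 15.554039     252  0.077554               EUT     rsb
```

Both selection scans call candidate regions containing the injected core
SNP (position 12.6 Mbp on chromosome 2); `top_stat` is the region's best
q value, and the dominant ancestry of the swept region is EUT.  The 38
suggestive GWA regions come from the purely polygenic phenotype — many
weak signals, none exceptional.  The same stages are exposed individually
on the command line (`admixscan simulate`, `ancestry`, `gwa`, `ihs`,
`rsb`, `regions`, `overlap`, `grm`, or `admixscan run` for the whole
pipeline).

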