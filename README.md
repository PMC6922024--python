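# popgenpipe

Population-genomics toolkit for diploid biallelic SNP-array panels:

- **genotype_io** — PLINK PED/MAP and BED/BIM/FAM readers/writers, panel
  intersection with allele harmonization, fixed-order QC filtering
  (sample missingness → autosomes → call rate → MAF), unified additive
  relationship (UAR) matrix, and greedy relatedness pruning.
- **diversity** — observed heterozygosity, Nei's unbiased expected
  heterozygosity, hypergeometric rarefied allelic richness, and multilocus
  Fis with a seeded percentile bootstrap CI.
- **roh** — window-free consecutive-run ROH detection (maximal runs with
  bounded het/missing allowances), the minimum-SNP threshold
  `l = ceil(ln(alpha/(n_s n_i)) / ln(1 - het))`, half-open length classes
  (1–2, 2–4, 4–8, 8–16, >16 Mb), and genomic inbreeding F_ROH at
  configurable length floors (default denominator 2.44 Gb).
- **ne_ld** — historical effective population size from distance-binned
  dosage r², with explicit sample-size correction `r² − 1/(βn)`, linear or
  Sved–Feldman physical→genetic mapping, and the inversion
  `Ne(t) = (1/(4c))(1/r²_adj − α)` at `t = 1/(2c)` (default α = 2.2).
- **structure** — pairwise Weir–Cockerham FST (ratio-of-sums multilocus θ),
  IBS distance matrices, Torgerson MDS, genotype PCA (Patterson or unit
  scaling), and exporters (PHYLIP, NEXUS, ADMIXTURE PED, TreeMix counts).
- **synthetic_data** — a Wright–Fisher gene-dropping simulator (Poisson
  crossovers on a 1 cM/Mb map) that records true IBD tracts, pedigree F
  from grafted mating loops, and drift expectations; plus an
  msprime-backed coalescent generator for LD/Ne cross-validation.
- **pipeline / cli** — end-to-end orchestration with a JSON provenance
  manifest and a `popgenpipe` command-line interface.

## CLI

```sh
popgenpipe simulate --out scratch/sim --seed 1       # synthetic 5-pop panel
popgenpipe qc --in scratch/sim --out scratch/clean   # QC + relatedness pruning
popgenpipe diversity --in scratch/clean --out scratch/div.tsv
popgenpipe roh --in scratch/clean --out-dir scratch/roh
popgenpipe ne --in scratch/clean --out-dir scratch/ne
popgenpipe structure --in scratch/clean --out-dir scratch/struct
popgenpipe run --in scratch/sim --out-dir scratch/full --seed 1   # everything
popgenpipe validate --bundle scratch/full --reference ref.tsv
```

`popgenpipe run` accepts a plain `key = value` config file (`--config`);
see `popgenpipe.pipeline.PipelineConfig` for the keys. Every output table
carries a commented metadata header and the run writes `manifest.json`
recording parameters, seeds, and stepwise sample/SNP counts; identical
inputs and config give byte-identical outputs.

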