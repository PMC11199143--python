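# traitdrift

Simulation pipeline for studying how population bottlenecks, migration and
growth reshape the heritability and genetic architecture of a polygenic
trait, including a GWAS-detectability thresholding analysis.

An ancestral population of size `N0` splits `T` generations ago into a
Reference population (constant size `N0`) and a Bottlenecked population
(founded with `N` individuals, optionally growing at rate `g` and receiving
migrants from the Reference at per-generation fraction `m`). Genealogies are
simulated with [msprime], mutations are added under the infinite-sites
model, and a polygenic trait is overlaid on the Reference population: per-SNP
effect sizes are drawn as `beta_j ~ N(0, [f_j(1-f_j)]^s)` with `s = -1` by
default, and environmental variance is calibrated so Reference heritability
`h2 = Vg/(Vg+Ve)` hits a target (0.5 by default). The same effect sizes and
environmental variance are then carried into the bottlenecked population,
where drift has reshaped allele frequencies, and heritability is recomputed.
A power-thresholding stage mimics GWAS detectability: per-SNP scores
(variance explained `f(1-f)beta^2`, or marginal association p-values) are
pooled over many independent trait simulations, a top-`1/2^n` quantile
cutoff is calibrated, and heritability is recomputed from the surviving SNPs.

[msprime]: https://tskit.dev/msprime/

## Layout

| module | contents |
| --- | --- |
| `traitdrift.scenario_sim` | `DemographyConfig`, demography builder, genotype simulation, `GenotypeDataset`, CSV/VCF export |
| `traitdrift.trait_model` | effect-size draws, genetic values, `Ve` calibration, phenotype simulation |
| `traitdrift.heritability` | `h2 = Vg/(Vg+Ve)`, per-population evaluation of a trait |
| `traitdrift.thresholding` | variance explained, per-SNP GWAS p-values, quantile threshold calibration, thresholded heritability |
| `traitdrift.stats` | empirical bootstrap CIs for variances, Pearson r with Fisher-z SEs, OLS slope |
| `traitdrift.experiments` | replicate orchestration, parameter sweeps, threshold experiment |
| `traitdrift.cli` | `traitdrift` command-line interface |

## CLI

```sh
# one replicate: dump genotype matrices, trait and heritability result
traitdrift simulate --n0 2000 --n 400 --t 200 \
    --genome-length-bp 200000 --genome-length-morgans 0.002 \
    --causal-mutation-rate 2e-8 --n-sample-ref 100 --n-sample-bot 100 \
    --seed 42 --out out/replicate1

# sweep a demographic parameter (N, T, m or g)
traitdrift sweep --config config.yaml --param N --values 500,1000,2000,4000,8000 \
    --reps 30 --master-seed 1 --out out/nsweep

# GWAS-detectability thresholding experiment
traitdrift threshold --config config.yaml --mode ve --n-list 1,2,3 \
    --calib-reps 200 --reps 200 --master-seed 1 --out out/threshold

# summarize a replicate CSV
traitdrift summarize out/nsweep_records.csv --out out/nsweep_resummary.csv
```

`--config` accepts a flat JSON/YAML file of `DemographyConfig` fields;
explicit flags override it. All randomness flows from the given seeds, so
every table is bit-reproducible.

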