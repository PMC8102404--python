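# fluxlip

Toolkit linking a transporter knockout to systemic lipid metabolism through
three computational arms:

1. **Constraint-based modelling** — load SBML / COBRA-JSON models, build
   condition-specific (wildtype vs knockout) variants from transcriptomic
   and metabolite constraints, sample the feasible flux polytope with
   artificial-centering hit-and-run, and call differentially altered
   reactions (per-reaction two-group ANOVA F test, p < 0.001 with >2-fold
   or <0.5-fold change), rolled up to subsystem tallies and affected /
   lipid-annotated metabolite sets.
2. **Targeted metabolomics statistics** — group-minimum imputation, Welch
   (or pooled Student) t tests, fold changes, Cohen's d, Benjamini-Hochberg
   adjustment, significance/trend tiers, and per-subpathway enrichment
   ratios `E = (k/m) / ((n-k)/(N-m))`.
3. **Lipid chemoinformatics** — a ~32-feature RDKit descriptor panel
   (ring count, carboxyls, hydroxyls, rotatable bonds, stereocenters,
   sp3/acyclic carbons, positive-charge density, Bertz complexity, ...),
   correlation-pruned information-gain feature selection, class balancing
   (down/up/combined), leave-one-out validation of four classifier types,
   and a force-optimized FreeViz-style 2-D projection.

A synthetic-data module generates desk-scale inputs with exact ground
truth for every stage: toy metabolic networks with a deletable uptake
exchange (the knockout stand-in), lognormal metabolite tables with planted
directional effects, and two structural lipid classes (acyclic carboxylic
chains vs polycyclic / charged species).

Sign convention everywhere: positive exchange flux = secretion, negative =
uptake.

## CLI

Every stage is a `fluxlip` subcommand; seeds are mandatory wherever
randomness is involved.

```sh
# synthetic inputs
fluxlip synth network      --seed 1 --out out/net
fluxlip synth metabolomics --seed 1 --out out/met
fluxlip synth lipids       --seed 1 --out out/lip

# condition-specific model building (expression / constraints / knockout)
fluxlip context --model out/net/wildtype.json --expression expr.tsv \
    --knockout EX_upt_1 --out out/ko.json

# flux sampling and differential flux calling
fluxlip sample --model out/net/wildtype.json --n 2000 --seed 1 --out out/wt.tsv
fluxlip sample --model out/net/knockout.json --n 2000 --seed 2 --out out/ko.tsv
fluxlip diffflux --wt out/wt.tsv --ko out/ko.tsv \
    --model out/net/wildtype.json --alpha 0.001 --fc 2 --out out/diff

# metabolomics statistics and enrichment
fluxlip metstats --table out/met/metabolomics --case KO --control WT \
    --out out/stats

# descriptors, LOO classification, FreeViz
fluxlip chemml --molecules out/lip/lipids.tsv --model random_forest \
    --sampling downsample --seed 7 --out out/ml

# whole pipeline from one YAML config (writes a manifest with hashes)
fluxlip run --config pipeline.yaml
```

## Layout

```
src/fluxlip/
  model_core.py          models, validation, FBA, FVA (cobrapy/GLPK backend)
  context_builder.py     GPR scoring, expression/metabolite constraints, knockouts
  flux_sampler.py        ACHR polytope sampling + L1 normalization
  diff_flux.py           F tests, fold-change filters, subsystem/metabolite rollup
  metabolomics_stats.py  imputation, Welch/Student, BH, tiers, enrichment, overlap
  chem_ml.py             descriptors, feature selection, balancing, LOO, FreeViz
  synthetic_data.py      ground-truth generators for all three arms
  cli.py                 subcommands + config-driven pipeline with manifest
```
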