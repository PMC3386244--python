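# introsim

Forward simulation and likelihood inference for multi-generation competition
experiments that track an introgressed genomic segment against its resident
counterpart.

The package models a neutral microsatellite marker linked (at recombination
fraction `c`, females only) to a selected "incompatibility" locus with
selection coefficient `s` and dominance `h`. It provides:

- `introsim.simulate` — individual-based simulator of one bottle replicate:
  viability selection, destructive sampling of 20 males + 20 females at
  scheduled generations, and random mating back to a fixed census (default
  150 + 150), plus a deterministic infinite-population oracle
  (`expected_trajectory`).
- `introsim.batch` — a vectorised engine that advances thousands of
  replicates at once on genotype-count state; used to build the binned
  frequency distributions behind the likelihood.
- `introsim.likelihood` — 40-bin frequency distributions per sampled
  generation, the pooled-bin log-likelihood of observed replicate
  frequencies, grid-search MLE of `(s, c)` at each dominance level, and the
  summary-table aggregation of per-marker estimates.
- `introsim.stats` — mating-success share decomposition and exact sign test,
  fertility summaries with one-way ANOVA, a genotype-permutation linkage
  disequilibrium test, and two-group trajectory comparison.
- `introsim.synth` — generators for every input the pipeline consumes
  (replicate trajectories, mating-pair counts, fertility records) under
  known ground-truth parameters.
- `introsim.datasets` — the published empirical tables (mating counts,
  fertility line means, per-marker MLEs) shipped as CSV.
- `introsim.io` / `introsim.cli` — config loading, validated CSV
  round-tripping, and pipeline orchestration.

## CLI

```sh
# simulate replicate trajectories at fixed parameters
introsim simulate --s 0.4 --h 0.5 --c 0.0001 --iterations 1000 --seed 1 --out traj.csv

# generate the default six-experiment synthetic study
introsim synth --seed 1 --out study.csv

# grid-search MLE per experiment in a trajectory CSV
introsim fit --obs study.csv --iterations 2000 --seed 1 --out fit/

# table statistics
introsim stats mating --in mating.csv --out mating_report.tsv

# end-to-end desk-scale pipeline (synth -> fit -> stats -> reports + manifest)
introsim run-all --seed 1 --out artifacts/
```

Configuration files (YAML or JSON) can override the experiment design, the
inference grid, iteration counts and the fitness scheme; see
`introsim.io.load_config`.

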