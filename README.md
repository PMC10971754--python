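# coocnet

Compositional co-occurrence network analysis for microbiome count tables:

- **synthetic**: generators with known ground truth — planted
  conditional-dependence graphs, logistic-normal → multinomial count
  tables with library-size and batch variation, biomass covariates, and
  presence–absence site matrices under niche vs stochastic occupancy.
- **preprocess**: rare-taxon filtering (total count ≤ 2), per-batch
  library-size normalization, replicate-run averaging, bacterial-domain
  filtering, taxonomic-rank conglomeration, biomass-quantile grouping,
  presence–absence conversion.
- **inference**: signed, undirected network estimation via CLR transform,
  per-node L1-penalized neighborhood regression along a log-spaced
  penalty path, and subsample-stability penalty selection
  (edge instability `2θ(1−θ)`, threshold 0.05).
- **topology**: the per-network measure set (nodes, edges, signed edge
  counts and ratio, average path length, degree heterogeneity, maximized
  Newman modularity, average degree, global transitivity), hub scoring
  (Kleinberg-style centrality in [0, 1], hubs at ≥ 0.5), and
  signed-neighbor queries.
- **ensemble**: repeated subsampled network construction per group with
  Kruskal–Wallis and pairwise rank-sum comparisons of the topology
  measures.
- **ordinal**: proportional-odds logistic regression of biomass quantile
  on topology measures, with collinearity screening, exhaustive and
  stepwise AIC subset selection, and reciprocal odds-ratio
  interpretation.
- **zeta**: multi-site shared-species (zeta) diversity, exact up to an
  enumeration cap and Monte-Carlo sampled beyond it, with exponential vs
  power-law decline fits whose AIC comparison classifies community
  assembly as stochastic vs niche-driven.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(oracle equivalences, recovery experiments, and a full scaled-down
pipeline run) and takes ~11 minutes on one CPU; the remaining suites run
in under a minute.

## Command line

Every stage is a subcommand of `coocnet` (see `coocnet --help`):

```sh
coocnet simulate --seed 1 --n-taxa 100 --n-samples 200 --out-dir sim/
coocnet preprocess --abundance sim/abundance.tsv --taxonomy sim/taxonomy.tsv \
    --metadata sim/metadata.tsv --out-dir prep/
coocnet network --abundance prep/abundance_base.tsv --seed 1 --out-dir net/
coocnet ensemble --abundance sim/abundance.tsv --metadata sim/metadata.tsv \
    --n-per 50 --n-reps 100 --seed 1 --out-dir ens/
coocnet regress --metrics ens/metrics.tsv --out-dir reg/
coocnet zeta --presence sim/assembly_niche.tsv --i-max 50 --out decline.tsv
coocnet run --config config.yaml --seed 1       # full pipeline
```

The full pipeline (`run`) takes a YAML config naming the three input TSVs
(abundance: taxa × samples; taxonomy: taxon → class/order/family/genus/
species; metadata: sample → population, biomass_g, batch, run_group),
executes preprocess → per-rank network ensembles → ordinal regression →
zeta assembly under one master seed, and writes per-rank metrics,
comparison, odds-ratio and zeta tables plus a provenance manifest.
Identical configs and seeds give byte-identical outputs.

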