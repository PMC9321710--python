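# paretoflux

Multiobjective evolutionary strain design over constraint-based metabolic
models. `paretoflux` searches binary gene-deletion vectors (optionally with
heterologous pathway knock-ins) on a stoichiometric model, scoring each
candidate strain with FBA / FVA / parsimonious-FBA derived objectives —
growth rate, product yield, min/max productivity, knockout count and
chromosome co-location — and accumulating a Pareto archive of mutually
non-dominated feasible strains.

Main components:

| module | contents |
| --- | --- |
| `paretoflux.model` | `StoichiometricModel`, `StrainDesign`, `PathwayDefinition`, knockout (`apply_design`) and knock-in (`add_pathway`) operations |
| `paretoflux.gpr` | gene–protein–reaction Boolean rules: parser (AND binds tighter than OR) and evaluator |
| `paretoflux.io` | COBRA-style JSON read/write, SBML L3+FBC read (via optional `cobra`) |
| `paretoflux.lp` | FBA, FVA and pFBA as linear programs (HiGHS via `scipy.optimize.linprog`) |
| `paretoflux.metrics` | yield, productivity, FVA productivity ranges, cofactor production flux-sums, wild-type percent variation |
| `paretoflux.loci` | chromosome decoding for Y. lipolytica (`YALI0…`) and S. cerevisiae systematic (`Y??nnn[WC]`) gene names; same-chromosome score |
| `paretoflux.moea` | NSGA-II-style search, Pareto archive, constraint handling (growth floor, essential genes, synthetic lethals, cofactor bounds), exhaustive brute-force oracle |
| `paretoflux.toys` | built-in synthetic models with closed-form optima (no downloads needed) |
| `paretoflux.reporting` / `paretoflux.cli` / `paretoflux.config` | strain tables, front export/import, YAML run configs, `paretoflux` CLI |

## CLI

```bash
# evolutionary search from a YAML config; exports front.json / front.csv /
# strains.csv and a per-generation log
paretoflux run --config config.yaml --seed 1 --out results/

# score a single design
paretoflux evaluate --config config.yaml --delete GENE1 --delete GENE2

# exhaustive oracle front (toy-scale models only)
paretoflux bruteforce --config config.yaml --out front.json

# emit the built-in synthetic models as COBRA-style JSON
paretoflux fixtures --out fixtures/
```

A minimal config:

```yaml
model: {builtin: core}          # or {path: model.json, dialect: cobra-json}
pathways: [builtin-core-pathway]
moea:
  objectives: [growth_rate, product_yield]
  population_size: 60
  generations: 50
  max_deletions: 3
  growth_floor_fraction: 0.9
  essential_genes: [g_ess1, g_ess2]
  knockins: [carotene]
  rng_seed: 1
```

## Notes

- Exchange fluxes use the standard sign convention: uptake negative,
  secretion positive.
- Models are immutable values; `apply_design`/`add_pathway` return copies.
- `run_moea` is fully deterministic for a fixed `rng_seed`.
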