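# chronopath

**Host–pathogen digital coevolution and time-travelling invasion
experiments.**

Thawing permafrost and melting glaciers release long-dormant
microorganisms into communities that stopped coevolving with them ages
ago. Whether such *time-travelling* pathogens can establish, and what
they do to the diversity of the communities they invade, is nearly
impossible to measure directly — but it can be studied in silico.
`chronopath` provides, at desk scale:

- a reduced **digital coevolution world**: free-living hosts on a
  toroidal grid earn CPU cycles by performing nine logic tasks
  (NOT … EQU) on limited resources with by-product excretion, while
  pathogens steal host CPU, transmit by propagules thrown at random
  cells, and infect via task matching — a pathogen must perform at least
  one task its host performs (so hosts evolve resistance by changing
  task repertoire);
- a **paired-futures protocol**: control and treated runs share one seed
  and are bit-identical until a manipulation update, at which a pathogen
  sampled from the community's own past (or, as baselines, an extant
  pathogen, or merely a fresh RNG stream) is injected — any
  post-manipulation difference is causally attributable to the
  manipulation;
- the **outcome analytics**: capped lineage persistence and
  population-size-matched comparison with native pathogens, prevalence
  trajectories, AUC-based relative diversity change
  100·(A_con − A_inv)/A_con on richness / Shannon H′ / Faith's PD,
  exceedance versus the control-control null, a 21-feature Spearman
  screen, exact rank-sum loss-vs-gain comparison, exact binomial
  excess-persistence tails, random-forest prediction with out-of-bag
  explained variance, and the substitutions→bacterial-generations
  calibration.

The model, conventions and parameter choices are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

One paired time-travelling invasion at the standard desk scale
(a 10,000-update run; windows are 1/25 of their full-scale lengths):

```python
from chronopath import (build_config, run_pair, persistence_table,
                        native_comparison, pair_change)

config = build_config(207, scale=0.04)          # 144-cell world, T = 10,000
pair = run_pair(config, seed=2, kind="time_travel")

print(pair.t_sample, pair.t_manipulate)          # 6000 7480
print(pair.invader.tasks)                        # (1, 0, 0, 0, 0, 1, 1, 1, 0)
print(pair.invader_provenance)                   # {'update': 6000, 'abundance': 20,
                                                 #  'n_injected': 2}

table = persistence_table(pair)
print(int(table[table.is_invader].persistence.iloc[0]))   # 4   (cap = 2000)
print(native_comparison(table))                           # 0.0

change = pair_change(pair)
print(f"{change.signed_pct:+.2f}%")              # +37.58%
```

Reading the output: the invader was sampled at update 6,000 (abundance
20, lineage since gone extinct) and re-injected at update 7,480 into 5%
of cells, establishing only 2 individuals. Its lineage survived 4
updates — outlasting none of the native pathogen lineages of equal or
larger population — yet the invaded community still ended the
100-update comparison window with 37.6% *less* free-living richness
than its untouched twin: even an invasion that fails almost instantly
can perturb a small community's trajectory. Whether such changes exceed
ordinary replicate-to-replicate noise is what the `control_control`
baseline quantifies.

The same protocol is available from the shell:

```sh
chronopath campaign --kind time_travel --n-configs 30 --replicates 2 \
    --seed 1729 --out runs/tt
chronopath persistence --pair-dir runs/tt/pair_0000
chronopath diversity   --pair-dir runs/tt/pair_0000 --sensitivity
chronopath analyze     --campaign-dir runs/tt --out runs/tt/analysis
chronopath calibrate   --updates 250000
# 250000 updates ~ 2,000,000 - 4,000,000 bacterial generations
```

Pair directories hold versioned TSV tables (census, infection edges,
phylogeny), Newick trees, and YAML config/provenance records that
suffice to regenerate both trajectories bit-identically.

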