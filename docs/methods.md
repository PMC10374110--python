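# Methods

`chronopath` studies the ecological risk posed by "time-travelling"
pathogens — pathogens sampled from the recorded past of a coevolved
community and re-introduced into that same community's future — using a
reduced digital host–pathogen coevolution model and a paired-futures
(counterfactual replay) experimental design. This note documents the
model, its parameters, the analysis conventions, and the places where the
design was genuinely open.

## The world model

The simulator is a deliberately reduced stand-in for an Avida-style
artificial-life system. It keeps the ecological skeleton that the
analyses depend on — task-based merit, resource-mediated environmental
feedback, task-matching infection, propagule transmission, and
genotype-level phylogenies — while replacing instruction-level genomes
with a 9-bit task vector.

**Organisms and genotypes.** Sessile hosts occupy at most one cell of a
toroidal grid; each host can carry at most one pathogen. A genotype is a
9-bit vector over the nine logic tasks (NOT, NAND, AND, ORN, OR, ANDN,
NOR, XOR, EQU) with complexity weights (1, 1, 2, 2, 3, 3, 4, 4, 5).
Every mutated offspring founds a new genotype, recorded in a phylogeny
with its parent, birth update, and mutation count; a distinct genotype is
treated as a distinct species. Host and pathogen lifestyles are separate
forests and never interconvert.

**Resources.** Nine resource pools receive a uniformly random inflow
each update (per-resource upper bounds drawn per world; between 2 and 9
resources receive any external inflow at all) and lose a uniformly random
fraction (up to 10%) per update. Each task consumes its own resource
(the task→resource map is a per-world random permutation) and excretes a
by-product into a randomly assigned resource at a per-world ratio drawn
from [0, 0.5], wiring a random biochemical network: a task with no
external inflow can still be rewarded if upstream tasks feed it.

**Scheduling and merit.** Each update a global CPU budget of 30 cycles ×
(living organisms) is divided among hosts in proportion to merit, where
merit = 2^(Σ weights of tasks performed this update) and a task is
performed when its resource pool is non-empty. Pathogens own no merit;
an infected host forfeits a fixed fraction (default 0.5) of its
allocation to its pathogen. Organisms accumulate CPU and replicate on
crossing a cost threshold.

**Replication.** All hosts over threshold replicate synchronously within
an update; each offspring is placed in a uniformly chosen Moore
neighbour, overwriting any occupant (whose pathogen dies with it); when
two offspring claim one cell in the same update, the first claimant wins.
Pathogens over threshold emit a brood of propagules to uniformly random
cells; a propagule survives only if its cell holds a susceptible,
uninfected host. Infection requires task overlap: the pathogen must
perform at least one task its host performs. Each task bit flips
independently with probability 0.002 per replication (drawn as a
conditional binomial, exactly equivalent to nine independent coin
flips). Leftover CPU after replication is capped at one replication
cost, bounding reproduction at one brood per organism per update. Hosts
die only by overwrite; a pathogen dies with its host or after a fixed
number of broods.

**Bootstrapping.** A run starts from a single task-less host ancestor
seeded into 10% of cells. The pathogen ancestor (performing NOT and
NAND) is registered at time zero but enters the grid at 1% of the run
length — retried each update until at least one susceptible host has
evolved — infecting up to 5% of cells.

### Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `cpu_per_org` | 30 | cycles/organism/update | the conventional update definition |
| `host_repl_cost` | 150 | cycles | host generation time of ~5 updates at baseline merit |
| `path_repl_cost` | 40 | cycles | pathogens replicate several-fold faster than hosts, as viruses do |
| `theft_fraction` | 0.5 | — | substantial but survivable virulence; unspecified by the underlying biology, exposed as a knob |
| `host_mut_rate`, `path_mut_rate` | 0.002 | flips/bit/replication | ~1.8% of offspring mutate; sustains standing variation without mutational meltdown |
| `propagules_per_rep` | 3 | propagules/brood | keeps pathogen R₀ above 1 in susceptible communities at desk scale |
| `path_max_reps` | 30 | broods | prevents immortal pathogens on long-lived hosts |
| `injection_fraction` | 0.05 | — | invasion propagule pressure (5% of cells) |
| `byproduct_ratio` | U[0, 0.5] | — | the by-product biochemistry range |
| scale | 0.04 | — | shrinks world area, run length and every window 25-fold |

Replication costs, propagule number, theft fraction, pathogen lifespan
and the ancestors' task sets have no counterpart measurement to copy;
they were chosen once so that a scaled run exhibits the qualitative
regime the analyses presume — hosts evolve complex tasks under infection
pressure, pathogens persist to the manipulation update in roughly
two-thirds of worlds (with genuine extinctions in the rest), and both
communities maintain tens of coexisting genotypes — and are exposed in
`SimConfig` rather than asserted as faithful to any particular system.

### Scaling

A single `scale` factor multiplies the world-size range (2,500–15,000
cells at scale 1), the run length (250,000 updates), and every protocol
window. The package default for experiments, tests and the acceptance
script is scale 0.04: 10,000-update runs on 100–600-cell worlds, with
the invader sourced from [2,000, 6,000], the manipulation in
[6,000, 8,000], a 2,000-update persistence horizon, and a 100-update
diversity window at 4-update resolution. These sizes are the package's
standard desk-scale operating point; campaign statistics at this scale
are qualitative analogues, not reproductions, of full-scale results.

## The paired-futures protocol

Each experiment is a pair of runs sharing one seed. The control runs to
the horizon T. The treated run re-runs from the same seed — consuming
the identical RNG stream, hence bit-identical snapshots — until the
manipulation update t_m (drawn uniformly from [0.6T, 0.8T], snapped to
the snapshot grid), then:

- **time_travel** — a pathogen genotype sampled from a past snapshot
  (snapshot uniform over [0.2T, 0.6T]; genotype abundance-weighted) is
  injected into 5% of cells; it establishes only in cells holding a
  susceptible, uninfected host, and never displaces a resident
  infection.
- **contemporary** — an extant pathogen sampled at t_m is injected the
  same way, controlling for the density shock of injection itself.
- **control_control** — the treated run simply switches to a fresh RNG
  stream: two alternative futures of the same community, the null for
  change magnitudes.

Injection consumes a dedicated RNG stream, so post-manipulation
divergence is attributable to the manipulation alone. The invader's
whole lineage (itself and every descendant genotype) is required to be
extinct at t_m; at desk scale this must be enforced by resampling (up to
200 tries), and a pair with no such invader is flagged and excluded.
Pairs whose pathogens are globally extinct before t_m are excluded
(`pathogen_extinct_pre_invasion`), mirroring the exclusion of
pathogen-extinct simulations from campaign analyses.

Snapshots are recorded every 1,000 × scale updates throughout and every
100 × scale updates for a 10,000 × scale span after the manipulation.

## Outcome metrics and conventions

**Lineage membership.** A lineage is its root genotype plus every
descendant born at or after t_m; descendants that split off earlier
count as lineage roots in their own right. Applied identically to the
invader and to natives, so the size-matched comparison is fair.

**Persistence** is measured on the recorded cadence with the last-seen
convention — a lineage present at snapshot s and absent at the next is
credited through s — capped at 0.2T (the minimum post-manipulation span,
50,000 updates at full scale). Native lineages are the pathogen
genotypes extant in the treated community at t_m. The per-pair summary
is the fraction of natives, restricted to those at least as abundant as
the invader at t_m, whose persistence is strictly below the invader's;
pairs with no qualifying native are dropped from that statistic.

**Excess persistence.** Whether the number of invaders persisting to
the cap exceeds expectation is an exact upper-tail binomial probability
P(X ≥ k), summed in log space. The baseline success probability q
defaults to the campaign-wide fraction of native lineages reaching the
cap; the alternative reading (the invader share of pathogen individuals
at t_m) can be passed instead — the two interpretations differ in the
published record and neither is asserted here.

**Diversity** is computed on free-living organisms only: richness,
abundance, Shannon H′ = −Σ pᵢ ln pᵢ (natural log; the base is a
convention choice), Pielou evenness H′/ln S, and Faith's PD (sum of
branch lengths of the minimal subtree spanning the extant genotypes and
the root). Phylogeny branch lengths default to mutation counts, with
update-time lengths as an option; neither unit is claimed canonical.

**Relative change** over a window W after t_m (default 0.01T) is
100 × (A_control − A_treated) / A_control, where A is the trapezoid AUC
of the metric on the recorded grid; positive = loss in the treated
community. The trapezoid rule is a choice — only the grid resolution is
inherent. Window sensitivity re-runs the statistic over 0.2×–2× the
standard window. Control-control pairs designate the reference
trajectory a priori (the control stream), so the sign of their changes
is well-defined noise.

**Feature screen.** 21 predictors per included pair (world size, mean
resource inflow, resources with inflow, host/pathogen richness,
abundance and density at t_m, invader pre-invasion lineage persistence,
mean/total/source abundance, task count, maximum task complexity, source
and post-invasion generalism, mean phylogenetic distance to natives, the
sampling lag, invader age, community age) against persistence and
signed/absolute change, with Spearman rank correlations and no
multiple-testing correction — the screen is descriptive, not
confirmatory. "Net available resources" is operationalized as mean
total inflow per update (no formula exists to copy); density is
individuals per cell over the whole grid. High-loss and high-gain
subgroups (|signed change| > 5%) are compared with a two-sided rank-sum
test, exact by enumeration for untied pooled samples of ≤ 12, otherwise
the tie-corrected normal approximation without continuity correction.

**Prediction.** Random-forest regression (1,000 trees, one-third of
features per split, leaf size 5) for persistence from the 17-feature
subset (dropping the three environmental variables and post-invasion
generalism), and for signed/absolute change from those features plus
persistence. Performance is out-of-bag explained variance. Importance
is the percent increase in in-sample MSE under feature permutation
(5 repeats); this is a deliberate simplification of the per-tree
out-of-bag permutation scheme and is used for ranking, not inference.

**Generations equivalence.** Updates are anchored to microbial time by
a Fermi estimate: ~400 substitutions along the focal parasite lineage
per 250,000-update run, one digital substitution equated to one E. coli
substitution, and 1–2 × 10⁻⁴ substitutions per generation, giving
≈ 2–4 million generations per full run and 0.4–2.4 million for the
invader-sourcing window. `observed_subs_per_run` recomputes the
substitution count empirically from a trajectory's phylogeny.

## Numerical and degenerate-case choices

- Merit allocation is continuous (no integer cycle quantization); ties
  in placement are broken by draw order, which is itself seeded.
- A task is "performed" when its pool is positive; consumption is capped
  by the pool, so pools never go negative and excretion never exceeds
  ratio × consumption.
- Rank correlation on a constant vector, persistence of an unknown
  genotype, sampling from a pathogen-free window, and a
  population-matched comparison with no qualifying native all raise
  typed errors rather than returning sentinels.
- Shannon on a single genotype is 0; evenness is defined as 0 for S = 1.
- Binomial tails smaller than the smallest positive float are available
  in log space.
- World sizes are drawn as near-square rows × columns factorizations
  kept inside the scaled size range.

## What the generator does and does not emulate

The synthetic worlds reproduce the statistical structure the analysis
layer assumes: paired bit-identical histories, genotype-level phylogenies
with mutation-count branch lengths, task-matching infection networks,
resource-mediated environmental heterogeneity across worlds, and
invasion outcomes spanning instant failure to community takeover. They
do not emulate instruction-level genomes (so genotype space is far
smaller than Avida's and "species" turnover is correspondingly coarser),
plasticity, multi-infection, sexual recombination, or the sheer scale of
thousand-run campaigns. Passing tests therefore demonstrate that the
protocol and metrics are implemented correctly and behave sensibly on
communities with the right structure — not that any particular
full-scale statistic would be reproduced.

## Known limitations

- At desk scale, stochastic divergence between replicate futures is
  relatively larger than at full scale; the control-control null is
  wide, and individual-pair change estimates are noisy.
- The enforced invader-extinction constraint biases invaders toward
  extinct side-branches, i.e. toward low past abundance, more strongly
  than at full scale where turnover is slower relative to the sampling
  gap.
- Host density is nearly always 1 (worlds fill and stay full), so
  host-density features carry little variance at this scale.
- The random forest's OOB explained variance on a few dozen rows is
  volatile; the acceptance script reports whatever the campaign yields,
  which can be negative.
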