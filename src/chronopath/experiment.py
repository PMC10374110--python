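"""Paired-futures experiment engine.

Every experiment is a pair of runs sharing one seed: a control run to the
full horizon, and a treated run that replays the identical eco-evolutionary
history up to a manipulation update and then diverges.  Because replay is
by re-running from the seed with an identically consumed RNG stream, every
recorded snapshot strictly before the manipulation is bit-identical across
the pair, so any post-manipulation difference is attributable to the
manipulation alone.  Three manipulation kinds are supported:

``time_travel``
    inject a pathogen genotype sampled (abundance-weighted) from a past
    snapshot of the same community, required to have a fully extinct
    lineage at the time of injection;
``contemporary``
    inject an extant pathogen sampled at the manipulation update,
    controlling for the density shock of injection itself;
``control_control``
    swap to a fresh RNG stream and continue - two alternative futures of
    the same community, the null for diversity-change magnitude.

The injection consumes a dedicated RNG stream so the main stream's replay
is untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyWindowError
from .world import (
    HOST,
    MANIPULATE_WINDOW,
    SAMPLE_WINDOW,
    CommunityTrajectory,
    GenotypeRecord,
    SimConfig,
    WorldState,
    build_config,
    default_schedule,
    run,
    sample_invader,
)

KINDS = ("time_travel", "control_control", "contemporary")

#: attempts at finding a past pathogen whose lineage is extinct at the
#: manipulation update before the pair is flagged and excluded
MAX_INVADER_TRIES = 200


@dataclass
class ExperimentPair:
    """A control/treated pair of trajectories sharing one seed."""

    config: SimConfig
    seed: int
    kind: str
    t_sample: int | None
    t_manipulate: int
    invader: GenotypeRecord | None
    invader_provenance: dict | None
    control: CommunityTrajectory
    treated: CommunityTrajectory | None
    reference: str = "control"          # designated a priori
    included: bool = True
    exclusion_reason: str | None = None

    @property
    def cap(self) -> int:
        """Persistence horizon: one fifth of the run (50,000 at full scale)."""
        from .world import PERSISTENCE_CAP_FRAC
        return int(round(self.config.T * PERSISTENCE_CAP_FRAC))

    @property
    def change_window(self) -> int:
        """Diversity-comparison window: 1% of the run (2,500 full scale)."""
        from .world import CHANGE_WINDOW_FRAC
        return max(self.config.fine_cadence,
                   int(round(self.config.T * CHANGE_WINDOW_FRAC)))


@dataclass
class CampaignResult:
    """All pairs of a campaign plus the extinction-exclusion bookkeeping."""

    kind: str
    master_seed: int
    pairs: list[ExperimentPair] = field(default_factory=list)

    @property
    def included(self) -> list[ExperimentPair]:
        return [p for p in self.pairs if p.included]

    @property
    def excluded(self) -> list[ExperimentPair]:
        return [p for p in self.pairs if not p.included]

    def exclusion_reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.excluded:
            out[p.exclusion_reason] = out.get(p.exclusion_reason, 0) + 1
        return out


# ---------------------------------------------------------------------------
# Scheduling and injection
# ---------------------------------------------------------------------------


def schedule_times(config: SimConfig, rng: np.random.Generator) -> tuple[int, int]:
    """Draw the invader-sourcing and manipulation updates.

    ``t_sample`` is uniform on [0.2T, 0.6T] and ``t_manipulate`` uniform on
    [0.6T, 0.8T] (the full-scale 50,000-150,000 and 150,000-200,000 update
    windows), both snapped to the coarse snapshot grid; the ordering
    ``t_sample < t_manipulate`` is guaranteed by the disjoint windows.
    """
    T = config.T
    c = config.coarse_cadence

    def pick(lo_frac: float, hi_frac: float) -> int:
        lo = math.ceil(lo_frac * T / c)
        hi = math.floor(hi_frac * T / c)
        return int(rng.integers(lo, hi + 1)) * c

    t_sample = pick(*SAMPLE_WINDOW)
    t_manipulate = pick(*MANIPULATE_WINDOW)
    if t_sample >= t_manipulate:  # only possible in degenerate tiny runs
        t_manipulate = t_sample + c
    return t_sample, t_manipulate


def inject(world: WorldState, genotype: GenotypeRecord, fraction: float,
           rng: np.random.Generator) -> int:
    """Inject a pathogen genotype into a fraction of the world's cells.

    ``ceil(fraction * n_cells)`` distinct cells are chosen uniformly; in
    each, the resident host becomes infected by a new instance of the
    genotype iff the cell holds a host that is susceptible and uninfected;
    otherwise that propagule dies.  Existing infections are never
    displaced.  Returns the number of individuals established.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if genotype.kind == HOST:
        raise ValueError("only pathogen genotypes can be injected")
    gid = genotype.id
    if gid >= world.phylo.n or tuple(int(b) for b in world.phylo.bits[gid]) != tuple(genotype.tasks):
        raise ValueError("genotype is not registered in this world's phylogeny")
    n = world.config.n_cells
    k = min(n, math.ceil(fraction * n))
    cells = rng.choice(n, size=k, replace=False)
    gmask = int(world.phylo.mask[gid])
    placed = 0
    for cell in cells:
        cell = int(cell)
        hg = world.host_gid[cell]
        if hg < 0 or world.path_gid[cell] >= 0:
            continue
        if not gmask & int(world.phylo.mask[hg]):
            continue  # resistant host
        world.place_pathogen(cell, gid)
        placed += 1
    return placed


def lineage_extinct_at(trajectory: CommunityTrajectory, gid: int, update: int) -> bool:
    """True iff the genotype and every genotype descended from it are
    absent from the census at ``update`` (complete phylogenetic
    separation between a would-be invader and the recipient community)."""
    i = trajectory.index_of(update)
    alive = set(int(g) for g in trajectory.path_ids[i])
    alive |= set(int(g) for g in trajectory.host_ids[i])
    if gid in alive:
        return False
    return not any(int(d) in alive for d in trajectory.phylogeny.descendants(gid))


# ---------------------------------------------------------------------------
# Pairs
# ---------------------------------------------------------------------------


def _sample_extinct_invader(control: CommunityTrajectory,
                            t_sample: int, t_manipulate: int,
                            rng: np.random.Generator):
    """Find a past pathogen whose whole lineage is extinct at the
    manipulation update.  The scheduled ``t_sample`` snapshot is tried
    first; further tries resample both the snapshot (uniform over the
    sourcing window) and the genotype.  Returns (record, provenance) or
    None after ``MAX_INVADER_TRIES`` failures."""
    T = control.config.T
    window_all = (int(SAMPLE_WINDOW[0] * T), int(SAMPLE_WINDOW[1] * T))
    for attempt in range(MAX_INVADER_TRIES):
        window = (t_sample, t_sample) if attempt == 0 else window_all
        try:
            rec, prov = sample_invader(control, window, rng)
        except EmptyWindowError:
            if attempt == 0:
                continue
            return None
        if lineage_extinct_at(control, rec.id, t_manipulate):
            return rec, prov
    return None


def run_pair(config: SimConfig, seed: int, kind: str) -> ExperimentPair:
    """Run one control/treated pair.

    The control run goes to the full horizon first; pairs whose pathogens
    are globally extinct at the manipulation update are flagged excluded
    and their treated run is skipped (nothing to inject into or compare).
    All randomness derives from ``seed``: a stream for the protocol times,
    the shared replayed run stream, and a dedicated injection stream.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}")
    ss = np.random.SeedSequence([int(seed), abs(int(config.seed)) % (2**31)])
    s_times, s_run, s_inject, s_swap = ss.spawn(4)
    run_seed = int(s_run.generate_state(1)[0] % (2**31))

    rng_times = np.random.default_rng(s_times)
    t_sample, t_manipulate = schedule_times(config, rng_times)
    schedule = default_schedule(config, t_manipulate)

    control = run(config, schedule=schedule, seed=run_seed)

    pair = ExperimentPair(
        config=config, seed=seed, kind=kind,
        t_sample=None if kind == "control_control" else t_sample,
        t_manipulate=t_manipulate,
        invader=None, invader_provenance=None,
        control=control, treated=None,
    )

    if not control.pathogens_alive_at(t_manipulate):
        pair.included = False
        pair.exclusion_reason = "pathogen_extinct_pre_invasion"
        return pair

    rng_inject = np.random.default_rng(s_inject)

    if kind == "time_travel":
        found = _sample_extinct_invader(control, t_sample, t_manipulate, rng_inject)
        if found is None:
            pair.included = False
            pair.exclusion_reason = "no_extinct_invader"
            return pair
        rec, prov = found
        pair.t_sample = prov["update"]
        pair.invader, pair.invader_provenance = rec, prov

        def manipulate(world: WorldState) -> None:
            prov["n_injected"] = inject(world, rec, config.injection_fraction,
                                        rng_inject)

    elif kind == "contemporary":
        captured: dict = {}

        def manipulate(world: WorldState) -> None:
            ng = world.phylo.n
            alive = np.flatnonzero(world.path_abund[:ng])
            counts = world.path_abund[alive].astype(np.float64)
            gid = int(rng_inject.choice(alive, p=counts / counts.sum()))
            rec = world.phylo.record(gid)
            captured["record"] = rec
            captured["provenance"] = {
                "update": t_manipulate,
                "abundance": int(world.path_abund[gid]),
            }
            captured["provenance"]["n_injected"] = inject(
                world, rec, config.injection_fraction, rng_inject)

    else:  # control_control: swap to a fresh stream, nothing injected
        swap_seed = int(s_swap.generate_state(1)[0] % (2**31))

        def manipulate(world: WorldState) -> None:
            world.rng = np.random.default_rng(swap_seed)

    pair.treated = run(config, schedule=schedule, seed=run_seed,
                       manipulation=(t_manipulate, manipulate))
    if kind == "contemporary":
        pair.invader = captured["record"]
        pair.invader_provenance = captured["provenance"]
    return pair


def run_campaign(n_configs: int,
                 replicates_per_config: int,
                 kind: str,
                 master_seed: int,
                 scale: float = 0.04,
                 progress: bool = False,
                 **config_overrides) -> CampaignResult:
    """Run a campaign of paired experiments.

    ``n_configs`` seeded worlds are drawn (random size, random
    biochemistry) and each is run ``replicates_per_config`` times with
    distinct pair seeds, mirroring the replicate structure of a
    multi-world invasion campaign.  All seeds derive from ``master_seed``;
    identical arguments give an identical campaign.
    """
    if n_configs <= 0 or replicates_per_config <= 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(master_seed)
    config_seeds = rng.integers(0, 2**31, n_configs)
    pair_seeds = rng.integers(0, 2**31, (n_configs, replicates_per_config))
    result = CampaignResult(kind=kind, master_seed=master_seed)
    for i in range(n_configs):
        config = build_config(int(config_seeds[i]), scale=scale, **config_overrides)
        for j in range(replicates_per_config):
            pair = run_pair(config, int(pair_seeds[i, j]), kind)
            result.pairs.append(pair)
            if progress:
                status = "ok" if pair.included else pair.exclusion_reason
                print(f"[campaign {kind}] config {i+1}/{n_configs} "
                      f"rep {j+1}/{replicates_per_config}: {status}", flush=True)
    return result
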