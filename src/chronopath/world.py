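"""Reduced digital host-pathogen coevolution world.

A desk-scale stand-in for an Avida-style artificial-life system.  Sessile
free-living "hosts" occupy a toroidal grid and are rewarded with CPU cycles
for performing any of nine logic tasks (NOT ... EQU) on limited, randomly
inflowing resources; performing a task excretes a by-product resource at a
configurable ratio, wiring a small biochemical network.  Pathogens cannot
use resources directly: they live on hosts (at most one per host), steal a
fraction of the host's CPU allocation, and transmit via propagules thrown
at uniformly random grid cells, surviving only when the target cell holds a
susceptible, uninfected host.  Infection requires task overlap: the
pathogen must perform at least one task its host performs, so hosts can
evolve resistance by changing task repertoire and pathogens can broaden
their host range by acquiring popular tasks.

Genomes are reduced to a 9-bit task vector; each replication flips every
bit independently with a small probability, and every mutated offspring is
registered as a new genotype ("species") in a birth-ordered phylogeny.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptyWindowError, WorldCorruptionError

# ---------------------------------------------------------------------------
# Tasks
# ---------------------------------------------------------------------------

#: The canonical nine logic tasks, in fixed bit order.
TASK_NAMES = ("NOT", "NAND", "AND", "ORN", "OR", "ANDN", "NOR", "XOR", "EQU")

#: Complexity weight of each task (minimum building blocks needed); merit
#: reward is multiplicative in 2**weight, the standard reward ladder.
TASK_COMPLEXITY = np.array([1, 1, 2, 2, 3, 3, 4, 4, 5], dtype=np.float64)

N_TASKS = 9

HOST = 0
PATHOGEN = 1

_TASK_INDEX = {name: i for i, name in enumerate(TASK_NAMES)}


def taskset(*names: str) -> np.ndarray:
    """Build a 9-element 0/1 task vector from task names.

    >>> taskset("NOT", "AND")
    array([1, 0, 1, 0, 0, 0, 0, 0, 0], dtype=uint8)
    """
    bits = np.zeros(N_TASKS, dtype=np.uint8)
    for name in names:
        bits[_TASK_INDEX[name.upper()]] = 1
    return bits


def task_names(bits: np.ndarray) -> tuple[str, ...]:
    """Names of the tasks switched on in a task vector."""
    return tuple(TASK_NAMES[i] for i in np.flatnonzero(np.asarray(bits)))


def can_infect(pathogen_tasks: np.ndarray, host_tasks: np.ndarray) -> bool:
    """Task-matching infection rule: a pathogen can infect a host iff it
    performs at least one task the host performs (non-empty intersection
    of the two task sets).  A task-less pathogen infects nothing; a
    task-less host is resistant to everything."""
    p = np.asarray(pathogen_tasks)
    h = np.asarray(host_tasks)
    if p.shape != (N_TASKS,) or h.shape != (N_TASKS,):
        raise ValueError("task vectors must have exactly 9 positions")
    return bool(np.any((p != 0) & (h != 0)))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

# Full-scale protocol constants; a single ``scale`` factor shrinks all of
# them proportionally (world area, run length, every window).
FULL_T = 250_000
FULL_CELLS_MIN = 2_500
FULL_CELLS_MAX = 15_000
FULL_FINE_CADENCE = 100   # snapshot every 100 updates near the manipulation
COARSE_FACTOR = 10        # coarse cadence = 10 x fine

# Fractions of the run length defining the invasion protocol.
SAMPLE_WINDOW = (0.2, 0.6)       # invader sourced from [0.2T, 0.6T]
MANIPULATE_WINDOW = (0.6, 0.8)   # manipulation applied in [0.6T, 0.8T]
PERSISTENCE_CAP_FRAC = 0.2       # persistence capped at 0.2T (50,000 full scale)
CHANGE_WINDOW_FRAC = 0.01        # diversity window 0.01T (2,500 full scale)


@dataclass
class SimConfig:
    """Full parameterization of one world.

    ``build_config`` draws the stochastic parts (world size, biochemistry)
    from a seeded RNG; everything else holds field defaults unless
    overridden.  All updates are 0-based; cells are 0-based row-major.
    """

    seed: int
    n_rows: int
    n_cols: int
    total_updates: int
    scale: float = 1.0

    # scheduler
    cpu_per_org: float = 30.0           # mean CPU cycles per organism per update
    host_repl_cost: float = 150.0       # cycles to produce one host offspring
    path_repl_cost: float = 40.0        # cycles to produce one pathogen brood
    theft_fraction: float = 0.5         # share of host cycles taken by its pathogen

    # mutation (per task bit, per replication)
    host_mut_rate: float = 0.002
    path_mut_rate: float = 0.002

    # pathogen life history
    propagules_per_rep: int = 3
    path_max_reps: int = 30             # pathogen dies after this many replications
    path_intro_update: int = 0
    path_intro_fraction: float = 0.05

    # invasion protocol
    injection_fraction: float = 0.05

    # founders
    host_ancestor_tasks: tuple[int, ...] = (0,) * N_TASKS
    path_ancestor_tasks: tuple[int, ...] = (1, 1, 0, 0, 0, 0, 0, 0, 0)
    host_init_fraction: float = 0.1

    # resources / biochemistry
    task_resource: tuple[int, ...] = tuple(range(N_TASKS))
    byproduct_resource: tuple[int, ...] = tuple(range(N_TASKS))
    byproduct_ratio: tuple[float, ...] = (0.25,) * N_TASKS
    inflow_high: tuple[float, ...] = (10.0,) * N_TASKS
    outflow_high: float = 0.1           # max fraction of each pool drained per update
    consume_per_task: float = 1.0

    # recording
    fine_cadence: int = FULL_FINE_CADENCE
    coarse_cadence: int = FULL_FINE_CADENCE * COARSE_FACTOR

    def __post_init__(self) -> None:
        for name in ("theft_fraction", "host_mut_rate", "path_mut_rate",
                     "path_intro_fraction", "host_init_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.injection_fraction < 1.0:
            raise ValueError("injection_fraction must be in (0, 1)")
        if self.total_updates <= 0:
            raise ValueError("total_updates must be positive")
        if sorted(self.task_resource) != list(range(N_TASKS)):
            raise ValueError("task_resource must be a permutation of the 9 resources")
        if any(not 0.0 <= r <= 0.5 for r in self.byproduct_ratio):
            raise ValueError("by-product ratios must lie in [0, 0.5]")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def T(self) -> int:
        return self.total_updates

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def build_config(master_seed: int, scale: float = 1.0, **overrides) -> SimConfig:
    """Draw a seeded world configuration.

    World area is uniform on the (scaled) [2500, 15000]-cell range; the
    task->resource map is a random permutation; each task excretes into a
    random resource at a ratio uniform on [0, 0.5]; between 2 and 9
    resources receive external inflow (the rest are available only as
    by-products), spanning worlds with few scarce resources to many
    abundant ones.  Identical ``(master_seed, scale)`` give identical
    configs.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(master_seed)

    lo = max(4, int(round(FULL_CELLS_MIN * scale)))
    hi = max(lo + 1, int(round(FULL_CELLS_MAX * scale)))
    while True:  # factor into a near-square grid without leaving the range
        n = int(rng.integers(lo, hi + 1))
        rows = max(2, math.isqrt(n))
        cols = max(2, n // rows)
        if lo <= rows * cols <= hi:
            break

    total = max(10, int(round(FULL_T * scale)))
    fine = max(1, int(round(FULL_FINE_CADENCE * scale)))
    coarse = fine * COARSE_FACTOR

    task_resource = tuple(int(x) for x in rng.permutation(N_TASKS))
    byproduct_resource = tuple(int(x) for x in rng.integers(0, N_TASKS, N_TASKS))
    byproduct_ratio = tuple(float(x) for x in rng.uniform(0.0, 0.5, N_TASKS))

    n_active = int(rng.integers(2, N_TASKS + 1))
    active = rng.choice(N_TASKS, size=n_active, replace=False)
    inflow = np.zeros(N_TASKS)
    inflow[active] = rng.uniform(1.0, 20.0, n_active)

    cfg = SimConfig(
        seed=int(master_seed),
        n_rows=rows,
        n_cols=cols,
        total_updates=total,
        scale=scale,
        path_intro_update=max(1, int(round(total * 0.01))),
        task_resource=task_resource,
        byproduct_resource=byproduct_resource,
        byproduct_ratio=byproduct_ratio,
        inflow_high=tuple(float(x) for x in inflow),
        fine_cadence=fine,
        coarse_cadence=coarse,
        **overrides,
    )
    return cfg


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeRecord:
    """One node of the genotype phylogeny; a distinct genotype is a
    distinct species.  ``parent_id`` is ``None`` for the two ancestors."""

    id: int
    parent_id: int | None
    kind: int                      # HOST or PATHOGEN
    tasks: tuple[int, ...]         # 9-element 0/1 vector
    birth_update: int
    mutations_from_parent: int

    @property
    def task_count(self) -> int:
        return int(sum(self.tasks))


class Phylogeny:
    """Birth-ordered genotype forest stored in flat, growable arrays.

    Rooted at (at most) two ancestors, one host and one pathogen; every
    other genotype points at the genotype whose replication produced it.
    Branch lengths are available either as mutation counts or as
    birth-time differences.
    """

    def __init__(self, capacity: int = 256):
        self._n = 0
        self.parent = np.full(capacity, -1, dtype=np.int64)
        self.kind = np.zeros(capacity, dtype=np.int8)
        self.birth = np.zeros(capacity, dtype=np.int64)
        self.nmut = np.zeros(capacity, dtype=np.int32)
        self.bits = np.zeros((capacity, N_TASKS), dtype=np.uint8)
        self.bits_f = np.zeros((capacity, N_TASKS), dtype=np.float64)
        # packed task bits (bit i set iff task i performed); lets the inner
        # loop test infection compatibility with one integer AND
        self.mask = np.zeros(capacity, dtype=np.int64)

    @property
    def n(self) -> int:
        return self._n

    def __len__(self) -> int:
        return self._n

    def _grow(self) -> None:
        cap = len(self.parent) * 2
        for name in ("parent", "kind", "birth", "nmut", "mask"):
            arr = getattr(self, name)
            new = np.zeros(cap, dtype=arr.dtype)
            if name == "parent":
                new[:] = -1
            new[: self._n] = arr[: self._n]
            setattr(self, name, new)
        for name in ("bits", "bits_f"):
            arr = getattr(self, name)
            new = np.zeros((cap, N_TASKS), dtype=arr.dtype)
            new[: self._n] = arr[: self._n]
            setattr(self, name, new)

    def add(self, parent: int | None, kind: int, birth: int,
            bits: np.ndarray, nmut: int) -> int:
        if parent is not None:
            if not 0 <= parent < self._n:
                raise ValueError(f"unknown parent genotype {parent}")
            if birth < self.birth[parent]:
                raise ValueError("child cannot be born before its parent")
            if self.kind[parent] != kind:
                raise ValueError("lifestyles never interconvert")
        if self._n == len(self.parent):
            self._grow()
        gid = self._n
        self.parent[gid] = -1 if parent is None else parent
        self.kind[gid] = kind
        self.birth[gid] = birth
        self.nmut[gid] = nmut
        self.bits[gid] = bits
        self.bits_f[gid] = bits
        self.mask[gid] = int(np.packbits(self.bits[gid], bitorder="little")[0]) | (
            int(self.bits[gid][8]) << 8)
        self._n += 1
        return gid

    def record(self, gid: int) -> GenotypeRecord:
        if not 0 <= gid < self._n:
            raise KeyError(f"unknown genotype {gid}")
        p = int(self.parent[gid])
        return GenotypeRecord(
            id=gid,
            parent_id=None if p < 0 else p,
            kind=int(self.kind[gid]),
            tasks=tuple(int(b) for b in self.bits[gid]),
            birth_update=int(self.birth[gid]),
            mutations_from_parent=int(self.nmut[gid]),
        )

    def children_lists(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self._n)]
        for g in range(self._n):
            p = self.parent[g]
            if p >= 0:
                out[p].append(g)
        return out

    def descendants(self, root: int, min_birth: int | None = None) -> np.ndarray:
        """All genotypes below ``root`` (excluding it), optionally only
        those born at or after ``min_birth``.  Iterative, so safe on the
        long parent chains a mutation-limited run produces."""
        if not 0 <= root < self._n:
            raise KeyError(f"unknown genotype {root}")
        children = self.children_lists()
        out: list[int] = []
        stack = list(children[root])
        while stack:
            g = stack.pop()
            stack.extend(children[g])
            if min_birth is None or self.birth[g] >= min_birth:
                out.append(g)
        return np.array(sorted(out), dtype=np.int64)

    def root_path(self, gid: int) -> list[int]:
        """Genotypes from ``gid`` up to (and including) its root."""
        if not 0 <= gid < self._n:
            raise KeyError(f"unknown genotype {gid}")
        path = [gid]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def branch_length(self, gid: int, unit: str = "mutations") -> float:
        """Length of the branch above ``gid`` (0 for roots)."""
        p = self.parent[gid]
        if p < 0:
            return 0.0
        if unit == "mutations":
            return float(self.nmut[gid])
        if unit == "updates":
            return float(self.birth[gid] - self.birth[p])
        raise ValueError(f"unknown branch unit {unit!r}")

    def patristic_distance(self, a: int, b: int, unit: str = "mutations") -> float:
        """Path length between two genotypes through their MRCA."""
        pa = self.root_path(a)
        pb = set(self.root_path(b))
        mrca = next(g for g in pa if g in pb)
        dist = 0.0
        g = a
        while g != mrca:
            dist += self.branch_length(g, unit)
            g = int(self.parent[g])
        g = b
        while g != mrca:
            dist += self.branch_length(g, unit)
            g = int(self.parent[g])
        return dist

    def roots(self) -> list[int]:
        return [g for g in range(self._n) if self.parent[g] < 0]


# ---------------------------------------------------------------------------
# Trajectory recording
# ---------------------------------------------------------------------------


@dataclass
class RecorderSchedule:
    """Snapshot cadence: coarse everywhere, fine inside one window.

    Mirrors the recording scheme of paired-invasion experiments: censuses
    every ``fine`` updates for a span after the manipulation, every
    ``coarse`` updates elsewhere.  ``fine_start=0, fine_end=T`` records
    fine throughout.
    """

    fine: int
    coarse: int
    fine_start: int = 0
    fine_end: int | None = None

    def times(self, total: int) -> np.ndarray:
        end = total if self.fine_end is None else min(self.fine_end, total)
        coarse_ticks = np.arange(0, total + 1, self.coarse)
        fine_ticks = np.arange(self.fine_start, end + 1, self.fine)
        ticks = np.union1d(coarse_ticks, fine_ticks)
        ticks = np.union1d(ticks, [0, total])
        return ticks.astype(np.int64)


def default_schedule(config: SimConfig, t_manipulate: int | None = None) -> RecorderSchedule:
    """Fine cadence for a 100-fine-tick span after the manipulation (the
    first 10,000 updates post-invasion at full scale), coarse elsewhere;
    fine throughout when there is no manipulation."""
    if t_manipulate is None:
        return RecorderSchedule(fine=config.fine_cadence, coarse=config.coarse_cadence,
                                fine_start=0, fine_end=None)
    span = config.fine_cadence * 100
    return RecorderSchedule(
        fine=config.fine_cadence,
        coarse=config.coarse_cadence,
        fine_start=t_manipulate,
        fine_end=min(config.T, t_manipulate + span),
    )


@dataclass
class CommunityTrajectory:
    """Recorded history of one run: per-snapshot genotype censuses,
    pathogen->host infection edges, and the full genotype phylogeny."""

    config: SimConfig
    seed: int
    updates: np.ndarray                       # snapshot times, strictly increasing
    host_ids: list[np.ndarray]
    host_counts: list[np.ndarray]
    path_ids: list[np.ndarray]
    path_counts: list[np.ndarray]
    edge_path: list[np.ndarray]
    edge_host: list[np.ndarray]
    edge_count: list[np.ndarray]
    phylogeny: Phylogeny
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.updates)

    def index_of(self, update: int) -> int:
        i = int(np.searchsorted(self.updates, update))
        if i >= len(self.updates) or self.updates[i] != update:
            raise KeyError(f"update {update} is not a recorded snapshot")
        return i

    def snapshot_indices(self, lo: int, hi: int) -> np.ndarray:
        """Indices of snapshots with lo <= update <= hi."""
        return np.flatnonzero((self.updates >= lo) & (self.updates <= hi))

    def pathogens_alive_at(self, update: int) -> bool:
        i = self.index_of(update)
        return len(self.path_ids[i]) > 0

    def snapshot_digest(self, i: int) -> str:
        h = hashlib.sha256()
        for arr in (self.host_ids[i], self.host_counts[i],
                    self.path_ids[i], self.path_counts[i],
                    self.edge_path[i], self.edge_host[i], self.edge_count[i]):
            h.update(np.ascontiguousarray(arr, dtype=np.int64).tobytes())
        return h.hexdigest()

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(self.updates.tobytes())
        for i in range(len(self.updates)):
            h.update(self.snapshot_digest(i).encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# World state
# ---------------------------------------------------------------------------


class _MutationSampler:
    """Per-bit mutation drawn in two stages: one uniform decides whether
    any bit flips (probability 1-(1-mu)^9), and only then the flip count is
    drawn from the conditional binomial and placed on uniformly chosen
    positions.  Exactly equivalent to 9 independent per-bit coin flips, but
    the common no-mutation case costs a single draw."""

    def __init__(self, mu: float):
        self.mu = float(mu)
        k = np.arange(10)
        pmf = np.array([math.comb(9, int(i)) for i in k], dtype=np.float64)
        pmf = pmf * self.mu ** k * (1.0 - self.mu) ** (9 - k)
        self.p_any = float(1.0 - pmf[0])
        if self.p_any > 0:
            cond = pmf[1:] / pmf[1:].sum()
            self._cum = np.cumsum(cond)
        else:
            self._cum = np.ones(9)

    def flips(self, rng: np.random.Generator) -> np.ndarray:
        """Flip pattern conditioned on at least one flip (uint8[9])."""
        k = int(np.searchsorted(self._cum, rng.random())) + 1
        out = np.zeros(N_TASKS, dtype=np.uint8)
        out[rng.choice(N_TASKS, size=k, replace=False)] = 1
        return out


def _neighbor_table(rows: int, cols: int) -> np.ndarray:
    """Moore (8-cell) neighbourhood on a torus, row-major indexing."""
    n = rows * cols
    r, c = np.divmod(np.arange(n), cols)
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    nbr = np.empty((n, 8), dtype=np.int64)
    for k, (dr, dc) in enumerate(offsets):
        nbr[:, k] = ((r + dr) % rows) * cols + (c + dc) % cols
    return nbr


class WorldState:
    """Mutable simulation state: grid occupancy, per-organism CPU
    accumulators, resource pools, the RNG, and the genotype phylogeny.

    The array representation makes two invariants structural: a cell holds
    at most one host (one slot per cell) and a host carries at most one
    pathogen (one pathogen slot per cell, only meaningful where a host
    sits).  ``audit`` re-derives everything else from scratch.
    """

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        n = config.n_cells
        self.config = config
        self.rng = rng
        self.update = 0
        self.host_gid = np.full(n, -1, dtype=np.int64)
        self.host_cpu = np.zeros(n, dtype=np.float64)
        self.path_gid = np.full(n, -1, dtype=np.int64)
        self.path_cpu = np.zeros(n, dtype=np.float64)
        self.path_reps = np.zeros(n, dtype=np.int32)
        self.nbr = _neighbor_table(config.n_rows, config.n_cols)
        self.pools = np.array(config.inflow_high, dtype=np.float64) * 2.0
        self.phylo = Phylogeny()
        cap = 256
        self.host_abund = np.zeros(cap, dtype=np.int64)
        self.path_abund = np.zeros(cap, dtype=np.int64)
        self.n_hosts = 0
        self.n_paths = 0
        self.path_introduced = False
        self.total_inflow = 0.0
        self._task_res = np.array(config.task_resource, dtype=np.int64)
        self._byp_res = np.array(config.byproduct_resource, dtype=np.int64)
        self._byp_ratio = np.array(config.byproduct_ratio, dtype=np.float64)
        self._inflow_high = np.array(config.inflow_high, dtype=np.float64)
        self._last_consumed = np.zeros(N_TASKS)
        self._last_excreted = np.zeros(N_TASKS)
        self._host_mut = _MutationSampler(config.host_mut_rate)
        self._path_mut = _MutationSampler(config.path_mut_rate)

    # -- bookkeeping ------------------------------------------------------

    def _ensure_abund_capacity(self) -> None:
        need = self.phylo.n
        if need > len(self.host_abund):
            cap = max(need, len(self.host_abund) * 2)
            for name in ("host_abund", "path_abund"):
                arr = getattr(self, name)
                new = np.zeros(cap, dtype=arr.dtype)
                new[: len(arr)] = arr
                setattr(self, name, new)

    def register_genotype(self, parent: int | None, kind: int,
                          bits: np.ndarray, nmut: int) -> int:
        gid = self.phylo.add(parent, kind, self.update, bits, nmut)
        self._ensure_abund_capacity()
        return gid

    def kill_pathogen(self, cell: int) -> None:
        g = self.path_gid[cell]
        if g >= 0:
            self.path_abund[g] -= 1
            self.n_paths -= 1
            self.path_gid[cell] = -1
            self.path_cpu[cell] = 0.0
            self.path_reps[cell] = 0

    def place_host(self, cell: int, gid: int, cpu: float = 0.0) -> None:
        """Put a host into a cell, overwriting any occupant (and killing
        the occupant's pathogen, which dies with its host)."""
        old = self.host_gid[cell]
        if old >= 0:
            self.kill_pathogen(cell)
            self.host_abund[old] -= 1
        else:
            self.n_hosts += 1
        self.host_gid[cell] = gid
        self.host_cpu[cell] = cpu
        self.host_abund[gid] += 1

    def place_pathogen(self, cell: int, gid: int) -> None:
        if self.host_gid[cell] < 0 or self.path_gid[cell] >= 0:
            raise WorldCorruptionError("pathogen placed on empty or infected cell")
        self.path_gid[cell] = gid
        self.path_cpu[cell] = 0.0
        self.path_reps[cell] = 0
        self.path_abund[gid] += 1
        self.n_paths += 1

    # -- audits -----------------------------------------------------------

    def audit(self) -> None:
        """Full invariant audit; raises WorldCorruptionError on failure."""
        ng = self.phylo.n
        occ = self.host_gid >= 0
        if int(occ.sum()) != self.n_hosts:
            raise WorldCorruptionError("host count out of sync with grid")
        inf = self.path_gid >= 0
        if int(inf.sum()) != self.n_paths:
            raise WorldCorruptionError("pathogen count out of sync with grid")
        if np.any(inf & ~occ):
            raise WorldCorruptionError("pathogen on an empty cell")
        hcount = np.bincount(self.host_gid[occ], minlength=ng)
        if not np.array_equal(hcount, self.host_abund[:ng]):
            raise WorldCorruptionError("host abundance ledger mismatch")
        pcount = np.bincount(self.path_gid[inf], minlength=ng)
        if not np.array_equal(pcount, self.path_abund[:ng]):
            raise WorldCorruptionError("pathogen abundance ledger mismatch")
        if np.any(self.host_gid[occ] >= ng) or np.any(self.path_gid[inf] >= ng):
            raise WorldCorruptionError("orphan genotype on the grid")
        if np.any(self.pools < -1e-9):
            raise WorldCorruptionError("negative resource pool")
        if np.any(self._last_excreted > self._byp_ratio * self._last_consumed + 1e-9):
            raise WorldCorruptionError("by-product excretion exceeds ratio bound")
        cells = np.flatnonzero(inf)
        if len(cells):
            overlap = self.phylo.mask[self.path_gid[cells]] \
                & self.phylo.mask[self.host_gid[cells]]
            if np.any(overlap == 0):
                raise WorldCorruptionError("infection without task overlap")

    # -- census -----------------------------------------------------------

    def census(self):
        ng = self.phylo.n
        h_alive = np.flatnonzero(self.host_abund[:ng])
        p_alive = np.flatnonzero(self.path_abund[:ng])
        h_counts = self.host_abund[h_alive].copy()
        p_counts = self.path_abund[p_alive].copy()
        cells = np.flatnonzero(self.path_gid >= 0)
        if len(cells):
            key = self.path_gid[cells] * (ng + 1) + self.host_gid[cells]
            uk, cnt = np.unique(key, return_counts=True)
            e_path = uk // (ng + 1)
            e_host = uk % (ng + 1)
            e_count = cnt.astype(np.int64)
        else:
            e_path = e_host = e_count = np.empty(0, dtype=np.int64)
        return (h_alive, h_counts, p_alive, p_counts, e_path, e_host, e_count)


def init_world(config: SimConfig, seed: int | None = None) -> WorldState:
    """Seed a fresh world: the host ancestor occupies a random fraction of
    cells; the pathogen ancestor is registered in the phylogeny but only
    enters the grid at ``config.path_intro_update`` (once at least one
    susceptible host exists)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    world = WorldState(config, rng)
    anc_bits = np.array(config.host_ancestor_tasks, dtype=np.uint8)
    host_anc = world.register_genotype(None, HOST, anc_bits, 0)
    world.register_genotype(None, PATHOGEN,
                            np.array(config.path_ancestor_tasks, dtype=np.uint8), 0)
    n_seed = max(1, int(round(config.host_init_fraction * config.n_cells)))
    cells = rng.choice(config.n_cells, size=n_seed, replace=False)
    jitter = rng.uniform(0.0, 0.5 * config.host_repl_cost, n_seed)
    for cell, cpu in zip(cells, jitter):
        world.place_host(int(cell), host_anc, float(cpu))
    return world


# ---------------------------------------------------------------------------
# The update loop
# ---------------------------------------------------------------------------


def _introduce_pathogens(world: WorldState) -> None:
    cfg = world.config
    anc = 1  # pathogen ancestor id fixed by init_world
    anc_bits = world.phylo.bits_f[anc]
    occ = np.flatnonzero(world.host_gid >= 0)
    if len(occ) == 0:
        return
    susceptible = (world.phylo.bits_f[world.host_gid[occ]] @ anc_bits) > 0
    cand = occ[susceptible & (world.path_gid[occ] < 0)]
    if len(cand) == 0:
        return  # retry next update
    k = min(len(cand), max(1, math.ceil(cfg.path_intro_fraction * cfg.n_cells)))
    chosen = world.rng.choice(cand, size=k, replace=False)
    for cell in chosen:
        world.place_pathogen(int(cell), anc)
    world.path_introduced = True


def step(world: WorldState) -> WorldState:
    """Execute one update in place (also returns the world).

    Order of operations: resource inflow/outflow -> (one-off) pathogen
    introduction -> task performance and merit -> merit-proportional CPU
    allocation with pathogen theft -> host replication (offspring overwrite
    a random Moore neighbour) -> pathogen replication (propagules to
    uniformly random cells).
    """
    cfg = world.config
    rng = world.rng
    u = world.update

    # 1. environment: randomized inflow, fractional outflow
    inflow = rng.uniform(0.0, world._inflow_high)
    outfrac = rng.uniform(0.0, cfg.outflow_high, N_TASKS)
    world.pools += inflow
    world.pools *= 1.0 - outfrac
    world.total_inflow += float(inflow.sum())

    if not world.path_introduced and u >= cfg.path_intro_update:
        _introduce_pathogens(world)

    if world.n_hosts == 0:
        world.update = u + 1
        return world

    ng = world.phylo.n
    bits_f = world.phylo.bits_f[:ng]
    host_gid = world.host_gid
    path_gid = world.path_gid
    host_cpu = world.host_cpu
    path_cpu = world.path_cpu

    # 2. task performance: a task runs when its input resource is present
    pool_for_task = world.pools[world._task_res]
    avail = (pool_for_task > 1e-12).astype(np.float64)
    doers = (world.host_abund[:ng].astype(np.float64) @ bits_f) * avail
    demand = doers * cfg.consume_per_task
    consumed = np.minimum(pool_for_task, demand)
    excreted = consumed * world._byp_ratio
    world.pools[world._task_res] = pool_for_task - consumed
    np.add.at(world.pools, world._byp_res, excreted)
    np.maximum(world.pools, 0.0, out=world.pools)
    world._last_consumed = consumed
    world._last_excreted = excreted

    # 3. merit and CPU allocation (global budget, merit-proportional)
    expo = bits_f @ (TASK_COMPLEXITY * avail)
    merit_g = np.exp2(expo)
    occ = np.flatnonzero(host_gid >= 0)
    merit_c = merit_g[host_gid[occ]]
    budget = cfg.cpu_per_org * (world.n_hosts + world.n_paths)
    share = merit_c * (budget / merit_c.sum())

    infected = path_gid[occ] >= 0
    theft = share * (cfg.theft_fraction * infected)
    host_cpu[occ] += share - theft
    path_cpu[occ] += theft

    # 4. host replication: all hosts over the cost threshold replicate
    # synchronously; each offspring goes to a uniformly chosen Moore
    # neighbour, overwriting the occupant (and its pathogen, which dies
    # with the host).  The first offspring to claim a cell this update
    # wins; collisions kill the later propagating offspring.
    hcost = cfg.host_repl_cost
    rep = occ[host_cpu[occ] >= hcost]
    if len(rep):
        host_cpu[rep] = np.minimum(host_cpu[rep] - hcost, hcost)
        nbr_pick = rng.integers(0, 8, len(rep))
        targets = world.nbr[rep, nbr_pick]
        mut_u = rng.random(len(rep))
        children = host_gid[rep].copy()
        bits8 = world.phylo.bits
        for i in np.flatnonzero(mut_u < world._host_mut.p_any):
            f = world._host_mut.flips(rng)
            parent = int(children[i])
            children[i] = world.register_genotype(
                parent, HOST, bits8[parent] ^ f, int(f.sum()))
        _, first = np.unique(targets, return_index=True)
        cells = targets[first]
        gids = children[first]
        old = host_gid[cells]
        had_host = old >= 0
        if had_host.any():
            np.add.at(world.host_abund, old[had_host], -1)
        pg = path_gid[cells]
        had_path = pg >= 0
        if had_path.any():
            np.add.at(world.path_abund, pg[had_path], -1)
            world.n_paths -= int(had_path.sum())
            path_gid[cells] = -1
            path_cpu[cells] = 0.0
            world.path_reps[cells] = 0
        host_gid[cells] = gids
        host_cpu[cells] = 0.0
        np.add.at(world.host_abund, gids, 1)
        world.n_hosts += int((~had_host).sum())

    # 5. pathogen replication: broods of propagules to uniformly random
    # cells.  The mutation-free majority is resolved in one vectorized
    # pass (first propagule to reach an open cell wins); the rare mutated
    # propagules are handled individually afterwards.
    pcost = cfg.path_repl_cost
    prep = np.flatnonzero(path_cpu >= pcost)
    if len(prep):
        n_prop = cfg.propagules_per_rep
        path_cpu[prep] = np.minimum(path_cpu[prep] - pcost, pcost)
        world.path_reps[prep] += 1
        parents = np.repeat(path_gid[prep], n_prop)
        targets = rng.integers(0, cfg.n_cells, len(prep) * n_prop)
        mut_u = rng.random(len(prep) * n_prop)
        p_any = world._path_mut.p_any
        bits8 = world.phylo.bits
        mask = world.phylo.mask
        hg = host_gid[targets]
        landed = (hg >= 0) & (path_gid[targets] < 0)
        mutated = mut_u < p_any

        plain = np.flatnonzero(landed & ~mutated &
                               ((mask[parents] & mask[np.maximum(hg, 0)]) != 0))
        if len(plain):
            t_sel = targets[plain]
            _, first = np.unique(t_sel, return_index=True)
            chosen = plain[first]
            cells = targets[chosen]
            gids = parents[chosen]
            path_gid[cells] = gids
            path_cpu[cells] = 0.0
            world.path_reps[cells] = 0
            np.add.at(world.path_abund, gids, 1)
            world.n_paths += len(cells)

        for i in np.flatnonzero(landed & mutated):
            target = int(targets[i])
            h = host_gid[target]
            if h < 0 or path_gid[target] >= 0:
                continue  # cell claimed by an earlier propagule
            f = world._path_mut.flips(rng)
            parent = int(parents[i])
            child_bits = bits8[parent] ^ f
            if not np.any(child_bits & bits8[h]):
                continue  # host resistant to the mutated propagule
            child = world.register_genotype(parent, PATHOGEN, child_bits, int(f.sum()))
            world.place_pathogen(target, child)

        # replication-age cap: a pathogen dies after its final brood
        for cell in prep[world.path_reps[prep] >= cfg.path_max_reps]:
            world.kill_pathogen(int(cell))

    world.update = u + 1
    return world


# ---------------------------------------------------------------------------
# Running and sampling
# ---------------------------------------------------------------------------


def run(config: SimConfig,
        until: int | None = None,
        schedule: RecorderSchedule | None = None,
        seed: int | None = None,
        manipulation: tuple[int, object] | None = None,
        audit_every: int = 0) -> CommunityTrajectory:
    """Run a world and record its trajectory.

    ``manipulation`` is an optional ``(t_manipulate, fn)`` pair; ``fn`` is
    called with the world immediately before the snapshot at that update,
    so all recorded snapshots strictly before ``t_manipulate`` are
    bit-identical between a manipulated run and its unmanipulated twin.
    ``audit_every > 0`` runs the full invariant audit at that cadence.
    Bit-deterministic given ``(config, seed)``.
    """
    T = config.T if until is None else int(until)
    if T > config.T:
        raise ValueError("until exceeds the configured run length")
    if schedule is None:
        schedule = default_schedule(
            config, manipulation[0] if manipulation else None)
    times = schedule.times(T)
    times = times[times <= T]

    world = init_world(config, seed)
    rec_updates: list[int] = []
    cols: tuple[list, ...] = ([], [], [], [], [], [], [])
    ti = 0
    for u in range(T + 1):
        if manipulation is not None and u == manipulation[0]:
            manipulation[1](world)
        if ti < len(times) and times[ti] == u:
            snap = world.census()
            rec_updates.append(u)
            for lst, arr in zip(cols, snap):
                lst.append(arr)
            ti += 1
        if audit_every and u % audit_every == 0:
            world.audit()
        if u < T:
            step(world)

    return CommunityTrajectory(
        config=config,
        seed=config.seed if seed is None else seed,
        updates=np.array(rec_updates, dtype=np.int64),
        host_ids=cols[0], host_counts=cols[1],
        path_ids=cols[2], path_counts=cols[3],
        edge_path=cols[4], edge_host=cols[5], edge_count=cols[6],
        phylogeny=world.phylo,
        meta={"total_inflow": world.total_inflow,
              "final_update": world.update,
              "n_hosts": world.n_hosts,
              "n_paths": world.n_paths},
    )


def sample_invader(trajectory: CommunityTrajectory,
                   window: tuple[int, int],
                   rng: np.random.Generator) -> tuple[GenotypeRecord, dict]:
    """Sample a stored pathogen from a past window of a trajectory.

    A snapshot is chosen uniformly among the recorded snapshots in
    ``window`` that contain at least one living pathogen, then a pathogen
    genotype is drawn with probability proportional to its abundance in
    that snapshot.  Returns the genotype record plus provenance
    ``{"update", "abundance"}``.
    """
    lo, hi = window
    idx = trajectory.snapshot_indices(lo, hi)
    idx = np.array([i for i in idx if len(trajectory.path_ids[i]) > 0])
    if len(idx) == 0:
        raise EmptyWindowError(
            f"no living pathogens in any snapshot within [{lo}, {hi}]")
    i = int(rng.choice(idx))
    ids = trajectory.path_ids[i]
    counts = trajectory.path_counts[i].astype(np.float64)
    gid = int(rng.choice(ids, p=counts / counts.sum()))
    prov = {
        "update": int(trajectory.updates[i]),
        "abundance": int(counts[np.flatnonzero(ids == gid)[0]]),
    }
    return trajectory.phylogeny.record(gid), prov
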