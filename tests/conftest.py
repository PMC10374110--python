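"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive every quantity from the raw census
tables by direct scanning/summation, sharing no code with the library
implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from chronopath.world import (
    HOST,
    PATHOGEN,
    CommunityTrajectory,
    Phylogeny,
    SimConfig,
)


# ---------------------------------------------------------------------------
# Toy-trajectory construction
# ---------------------------------------------------------------------------


def toy_config(seed: int = 0, total: int = 1000, cadence: int = 100) -> SimConfig:
    return SimConfig(seed=seed, n_rows=10, n_cols=10, total_updates=total,
                     fine_cadence=cadence, coarse_cadence=cadence,
                     path_intro_update=1)


def build_trajectory(config, updates, host_census, path_census, edges, phylo):
    """Assemble a CommunityTrajectory from per-update census dicts.

    ``host_census``/``path_census`` map update -> {genotype: abundance};
    ``edges`` maps update -> [(pathogen, host, count)].
    """
    updates = np.asarray(updates, dtype=np.int64)
    cols = {k: [] for k in ("hi", "hc", "pi", "pc", "ep", "eh", "ec")}
    for u in updates:
        h = host_census.get(int(u), {})
        p = path_census.get(int(u), {})
        e = edges.get(int(u), [])
        cols["hi"].append(np.array(sorted(h), dtype=np.int64))
        cols["hc"].append(np.array([h[g] for g in sorted(h)], dtype=np.int64))
        cols["pi"].append(np.array(sorted(p), dtype=np.int64))
        cols["pc"].append(np.array([p[g] for g in sorted(p)], dtype=np.int64))
        cols["ep"].append(np.array([x[0] for x in e], dtype=np.int64))
        cols["eh"].append(np.array([x[1] for x in e], dtype=np.int64))
        cols["ec"].append(np.array([x[2] for x in e], dtype=np.int64))
    return CommunityTrajectory(
        config=config, seed=config.seed, updates=updates,
        host_ids=cols["hi"], host_counts=cols["hc"],
        path_ids=cols["pi"], path_counts=cols["pc"],
        edge_path=cols["ep"], edge_host=cols["eh"], edge_count=cols["ec"],
        phylogeny=phylo, meta={"total_inflow": 0.0})


def random_pathogen_phylogeny(rng: np.random.Generator, n_extra: int) -> Phylogeny:
    """Host root 0, pathogen root 1, plus ``n_extra`` random pathogen
    genotypes with random parents, birth times and mutation counts."""
    phylo = Phylogeny()
    bits = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0], dtype=np.uint8)
    phylo.add(None, HOST, 0, bits, 0)
    phylo.add(None, PATHOGEN, 0, bits, 0)
    for _ in range(n_extra):
        parents = [g for g in range(phylo.n) if phylo.kind[g] == PATHOGEN]
        parent = int(rng.choice(parents))
        birth = int(phylo.birth[parent]) + int(rng.integers(0, 400))
        phylo.add(parent, PATHOGEN, birth, bits, int(rng.integers(1, 4)))
    return phylo


def random_toy_trajectory(rng: np.random.Generator, n_genotypes: int = 8,
                          total: int = 1000, cadence: int = 100):
    """Random pathogen census over a random phylogeny, for oracle tests."""
    config = toy_config(int(rng.integers(0, 2**31)), total, cadence)
    phylo = random_pathogen_phylogeny(rng, n_genotypes)
    updates = list(range(0, total + 1, cadence))
    path_census = {}
    for u in updates:
        present = {}
        for g in range(1, phylo.n):
            if phylo.birth[g] <= u and rng.random() < 0.5:
                present[g] = int(rng.integers(1, 30))
        path_census[u] = present
    host_census = {u: {0: 50} for u in updates}
    traj = build_trajectory(config, updates, host_census, path_census, {}, phylo)
    return traj, path_census


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def oracle_members(phylo: Phylogeny, root: int, t_manipulate: int) -> set[int]:
    """Root plus descendants born >= t_manipulate, by parent-chain walks."""
    members = {root}
    for g in range(phylo.n):
        if g == root or phylo.birth[g] < t_manipulate:
            continue
        a = g
        while a >= 0:
            if a == root:
                members.add(g)
                break
            a = int(phylo.parent[a])
    return members


def oracle_persistence(path_census: dict, members: set[int],
                       t_manipulate: int, cap: int) -> int:
    """Exhaustive scan of the census table, last-seen convention."""
    alive_at = [u for u, pres in path_census.items()
                if t_manipulate < u <= t_manipulate + cap
                and any(g in members and pres[g] > 0 for g in pres)]
    if not alive_at:
        return 0
    return min(max(alive_at) - t_manipulate, cap)


def oracle_shannon(abundances) -> float:
    n = float(sum(abundances))
    total = 0.0
    for a in abundances:
        p = a / n
        total -= p * np.log(p)
    return total


def oracle_faith_pd(phylo: Phylogeny, extant, unit: str = "mutations") -> float:
    """Sum of branch lengths over the union of root paths (edge set)."""
    edges: set[int] = set()
    for g in extant:
        a = int(g)
        while phylo.parent[a] >= 0:
            edges.add(a)
            a = int(phylo.parent[a])
    total = 0.0
    for child in edges:
        p = int(phylo.parent[child])
        if unit == "mutations":
            total += float(phylo.nmut[child])
        else:
            total += float(phylo.birth[child] - phylo.birth[p])
    return total


def oracle_trapezoid(x, y) -> float:
    total = 0.0
    for i in range(len(x) - 1):
        total += 0.5 * (y[i] + y[i + 1]) * (x[i + 1] - x[i])
    return total


# ---------------------------------------------------------------------------
# Expensive shared fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_pair():
    """One included time-travel pair at the standard test scale."""
    from chronopath import build_config, run_pair

    config = build_config(207, scale=0.04)
    pair = run_pair(config, seed=2, kind="time_travel")
    assert pair.included, "fixture pair unexpectedly excluded"
    return pair


@pytest.fixture(scope="session")
def tiny_trajectory():
    """A cheap full simulator run for IO and metric smoke tests."""
    from chronopath import build_config, run

    config = build_config(11, scale=0.01)
    return run(config)
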