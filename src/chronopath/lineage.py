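"""Lineage persistence, prevalence, and the excess-persistence test.

Invasion success is measured from the invader's side: how long the
invader's lineage (the injected genotype plus every genotype descended
from it after the manipulation) remains extant in the recipient community,
capped at a fixed horizon, and how that compares with the native pathogen
lineages of the same community once small natives are excluded
(population-size matching).  A one-sided exact binomial tail quantifies
whether the number of maximally persistent invaders exceeds what the
background rate among native lineages predicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import NoQualifyingNativesError
from .world import CommunityTrajectory

__all__ = [
    "LineageQuery",
    "lineage_members",
    "lineage_persistence",
    "persistence_table",
    "native_comparison",
    "prevalence_series",
    "excess_persistence_test",
]


@dataclass(frozen=True)
class LineageQuery:
    """A lineage to follow after the manipulation.

    ``members`` is the root genotype plus every descendant born at or
    after ``t_manipulate``: descendants that split off earlier are treated
    as lineages in their own right.  ``cap`` is the assessment horizon in
    updates after ``t_manipulate``.
    """

    root: int
    t_manipulate: int
    cap: int
    members: frozenset[int]

    @classmethod
    def build(cls, trajectory: CommunityTrajectory, root: int,
              t_manipulate: int, cap: int) -> "LineageQuery":
        phylo = trajectory.phylogeny
        if not 0 <= root < phylo.n:
            raise KeyError(f"unknown root genotype {root}")
        desc = phylo.descendants(root, min_birth=t_manipulate)
        return cls(root=root, t_manipulate=int(t_manipulate), cap=int(cap),
                   members=frozenset([int(root), *map(int, desc)]))


def lineage_members(trajectory: CommunityTrajectory, root: int,
                    t_manipulate: int) -> frozenset[int]:
    """Root plus all descendants born at or after the manipulation."""
    return LineageQuery.build(trajectory, root, t_manipulate, 0).members


def _last_alive_in_window(trajectory: CommunityTrajectory,
                          t0: int, t1: int, kind: str = "pathogen") -> dict[int, int]:
    """Last snapshot update in (t0, t1] at which each genotype is extant."""
    ids_per = trajectory.path_ids if kind == "pathogen" else trajectory.host_ids
    out: dict[int, int] = {}
    for i in trajectory.snapshot_indices(t0 + 1, t1):
        u = int(trajectory.updates[i])
        for g in ids_per[i]:
            out[int(g)] = u
    return out


def lineage_persistence(trajectory: CommunityTrajectory,
                        query: LineageQuery) -> int:
    """Post-manipulation persistence of a lineage, in updates.

    Computed on the recorded snapshot cadence with the last-seen
    convention: a lineage present at snapshot ``s`` and absent at the next
    is credited through ``s``, i.e. persistence is the time from the
    manipulation to the last snapshot at which any member is extant,
    capped at ``query.cap``.  A lineage never seen after the manipulation
    scores 0.
    """
    t0, cap = query.t_manipulate, query.cap
    last = _last_alive_in_window(trajectory, t0, t0 + cap)
    seen = [u for g, u in last.items() if g in query.members]
    if not seen:
        return 0
    return min(max(seen) - t0, cap)


def persistence_table(pair, cap: int | None = None) -> pd.DataFrame:
    """Per-genotype persistence ledger for one included invasion pair.

    One row per pathogen genotype extant in the treated community at the
    manipulation update (natives) plus the invader; columns are the
    genotype id, its lineage persistence over the capped horizon, its
    population size at the manipulation update, and an invader flag.
    """
    if not pair.included or pair.treated is None:
        raise ValueError("persistence table requires an included pair")
    traj = pair.treated
    t0 = pair.t_manipulate
    cap = pair.cap if cap is None else int(cap)
    i = traj.index_of(t0)
    ids = [int(g) for g in traj.path_ids[i]]
    counts = {int(g): int(c) for g, c in zip(traj.path_ids[i], traj.path_counts[i])}

    inv = pair.invader.id if pair.invader is not None else None
    if inv is not None and inv not in ids:
        ids.append(inv)
        counts[inv] = 0

    rows = []
    for g in ids:
        q = LineageQuery.build(traj, g, t0, cap)
        rows.append({
            "genotype": g,
            "persistence": lineage_persistence(traj, q),
            "n_at_manipulation": counts[g],
            "is_invader": g == inv,
        })
    df = pd.DataFrame(rows)
    if inv is not None and int(df["is_invader"].sum()) != 1:
        raise ValueError("exactly one invader row expected")
    return df


def native_comparison(table: pd.DataFrame) -> float:
    """Fraction of qualifying native pathogens the invader outlasts.

    Natives with a population smaller than the invader's at the
    manipulation update are dropped (size matching); the statistic is the
    fraction of the remaining natives whose lineage persistence is
    strictly below the invader's.  Raises when no native qualifies, in
    which case the pair contributes nothing to this statistic.
    """
    inv = table[table["is_invader"]]
    if len(inv) != 1:
        raise ValueError("table must contain exactly one invader row")
    n_inv = int(inv["n_at_manipulation"].iloc[0])
    p_inv = float(inv["persistence"].iloc[0])
    natives = table[~table["is_invader"]]
    qual = natives[natives["n_at_manipulation"] >= n_inv]
    if len(qual) == 0:
        raise NoQualifyingNativesError(
            "no native pathogen at least as abundant as the invader")
    return float((qual["persistence"] < p_inv).mean())


def prevalence_series(trajectory: CommunityTrajectory,
                      query: LineageQuery) -> pd.DataFrame:
    """Invader-lineage share of the pathogen community over time.

    For every recorded update in (t_manipulate, t_manipulate + cap] with
    at least one living pathogen: the lineage's share of pathogen species
    (distinct genotypes) and of pathogen individuals, both in percent.
    Snapshots without pathogens are omitted (shares undefined).
    """
    t0, cap = query.t_manipulate, query.cap
    rows = []
    for i in trajectory.snapshot_indices(t0, t0 + cap):
        ids = trajectory.path_ids[i]
        if len(ids) == 0:
            continue
        counts = trajectory.path_counts[i]
        member = np.array([int(g) in query.members for g in ids])
        rows.append({
            "update": int(trajectory.updates[i]),
            "species_share": 100.0 * member.mean(),
            "individual_share": 100.0 * counts[member].sum() / counts.sum(),
        })
    return pd.DataFrame(rows, columns=["update", "species_share", "individual_share"])


def excess_persistence_test(k_persistent: int, n_invaders: int,
                            q_baseline: float, log: bool = False) -> float:
    """Exact upper-tail binomial probability P(X >= k), X ~ Bin(n, q).

    The probability of observing at least ``k_persistent`` maximally
    persistent invaders among ``n_invaders`` if each were an ordinary
    pathogen persisting to the horizon with probability ``q_baseline``.
    Summed in log space so astronomically small tails stay finite;
    ``log=True`` returns the natural log of the p-value (tails smaller
    than the smallest positive float otherwise round to 0).
    """
    k, n, q = int(k_persistent), int(n_invaders), float(q_baseline)
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 < q < 1.0:
        raise ValueError("baseline probability must be in (0, 1)")
    if k == 0:
        return 0.0 if log else 1.0
    i = np.arange(k, n + 1)
    logpmf = (gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
              + i * np.log(q) + (n - i) * np.log1p(-q))
    logp = float(logsumexp(logpmf))
    return logp if log else float(np.exp(logp))
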