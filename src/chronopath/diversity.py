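"""Diversity trajectories and the AUC-based relative-change statistic.

The community impact of a manipulation is read off paired diversity
trajectories: for each pair, the area under the curve (trapezoid rule) of
a diversity measure versus time over a short post-manipulation window is
computed for the reference (control) and treated runs, and the effect is
the relative percent change 100 x (A_ref - A_treated) / A_ref.  Positive
values are losses (treated below reference), matching the loss/gain
vocabulary used throughout.  Diversity is measured on free-living
organisms only: genotype richness, total abundance, Shannon H' (natural
log), Pielou evenness, and Faith's phylogenetic diversity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .world import CommunityTrajectory, Phylogeny

__all__ = [
    "shannon",
    "pielou",
    "faith_pd",
    "faith_pd_newick",
    "diversity_series",
    "ChangeResult",
    "auc_change",
    "pair_change",
    "window_sensitivity",
    "exceedance_vs_null",
]


def shannon(abundances) -> float:
    """Shannon diversity H' = -sum p_i ln p_i over genotype frequencies."""
    a = np.asarray(abundances, dtype=np.float64)
    if a.size == 0:
        raise ValueError("empty community")
    if np.any(a <= 0):
        raise ValueError("abundances must be positive")
    p = a / a.sum()
    return float(-(p * np.log(p)).sum())


def pielou(abundances) -> float:
    """Pielou evenness H'/ln S; defined as 0 for a single genotype."""
    a = np.asarray(abundances, dtype=np.float64)
    s = a.size
    if s <= 1:
        return 0.0
    return shannon(a) / np.log(s)


def faith_pd(phylogeny: Phylogeny, extant_ids, unit: str = "mutations") -> float:
    """Faith's phylogenetic diversity of a set of extant genotypes.

    Sum of branch lengths of the minimal subtree connecting the extant
    genotypes to their root(s); branch lengths are mutation counts by
    default, or birth-time differences with ``unit="updates"``.
    """
    total = 0.0
    visited: set[int] = set()
    for g in extant_ids:
        g = int(g)
        if not 0 <= g < phylogeny.n:
            raise KeyError(f"unknown genotype {g}")
        while g not in visited:
            visited.add(g)
            total += phylogeny.branch_length(g, unit)
            p = int(phylogeny.parent[g])
            if p < 0:
                break
            g = p
    return total


def faith_pd_newick(newick: str, tip_labels) -> float:
    """Faith's PD of labelled nodes on an external Newick tree.

    Convenience entry point for trees produced outside the simulator;
    sums the branch lengths of the minimal subtree connecting the given
    labels (leaves or labelled internal nodes) to the root.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=False)
    by_label = {}
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            by_label[node.taxon.label] = node
        elif node.label is not None:
            by_label[node.label] = node
    total = 0.0
    visited = set()
    for label in tip_labels:
        if label not in by_label:
            raise KeyError(f"unknown tree label {label!r}")
        node = by_label[label]
        while node is not None and id(node) not in visited:
            visited.add(id(node))
            if node.edge.length is not None and node.parent_node is not None:
                total += float(node.edge.length)
            node = node.parent_node
    return total


def diversity_series(trajectory: CommunityTrajectory,
                     lo: int | None = None,
                     hi: int | None = None,
                     include_pd: bool = True,
                     pd_unit: str = "mutations") -> pd.DataFrame:
    """Free-living diversity at each recorded update in [lo, hi].

    Columns: richness (distinct genotypes), abundance (individuals),
    shannon, evenness, and (optionally) faith_pd.  Snapshots with no
    free-living organisms are skipped.
    """
    lo = int(trajectory.updates[0]) if lo is None else int(lo)
    hi = int(trajectory.updates[-1]) if hi is None else int(hi)
    rows = []
    for i in trajectory.snapshot_indices(lo, hi):
        ids = trajectory.host_ids[i]
        if len(ids) == 0:
            continue
        counts = trajectory.host_counts[i]
        row = {
            "update": int(trajectory.updates[i]),
            "richness": int(len(ids)),
            "abundance": int(counts.sum()),
            "shannon": shannon(counts),
            "evenness": pielou(counts),
        }
        if include_pd:
            row["faith_pd"] = faith_pd(trajectory.phylogeny, ids, pd_unit)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ChangeResult:
    """Relative diversity change of one pair over one window."""

    metric: str
    window: int                      # window length, updates
    signed_pct: float                # 100 (A_ref - A_treated) / A_ref; loss > 0
    abs_pct: float                   # |signed_pct|
    per_timepoint: pd.DataFrame      # update, reference, treated, change_pct


def auc_change(control: pd.DataFrame, treated: pd.DataFrame,
               t_start: int, window: int,
               metric: str = "richness") -> ChangeResult:
    """AUC-based relative change between two diversity series.

    Both series must cover every recorded update in
    [t_start, t_start + window]; the AUC uses the trapezoid rule on that
    shared grid (the recording resolution).  Signed change is
    100 x (A_control - A_treated) / A_control, so a treated community
    uniformly below its control scores positive (a loss).
    """
    t_end = t_start + window
    c = control[(control["update"] >= t_start) & (control["update"] <= t_end)]
    t = treated[(treated["update"] >= t_start) & (treated["update"] <= t_end)]
    if len(c) < 2:
        raise ValueError("window contains fewer than two control snapshots")
    if not np.array_equal(c["update"].values, t["update"].values):
        raise ValueError("control and treated series are on different grids")
    x = c["update"].values.astype(np.float64)
    yc = c[metric].values.astype(np.float64)
    yt = t[metric].values.astype(np.float64)
    a_con = float(np.trapezoid(yc, x))
    a_tre = float(np.trapezoid(yt, x))
    if a_con == 0.0:
        raise ValueError("control AUC is zero; relative change undefined")
    signed = 100.0 * (a_con - a_tre) / a_con
    with np.errstate(divide="ignore", invalid="ignore"):
        per = 100.0 * (yc - yt) / yc
    series = pd.DataFrame({"update": x.astype(np.int64), "reference": yc,
                           "treated": yt, "change_pct": per})
    return ChangeResult(metric=metric, window=int(window),
                        signed_pct=signed, abs_pct=abs(signed),
                        per_timepoint=series)


def pair_change(pair, window: int | None = None,
                metric: str = "richness") -> ChangeResult:
    """Relative diversity change of an experiment pair.

    The reference series is the trajectory the pair designates a priori
    (the control); the window defaults to the pair's standard
    ecological-time-scale window (1% of the run).
    """
    if pair.treated is None:
        raise ValueError("pair has no treated trajectory")
    window = pair.change_window if window is None else int(window)
    t0 = pair.t_manipulate
    need_pd = metric == "faith_pd"
    ref = diversity_series(pair.control, t0, t0 + window, include_pd=need_pd)
    tre = diversity_series(pair.treated, t0, t0 + window, include_pd=need_pd)
    return auc_change(ref, tre, t0, window, metric)


def window_sensitivity(pair, windows=None, metric: str = "richness") -> dict[int, ChangeResult]:
    """Relative change across several window lengths.

    Defaults to the {500, 1000, 2500, 5000}-update grid scaled to the
    pair's run length (0.2x to 2x the standard window).
    """
    if windows is None:
        base = pair.change_window
        windows = [max(pair.config.fine_cadence, int(round(f * base)))
                   for f in (0.2, 0.4, 1.0, 2.0)]
    return {int(w): pair_change(pair, window=int(w), metric=metric)
            for w in windows}


def exceedance_vs_null(treated_changes, null_changes, percentile: float = 95.0) -> float:
    """Fraction of treated changes above a percentile of the null.

    The null distribution is the relative change observed between
    unmanipulated replicate futures (control-control pairs); exceeding its
    upper tail indicates change beyond replicate-to-replicate stochasticity.
    """
    treated = np.asarray(treated_changes, dtype=np.float64)
    null = np.asarray(null_changes, dtype=np.float64)
    if treated.size == 0 or null.size == 0:
        raise ValueError("both samples must be non-empty")
    threshold = np.percentile(null, percentile)
    return float((treated > threshold).mean())
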