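"""Feature extraction and statistical analysis of invasion campaigns.

Each included invasion pair is summarized by 21 pre-registered predictors
of invasion outcome - properties of the simulated world, of the recipient
community at the manipulation update, and of the invader's first,
pre-invasion existence - plus three outcomes: invader lineage persistence
and the signed and absolute relative diversity change.  Screening uses
Spearman rank correlations (no multiplicity correction, by design: the
screen is descriptive); high-loss versus high-gain subgroups are compared
with a two-sided rank-sum test (exact by enumeration for small groups);
prediction uses random-forest regression with out-of-bag explained
variance and permutation importances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .diversity import diversity_series, pair_change, window_sensitivity
from .errors import ConstantInputError
from .lineage import LineageQuery, lineage_persistence
from .world import TASK_COMPLEXITY

__all__ = [
    "FEATURES",
    "MODEL_FEATURES",
    "OUTCOMES",
    "extract_features",
    "feature_table",
    "spearman",
    "spearman_screen",
    "ranksum_two_sided",
    "loss_gain_comparison",
    "RFReport",
    "rf_model",
    "rf_reports",
]

#: the 21 predictors, in their conventional (i)-(xxi) order
FEATURES = (
    "world_size",                # (i)    number of grid cells
    "net_resources",             # (ii)   mean total resource inflow per update
    "n_resource_types",          # (iii)  resources with external inflow
    "host_richness",             # (iv)   free-living genotypes at manipulation
    "path_richness",             # (v)    pathogen genotypes at manipulation
    "host_abundance",            # (vi)
    "path_abundance",            # (vii)
    "host_density",              # (viii) individuals per grid cell
    "path_density",              # (ix)
    "pre_persistence",           # (x)    invader lineage persistence pre-invasion
    "pre_abundance_mean",        # (xi)   mean abundance while present pre-invasion
    "pre_abundance_total",       # (xii)  summed over pre-invasion snapshots
    "source_abundance",          # (xiii) abundance in the source snapshot
    "task_count",                # (xiv)
    "max_task_complexity",       # (xv)
    "source_generalism",         # (xvi)  host species infected in source snapshot
    "post_generalism_median",    # (xvii) median hosts infected post-invasion
    "phylo_distance_mean",       # (xviii) invader vs native pathogens
    "sample_lag",                # (xix)  t_manipulate - t_sample
    "invader_age",               # (xx)   t_sample
    "community_age",             # (xxi)  t_manipulate
)

#: the 17-feature modelling subset: environmental variables (i-iii) and the
#: post-invasion generalism (xvii) are excluded from the predictive models
MODEL_FEATURES = tuple(f for f in FEATURES if f not in
                       ("world_size", "net_resources", "n_resource_types",
                        "post_generalism_median"))

OUTCOMES = ("persistence", "signed_change_pct", "abs_change_pct")


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def _generalism_at(trajectory, members: frozenset[int], i: int) -> int:
    """Distinct host genotypes infected by lineage members at snapshot i."""
    ep, eh = trajectory.edge_path[i], trajectory.edge_host[i]
    hosts = {int(h) for p, h in zip(ep, eh) if int(p) in members}
    return len(hosts)


def extract_features(pair) -> dict[str, float]:
    """The 21 predictors and 3 outcomes of one included invasion pair.

    Community state is read from the shared (control) trajectory at the
    manipulation update, i.e. the recipient community the instant before
    injection; invader history comes from the same shared trajectory
    restricted to pre-manipulation snapshots; outcomes are measured on the
    treated trajectory against the control.
    """
    if not pair.included or pair.treated is None or pair.invader is None:
        raise ValueError("features require an included pair with an invader")
    con, tre = pair.control, pair.treated
    cfg = pair.config
    t_m = pair.t_manipulate
    t_s = pair.t_sample
    inv = pair.invader.id
    phylo = con.phylogeny

    i_m = con.index_of(t_m)
    host_ab = int(con.host_counts[i_m].sum())
    path_ab = int(con.path_counts[i_m].sum())

    # invader pre-invasion history on the shared trajectory
    pre = con.snapshot_indices(0, t_m - 1)
    present_ab = []
    first_seen = last_seen = None
    members_pre = frozenset([inv, *map(int, phylo.descendants(inv))])
    for i in pre:
        ids = con.path_ids[i]
        sel = np.flatnonzero(ids == inv)
        if len(sel):
            present_ab.append(int(con.path_counts[i][sel[0]]))
        here = any(int(g) in members_pre for g in ids)
        if here:
            u = int(con.updates[i])
            last_seen = u
            if first_seen is None:
                first_seen = u
    pre_persistence = 0 if first_seen is None else last_seen - first_seen

    # post-invasion generalism: median number of distinct host genotypes
    # infected by the invader lineage over the standard window
    q = LineageQuery.build(tre, inv, t_m, pair.cap)
    window = pair.change_window
    gen_post = [
        _generalism_at(tre, q.members, i)
        for i in tre.snapshot_indices(t_m, t_m + window)
    ]

    natives = [int(g) for g in con.path_ids[i_m] if int(g) != inv]
    if natives:
        dists = [phylo.patristic_distance(inv, g) for g in natives]
        phylo_dist = float(np.mean(dists))
    else:
        phylo_dist = 0.0

    i_s = con.index_of(t_s)
    tasks = np.array(pair.invader.tasks)

    change = pair_change(pair)

    feats = {
        "world_size": float(cfg.n_cells),
        "net_resources": float(con.meta["total_inflow"]) / cfg.T,
        "n_resource_types": float(sum(1 for x in cfg.inflow_high if x > 0)),
        "host_richness": float(len(con.host_ids[i_m])),
        "path_richness": float(len(con.path_ids[i_m])),
        "host_abundance": float(host_ab),
        "path_abundance": float(path_ab),
        "host_density": host_ab / cfg.n_cells,
        "path_density": path_ab / cfg.n_cells,
        "pre_persistence": float(pre_persistence),
        "pre_abundance_mean": float(np.mean(present_ab)) if present_ab else 0.0,
        "pre_abundance_total": float(np.sum(present_ab)) if present_ab else 0.0,
        "source_abundance": float(pair.invader_provenance["abundance"]),
        "task_count": float(tasks.sum()),
        "max_task_complexity": float(TASK_COMPLEXITY[tasks > 0].max()) if tasks.any() else 0.0,
        "source_generalism": float(_generalism_at(con, frozenset([inv]), i_s)),
        "post_generalism_median": float(np.median(gen_post)) if gen_post else 0.0,
        "phylo_distance_mean": phylo_dist,
        "sample_lag": float(t_m - t_s),
        "invader_age": float(t_s),
        "community_age": float(t_m),
        "persistence": float(lineage_persistence(tre, q)),
        "signed_change_pct": change.signed_pct,
        "abs_change_pct": change.abs_pct,
    }
    return feats


def feature_table(campaign) -> pd.DataFrame:
    """Feature vectors for every included pair of a time-travel campaign.

    One row per included pair (no silent drops); raises if the campaign
    kind does not carry invader provenance.
    """
    rows = [extract_features(p) for p in campaign.included]
    df = pd.DataFrame(rows, columns=list(FEATURES) + list(OUTCOMES))
    if len(df) != len(campaign.included):
        raise RuntimeError("feature table lost rows")
    return df


# ---------------------------------------------------------------------------
# Univariate statistics
# ---------------------------------------------------------------------------


def spearman(x, y) -> float:
    """Spearman rank correlation with midrank ties."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("rank correlation undefined for constant input")
    return float(sps.spearmanr(x, y).statistic)


def spearman_screen(table: pd.DataFrame,
                    features=FEATURES, outcomes=OUTCOMES) -> pd.DataFrame:
    """Feature-by-outcome Spearman correlation matrix.

    Constant features yield NaN for every outcome rather than an error, so
    a degenerate campaign still produces a complete screen.
    """
    out = pd.DataFrame(index=list(features), columns=list(outcomes), dtype=float)
    for f in features:
        for o in outcomes:
            try:
                out.loc[f, o] = spearman(table[f], table[o])
            except ConstantInputError:
                out.loc[f, o] = np.nan
    return out


def _ranksum_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all C(n, n_a) rank splits."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n, na = len(pooled), len(a)
    w_obs = ranks[:na].sum()
    total = lo = hi = 0
    mean_w = na * (n + 1) / 2.0
    for combo in itertools.combinations(range(n), na):
        w = ranks[list(combo)].sum()
        total += 1
        if w <= w_obs:
            lo += 1
        if w >= w_obs:
            hi += 1
    if w_obs == mean_w:
        return 1.0
    return min(1.0, 2.0 * min(lo, hi) / total)


def ranksum_two_sided(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two independent groups.

    Exact by enumeration when the pooled sample has at most 12 untied
    values; otherwise the normal approximation with midranks and tie
    correction (no continuity correction).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= 12 and no_ties:
        return _ranksum_exact(a, b)
    ranks = sps.rankdata(pooled)
    na, nb = len(a), len(b)
    n = na + nb
    w = ranks[:na].sum()
    mu = na * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / ((n - 1) * n)
    var = na * nb / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (w - mu) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def loss_gain_comparison(table: pd.DataFrame, threshold: float = 5.0,
                         variable: str = "persistence") -> dict:
    """Compare a variable between high-loss and high-gain invasions.

    Subgroups are pairs whose signed diversity change exceeds +threshold %
    (losses) or falls below -threshold % (gains); the comparison is the
    two-sided rank-sum test.
    """
    loss = table[table["signed_change_pct"] > threshold][variable].values
    gain = table[table["signed_change_pct"] < -threshold][variable].values
    out = {"n_loss": int(len(loss)), "n_gain": int(len(gain)),
           "variable": variable, "threshold": threshold, "p": np.nan}
    if len(loss) and len(gain):
        out["p"] = ranksum_two_sided(loss, gain)
    return out


# ---------------------------------------------------------------------------
# Random-forest prediction
# ---------------------------------------------------------------------------


@dataclass
class RFReport:
    """Random-forest regression summary."""

    outcome: str
    n_rows: int
    n_trees: int
    oob_explained_variance: float          # OOB R^2, as a fraction
    importances: pd.Series                 # % increase in MSE per feature


def rf_model(X: pd.DataFrame, y, outcome: str = "outcome",
             n_trees: int = 1000, seed: int = 0,
             importance: bool = True) -> RFReport:
    """Fit a random-forest regression and report OOB performance.

    Follows the standard regression-forest recipe: ``n_trees`` trees,
    one-third of the features tried per split, leaf size 5.  Performance
    is out-of-bag explained variance (OOB R^2); importance is the percent
    increase in mean squared error when a feature is randomly permuted,
    relative to the unpermuted MSE (``importance=False`` skips it and
    reports zeros).
    """
    y = np.asarray(y, dtype=np.float64)
    if len(X) < 20:
        raise ValueError("need at least 20 complete rows")
    if len(X) != len(y):
        raise ValueError("X and y disagree on length")
    model = RandomForestRegressor(
        n_estimators=n_trees, oob_score=True, max_features=1 / 3,
        min_samples_leaf=5, random_state=int(seed), n_jobs=1)
    model.fit(X.values, y)
    if importance:
        baseline_mse = float(np.mean((model.predict(X.values) - y) ** 2))
        perm = permutation_importance(
            model, X.values, y, scoring="neg_mean_squared_error",
            n_repeats=5, random_state=int(seed))
        if baseline_mse > 0:
            pct = 100.0 * perm.importances_mean / baseline_mse
        else:
            pct = perm.importances_mean * 0.0
    else:
        pct = np.zeros(X.shape[1])
    return RFReport(
        outcome=outcome,
        n_rows=len(X),
        n_trees=n_trees,
        oob_explained_variance=float(model.oob_score_),
        importances=pd.Series(pct, index=list(X.columns)).sort_values(ascending=False),
    )


def rf_reports(table: pd.DataFrame, n_trees: int = 1000, seed: int = 0) -> dict[str, RFReport]:
    """The three standard forests: persistence from the 17-feature subset,
    and signed/absolute diversity change from those features plus
    post-invasion persistence."""
    out = {}
    X17 = table[list(MODEL_FEATURES)]
    out["persistence"] = rf_model(X17, table["persistence"],
                                  "persistence", n_trees, seed)
    Xp = table[list(MODEL_FEATURES) + ["persistence"]]
    for outcome in ("signed_change_pct", "abs_change_pct"):
        out[outcome] = rf_model(Xp, table[outcome], outcome, n_trees, seed)
    return out
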