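"""On-disk formats: versioned TSV tables, Newick trees, YAML configs.

A trajectory is three tab-separated tables, each with a ``#schema=``
version comment and a one-line header:

census.tsv       update  genotype_id  kind  abundance
infections.tsv   update  pathogen_genotype  host_genotype  count
phylogeny.tsv    id  parent_id  kind  birth_update  mutations_from_parent  task_bits

``task_bits`` is the 9-character 0/1 task vector.  A pair directory adds
``config.yaml`` and ``provenance.yaml`` (seeds, manipulation times,
injected genotype, inclusion flag), which suffice to regenerate both
trajectories bit-identically.  All readers validate on the way in and
raise :class:`~chronopath.errors.SchemaError` with a line number.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .experiment import ExperimentPair
from .world import (
    HOST,
    PATHOGEN,
    CommunityTrajectory,
    Phylogeny,
    SimConfig,
)

SCHEMA_VERSION = 1
_KIND_STR = {HOST: "host", PATHOGEN: "pathogen"}
_KIND_INT = {"host": HOST, "pathogen": PATHOGEN}


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


def write_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"schema": f"chronopath.config.v{SCHEMA_VERSION}",
                        **dataclasses.asdict(config)}, fh, sort_keys=True)


def read_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "seed" not in data:
        raise SchemaError(f"not a config file: {path}")
    data.pop("schema", None)
    for name in ("host_ancestor_tasks", "path_ancestor_tasks", "task_resource",
                 "byproduct_resource", "byproduct_ratio", "inflow_high"):
        if name in data:
            data[name] = tuple(data[name])
    return SimConfig(**data)


# ---------------------------------------------------------------------------
# Trajectory tables
# ---------------------------------------------------------------------------


def _write_table(path, schema: str, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(f"#schema=chronopath.{schema}.v{SCHEMA_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_table(path, schema: str, columns) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith(f"#schema=chronopath.{schema}."):
        raise SchemaError(f"{path}: missing or wrong schema comment", line=1)
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != list(columns):
        raise SchemaError(f"{path}: expected columns {list(columns)}", line=2)
    return df


def trajectory_frames(traj: CommunityTrajectory) -> dict[str, pd.DataFrame]:
    """The census / infections / phylogeny tables of a trajectory."""
    cen = []
    inf = []
    for i, u in enumerate(traj.updates):
        for g, c in zip(traj.host_ids[i], traj.host_counts[i]):
            cen.append((int(u), int(g), "host", int(c)))
        for g, c in zip(traj.path_ids[i], traj.path_counts[i]):
            cen.append((int(u), int(g), "pathogen", int(c)))
        for p, h, c in zip(traj.edge_path[i], traj.edge_host[i], traj.edge_count[i]):
            inf.append((int(u), int(p), int(h), int(c)))
    phy = traj.phylogeny
    phy_rows = [
        (g, "" if phy.parent[g] < 0 else int(phy.parent[g]),
         _KIND_STR[int(phy.kind[g])], int(phy.birth[g]), int(phy.nmut[g]),
         "".join(str(int(b)) for b in phy.bits[g]))
        for g in range(phy.n)
    ]
    return {
        "census": pd.DataFrame(
            cen, columns=["update", "genotype_id", "kind", "abundance"]),
        "infections": pd.DataFrame(
            inf, columns=["update", "pathogen_genotype", "host_genotype", "count"]),
        "phylogeny": pd.DataFrame(
            phy_rows, columns=["id", "parent_id", "kind", "birth_update",
                               "mutations_from_parent", "task_bits"]),
    }


def write_trajectory(traj: CommunityTrajectory, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    frames = trajectory_frames(traj)
    _write_table(d / "census.tsv", "census", frames["census"])
    _write_table(d / "infections.tsv", "infections", frames["infections"])
    _write_table(d / "phylogeny.tsv", "phylogeny", frames["phylogeny"])
    with open(d / "meta.yaml", "w") as fh:
        yaml.safe_dump({"seed": int(traj.seed),
                        "updates": [int(u) for u in traj.updates],
                        **{k: (float(v) if isinstance(v, float) else int(v))
                           for k, v in traj.meta.items()}}, fh)


def _read_phylogeny_table(path) -> Phylogeny:
    df = _read_table(path, "phylogeny",
                     ["id", "parent_id", "kind", "birth_update",
                      "mutations_from_parent", "task_bits"])
    phylo = Phylogeny()
    for row_no, row in enumerate(df.itertuples(index=False), start=3):
        gid = int(row.id)
        if gid != phylo.n:
            raise SchemaError("phylogeny ids must be consecutive from 0", line=row_no)
        parent = None if pd.isna(row.parent_id) or row.parent_id == "" \
            else int(row.parent_id)
        if parent is not None and parent >= gid:
            raise SchemaError(f"genotype {gid} cites unknown or later parent "
                              f"{parent}", line=row_no)
        bits_str = str(row.task_bits).zfill(9)
        if len(bits_str) != 9 or set(bits_str) - {"0", "1"}:
            raise SchemaError(f"bad task_bits {row.task_bits!r}", line=row_no)
        kind = _KIND_INT.get(str(row.kind))
        if kind is None:
            raise SchemaError(f"bad kind {row.kind!r}", line=row_no)
        bits = np.array([int(c) for c in bits_str], dtype=np.uint8)
        phylo.add(parent, kind, int(row.birth_update), bits,
                  int(row.mutations_from_parent))
    return phylo


def read_trajectory(directory, config: SimConfig | None = None) -> CommunityTrajectory:
    """Read and validate a trajectory directory; read(write(x)) == x."""
    d = Path(directory)
    if config is None:
        config = read_config(d / "config.yaml") if (d / "config.yaml").exists() \
            else read_config(d.parent / "config.yaml")
    phylo = _read_phylogeny_table(d / "phylogeny.tsv")
    cen = _read_table(d / "census.tsv", "census",
                      ["update", "genotype_id", "kind", "abundance"])
    inf = _read_table(d / "infections.tsv", "infections",
                      ["update", "pathogen_genotype", "host_genotype", "count"])
    with open(d / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    updates = np.array(meta.pop("updates"), dtype=np.int64)
    if np.any(np.diff(updates) <= 0):
        raise SchemaError("snapshot updates must be strictly increasing")
    seed = int(meta.pop("seed"))

    if (cen["abundance"] < 0).any():
        line = int(cen.index[cen["abundance"] < 0][0]) + 3
        raise SchemaError("negative abundance in census", line=line)
    if (cen["genotype_id"] >= phylo.n).any() or (cen["genotype_id"] < 0).any():
        line = int(cen.index[(cen["genotype_id"] >= phylo.n)
                             | (cen["genotype_id"] < 0)][0]) + 3
        raise SchemaError("census cites a genotype missing from the phylogeny",
                          line=line)
    known = set(int(u) for u in updates)
    bad = ~cen["update"].isin(known)
    if bad.any():
        raise SchemaError("census row at an unrecorded update",
                          line=int(cen.index[bad][0]) + 3)

    idx = {int(u): i for i, u in enumerate(updates)}
    n = len(updates)
    host_ids = [[] for _ in range(n)]
    host_counts = [[] for _ in range(n)]
    path_ids = [[] for _ in range(n)]
    path_counts = [[] for _ in range(n)]
    for row in cen.itertuples(index=False):
        i = idx[int(row.update)]
        if row.kind == "host":
            host_ids[i].append(int(row.genotype_id))
            host_counts[i].append(int(row.abundance))
        else:
            path_ids[i].append(int(row.genotype_id))
            path_counts[i].append(int(row.abundance))
    edge_path = [[] for _ in range(n)]
    edge_host = [[] for _ in range(n)]
    edge_count = [[] for _ in range(n)]
    for row in inf.itertuples(index=False):
        if int(row.update) not in idx:
            raise SchemaError("infection row at an unrecorded update")
        i = idx[int(row.update)]
        edge_path[i].append(int(row.pathogen_genotype))
        edge_host[i].append(int(row.host_genotype))
        edge_count[i].append(int(row.count))

    as_arr = lambda lists: [np.array(x, dtype=np.int64) for x in lists]
    return CommunityTrajectory(
        config=config, seed=seed, updates=updates,
        host_ids=as_arr(host_ids), host_counts=as_arr(host_counts),
        path_ids=as_arr(path_ids), path_counts=as_arr(path_counts),
        edge_path=as_arr(edge_path), edge_host=as_arr(edge_host),
        edge_count=as_arr(edge_count),
        phylogeny=phylo, meta=meta)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def export_newick(phylo: Phylogeny, unit: str = "mutations") -> dict[int, str]:
    """One Newick string per root (the host and pathogen trees).

    Node labels are ``g<id>``; branch lengths are in the requested unit
    (mutation counts or update-time).  Built iteratively, so arbitrarily
    deep ancestor chains are safe; re-parsing yields identical topology
    and path lengths.
    """
    children = phylo.children_lists()
    out: dict[int, str] = {}
    for root in phylo.roots():
        piece: dict[int, str] = {}
        stack = [(root, False)]
        while stack:
            g, expanded = stack.pop()
            if not expanded and children[g]:
                stack.append((g, True))
                stack.extend((c, False) for c in children[g])
                continue
            label = f"g{g}"
            length = phylo.branch_length(g, unit)
            if children[g]:
                inner = ",".join(piece.pop(c) for c in children[g])
                piece[g] = f"({inner}){label}:{length:g}"
            else:
                piece[g] = f"{label}:{length:g}"
        text = piece[root]
        # drop the meaningless root branch length
        text = text.rsplit(":", 1)[0] + ";"
        out[root] = text
    return out


def write_newick(phylo: Phylogeny, directory, unit: str = "mutations") -> None:
    d = Path(directory)
    names = {HOST: "hosts", PATHOGEN: "pathogens"}
    for root, text in export_newick(phylo, unit).items():
        (d / f"{names[int(phylo.kind[root])]}.nwk").write_text(text + "\n")


# ---------------------------------------------------------------------------
# Pair directories
# ---------------------------------------------------------------------------


def write_pair(pair: ExperimentPair, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_config(pair.config, d / "config.yaml")
    prov = {
        "kind": pair.kind,
        "seed": int(pair.seed),
        "t_sample": None if pair.t_sample is None else int(pair.t_sample),
        "t_manipulate": int(pair.t_manipulate),
        "reference": pair.reference,
        "included": bool(pair.included),
        "exclusion_reason": pair.exclusion_reason,
        "invader": None if pair.invader is None else {
            "id": pair.invader.id,
            "task_bits": "".join(str(b) for b in pair.invader.tasks),
            **(pair.invader_provenance or {}),
        },
    }
    with open(d / "provenance.yaml", "w") as fh:
        yaml.safe_dump(prov, fh, sort_keys=True)
    write_trajectory(pair.control, d / "control")
    write_newick(pair.control.phylogeny, d / "control")
    if pair.treated is not None:
        write_trajectory(pair.treated, d / "treated")
        write_newick(pair.treated.phylogeny, d / "treated")


def read_pair(directory) -> ExperimentPair:
    d = Path(directory)
    config = read_config(d / "config.yaml")
    with open(d / "provenance.yaml") as fh:
        prov = yaml.safe_load(fh)
    control = read_trajectory(d / "control", config)
    treated = read_trajectory(d / "treated", config) \
        if (d / "treated" / "census.tsv").exists() else None
    invader = None
    provenance = None
    if prov.get("invader"):
        gid = int(prov["invader"]["id"])
        invader = (treated or control).phylogeny.record(gid)
        provenance = {k: v for k, v in prov["invader"].items()
                      if k not in ("id", "task_bits")}
    return ExperimentPair(
        config=config, seed=int(prov["seed"]), kind=prov["kind"],
        t_sample=prov["t_sample"], t_manipulate=int(prov["t_manipulate"]),
        invader=invader, invader_provenance=provenance,
        control=control, treated=treated,
        reference=prov.get("reference", "control"),
        included=bool(prov["included"]),
        exclusion_reason=prov.get("exclusion_reason"),
    )


# ---------------------------------------------------------------------------
# Synthetic fixtures with known ground truth
# ---------------------------------------------------------------------------


def _toy_config(seed: int) -> SimConfig:
    return SimConfig(seed=seed, n_rows=10, n_cols=10, total_updates=1000,
                     scale=0.004, fine_cadence=100, coarse_cadence=100,
                     path_intro_update=1)


def _toy_trajectory(config, host_rows, path_rows, edges, phylo) -> CommunityTrajectory:
    updates = np.arange(0, config.T + 1, 100, dtype=np.int64)
    n = len(updates)
    cols = {k: [[] for _ in range(n)] for k in
            ("hi", "hc", "pi", "pc", "ep", "eh", "ec")}
    for i in range(n):
        for g, c in host_rows(int(updates[i])):
            cols["hi"][i].append(g)
            cols["hc"][i].append(c)
        for g, c in path_rows(int(updates[i])):
            cols["pi"][i].append(g)
            cols["pc"][i].append(c)
        for p, h, c in edges(int(updates[i])):
            cols["ep"][i].append(p)
            cols["eh"][i].append(h)
            cols["ec"][i].append(c)
    arr = lambda key: [np.array(x, dtype=np.int64) for x in cols[key]]
    return CommunityTrajectory(
        config=config, seed=config.seed, updates=updates,
        host_ids=arr("hi"), host_counts=arr("hc"),
        path_ids=arr("pi"), path_counts=arr("pc"),
        edge_path=arr("ep"), edge_host=arr("eh"), edge_count=arr("ec"),
        phylogeny=phylo, meta={"total_inflow": 1000.0})


def make_fixture(name: str, seed: int = 0,
                 directory=None) -> tuple[ExperimentPair, dict]:
    """Hand-built pair fixtures with ground truth computed by direct
    arithmetic (independent of the metric implementations).

    Recipes: ``identical_pair`` (treated == control, zero change
    everywhere), ``invader_takeover`` (the invader lineage is the entire
    post-manipulation pathogen community), ``loss_05pct`` (constant
    richness 20 vs 19 after the manipulation, an exact 5% loss).
    Returns the pair and its manifest of expected values; optionally
    writes the pair directory plus ``manifest.yaml``.
    """
    config = _toy_config(seed)
    t_m = 500
    cap = int(config.T * 0.2)  # 200
    window = 100

    # shared toy phylogeny: host root 0 with hosts 2..21; pathogen root 1
    # with natives 22, 23 and invader 24 (born pre-manipulation, lineage
    # child 25 born post-manipulation)
    phylo = Phylogeny()
    phylo.add(None, HOST, 0, np.array([1, 0, 0, 0, 0, 0, 0, 0, 0], np.uint8), 0)
    phylo.add(None, PATHOGEN, 0, np.array([1, 0, 0, 0, 0, 0, 0, 0, 0], np.uint8), 0)
    for k in range(20):
        phylo.add(0, HOST, 0, np.array([1, 0, 0, 0, 0, 0, 0, 0, 0], np.uint8), 1)
    phylo.add(1, PATHOGEN, 0, np.array([1, 1, 0, 0, 0, 0, 0, 0, 0], np.uint8), 1)  # 22
    phylo.add(1, PATHOGEN, 0, np.array([1, 0, 1, 0, 0, 0, 0, 0, 0], np.uint8), 1)  # 23
    phylo.add(1, PATHOGEN, 100, np.array([1, 0, 0, 1, 0, 0, 0, 0, 0], np.uint8), 1)  # 24
    phylo.add(24, PATHOGEN, 600, np.array([1, 0, 0, 1, 1, 0, 0, 0, 0], np.uint8), 1)  # 25
    invader = phylo.record(24)
    hosts = list(range(2, 22))

    def hosts_n(n):
        return lambda u: [(g, 5) for g in hosts[:n]]

    natives = lambda u: [(22, 10), (23, 5)]
    native_edges = lambda u: [(22, 2, 10), (23, 3, 5)]

    if name == "identical_pair":
        control = _toy_trajectory(config, hosts_n(20), natives, native_edges, phylo)
        treated = _toy_trajectory(config, hosts_n(20), natives, native_edges, phylo)
        manifest = {"signed_change_pct": 0.0, "abs_change_pct": 0.0}
        pair = ExperimentPair(config=config, seed=seed, kind="control_control",
                              t_sample=None, t_manipulate=t_m, invader=None,
                              invader_provenance=None, control=control,
                              treated=treated)
    elif name == "invader_takeover":
        # invader appears pre-manipulation at updates 100-200, goes
        # extinct, is reinjected at t_m and (with child 25) replaces all
        # natives from t_m on, surviving through the cap
        def paths_treated(u):
            if 100 <= u <= 200:
                return [(22, 10), (23, 5), (24, 3)]
            if u < t_m:
                return [(22, 10), (23, 5)]
            if u < 600:
                return [(24, 8)]
            return [(24, 4), (25, 6)]

        def paths_control(u):
            if 100 <= u <= 200:
                return [(22, 10), (23, 5), (24, 3)]
            return [(22, 10), (23, 5)]

        def edges_treated(u):
            if u < t_m:
                return native_edges(u)
            return [(24, 2, 4), (25, 3, 4)] if u >= 600 else [(24, 2, 8)]

        control = _toy_trajectory(config, hosts_n(20), paths_control,
                                  native_edges, phylo)
        treated = _toy_trajectory(config, hosts_n(20), paths_treated,
                                  edges_treated, phylo)
        manifest = {
            # alive at every snapshot through t_m + cap -> capped value
            "persistence": cap,
            "prevalence_final": (100.0, 100.0),
            "pre_persistence": 100,  # present at updates 100 and 200
        }
        pair = ExperimentPair(config=config, seed=seed, kind="time_travel",
                              t_sample=200, t_manipulate=t_m, invader=invader,
                              invader_provenance={"update": 200, "abundance": 3},
                              control=control, treated=treated)
    elif name == "loss_05pct":
        def hosts_treated(u):
            return [(g, 5) for g in hosts[: (20 if u < t_m else 19)]]

        control = _toy_trajectory(config, hosts_n(20), natives, native_edges, phylo)
        treated = _toy_trajectory(config, hosts_treated, natives, native_edges, phylo)
        # ground truth by direct trapezoid arithmetic on constant series:
        a_con = 20.0 * window
        a_tre = 19.0 * window
        manifest = {"signed_change_pct": 100.0 * (a_con - a_tre) / a_con}
        pair = ExperimentPair(config=config, seed=seed, kind="control_control",
                              t_sample=None, t_manipulate=t_m, invader=None,
                              invader_provenance=None, control=control,
                              treated=treated)
    else:
        raise ValueError(f"unknown fixture recipe {name!r}")

    if directory is not None:
        write_pair(pair, directory)
        with open(Path(directory) / "manifest.yaml", "w") as fh:
            yaml.safe_dump({"recipe": name, **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in manifest.items()}}, fh)
    return pair, manifest
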