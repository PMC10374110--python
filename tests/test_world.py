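"""Simulator unit and property tests: configuration, infection rule,
update loop invariants, determinism, and invader sampling."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronopath.errors import EmptyWindowError, WorldCorruptionError
from chronopath.world import (
    HOST,
    PATHOGEN,
    RecorderSchedule,
    TASK_COMPLEXITY,
    build_config,
    can_infect,
    init_world,
    run,
    sample_invader,
    step,
    taskset,
)
from conftest import build_trajectory, random_pathogen_phylogeny, toy_config


class TestBuildConfig:
    def test_identical_seed_gives_identical_config(self):
        a = build_config(123, scale=0.04)
        b = build_config(123, scale=0.04)
        assert dataclasses.asdict(a) == dataclasses.asdict(b)

    def test_rejects_non_positive_scale(self):
        with pytest.raises(ValueError):
            build_config(1, scale=0.0)

    def test_byproduct_ratios_within_bounds(self):
        for seed in range(1000):
            cfg = build_config(seed, scale=0.02)
            assert all(0.0 <= r <= 0.5 for r in cfg.byproduct_ratio)

    def test_full_scale_world_sizes_within_range(self):
        sizes = [build_config(seed, scale=1.0).n_cells for seed in range(1000)]
        assert all(2500 <= n <= 15000 for n in sizes)
        assert min(sizes) < 5000 < max(sizes)  # actually spans the range

    def test_task_resource_is_permutation(self):
        cfg = build_config(7, scale=0.05)
        assert sorted(cfg.task_resource) == list(range(9))


class TestCanInfect:
    def test_overlap_infects(self):
        assert can_infect(taskset("AND"), taskset("NOT", "AND"))

    def test_taskless_pathogen_infects_nothing(self):
        assert not can_infect(taskset(), taskset("NOT", "EQU"))

    def test_disjoint_tasks_resist(self):
        assert not can_infect(taskset("NAND"), taskset("NOT"))

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.booleans(), min_size=9, max_size=9),
           st.lists(st.booleans(), min_size=9, max_size=9))
    def test_matches_set_intersection(self, p, h):
        p = np.array(p, dtype=np.uint8)
        h = np.array(h, dtype=np.uint8)
        expected = bool(set(np.flatnonzero(p)) & set(np.flatnonzero(h)))
        assert can_infect(p, h) == expected

    def test_rejects_wrong_length(self):
        with pytest.raises(ValueError):
            can_infect(np.ones(8, dtype=np.uint8), taskset("NOT"))


class TestInitWorld:
    def test_single_host_genotype_seeded(self):
        cfg = build_config(5, scale=0.01)
        w = init_world(cfg)
        alive_hosts = np.flatnonzero(w.host_abund[: w.phylo.n])
        assert list(alive_hosts) == [0]
        assert w.n_paths == 0

    def test_abundance_equals_seeded_organisms(self):
        cfg = build_config(5, scale=0.01)
        w = init_world(cfg)
        assert w.n_hosts == int((w.host_gid >= 0).sum())
        assert w.n_hosts == int(w.host_abund[: w.phylo.n].sum())
        w.audit()

    def test_phylogeny_has_exactly_two_ancestors(self):
        w = init_world(build_config(5, scale=0.01))
        assert w.phylo.n == 2
        assert int(w.phylo.kind[0]) == HOST
        assert int(w.phylo.kind[1]) == PATHOGEN


class TestStep:
    def test_no_pathogens_stay_no_pathogens(self):
        # lifestyles never interconvert: with the pathogen introduction
        # pushed past the horizon, no pathogen ever appears
        cfg = build_config(3, scale=0.01).with_(path_intro_update=10**9)
        w = init_world(cfg)
        for _ in range(300):
            step(w)
        assert w.n_paths == 0
        w.audit()

    def test_zero_mutation_leaves_genotype_set_unchanged(self):
        cfg = build_config(3, scale=0.01).with_(host_mut_rate=0.0,
                                                path_mut_rate=0.0)
        w = init_world(cfg)
        for _ in range(300):
            step(w)
        assert w.phylo.n == 2

    def test_audit_passes_throughout_small_run(self):
        cfg = build_config(17, scale=0.008)
        run(cfg, audit_every=1)  # raises WorldCorruptionError on violation

    def test_audit_detects_pathogen_on_empty_cell(self):
        w = init_world(build_config(3, scale=0.01))
        empty = int(np.flatnonzero(w.host_gid < 0)[0])
        w.path_gid[empty] = 1  # corrupt: pathogen with no host
        with pytest.raises(WorldCorruptionError):
            w.audit()


class TestRun:
    def test_bit_determinism(self):
        cfg = build_config(9, scale=0.01)
        assert run(cfg).digest() == run(cfg).digest()

    def test_snapshot_schedule_matches_cadence(self):
        cfg = build_config(9, scale=0.01)
        sched = RecorderSchedule(fine=10, coarse=100, fine_start=0, fine_end=500)
        traj = run(cfg, until=2000, schedule=sched)
        expected = sorted(set(range(0, 501, 10)) | set(range(0, 2001, 100))
                          | {0, 2000})
        assert list(traj.updates) == expected

    def test_run_to_zero_contains_only_initial_census(self):
        traj = run(build_config(9, scale=0.01), until=0)
        assert list(traj.updates) == [0]

    def test_infection_edges_all_satisfy_can_infect(self, tiny_trajectory):
        traj = tiny_trajectory
        phylo = traj.phylogeny
        checked = 0
        for i in range(len(traj.updates)):
            for p, h in zip(traj.edge_path[i], traj.edge_host[i]):
                assert can_infect(phylo.bits[int(p)], phylo.bits[int(h)])
                checked += 1
        assert checked > 0

    def test_edge_counts_bounded_by_endpoint_abundances(self, tiny_trajectory):
        traj = tiny_trajectory
        for i in range(len(traj.updates)):
            path_n = dict(zip(map(int, traj.path_ids[i]),
                              map(int, traj.path_counts[i])))
            host_n = dict(zip(map(int, traj.host_ids[i]),
                              map(int, traj.host_counts[i])))
            for p, h, c in zip(traj.edge_path[i], traj.edge_host[i],
                               traj.edge_count[i]):
                assert c <= path_n[int(p)]
                assert c <= host_n[int(h)]

    def test_arms_race_complexity_does_not_decay(self):
        # over >= 20 seeded small runs, the mean maximum host task
        # complexity at the end is no lower than at the start
        start, end = [], []
        for seed in range(20):
            cfg = build_config(1000 + seed, scale=0.008)
            traj = run(cfg)
            phylo = traj.phylogeny

            def max_complexity(i):
                best = 0.0
                for g in traj.host_ids[i]:
                    bits = phylo.bits[int(g)]
                    if bits.any():
                        best = max(best, float(TASK_COMPLEXITY[bits > 0].max()))
                return best

            start.append(max_complexity(0))
            end.append(max_complexity(len(traj.updates) - 1))
        assert np.mean(end) >= np.mean(start)
        assert np.mean(end) > 0  # tasks actually evolved


class TestSampleInvader:
    def _two_genotype_trajectory(self):
        config = toy_config()
        phylo = random_pathogen_phylogeny(np.random.default_rng(0), 2)
        updates = list(range(0, 1001, 100))
        path_census = {u: ({2: 90, 3: 10} if u <= 500 else {}) for u in updates}
        host_census = {u: {0: 10} for u in updates}
        return build_trajectory(config, updates, host_census, path_census,
                                {}, phylo)

    def test_single_genotype_sampled_with_certainty(self):
        config = toy_config()
        phylo = random_pathogen_phylogeny(np.random.default_rng(0), 1)
        updates = [0, 100]
        traj = build_trajectory(config, updates, {u: {0: 5} for u in updates},
                                {100: {2: 7}}, {}, phylo)
        rec, prov = sample_invader(traj, (0, 100), np.random.default_rng(1))
        assert rec.id == 2
        assert prov == {"update": 100, "abundance": 7}

    def test_abundance_weighted_selection_frequencies(self):
        traj = self._two_genotype_trajectory()
        rng = np.random.default_rng(42)
        draws = 10_000
        hits = sum(sample_invader(traj, (100, 100), rng)[0].id == 2
                   for _ in range(draws))
        # Binomial(10000, 0.9): 3 sigma is ~90
        assert abs(hits - 0.9 * draws) < 3 * np.sqrt(draws * 0.9 * 0.1)

    def test_window_beyond_extinction_raises(self):
        traj = self._two_genotype_trajectory()
        with pytest.raises(EmptyWindowError):
            sample_invader(traj, (600, 1000), np.random.default_rng(0))
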