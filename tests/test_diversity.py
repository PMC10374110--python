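"""Diversity metrics and the AUC relative-change statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronopath.diversity import (
    auc_change,
    diversity_series,
    exceedance_vs_null,
    faith_pd,
    pair_change,
    pielou,
    shannon,
    window_sensitivity,
)
from chronopath.io import make_fixture
from chronopath.world import HOST, PATHOGEN, Phylogeny
from conftest import oracle_faith_pd, oracle_shannon, oracle_trapezoid


def _series(updates, values, metric="richness"):
    return pd.DataFrame({"update": updates, metric: values})


class TestShannon:
    def test_uniform_four_genotypes(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(np.log(4))

    def test_single_genotype_is_zero(self):
        assert shannon([17]) == 0.0

    def test_matches_direct_summation(self):
        assert shannon([50, 30, 20]) == pytest.approx(
            oracle_shannon([50, 30, 20]), rel=1e-12)

    def test_empty_and_non_positive_rejected(self):
        with pytest.raises(ValueError):
            shannon([])
        with pytest.raises(ValueError):
            shannon([3, 0])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.integers(min_value=1, max_value=1000),
                    min_size=1, max_size=30))
    def test_bounded_by_log_richness(self, abundances):
        h = shannon(abundances)
        assert -1e-9 <= h <= np.log(len(abundances)) + 1e-9
        assert 0.0 <= pielou(abundances) <= 1.0 + 1e-9


def _chain_phylogeny(lengths, kind=HOST):
    """Caterpillar: 0 -> 1 -> 2 ... with given mutation counts."""
    phylo = Phylogeny()
    bits = np.zeros(9, dtype=np.uint8)
    phylo.add(None, kind, 0, bits, 0)
    for i, m in enumerate(lengths):
        phylo.add(i, kind, (i + 1) * 10, bits, m)
    return phylo


class TestFaithPD:
    def test_star_tree_unit_branches(self):
        phylo = Phylogeny()
        bits = np.zeros(9, dtype=np.uint8)
        phylo.add(None, HOST, 0, bits, 0)
        for _ in range(3):
            phylo.add(0, HOST, 10, bits, 1)
        assert faith_pd(phylo, [1, 2, 3]) == 3.0

    def test_single_tip_equals_root_path(self):
        phylo = _chain_phylogeny([2, 1, 4])
        assert faith_pd(phylo, [3]) == 7.0

    def test_caterpillar_matches_path_union_oracle(self):
        phylo = _chain_phylogeny([1, 2, 3, 4, 5, 6])
        extant = [2, 4, 6]
        assert faith_pd(phylo, extant) == oracle_faith_pd(phylo, extant)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_trees_match_oracle_in_both_units(self, seed):
        rng = np.random.default_rng(seed)
        phylo = Phylogeny()
        bits = np.zeros(9, dtype=np.uint8)
        phylo.add(None, PATHOGEN, 0, bits, 0)
        for _ in range(rng.integers(5, 40)):
            parent = int(rng.integers(0, phylo.n))
            phylo.add(parent, PATHOGEN,
                      int(phylo.birth[parent]) + int(rng.integers(1, 50)),
                      bits, int(rng.integers(1, 5)))
        k = int(rng.integers(1, phylo.n))
        extant = rng.choice(phylo.n, size=k, replace=False)
        for unit in ("mutations", "updates"):
            assert faith_pd(phylo, extant, unit) == pytest.approx(
                oracle_faith_pd(phylo, extant, unit))

    def test_unknown_id_raises(self):
        phylo = _chain_phylogeny([1])
        with pytest.raises(KeyError):
            faith_pd(phylo, [99])

    @pytest.mark.parametrize("seed", range(5))
    def test_newick_route_agrees_with_phylogeny_route(self, seed):
        from chronopath.diversity import faith_pd_newick
        from chronopath.io import export_newick
        from conftest import random_pathogen_phylogeny

        rng = np.random.default_rng(seed)
        phylo = random_pathogen_phylogeny(rng, 25)
        path_ids = [g for g in range(phylo.n) if phylo.kind[g] == PATHOGEN]
        extant = rng.choice(path_ids, size=6, replace=False)
        text = export_newick(phylo)[1]
        got = faith_pd_newick(text, [f"g{g}" for g in extant])
        assert got == pytest.approx(faith_pd(phylo, extant))


class TestAucChange:
    def test_identical_series_zero_everywhere(self):
        u = list(range(0, 501, 100))
        c = _series(u, [10, 12, 11, 9, 10, 10])
        res = auc_change(c, c.copy(), 0, 500)
        assert res.signed_pct == 0.0
        assert (res.per_timepoint["change_pct"] == 0.0).all()

    def test_single_timepoint_formula(self):
        u = [0, 100]
        res = auc_change(_series(u, [100, 100]), _series(u, [68, 68]), 0, 100)
        assert (res.per_timepoint["change_pct"] == 32.0).all()

    def test_constant_ten_vs_nine_is_ten_percent_loss(self):
        u = list(range(0, 1001, 100))
        res = auc_change(_series(u, [10] * 11), _series(u, [9] * 11), 0, 1000)
        assert res.signed_pct == pytest.approx(10.0)
        assert res.abs_pct == pytest.approx(10.0)

    def test_matches_trapezoid_oracle_on_random_series(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            u = np.arange(0, 600, 100)
            yc = rng.integers(5, 40, len(u)).astype(float)
            yt = rng.integers(5, 40, len(u)).astype(float)
            res = auc_change(_series(u, yc), _series(u, yt), 0, 500)
            a_c = oracle_trapezoid(u, yc)
            a_t = oracle_trapezoid(u, yt)
            assert res.signed_pct == pytest.approx(100 * (a_c - a_t) / a_c)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        u = np.arange(0, 600, 100)
        yc = rng.integers(5, 40, len(u)).astype(float)
        yt = rng.integers(5, 40, len(u)).astype(float)
        r1 = auc_change(_series(u, yc), _series(u, yt), 0, 500)
        r2 = auc_change(_series(u, 7 * yc), _series(u, 7 * yt), 0, 500)
        assert r1.signed_pct == pytest.approx(r2.signed_pct)

    def test_loss_sign_convention(self):
        # treated uniformly below control => positive signed change
        u = list(range(0, 301, 100))
        res = auc_change(_series(u, [20] * 4), _series(u, [15] * 4), 0, 300)
        assert res.signed_pct > 0

    def test_zero_control_auc_rejected(self):
        u = [0, 100]
        with pytest.raises(ValueError):
            auc_change(_series(u, [0, 0]), _series(u, [1, 1]), 0, 100)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            auc_change(_series([0, 100], [1, 1]), _series([0, 50], [1, 1]),
                       0, 100)


class TestPairLevel:
    def test_identical_pair_zero_for_every_window(self):
        pair, _ = make_fixture("identical_pair")
        results = window_sensitivity(pair, windows=[100, 200, 300, 400])
        for w, res in results.items():
            assert res.window == w
            assert res.signed_pct == 0.0

    def test_default_window_grid_has_four_lengths(self, small_pair):
        results = window_sensitivity(small_pair)
        assert len(results) == 4
        assert sorted(results) == [20, 40, 100, 200]  # 0.2x-2x of 1% of T
        for w, res in results.items():
            assert res.window == w

    def test_loss_fixture_matches_manifest(self):
        pair, manifest = make_fixture("loss_05pct")
        res = pair_change(pair)
        assert res.signed_pct == pytest.approx(manifest["signed_change_pct"])
        assert res.abs_pct == pytest.approx(abs(manifest["signed_change_pct"]))

    def test_divergence_after_first_window_only(self):
        # treated equals control within the first window, diverges later
        pair, _ = make_fixture("identical_pair")
        t_m = pair.t_manipulate
        for i, u in enumerate(pair.treated.updates):
            if u >= t_m + 300:
                pair.treated.host_ids[i] = pair.treated.host_ids[i][:-2]
                pair.treated.host_counts[i] = pair.treated.host_counts[i][:-2]
        early = pair_change(pair, window=200)
        late = pair_change(pair, window=500)
        assert early.signed_pct == 0.0
        assert late.signed_pct > 0.0

    def test_series_from_simulation_matches_raw_census(self, tiny_trajectory):
        traj = tiny_trajectory
        series = diversity_series(traj, include_pd=True)
        i = len(traj.updates) - 1
        row = series.iloc[-1]
        counts = traj.host_counts[i]
        assert row["richness"] == len(traj.host_ids[i])
        assert row["abundance"] == counts.sum()
        assert row["shannon"] == pytest.approx(oracle_shannon(counts))
        assert row["faith_pd"] == pytest.approx(
            oracle_faith_pd(traj.phylogeny, traj.host_ids[i]))


class TestExceedance:
    def test_self_comparison_near_five_percent(self):
        rng = np.random.default_rng(0)
        null = rng.normal(size=20_000)
        assert exceedance_vs_null(null, null) == pytest.approx(0.05, abs=0.005)

    def test_all_below_null_minimum(self):
        assert exceedance_vs_null([-5, -6, -7], np.arange(100)) == 0.0

    def test_toy_samples_match_hand_count(self):
        null = np.arange(20)          # 95th percentile = 18.05
        treated = np.arange(10, 30)   # values 19..29 exceed: 11 of 20
        assert exceedance_vs_null(treated, null) == pytest.approx(11 / 20)
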