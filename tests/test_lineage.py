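"""Persistence and prevalence metrics against brute-force oracles, and
the exact binomial excess-persistence test."""

import numpy as np
import pytest
from scipy import stats as sps

from chronopath.errors import NoQualifyingNativesError
from chronopath.lineage import (
    LineageQuery,
    excess_persistence_test,
    lineage_persistence,
    native_comparison,
    persistence_table,
    prevalence_series,
)
from chronopath.io import make_fixture
from conftest import (
    build_trajectory,
    oracle_members,
    oracle_persistence,
    random_pathogen_phylogeny,
    random_toy_trajectory,
    toy_config,
)
import pandas as pd


class TestLineagePersistence:
    def _simple_trajectory(self, presence: dict[int, list[int]]):
        """presence: genotype -> updates at which it is alive."""
        config = toy_config()
        phylo = random_pathogen_phylogeny(np.random.default_rng(0), 4)
        updates = list(range(0, 1001, 100))
        census = {u: {g: 5 for g, ups in presence.items() if u in ups}
                  for u in updates}
        traj = build_trajectory(config, updates, {u: {0: 9} for u in updates},
                                census, {}, phylo)
        return traj, census

    def test_never_alive_after_manipulation_scores_zero(self):
        traj, _ = self._simple_trajectory({2: [0, 100, 200]})
        q = LineageQuery.build(traj, 2, 300, 500)
        assert lineage_persistence(traj, q) == 0

    def test_alive_through_cap_scores_cap(self):
        traj, _ = self._simple_trajectory({2: list(range(0, 1001, 100))})
        q = LineageQuery.build(traj, 2, 200, 500)
        assert lineage_persistence(traj, q) == 500

    def test_mid_window_extinction_matches_census_scan(self):
        presence = {2: [0, 100, 300, 400], 3: [500, 600]}
        traj, census = self._simple_trajectory(presence)
        q = LineageQuery.build(traj, 2, 100, 800)
        members = oracle_members(traj.phylogeny, 2, 100)
        assert lineage_persistence(traj, q) == \
            oracle_persistence(census, members, 100, 800)

    def test_unknown_root_raises(self):
        traj, _ = self._simple_trajectory({2: [0]})
        with pytest.raises(KeyError):
            LineageQuery.build(traj, 999, 0, 100)

    @pytest.mark.parametrize("seed", range(25))
    def test_randomized_fixtures_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        traj, census = random_toy_trajectory(rng)
        t_m = int(rng.choice([200, 300, 400, 500]))
        cap = int(rng.choice([200, 400, 600]))
        for root in range(1, traj.phylogeny.n):
            q = LineageQuery.build(traj, root, t_m, cap)
            members = oracle_members(traj.phylogeny, root, t_m)
            assert q.members == frozenset(members)
            assert lineage_persistence(traj, q) == \
                oracle_persistence(census, members, t_m, cap)

    @pytest.mark.parametrize("seed", range(5))
    def test_increasing_cap_never_decreases_persistence(self, seed):
        rng = np.random.default_rng(100 + seed)
        traj, _ = random_toy_trajectory(rng)
        for root in range(1, traj.phylogeny.n):
            values = [lineage_persistence(
                traj, LineageQuery.build(traj, root, 200, cap))
                for cap in (100, 200, 400, 800)]
            assert values == sorted(values)


class TestNativeComparison:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["genotype", "persistence",
                                           "n_at_manipulation", "is_invader"])

    def test_invader_outlasting_all_qualifying_natives(self):
        t = self._table([(1, 900, 10, True)] +
                        [(g, 100, 20, False) for g in range(2, 6)])
        assert native_comparison(t) == 1.0

    def test_invader_persisting_zero_outlasts_none(self):
        t = self._table([(1, 0, 5, True)] +
                        [(g, 50, 10, False) for g in range(2, 5)])
        assert native_comparison(t) == 0.0

    def test_size_matching_excludes_small_natives(self):
        # natives below the invader's population size must not count
        rows = [(1, 300, 10, True),
                (2, 100, 15, False), (3, 400, 12, False), (4, 200, 10, False),
                (5, 900, 3, False), (6, 0, 2, False), (7, 0, 1, False)]
        t = self._table(rows)
        # qualifying: genotypes 2, 3, 4; persistence < 300 for 2 and 4
        assert native_comparison(t) == pytest.approx(2 / 3)

    def test_no_qualifying_natives_signalled(self):
        t = self._table([(1, 10, 50, True), (2, 5, 3, False)])
        with pytest.raises(NoQualifyingNativesError):
            native_comparison(t)


class TestPrevalence:
    def test_sole_lineage_has_full_shares(self):
        pair, manifest = make_fixture("invader_takeover")
        q = LineageQuery.build(pair.treated, pair.invader.id,
                               pair.t_manipulate, pair.cap)
        prev = prevalence_series(pair.treated, q)
        assert (prev["species_share"] == 100.0).all()
        assert (prev["individual_share"] == 100.0).all()

    def test_extinct_invader_has_zero_shares(self):
        pair, _ = make_fixture("identical_pair")
        # genotype 24 is extinct after update 200 in this recipe
        q = LineageQuery.build(pair.treated, 24, 500, pair.cap)
        prev = prevalence_series(pair.treated, q)
        assert (prev["species_share"] == 0.0).all()

    def test_three_lineage_shares_match_hand_ratios(self):
        config = toy_config()
        phylo = random_pathogen_phylogeny(np.random.default_rng(1), 3)
        updates = [0, 100, 200]
        census = {u: {2: 10, 3: 30, 4: 60} for u in updates}
        traj = build_trajectory(config, updates, {u: {0: 5} for u in updates},
                                census, {}, phylo)
        q = LineageQuery.build(traj, 2, 0, 200)
        prev = prevalence_series(traj, q)
        # lineage membership of 2 depends on the random tree; recompute
        members = oracle_members(phylo, 2, 0)
        sp = 100.0 * sum(g in members for g in (2, 3, 4)) / 3
        ind = 100.0 * sum(census[100][g] for g in (2, 3, 4) if g in members) / 100
        assert prev["species_share"].iloc[1] == pytest.approx(sp)
        assert prev["individual_share"].iloc[1] == pytest.approx(ind)


class TestPersistenceTable:
    def test_fixture_pair_table(self):
        pair, manifest = make_fixture("invader_takeover")
        table = persistence_table(pair)
        assert int(table["is_invader"].sum()) == 1
        inv = table[table["is_invader"]].iloc[0]
        assert inv["persistence"] == manifest["persistence"]
        assert ((table["persistence"] >= 0)
                & (table["persistence"] <= pair.cap)).all()


class TestExcessPersistenceTest:
    def test_zero_successes_gives_one(self):
        assert excess_persistence_test(0, 10, 0.5) == 1.0

    def test_all_successes_closed_form(self):
        assert excess_persistence_test(10, 10, 0.5) == pytest.approx(2**-10)

    def test_matches_exhaustive_pmf_summation(self):
        k, n, q = 5, 12, 0.054
        brute = sum(sps.binom.pmf(i, n, q) for i in range(k, n + 1))
        assert excess_persistence_test(k, n, q) == pytest.approx(brute, rel=1e-12)

    @pytest.mark.parametrize("n,q", [(5, 0.3), (12, 0.054), (20, 0.7)])
    def test_tail_coherence_with_cdf(self, n, q):
        previous = np.inf
        for k in range(0, n + 1):
            p = excess_persistence_test(k, n, q)
            assert p == pytest.approx(sps.binom.sf(k - 1, n, q), rel=1e-10)
            assert p <= previous + 1e-15  # non-increasing in k
            previous = p

    def test_log_output_handles_astronomical_tails(self):
        logp = excess_persistence_test(748, 748, 0.054, log=True)
        assert logp < -1000
        assert np.isfinite(logp)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            excess_persistence_test(1, 10, 1.5)
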