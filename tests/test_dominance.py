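"""Dominance indices: David's Scores, Elo optimisation, standardisations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rankverse as rv
from rankverse.dominance import EloState, WinsMatrix, elo_ratings_at


def _brute_force_davids(w: np.ndarray) -> np.ndarray:
    """Step-by-step spreadsheet-style oracle for normalised David's Scores."""
    n = len(w)
    dij = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            nij = w[i, j] + w[j, i]
            pij = w[i, j] / nij if nij > 0 else 0.5
            dij[i, j] = pij - (pij - 0.5) / (nij + 1)
    w1 = dij.sum(axis=1)
    l1 = dij.sum(axis=0)
    w2 = np.array([sum(dij[i, j] * w1[j] for j in range(n)) for i in range(n)])
    l2 = np.array([sum(dij[j, i] * l1[j] for j in range(n)) for i in range(n)])
    ds = w1 + w2 - l1 - l2
    return (ds + n * (n - 1) / 2) / n


class TestWinsMatrix:
    def test_empty_log_gives_zero_matrix(self):
        events = pd.DataFrame({"winner": [], "loser": []})
        wm = rv.build_wins_matrix(events, ["A", "B", "C"])
        assert wm.w.sum() == 0

    def test_single_event(self):
        events = pd.DataFrame({"winner": ["A"], "loser": ["B"]})
        wm = rv.build_wins_matrix(events, ["A", "B"])
        assert wm.w[0, 1] == 1 and wm.w.sum() == 1

    def test_event_conservation(self, small_group):
        scale = rv.tune_upset_scale(small_group, 0.01)
        ev = rv.simulate_supplant_sequence(small_group, 818, upset_prob_scale=scale, seed=3)
        wm = rv.build_wins_matrix(ev, sorted(small_group["id"].unique()))
        assert wm.w.sum() == 818

    def test_unknown_id_named_in_error(self):
        events = pd.DataFrame({"winner": ["X"], "loser": ["B"]})
        with pytest.raises(KeyError, match="X"):
            rv.build_wins_matrix(events, ["A", "B"])


class TestDavidsScores:
    def test_all_tied_dyads_equal_scores(self):
        n = 4
        w = np.full((n, n), 3.0)
        np.fill_diagonal(w, 0)
        scores = rv.davids_scores(WinsMatrix(ids=list("ABCD"), w=w))
        assert np.allclose(scores, (n - 1) / 2)

    def test_two_individuals_sum_and_order(self):
        w = np.array([[0, 5], [0, 0]], float)
        scores = rv.davids_scores(WinsMatrix(ids=["A", "B"], w=w))
        assert scores.sum() == pytest.approx(1.0)
        assert scores["A"] > scores["B"]

    def test_three_individual_oracle(self):
        w = np.array([[0, 3, 2], [1, 0, 4], [0, 1, 0]], float)
        scores = rv.davids_scores(WinsMatrix(ids=list("ABC"), w=w))
        assert np.allclose(scores.to_numpy(), _brute_force_davids(w))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 7))
    def test_matches_oracle_and_invariants(self, seed, n):
        rng = np.random.default_rng(seed)
        w = rng.integers(0, 6, size=(n, n)).astype(float)
        np.fill_diagonal(w, 0)
        scores = rv.davids_scores(WinsMatrix(ids=[str(i) for i in range(n)], w=w))
        assert np.allclose(scores.to_numpy(), _brute_force_davids(w))
        assert scores.sum() == pytest.approx(n * (n - 1) / 2)
        assert scores.min() >= 0 and scores.max() <= n - 1

    def test_rejects_single_individual(self):
        with pytest.raises(ValueError):
            rv.davids_scores(WinsMatrix(ids=["A"], w=np.zeros((1, 1))))


class TestElo:
    def test_k_zero_ratings_constant(self):
        ev = pd.DataFrame({"winner": list("ABAB"), "loser": list("BABA"),
                           "date": pd.date_range("2020-01-01", periods=4)})
        state = EloState(ids=["A", "B"], k=0.0, start_values=np.array([10.0, -10.0]))
        traj = rv.elo_trajectory(ev, state)
        assert (traj["A"] == 10.0).all() and (traj["B"] == -10.0).all()

    def test_equal_start_single_event_split(self):
        ev = pd.DataFrame({"winner": ["A"], "loser": ["B"]})
        state = EloState(ids=["A", "B"], k=100.0)
        traj = rv.elo_trajectory(ev, state)
        # p = 0.5 forced by equal ratings, update = k (1 - p)
        assert traj.loc[0, "A"] == pytest.approx(50.0)
        assert traj.loc[0, "B"] == pytest.approx(-50.0)

    def test_rating_sum_conserved(self):
        rng = np.random.default_rng(0)
        ids = list("ABCDE")
        ev = pd.DataFrame({
            "winner": rng.choice(ids, 100),
            "loser": rng.choice(ids, 100),
        })
        ev = ev[ev.winner != ev.loser]
        start = rng.normal(0, 5, 5)
        state = EloState(ids=ids, k=32.0, start_values=start)
        traj = rv.elo_trajectory(ev, state)
        assert np.allclose(traj.sum(axis=1), start.sum())

    def test_unordered_dates_rejected(self):
        ev = pd.DataFrame({"winner": ["A", "B"], "loser": ["B", "A"],
                           "date": ["2020-02-01", "2020-01-01"]})
        with pytest.raises(ValueError):
            rv.elo_trajectory(ev, EloState(ids=["A", "B"], k=10.0))

    def test_query_date_returns_prior_ratings(self):
        ev = pd.DataFrame({"winner": ["A"], "loser": ["B"],
                           "date": ["2020-06-01"]})
        state = EloState(ids=["A", "B"], k=100.0)
        before = elo_ratings_at(ev, state, "2020-01-01")
        after = elo_ratings_at(ev, state, "2020-12-31")
        assert (before == 0.0).all()
        assert after["A"] == pytest.approx(50.0)


class TestOptimizeElo:
    def test_static_hierarchy_selects_k_zero(self, small_group):
        scale = rv.tune_upset_scale(small_group, 0.02)
        ev = rv.simulate_supplant_sequence(small_group, 300, upset_prob_scale=scale, seed=5)
        res = rv.optimize_elo(ev, k_grid=(0.0, 20.0, 60.0, 120.0))
        assert res["k"] == 0.0
        # grid optimality: selected k maximises the profile
        prof = res["profile"].set_index("k")["loglik"]
        assert prof.loc[res["k"]] == pytest.approx(prof.max())

    def test_single_event_tie_breaks_to_zero(self):
        ev = pd.DataFrame({"winner": ["A"], "loser": ["B"]})
        res = rv.optimize_elo(ev, k_grid=(0.0, 50.0, 100.0))
        assert res["k"] == 0.0

    def test_rank_reversals_detected_as_dynamics(self):
        # mid-sequence reversal of the hierarchy: k > 0 should win mostly
        ids = list("ABCDEF")
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            first = [(a, b) for _ in range(60)
                     for a, b in [sorted(rng.choice(6, 2, replace=False))]]
            second = [(b, a) for _ in range(60)
                      for a, b in [sorted(rng.choice(6, 2, replace=False))]]
            ev = pd.DataFrame(
                {"winner": [ids[a] for a, b in first] + [ids[a] for a, b in second],
                 "loser": [ids[b] for a, b in first] + [ids[b] for a, b in second]})
            res = rv.optimize_elo(ev, ids=ids, k_grid=(0.0, 10.0, 25.0, 50.0, 100.0))
            hits += res["k"] > 0
        assert hits >= 3

    def test_indices_recover_latent_order(self, small_group):
        # with n_events >= 20 N on a static hierarchy, the ordinal ranks from
        # both indices should match the latent order in nearly all replicates
        latent = small_group[small_group["year"] == 1].set_index("id")["latent_score"]
        order_true = latent.sort_values(ascending=False).index.tolist()
        scale = rv.tune_upset_scale(small_group, 0.007)
        ok = 0
        for rep in range(10):
            ev = rv.simulate_supplant_sequence(
                small_group, 400, upset_prob_scale=scale, seed=600 + rep)
            elo = rv.optimize_elo(ev, k_grid=(0.0,))["start_values"]
            wins = rv.build_wins_matrix(ev, sorted(latent.index))
            davids = rv.davids_scores(wins)
            ok += (elo.sort_values(ascending=False).index.tolist() == order_true
                   and davids.sort_values(ascending=False).index.tolist() == order_true)
        assert ok >= 9


class TestStandardise:
    def test_examples(self):
        vals = pd.Series({"A": 3.2, "B": 1.1})
        assert rv.standardise(vals, "ordinal").tolist() == [1, 2]
        assert rv.standardise(vals, "proportional").tolist() == [1.0, 0.0]

    def test_ordinal_proportional_exact_anticorrelation(self):
        rng = np.random.default_rng(3)
        vals = pd.Series(rng.normal(0, 100, 18))
        o = rv.standardise(vals, "ordinal").to_numpy(float)
        p = rv.standardise(vals, "proportional").to_numpy()
        assert np.corrcoef(o, p)[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_proportional_is_affine_in_ordinal(self):
        vals = pd.Series([5.0, 2.0, 9.0, -1.0])
        n = len(vals)
        o = rv.standardise(vals, "ordinal").to_numpy()
        p = rv.standardise(vals, "proportional").to_numpy()
        assert np.allclose(p, (n - o) / (n - 1))

    def test_sorting_consistency(self):
        vals = pd.Series([0.3, 2.2, -5.0, 1.4])
        o = rv.standardise(vals, "ordinal")
        assert vals.iloc[np.argsort(o.to_numpy())].is_monotonic_decreasing

    def test_ties_warn_and_break_by_id_order(self):
        vals = pd.Series({"A": 1.0, "B": 1.0, "C": 0.5})
        with pytest.warns(UserWarning, match="tied"):
            o = rv.standardise(vals, "ordinal")
        assert o.tolist() == [1, 2, 3]

    def test_single_individual_rejected(self):
        with pytest.raises(ValueError):
            rv.standardise(pd.Series([1.0]), "proportional")


class TestZStandardise:
    def test_mean_zero_unit_sd(self):
        z = rv.z_standardise([0.0, 1.0])
        assert z.mean() == pytest.approx(0.0) and z.std() == pytest.approx(1.0)

    def test_idempotence(self):
        x = np.array([3.0, -1.0, 4.5, 0.2])
        assert np.allclose(rv.z_standardise(rv.z_standardise(x)), rv.z_standardise(x))

    def test_equidistant_18_max(self):
        # closed form: max |z| of an equidistant sequence of length N is
        # (N-1)/2 / sqrt((N^2-1)/12)
        n = 18
        z = rv.z_standardise(np.linspace(0, 1, n))
        expected = (n - 1) / 2 / np.sqrt((n**2 - 1) / 12)
        assert z.max() == pytest.approx(expected, abs=1e-12)
        assert z.max() == pytest.approx(1.65, abs=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            rv.z_standardise([2.0, 2.0, 2.0])


class TestAgainstHierarchyRate:
    def test_six_of_818_prints_0_7_percent(self):
        ranks = pd.Series({f"i{k}": k for k in range(1, 11)})
        winners, losers = [], []
        for e in range(818):
            if e < 6:  # counter-hierarchy: lower-ranking individual wins
                winners.append("i10"); losers.append("i1")
            else:
                winners.append("i1"); losers.append("i2")
        ev = pd.DataFrame({"winner": winners, "loser": losers})
        rate = rv.against_hierarchy_rate(ev, ranks)
        assert round(100 * rate, 1) == 0.7

    def test_consistent_and_reversed_logs(self):
        ranks = pd.Series({"A": 1, "B": 2})
        ev = pd.DataFrame({"winner": ["A"] * 10, "loser": ["B"] * 10})
        assert rv.against_hierarchy_rate(ev, ranks) == 0.0
        rev = pd.DataFrame({"winner": ["B"] * 10, "loser": ["A"] * 10})
        assert rv.against_hierarchy_rate(rev, ranks) == 1.0

    def test_unranked_participant_rejected(self):
        ev = pd.DataFrame({"winner": ["A"], "loser": ["Z"]})
        with pytest.raises(KeyError, match="Z"):
            rv.against_hierarchy_rate(ev, pd.Series({"A": 1, "B": 2}))
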