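"""Synthetic generator: determinism, completeness, symmetry, distributions."""

import numpy as np
import pandas as pd
import pytest

import rankverse as rv


class TestSimulateGroup:
    def test_top_individual_has_proportional_rank_one(self):
        g = rv.simulate_group(rv.GroupConfig(n_individuals=3, n_years=1,
                                             latent_scores=[10.0, 5.0, 1.0]))
        top = g.loc[g["latent_score"].idxmax()]
        assert top["prop_rank"] == 1.0 and top["ordinal"] == 1

    def test_determinism(self):
        a = rv.simulate_group(rv.GroupConfig(seed=42))
        b = rv.simulate_group(rv.GroupConfig(seed=42))
        pd.testing.assert_frame_equal(a, b)

    def test_dyad_count_18_individuals(self):
        g = rv.simulate_group(rv.GroupConfig(n_individuals=18, n_years=3, seed=0))
        mech = rv.MechanismConfig(behaviour="aggression", family="zip",
                                  zero_inflation=0.3)
        tab = rv.simulate_dyadic_counts(g, mech, seed=1)
        per_year = tab.groupby("year").size()
        assert (per_year == 18 * 17).all()

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            rv.GroupConfig(n_individuals=2)

    def test_scores_must_decrease(self):
        with pytest.raises(ValueError):
            rv.GroupConfig(n_individuals=3, latent_scores=[1.0, 2.0, 3.0])


class TestSupplantSequence:
    def test_deterministic_hierarchy_no_upsets(self, small_group):
        ev = rv.simulate_supplant_sequence(small_group, 500,
                                           upset_prob_scale=1e-9, seed=1)
        ranks = small_group[small_group["year"] == 1].set_index("id")["ordinal"]
        assert rv.against_hierarchy_rate(ev, ranks) == 0.0

    def test_coin_flip_limit(self, small_group):
        ev = rv.simulate_supplant_sequence(small_group, 4000,
                                           upset_prob_scale=1e9, seed=2)
        ranks = small_group[small_group["year"] == 1].set_index("id")["ordinal"]
        assert rv.against_hierarchy_rate(ev, ranks) == pytest.approx(0.5, abs=0.03)

    def test_tuned_scale_hits_target_upset_rate(self):
        # the regime of a strictly linear hierarchy: ~6 upsets in 818 events
        g = rv.simulate_group(rv.GroupConfig(n_individuals=18, n_years=1, seed=0))
        scale = rv.tune_upset_scale(g, 6 / 818)
        ranks = g[g["year"] == 1].set_index("id")["ordinal"]
        rates = []
        for rep in range(20):
            ev = rv.simulate_supplant_sequence(g, 818, upset_prob_scale=scale,
                                               seed=900 + rep)
            rates.append(rv.against_hierarchy_rate(ev, ranks))
        # mean within 3 binomial SEs of 6/818
        p = 6 / 818
        se = np.sqrt(p * (1 - p) / (818 * 20))
        assert abs(np.mean(rates) - p) < 3 * se

    def test_dates_strictly_increasing_and_deterministic(self, small_group):
        a = rv.simulate_supplant_sequence(small_group, 50, seed=5)
        b = rv.simulate_supplant_sequence(small_group, 50, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert a["date"].is_monotonic_increasing
        assert a["date"].nunique() == 50


class TestDyadicCounts:
    def test_poisson_mean_with_no_effects(self):
        # all effects zero, lambda * effort = 3 -> sample mean tends to 3
        g = rv.simulate_group(rv.GroupConfig(n_individuals=18, n_years=3, seed=1))
        mech = rv.MechanismConfig(
            behaviour="proximity", family="poisson",
            baseline_log_rate=np.log(3.0), effort_log_mean=0.0, effort_log_sd=0.0,
        )
        tab = rv.simulate_dyadic_counts(g, mech, seed=2)
        assert tab["count"].mean() == pytest.approx(3.0, abs=0.15)

    def test_zero_inflation_fraction(self):
        g = rv.simulate_group(rv.GroupConfig(n_individuals=18, n_years=3, seed=1))
        mech = rv.MechanismConfig(
            behaviour="aggression", family="zip", baseline_log_rate=np.log(30.0),
            zero_inflation=0.5, effort_log_mean=0.0, effort_log_sd=0.0,
        )
        tab = rv.simulate_dyadic_counts(g, mech, seed=3)
        assert (tab["count"] == 0).mean() == pytest.approx(0.5, abs=0.04)

    def test_dth_rate_ratio_monte_carlo(self):
        # dth_effect = 1.5 and nothing else: mean count for sender-outranks
        # dyads over other dyads converges to e^1.5
        g = rv.simulate_group(rv.GroupConfig(n_individuals=18, n_years=3, seed=1))
        mech = rv.MechanismConfig(
            behaviour="aggression", family="zip", baseline_log_rate=np.log(4.0),
            dth_effect=1.5, effort_log_mean=0.0, effort_log_sd=0.0,
        )
        frames = [rv.simulate_dyadic_counts(g, mech, seed=s) for s in range(8)]
        tab = pd.concat(frames)
        rank = g[g["year"] == 1].set_index("id")["prop_rank"]
        outranks = rank.loc[tab["sender"]].to_numpy() > rank.loc[tab["receiver"]].to_numpy()
        ratio = tab["count"][outranks].mean() / tab["count"][~outranks].mean()
        assert ratio == pytest.approx(np.exp(1.5), rel=0.05)

    def test_proximity_symmetry_exact(self):
        g = rv.simulate_group(rv.GroupConfig(n_individuals=12, n_years=2, seed=4))
        mech = rv.default_mechanism("proximity")
        tab = rv.simulate_dyadic_counts(g, mech, seed=5)
        merged = tab.merge(
            tab, left_on=["sender", "receiver", "year"],
            right_on=["receiver", "sender", "year"], suffixes=("", "_rev"),
        )
        assert (merged["count"] == merged["count_rev"]).all()
        assert (merged["effort_hours"] == merged["effort_hours_rev"]).all()

    def test_zinb_overdispersed_poisson_not(self):
        g = rv.simulate_group(rv.GroupConfig(n_individuals=18, n_years=3, seed=1))
        base = dict(baseline_log_rate=np.log(5.0), effort_log_mean=0.0,
                    effort_log_sd=0.0)
        pois = pd.concat([
            rv.simulate_dyadic_counts(
                g, rv.MechanismConfig(behaviour="proximity", family="poisson",
                                      **base), seed=s)
            for s in range(4)
        ])
        nb = rv.simulate_dyadic_counts(
            g, rv.MechanismConfig(behaviour="grooming", family="zinb",
                                  nb_dispersion=0.8, **base), seed=6)
        assert pois["count"].var() / pois["count"].mean() == pytest.approx(1.0, abs=0.12)
        assert nb["count"].var() / nb["count"].mean() > 2.0

    def test_counts_deterministic_given_seed(self, small_group):
        mech = rv.default_mechanism("grooming")
        a = rv.simulate_dyadic_counts(small_group, mech, seed=9)
        b = rv.simulate_dyadic_counts(small_group, mech, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_nb_dispersion_with_poisson_rejected(self):
        with pytest.raises(ValueError):
            rv.MechanismConfig(behaviour="proximity", family="poisson",
                               nb_dispersion=2.0)

    def test_directional_effects_on_proximity_rejected(self):
        with pytest.raises(ValueError):
            rv.MechanismConfig(behaviour="proximity", family="poisson",
                               dth_effect=1.0)


def test_simulate_study_shapes():
    study = rv.simulate_study(rv.GroupConfig(n_individuals=8, n_years=2, seed=3),
                              n_supplants_per_year=50)
    assert set(study["counts"]["behaviour"]) == set(rv.BEHAVIOURS)
    assert len(study["events"]) == 100
    # completeness: every ordered pair, every behaviour, every year
    assert len(study["counts"]) == 4 * 2 * 8 * 7
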