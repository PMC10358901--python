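"""Fit one Bayesian zero-inflated mixed model and read its results.

Fits the higher-/lower-ranking factor specification to synthetic aggression
counts: a zero-inflated Poisson with sender rank and an indicator for the
sender outranking the receiver, crossed random effects for sender, receiver
and dyad, and the log observation effort as offset.
"""

import rankverse as rv

group = rv.simulate_group(rv.GroupConfig(n_individuals=12, n_years=1, seed=4))
mech = rv.MechanismConfig(behaviour="aggression", family="zip",
                          baseline_log_rate=-2.0, sender_effect=0.8,
                          dth_effect=1.5, zero_inflation=0.3,
                          re_sd_sender=0.2, re_sd_receiver=0.2, re_sd_dyad=0.2)
counts = rv.simulate_dyadic_counts(group, mech, seed=5)

scale = rv.tune_upset_scale(group, 0.007)
events = rv.simulate_supplant_sequence(group, 250, upset_prob_scale=scale, seed=6)
ranks = rv.compute_rank_tables(events, rv.MultiverseConfig(elo_k_grid=(0.0,)))

spec = rv.ModelSpec("factor_higher", behaviour="aggression", index="elo",
                    standardisation="raw")
design = rv.build_design(counts, ranks, spec)
fit = rv.fit_model(design, counts["count"].to_numpy(), rv.FamilySpec("zip"),
                   method="map", seed=7)

print(fit.fixed_effect_summaries.round(3))
print("sender_higher is the log rate ratio for attacking down the hierarchy; "
      f"the generating value was {mech.dth_effect}.")
print(f"posterior mean structural-zero probability pi = {fit.pi.mean():.2f} "
      f"(generated with {mech.zero_inflation})")

loo = rv.psis_loo(fit.pointwise_loglik)
r2 = rv.bayes_r2(fit)
print(f"LOO-IC = {loo.looic:.1f} (SE {2 * loo.se:.1f}); "
      f"Bayesian R^2 median = {r2['median']:.2f}")
arrow = rv.classify_effect(fit.coef_draws("rank_sender"), "raw")
print(f"sender-rank arrow: {arrow} (meaningful only if the 95% credible "
      "interval excludes 0)")
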