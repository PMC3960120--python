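"""How sensitive are these 24-trial designs? Type-I error and power.

Type-I error: how often the Experiment-1 first-attempt binomial rejects at
alpha = 0.05 when the agent is truly at chance (discrete exact tests are
conservative, so this sits below 0.05). Power: rejection rate against
knower agents of increasing accuracy theta — even a theta = 0.6 knower is
missed most of the time at n = 24, which is why single-subject designs need
the Monte-Carlo overall statistic as well.
"""

from fetchstats import estimate_type1, power_curve

t1 = estimate_type1("exp1_first_binomial", alpha=0.05, n_reps=500, seed=3)
print(f"type-I error at alpha=0.05: {t1.rejection_rate:.3f} (se {t1.mc_se:.3f})")

for est in power_curve("exp1_first_binomial", [0.4, 0.6, 0.8, 1.0],
                       alpha=0.05, n_reps=300, seed=3):
    print(f"power vs knower theta={est.theta:.1f}: "
          f"{est.rejection_rate:.3f} (se {est.mc_se:.3f})")
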