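"""Exact binomial tails and the 2x2 chi-square, under explicit conventions.

Small-N forced-choice reports mix one-tailed values (the smaller exact
tail) with two-tailed values (twice the smaller tail, capped at 1). The
same count can therefore carry two different printed p-values; this script
shows both for 12/24 successes at the 3-alternative chance level, and the
pair-asymmetry chi-square for 6/12 vs 1/12 correct retrievals.
"""

from fetchstats import binom_pvalue, chisq2x2

one = binom_pvalue(12, 24, 0.33, tail="smaller")
two = binom_pvalue(12, 24, 0.33, tail="two_sided_double")
print(f"12/24 at chance .33: one-tailed p = {one.p_value:.4f}, "
      f"two-tailed p = {two.p_value:.4f}")
print("(the same count: .063 one-tailed is .126 after tail doubling)")

capped = binom_pvalue(6, 12, 0.5, tail="two_sided_double")
print(f"6/12 at chance .5, two-tailed: p = {capped.p_value:.4f} (doubling caps at 1)")

chi = chisq2x2(6, 6, 1, 11)
print(f"pair A 6/12 vs pair B 1/12 correct: chi2 = {chi.statistic:.3f}, "
      f"df = {chi.df}, p = {chi.p_value:.4f}")
print("a significant asymmetry: the first-introduced pair was learned better.")
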