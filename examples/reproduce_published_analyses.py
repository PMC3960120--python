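"""Re-run every packaged analysis end-to-end from trial-level records.

The fixture reconstructs each dog's trials from the published counts; the
pipeline then recomputes every statistic (Monte-Carlo, binomial, chi-square)
under the documented conventions and prints one row per test.
"""

from fetchstats.pipeline import render_reports_csv, run_paper_reproduction

reports = run_paper_reproduction(n_sims=10_000, seed=20140319)
print(render_reports_csv(list(reports.values())))
print("# each row: one test from one subject's analysis; p_value is exact")
print("# for binomial/chi-square rows and simulation-based for monte_carlo rows")
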