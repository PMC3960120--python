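"""Agent-based simulation of the occlusion design (28 trials, 2 objects).

A referential "knower" maps the label to its referent whether or not the
referent was visible during naming; an "associative" learner maps the label
to whatever it saw, so it fails exactly when the target was occluded. The
two strategies are indistinguishable overall only for the associative agent
(about 50% correct); splitting by condition separates them cleanly.
"""

from fetchstats import AgentSpec, design_for, simulate, summarize_subject

design = design_for("exp3")
for name, agent in [
    ("random", AgentSpec(kind="random")),
    ("knower theta=0.9", AgentSpec(kind="knower", theta=0.9)),
    ("associative theta=0.9", AgentSpec(kind="associative", theta=0.9)),
]:
    records = simulate("exp3", agent, design, seed=11, subject_id="sim")
    s = summarize_subject(records, design)
    print(f"{name:24s} overall {s.overall_correct:2d}/28   "
          f"target visible {s.per_condition_correct.get('target_open', 0):2d}/14   "
          f"target occluded {s.per_condition_correct.get('target_occluded', 0):2d}/14")
print("the associative agent collapses to near 0/14 when the target was")
print("occluded during naming — the signature that separates association")
print("from referential word learning.")
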