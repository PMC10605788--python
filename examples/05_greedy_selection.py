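"""Greedy signal-group selection with a planted informative group.

Uses a cohort where only the magnetometer family carries surface
information and shows that round 1 of the sequential forward search
recovers it; every other group scores near the 1/9 chance level.

Runs seven short trainings (~half a minute on one CPU core).
"""

import gaitsurf as g
from gaitsurf.selection import greedy_signal_selection, make_holdout_evaluator

cfg = g.planted_mag_config(n_participants=4, trials_per_condition=1, seed=11)
cohort = g.filter_dataset(g.simulate_cohort(cfg))

config = g.TrainConfig(epochs=8, patience_stop=4, patience_lr=2, seed=11)
evaluator = make_holdout_evaluator(cohort, config, n_folds=4)
selected, trace, records = greedy_signal_selection(
    (g.Site.shankL, g.Site.shankR), 100, evaluator)

print("round 1 (each group alone, shank pair, L=100):")
for cand, acc in zip(trace.rounds[0].candidates, trace.rounds[0].accuracies):
    marker = "  <- selected" if cand == trace.rounds[0].accepted else ""
    print(f"  {cand[0]:>7}: {acc:.3f}{marker}")
print(f"\nselected set after the search: {selected}")
print(f"evaluations spent: {trace.n_evaluations}")
# Only Mag rises above chance (~0.11) because the planted cohort encodes
# the surface solely in the magnetic-field direction.
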