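"""Differential item functioning screen between gender groups.

Injects a uniform threshold shift into one item for the focal group,
calibrates empirical critical values by Monte-Carlo simulation, and runs
the iterative purification screen — the injected item should be the one
flagged.
"""

import numpy as np

from caremirt import sample_responses, sample_thetas
from caremirt.cohort import DIFInjection, default_true_params, inject_dif
from caremirt.dif import dif_impact, monte_carlo_thresholds, purify
from caremirt.mgrm import ItemResponseMatrix

truth = default_true_params()
ref, foc = inject_dif(truth, DIFInjection(item=2, uniform_shift=0.6))

thetas = sample_thetas(800, 0.5, 5)
data = ItemResponseMatrix(np.vstack([
    sample_responses(ref, thetas[:400], 6).values,
    sample_responses(foc, thetas[400:], 7).values,
]))
group = np.repeat(["female", "man"], 400)

thresholds = monte_carlo_thresholds(truth, (400, 400), n_sims=150, seed=8)
result = purify(data, truth, group, thresholds=thresholds)
print(result.table[["item", "lr_uniform", "lr_nonuniform",
                    "flag_uniform", "flag_nonuniform"]].round(2).to_string(index=False))
print(f"\nflagged: {result.flagged_items('any')} "
      f"(item03 carries the injected 0.6 threshold shift)")

grid = np.column_stack([np.linspace(-3, 3, 25)] * 2)
impact = dif_impact(ref, foc, grid)
print(f"max expected-score impact: {impact['score_difference'].abs().max():.2f} points "
      f"({impact['impact_theta'].abs().max():.3f} theta units)")
# A single shifted item moves the total expected score by well under one
# point — item-level DIF with negligible test-level impact.
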