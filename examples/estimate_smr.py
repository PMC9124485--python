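"""Estimate SMR by extrapolating oxygen uptake to zero activity.

Simulates paired (activity, MO2) measurement intervals for a small fish
population during acute cooling, fits MO2 = a * e^(b * activity) per fish
and temperature, and prints the extrapolated SMR (the intercept a)
alongside the generator's ground truth.
"""

import pandas as pd

from winterq import SyntheticConfig, generate_pairs, smr_individual, true_smr
from winterq.synthetic import FishTruth

cfg = SyntheticConfig(n_fish=4, seed=42)
pairs, truth = generate_pairs(cfg)
fish = {r.fish_id: FishTruth(r.fish_id, r.smr_ref_i, r.b_i, r.mass_kg,
                             r.total_length_cm) for r in truth.itertuples()}

print(f"{'fish':8} {'condition':14} {'SMR est':>8} {'SMR true':>9}  note")
for est in smr_individual(pairs):
    if not est.condition.startswith("acute"):
        continue
    expected = true_smr(fish[est.scope], est.temp_c, cfg)
    note = "fallback" if "fallback" in est.provenance else "extrapolated"
    print(f"{est.scope:8} {est.condition:14} {est.value:8.1f} {expected:9.1f}  {note}")

print("\nSMR est is the y-intercept of the per-fish exponential fit "
      "(mg O2 kg^-1 h^-1); at cold temperatures fish are nearly inactive, "
      "the activity spread shrinks, and the estimator falls back to the "
      "mean of the lowest-20 MO2 values.")
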