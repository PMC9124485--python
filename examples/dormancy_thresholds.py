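"""Find the temperature at which behaviour reaches its cold steady state.

Simulates a slow-cooling (1 degC day^-1 style) behaviour trial for 16
fish whose activity collapses steeply around 7 degC, then detects, per
behavioural metric, the warmest temperature at which further cooling no
longer changes behaviour relative to the coldest temperature (within-fish
paired tests vs the coldest temperature, Bonferroni-adjusted), plus the
mean temperature at which individual fish stop feeding.
"""

from winterq import SyntheticConfig, run_cooling_behaviour

cfg = SyntheticConfig(n_fish=16, dormancy_midpoint_c=7.0,
                      dormancy_steepness=8.0, activity_noise_floor=0.1,
                      seed=0)
bundle = run_cooling_behaviour(cfg=cfg, zero_tol=0.05)

print("cold steady states (threshold = warmest temperature of the steady range):")
for (metric, phase), res in sorted(bundle["steady_states"].items()):
    t = res.threshold_temp_c
    txt = f"<= {t:g} degC" if t is not None else "none detected"
    print(f"  {metric:18} {phase:6} {txt}")

print("\nmean transition temperatures (first persistent zero during cooling):")
for metric, res in bundle["transitions"].items():
    if res.n_transitioned:
        print(f"  {metric:9} {res.mean_temp_c:.2f} +/- {res.sem:.2f} degC "
              f"({res.n_transitioned}/{res.n_total} fish)")
    else:
        print(f"  {metric:9} population did not transition (0/{res.n_total})")

print("\nThe configured activity collapse is centred at 7 degC; the detector "
      "places the steady state one cooling step below the midpoint, where "
      "behaviour first becomes statistically flat.")
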