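"""Does cooling merely slow metabolism, or is it actively depressed?

Runs the full study twice on synthetic fish: once purely passive (SMR
follows a Q10 = 2.5 Arrhenius decline) and once with a 40% active
suppression of SMR below 8 degC (metabolic rate depression, MRD).  The
mean per-fish Q10 of extrapolated SMR over the full cooling interval
lands below the 3.5 inference threshold in the passive case and above it
when suppression is injected.
"""

from winterq import SyntheticConfig, run_respirometry_study, with_mrd

passive = SyntheticConfig(seed=1)
suppressed = with_mrd(passive, threshold_c=8.0, suppression=0.40)

for name, cfg in (("passive physiology", passive),
                  ("40% SMR suppression below 8 degC", suppressed)):
    bundle = run_respirometry_study(cfg=cfg, band=None)
    print(f"--- {name} ---")
    for label in ("full_cooling", "warm_half", "cold_half"):
        v = bundle["verdicts"][label]
        print(f"  {v['text']}")
    print()

print("A Q10 of ~2-3 reflects passive physicochemical slowing; the "
      "suppressed scenario inflates the full-interval Q10 to ~4 because "
      "SMR drops by more than temperature alone explains.")
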