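# winterq

Activity-controlled metabolic rate analysis for overwintering fishes.

Temperate fishes overwinter with strikingly low metabolic rates. The
open question for any given species is *why*: is resting metabolism
actively suppressed (metabolic rate depression, MRD, the ectotherm
analogue of hibernation), or does the animal simply stop moving while
cold slows its standard metabolic rate (SMR) through ordinary Arrhenius
physics? The distinction matters because spontaneous activity both
elevates oxygen uptake and itself declines with cooling — uncontrolled
comparisons of metabolic rate across temperatures therefore mimic MRD.

`winterq` is a library for physiologists running (or simulating)
cooling experiments with intermittent-closed respirometry and
simultaneous activity recording. It provides:

- **respirometry**: closed-period slope extraction (5-min equilibration
  exclusion), blank correction, `MO2 = (blank − raw) · V_eff / mass`;
- **behavior**: activity in body lengths min⁻¹, inactive-control
  subtraction, sheltering, vigilance and feeding reduction with
  half-open day/night clock windows;
- **smr**: SMR at each temperature by exponential extrapolation to zero
  activity (y = a·e^(bx), a = SMR), lowest-20 subsets, and
  activity-band-controlled means, with the documented fallback rules;
- **thermal**: Q10 = (r_cold/r_warm)^(10/(T_cold−T_warm)) per fish and
  interval, MRD classification against the conventional strict 3.5
  threshold, and Arrhenius (ln SMR vs 1/T_K) breakpoint detection;
- **dormancy**: behavioural dormancy thresholds as cold steady states
  (within-fish paired contrasts vs the coldest temperature, Bonferroni
  adjusted) and mean inactive/fasting transition temperatures;
- **synthetic**: a seeded generator of fish populations, paired
  activity/MO2 intervals, behaviour trials and raw oxygen traces with
  stored ground truth, so the full chain is testable end to end.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

`examples/mrd_detection.py` simulates 12 fish cooled from 14 to 2.5 °C
(true SMR Q10 = 2.5, activity exponentially coupled to oxygen uptake and
damped by cooling), estimates per-fish SMR by extrapolation at each
temperature, and classifies the thermal sensitivity — then repeats with
a 40% active suppression of SMR injected below 8 °C:

```
--- passive physiology ---
  full_cooling [extrapolated_individual]: mean Q10 = 2.63 +/- 0.03 (n=12); passive thermal effects (threshold 3.5); 0% of fish above threshold
  warm_half [extrapolated_individual]: mean Q10 = 2.57 +/- 0.05 (n=12); passive thermal effects (threshold 3.5); 0% of fish above threshold
  cold_half [extrapolated_individual]: mean Q10 = 2.70 +/- 0.07 (n=12); passive thermal effects (threshold 3.5); 0% of fish above threshold

--- 40% SMR suppression below 8 degC ---
  full_cooling [extrapolated_individual]: mean Q10 = 4.10 +/- 0.05 (n=12); MRD inferred (threshold 3.5); 100% of fish above threshold
  warm_half [extrapolated_individual]: mean Q10 = 2.57 +/- 0.05 (n=12); passive thermal effects (threshold 3.5); 0% of fish above threshold
  cold_half [extrapolated_individual]: mean Q10 = 6.85 +/- 0.17 (n=12); MRD inferred (threshold 3.5); 100% of fish above threshold
```

The passive scenario recovers a mean Q10 near the configured 2.5 — below
the 3.5 MRD-inference threshold — while the suppressed scenario exceeds
it over every interval that straddles the 8 °C suppression threshold
(and only those: the warm half stays passive). The other examples cover
SMR estimation against ground truth (`estimate_smr.py`), raw-trace
reduction (`respirometry_trace.py`) and behavioural dormancy thresholds
(`dormancy_thresholds.py`).

A thin CLI wraps the same pipelines:

```sh
winterq simulate --seed 1 --kind pairs --out pairs.csv
winterq run-exp2 --pairs pairs.csv --seed 1 --band 0.8:1.8 --outdir results/
winterq run-exp1 --seed 1 --outdir behaviour/
```

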