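# cardiomet

**Heart-rate telemetry to energetics for small endotherms.**

Small tropical bats and other lowland-tropical mammals can enter torpor-like
low-energy states while their body temperature stays high, because ambient
temperature leaves little room for the classic body-temperature drop.  In
that regime heart rate (f_H), not body temperature (T_b), is the informative
proxy for metabolic rate (MR).  `cardiomet` implements the full analysis
chain needed to exploit that fact:

1. **Heartbeat detection** — a heart-rate radio transmitter emits a
   continuous carrier that each cardiac muscle potential briefly interrupts.
   The detector band-limits the received audio with a linear-phase FIR
   filter (1500–2000 taps), counts envelope interruptions over
   non-overlapping 500-sample windows (96 windows s⁻¹ at 48 kHz), converts
   counts to bpm, and rejects static-induced outliers with a kernel-density
   90%-quantile filter.
2. **Open-flow respirometry** — excurrent/incurrent gas fractions to CO₂
   production, V̇CO₂ = (FeCO₂ − FiCO₂)·FR / (1 − FeCO₂·(1 − (1 − RER))),
   with baseline (reference-chamber) drift correction, the respiratory
   exchange ratio RER = V̇CO₂:V̇O₂, and energy conversion at 25.0 J ml⁻¹ CO₂.
3. **Calibration** — linear mixed models of MR on f_H, T_b and
   T_diff = T_b − T_a with individual as a random intercept, fit by maximum
   likelihood, ranked by AICc, with Nakagawa–Schielzeth marginal/conditional
   R² and likelihood-ratio tests; prediction of energy expenditure from
   heart rate alone.
4. **Field analysis** — synchronizes in-roost heart-rate, body-temperature
   and 15-min ambient streams, flags low-energy states (pooled 10% heart-rate
   quantile), summarizes by hour of day and scotophase, and applies the
   calibration to estimate daily energy expenditure.
5. **Synthetic data** — every input class above can be generated with known
   ground truth (beat times, metabolic-rate programmes, torpor schedules),
   so the whole pipeline is testable end to end without animal recordings.

## Worked example

Simulate a calibration experiment — 6 individuals × 150 observations of
daily energy expenditure generated from e(f_H) = 0.00106·f_H + 0.0527 kJ d⁻¹
with per-individual random intercepts — then let AICc pick the best
predictor and predict expenditure at a typical roosting heart rate:

```python
from cardiomet import synthetic as syn, calibration as cal

data = syn.simulate_calibration_dataset(syn.MixedModelSpec(seed=42))
table, fits = cal.model_selection(data, [("f_h",), ("t_b",), ("t_diff",), ("f_h", "t_b")])
print(table[["formula", "k", "n", "aicc", "delta_aicc", "r2m", "r2c"]].round(3))

best = fits[("f_h",)]
print(f"slope = {best.beta['f_h']:.5f} kJ/d per bpm, intercept = {best.beta['intercept']:.4f} kJ/d")
print(f"predicted expenditure at 147 bpm: {cal.predict_expenditure(147.0, best):.4f} kJ/d")
```

```
  formula  k   n      aicc  delta_aicc   r2m   r2c
      f_h  4 900 -1356.764       0.000 0.863 0.875
f_h + t_b  5 900 -1354.796       1.968 0.863 0.875
      t_b  4 900 -1318.548      38.215 0.857 0.870
   t_diff  4 900 -1236.955     119.808 0.845 0.857

slope = 0.00108 kJ/d per bpm, intercept = 0.0290 kJ/d
predicted expenditure at 147 bpm: 0.1879 kJ/d
```

The heart-rate-only model wins on AICc; adding body temperature costs more
(two AICc points) than its information is worth, and temperature-only models
trail far behind — the defining signature of torpor at high body
temperature.  The fitted slope recovers the generating 0.00106 kJ d⁻¹ bpm⁻¹
within sampling error, and the conditional R² (0.875) exceeds the marginal
(0.863) by the share of variance the individual intercepts explain.

The same stages are available from the shell:

```sh
cardiomet simulate --seed 1 --out audio.wav --bpm 300 --duration 60
cardiomet detect --wav audio.wav --out hr.csv
cardiomet run --seed 1 --out rundir/        # full synthetic demo pipeline
```

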