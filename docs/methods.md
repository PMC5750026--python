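# Methods

This note documents the models implemented in `cardiomet`, the defaults
that matter, what the synthetic generators do and do not emulate, and the
design choices made where the underlying protocols left the design open.

## Signal model and beat detection

The transmitter emits a continuous narrow-band carrier; each cardiac
muscle potential gates the carrier off briefly.  A beat therefore appears
in the received audio as a downward excursion of the amplitude envelope,
and detection operates on envelope drops, not peaks.

**Synthesis.**  Ground-truth beat times are the integer crossings of the
integrated instantaneous rate Λ(t) = ∫ r(s)/60 ds, computed on a 1-ms grid
and inverted by interpolation, so the emitted event list matches the
analytic rate integral to within one beat on any interval.  Each beat
multiplies the unit-amplitude carrier by (1 − depth) for the pulse width
(default 10 ms, depth 0.9), optionally with raised-cosine edges; the
default is rectangular, the simplest shape that exercises envelope
detection.  Additive white Gaussian noise (default sd 0.02) and optional
Poisson-timed wide-band static bursts emulate reception artifacts.
Programmes whose peak rate would overlap pulses are rejected outright
rather than clipped.  The default sample rate is 48 kHz, giving 96
500-sample analysis windows per second; 44.1 kHz gives 88.2, spanning the
88–96 windows s⁻¹ range of common recorder settings.

**Detection.**  The carrier is located as the dominant Welch-spectrum peak
(rejected as "no carrier" unless it clears the in-band median density by
10 dB), then isolated with a linear-phase FIR band-pass (default 1801 taps,
±150 Hz; forced odd so the group delay is compensated exactly by centred
convolution).  Output is insensitive (±2%) to tap counts anywhere in
1500–2000.  The envelope is the analytic-signal magnitude lightly smoothed
over 1 ms; the local carrier level is a per-0.25-s-block median,
interpolated — robust to the beats themselves, which occupy at most ~35%
of the time at the highest physiological rates, and to slow fading.  An
event is a ≥2 ms excursion below 0.5× the local level; events closer than
the 40 ms refractory merge (capping detectable rate at 1500 bpm, above the
1068 bpm field maximum).  A silent recording yields zero counts plus a
warning flag, not an exception, so batch runs survive dead segments.

**Density filter.**  The "90% quantile" kernel filter is read as the 90%
highest-density region of a Gaussian KDE (Silverman bandwidth) over the
whole recording: the density cutoff is the level at which the region's
integrated mass reaches 0.90, and observations below it are flagged.  A
config switch (`kde_mode="central"`) offers the alternative central 5–95%
value-interval reading; both are implemented because the phrasing is
ambiguous, HDR is the default because it rejects isolated static-induced
values without trimming a unimodal record's bulk.  A sliding-context
variant is intentionally not implemented; whole-recording context matches
how the filter is described.

**Hand-scoring emulation** reuses the automated detector on the first 10 s
of each minute and multiplies by six — only the sparse sampling scheme,
not human counting skill, is the method being emulated.  Its known bias
(a silent first 10 s records 0 bpm for an otherwise active minute) is
preserved deliberately.

## Respirometry

CO₂ production from a push-through system is computed with two selectable
denominators:

* `printed` (default): V̇CO₂ = (FeCO₂ − FiCO₂)·FR / (1 − FeCO₂·RER)
* `textbook`: V̇CO₂ = (FeCO₂ − FiCO₂)·FR / (1 − FeCO₂·(1 − 1/RER))

The relative difference between them is analytically
FeCO₂·(RER + 1/RER − 1) ≈ 1.05·FeCO₂ at RER 0.8 — about 0.1% at typical
excurrent concentrations — so the choice is documented and logged rather
than adjudicated.  O₂ consumption uses the CO₂-scrubbed configuration
V̇O₂ = FR·(FiO₂ − FeO₂)/(1 − FiO₂).  Energy conversion is 25.0 J ml⁻¹ CO₂;
mass-specific rates default to the 10.5 g study-animal mean when no
per-individual mass is supplied.  RER defaults to 0.8 and is recomputed as
the mean of pointwise ratios (ratio-of-means selectable).

**Baseline correction** estimates incurrent fractions from the
reference-chamber readings: per-baseline-period means interpolated
linearly across animal periods, which removes linear analyzer drift
exactly; a single baseline period falls back to a constant baseline
(logged).  No washout (response-time) deconvolution is applied — 5-min
sampling of a ~2 l chamber at 300 ml min⁻¹ is itself a smoothing source,
and is documented as such rather than corrected.

**Aggregation.**  1-Hz traces are averaged into 5-min gas samples; each
sample receives the mean of the T_b/f_H pairs inside it (five at the
standard 1-min body-temperature cadence; the actual count is reported, not
forced).  Heart rate at each T_b timestamp is the trailing 60-s mean —
causal, matching the pairing protocol.  Minimum metabolic states are the
records at or below each individual's 10% MR quantile
(linear-interpolation "type 7" convention, stated because conventions
differ); the 30%-quantile mean is reported alongside for comparison with
published basal rates.  Steady state is a rolling coefficient of variation
below 10% over 20 min (4 samples), with partial windows at the series
edges so a fully steady record is marked throughout.

**Forward model.**  The trace simulator inverts the module's own printed
equation (and the O₂ form) at the requested exchange ratio, so a
noise-free forward/inverse round trip recovers the metabolic-rate
programme to within 1% at steady state by construction — that closure is
what the round-trip tests verify, together with drift injection/removal.

## Calibration (mixed models)

With a continuous metabolic-rate response, the "generalized" mixed model
is the identity-link linear mixed model

MR_ij = β₀ + Σ β_p x_p,ij + u_i + ε_ij,  u_i ~ N(0, σ_u²), ε_ij ~ N(0, σ_e²),

fit by maximum likelihood (statsmodels `MixedLM`), because REML
likelihoods are not comparable across fixed-effect structures and the
fits feed AICc = −2ℓ + 2k + 2k(k+1)/(n − k − 1).  The parameter count k
is fixed effects + 2 variance components, a stated convention.
Candidates in a selection table are all fit on identical listwise-complete
rows; AICc ties break toward fewer parameters.  The default optimizer
occasionally diverges on intercept-only fits; the fitter falls back to
derivative-free optimizers and keeps the best finite optimum, and a
perfectly noise-free dataset (singular covariance) falls back to least
squares with zero variance components, flagged as a boundary fit.
Variance-boundary fits (σ_u → 0) are returned flagged, never raised, and
the likelihood-ratio test's conservativeness on a variance boundary is
documented in its docstring.

R² follows the variance-partition definitions: R²m = σ_f²/(σ_f² + σ_u² +
σ_e²) and R²c = (σ_f² + σ_u²)/(σ_f² + σ_u² + σ_e²), with σ_f² the
sample variance (ddof 1) of the fixed-effect linear predictor.

**Units.**  The reference calibration is expressed in kJ d⁻¹
(e(f_H) = 0.00106·f_H + 0.0527).  Because daily and hourly energy units
differ by 24×, every fit and prediction carries an explicit unit tag and a
mismatch raises; there is no silent rescaling.  The generator spec offers
an explicit `rescaled("kJ/h")` conversion for users who prefer hourly
units.

**Generator variance components.**  The calibration generator needs σ_u
and σ_e; only the conditional R² (~0.88) of the reference fit constrains
them.  We fix the marginal R² at 0.82 a priori, which with heart rate
uniform on the observed 59–999 bpm range gives σ_u = 0.0778 and
σ_e = 0.110 kJ d⁻¹ (analytic R²c = 0.880).  Likewise the
heart-rate-on-body-temperature generator (slope 14.985 bpm °C⁻¹,
conditional R² ~0.55) uses marginal R² 0.45 → σ_u = 18.35, σ_e = 38.93 bpm
with T_b uniform on 28–37 °C.  These are one-time choices, not fit to any
test outcome.

**Model-selection consistency.**  The selection-consistency experiment
pits the three single-predictor models {f_H}, {T_b}, {T_diff} against each
other: the scientific contrast is *which physiological variable carries
the metabolic information*, and on that contrast the heart-rate model wins
essentially always at these effect sizes.  Superset candidates (f_H plus a
temperature) are available in the default candidate list but are not the
consistency criterion, because AIC-family criteria accept a redundant
extra parameter in a known ~16% of replicates — a property of the
criterion, not of this pipeline.

## Field analysis

Each body-temperature observation is paired with the trailing 60-s mean
heart rate and the nearest 15-min ambient reading (linear interpolation
selectable).  No microclimate correction is attempted: the ambient station
sits hundreds of metres from the roosts and the mismatch is a property of
the data, so records where T_b < T_a are retained and flagged rather than
dropped.  Scotophase defaults to 18:15–06:15 local (closed at dusk, open
at dawn), an approximation for a near-equatorial site; both bounds are
configurable.

Low-energy states are flagged by the pooled 10% quantile of observed heart
rates (per-individual selectable) — pooled matches the "lowest 10% of
observed values" reading, in deliberate contrast to the per-individual MR
quantile used on the respirometry side.  Note an arithmetic consequence: a
pooled-quantile classifier flags exactly its quantile's share of records,
so its record-level sensitivity against scheduled torpor can only reach
1.0 when torpid records make up less than that share of the dataset.
Hourly summaries report empty hours as empty (n = 0, NaN means), never as
zeros.  The three field regressions (T_b ~ T_a, f_H ~ T_b, f_H ~ T_diff)
go through the calibration module's fitter — there is no second fitting
path — each on its own listwise-complete rows with n reported, since mixed
cadences make per-model n differ.  Daily energy totals integrate the
calibration prediction over observed coverage only (gaps are never
imputed); a day with more than 50% gap is flagged unreliable.

## Synthetic field data

The field generator emulates: a sinusoidal diel ambient cycle whose
photophase/scotophase means are 25.87/23.74 °C (amplitude 1.673 °C derived
analytically from those means, peak at the photophase midpoint, noise sd
0.3 °C at 15-min cadence); two-state heart rate (active 150 ± 20 bpm with
a 100 bpm floor, torpid 70 ± 8 bpm, i.e. below the ~90 bpm low-state
threshold) switching instantaneously on the scheduled bouts; body
temperature from the first-order thermal model
dT_b/dt = k_cool(T_a + heat_gain·MR − T_b) (defaults k_cool = 0.05 min⁻¹,
heat_gain = 20 °C per kJ h⁻¹), integrated with exact exponential updates
at 1-s steps — heart rate drops instantly at torpor entry, body
temperature follows with a ~20-min time constant; and nightly foraging
gaps (missing data) for 1 h from dusk.

It does **not** emulate: gradual heart-rate transitions or arousal
overshoots above 1000 bpm, roost microclimate buffering, multi-day torpor,
flight, weather, or per-individual behavioural differences.  Passing tests
therefore demonstrate that the pipeline recovers known structure under
clean two-state dynamics, not that the classifier is robust to every field
pathology; the density filter and quantile thresholds are exercised only
against the artifact classes the generator produces.

## Numerical choices and degenerate inputs

Seeds: every stochastic generator takes an explicit integer seed
(`numpy.random.default_rng`); identical spec + seed is bit-identical.
Replicate seeds in experiments derive from `SeedSequence.spawn`.  Beat
times are computed on a 1-ms grid (≤0.06 beats error at the 1068 bpm
extreme over a segment).  Quantiles are numpy's default linear
interpolation throughout.  KDE on a zero-variance series is a no-op;
filtering that would reject every value raises, signalling a pathological
recording.  Aggregation bins with no audio coverage are missing, not
zero.  AICc is undefined for n ≤ k + 1 and raises.

## Problem sizes

The acceptance script uses 100 replicates of 6 × 150 observations for
each recovery experiment (≈7 s total) and a 2-h 1-Hz trace for the
exchange-ratio round trip; test audio clips are 10–60 s at 48 kHz, sizes
at which every detection property is already stable.
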