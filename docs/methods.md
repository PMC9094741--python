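# Methods

`epwv` simulates and analyses the comparison between two ways of obtaining
aortic pulse wave velocity (PWV): a cuff device that *estimates* PWV from the
entered age and brachial blood pressure, and a transit-time *measurement*
that divides the jugulum-to-thigh-cuff path length by the corrected pulse
arrival time. Because the original per-subject data are access-restricted,
every stage runs on synthetic physiology whose population moments are
matched to the published cohort summaries; the analysis code itself is
data-agnostic and works on any table with the same schema.

## Cohort model

Two preset cohorts are shipped:

* **athletes** — n = 129, age 56 ± 11 years on [35, 86], BP 128 ± 15 / 78 ± 8
  mmHg, BMI 24.0 ± 3.5, 68% male, heart rate 61 ± 11 bpm; device protocol
  only.
* **agbresa** — n = 24 (bedrest-study baseline), age 33 ± 9 years on
  [24, 55], BP 125 ± 11 / 70 ± 7 mmHg, BMI 24.3 ± 2.1, 67% male, heart rate
  62 ± 9 bpm; device protocol plus transit-time measurement.

Ages follow a truncated normal on the stated range. Truncation shifts the
mean of a naively parameterised truncated normal, so the underlying location
is solved (Brent root find) such that the *truncated* mean equals the stated
cohort mean. The truncated SD is then necessarily below the nominal SD (no
distribution on [24, 55] with mean 33 attains SD 9); all calibrations below
therefore use the exact truncated moments, obtained from
`scipy.stats.truncnorm`.

Mean arterial pressure (MAP) carries an age trend,

    MAP = m0(preset) + 0.35 * age + N(0, 6^2)  mmHg,

with the intercept per preset chosen so that the cohort-mean MAP equals the
cuff convention `dbp + (sbp - dbp)/3` applied to the printed BP means. The
age trend is what lets a near-deterministic age+MAP device output show the
very high estimated-PWV ~ age correlations seen in the study; fully
independent MAP cannot. MAP is split into systolic/diastolic with an
independent pulse-pressure draw whose SD reproduces the printed systolic SD,
so `map_from_cuff(sbp, dbp)` returns the drawn MAP exactly.

Timing physiology: isovolumetric contraction time (ICT) ~ N(60, 10^2) ms
truncated at 30 ms, path length ~ N(1.00, 0.05^2) m — plausible adult values
chosen once; the published study reports neither distribution.

## Device surrogate

The proprietary estimator is replaced by a calibrated surrogate whose
deterministic core is a quadratic in entered age with a linear MAP term:

    f(a, m) = c0 + c1*a + c2*a^2 + c3*(m - 90),   c3 = 0.028 m/s per mmHg.

(c0, c1, c2) are solved from three anchors using the exact truncated age
moments: cohort-mean estimated PWV 5.8 m/s (bedrest) and 8.3 m/s (athletes)
— cohort expectations include the curvature term c2*Var(age) — and a
bedrest estimated-PWV ~ age R^2 of 0.88. The quadratic root whose vertex
lies below age 18 is taken, so f is strictly increasing on the accepted
domain (ages 18–100, MAP 50–140 mmHg). Solved defaults:
c0 = 4.43290, c1 = 0.00835754, c2 = 0.00100979.

Device repeatability follows the triplicate protocol: each repetition is
`f(entered_age, MAP) + b + e_i` with a per-subject deviation
b ~ N(0, 0.10^2) m/s drawn once and per-repetition noise
e_i ~ N(0, 0.10^2) m/s; the subject's value is the mean of three
repetitions. In the entered-age experiment b is held fixed across entries
(same person, same device) — this is exactly what lets a single subject
show near-perfect dependence on the entered age while cohorts show extra
spread. Entered age is the chronological age rounded to whole years.

True aortic PWV is linear in age with Gaussian spread,

    v(a) = 2.41594 + 0.0722442*a + N(0, 0.402492^2)  m/s,

matched to the printed measured PWV of 4.8 ± 0.6 m/s and a measured ~ age
R^2 of 0.55 in the bedrest cohort (again with truncated moments).

A consequence of fixing the device noise at sigma_b = sigma_r = 0.10 m/s
while anchoring the R^2 structure: the simulated cohort SDs of estimated
PWV (~0.59 and ~1.36 m/s) are smaller than the printed 1.1 and 1.8 m/s.
Means, R^2 values and the bias structure — the quantities the comparison
turns on — are matched; the marginal spread is not. The athletes' full-model
standardized age beta settles near 0.92 (printed: 0.93).

## Waveform synthesis

Each subject renders into a 30 s, 1 kHz, three-channel bundle: ECG (Gaussian
QRS complexes, sigma 8 ms), Doppler envelope (half-sine bursts of 300 ms
starting at valve opening), and a thigh-cuff pulse (raised-cosine upstroke,
rise time 80 ms, exponential decay tau = 250 ms, tapered to a flat baseline
at least 100 ms before the next beat). Beats are scheduled at 60/HR
intervals with 3% multiplicative jitter. White noise of SD 2% of channel
amplitude is added by default; optional 0.25 Hz baseline wander is off by
default. Ground truth satisfies `t_valve - t_r = ICT` and
`t_foot - t_valve = distance / true_pwv` exactly.

**Arrival-time convention.** `t_foot` is annotated under the
intersecting-tangent convention used by transit-time instruments. For a
raised-cosine upstroke of rise time T, the tangent foot trails the first
departure from baseline by (1/2 - 1/pi)*T (~14.5 ms at T = 80 ms), so the
renderer starts the upstroke at `t_foot - (1/2 - 1/pi)*T`; the tangent foot
of the clean waveform is then exactly `t_foot`, making the detector
round-trip unbiased. Annotating the upstroke onset instead would build a
14.5 ms systematic error into every transit time, which propagates to a
~7% PWV bias.

Morphology is deliberately simple: the contract is fiducial timing. Not
modelled: wave reflections, respiration, arrhythmia, cuff inflation
dynamics, pressure-dependence of stiffness within a beat. Passing tests
therefore certify the timing pipeline and the statistics, not robustness to
clinically realistic signal pathology.

## Fiducial detection

Runs blind to the truth annotations.

* **R-peaks**: local maxima above median + k*MAD (k = 6) separated by a
  300 ms refractory period; a recording is rejected when the largest
  excursion is within 2k*MAD of the noise floor; residual peaks below half
  the QRS amplitude are discarded; peak times are parabolically
  interpolated.
* **Pulse foot** (per beat window): signals are Savitzky–Golay smoothed
  (25 ms, order 2) for the value and first derivative; the tangent at the
  maximum-slope point (located by a least-squares parabola over ±8 ms of the
  derivative — robust to pointwise derivative noise) is intersected with the
  horizontal baseline fitted to the pre-upstroke segment. Under the default
  rendering the systematic error is below 0.7 ms at noise levels 0–5%. A
  maximum-second-derivative variant is available behind
  `DetectorConfig(foot_method="second_derivative")` for sensitivity
  analysis; it marks the early upstroke rather than the tangent foot.
* **Valve opening**: first crossing of 10% of the windowed envelope peak on
  the smoothed envelope, linearly extrapolated back to baseline. With the
  threshold fraction set to 0 and a noise-free signal it returns the exact
  onset sample.
* **Assembly**: greedy per-beat matching (first valve then first foot event
  before the next R-peak); beats violating `t_r < t_valve < t_foot` or with
  a missing event are flagged and excluded rather than failing the subject.
  Subject-level timing averages valid beats (median behind a flag); at
  least three valid beats are required.

## Statistics

* Quadratic regressions are OLS on {age, age^2, covariates}. Because the
  study style reports a single beta for "age" from a quadratic model, the
  fitted age polynomial `c1*age + c2*age^2` is z-scored as one composite
  predictor and the standardized fit is re-run; covariate betas come from
  the same standardized fit. Covariate adjustment and partial correlation
  give the same r here; both are quadratic in age.
* Bland–Altman: mean and SD of (estimated - measured), limits of agreement
  mean ± 1.96 SD, plus the linear trend of the difference against age. The
  difference-vs-age R^2 at n = 24 is highly cohort-dependent, so only the
  positive trend is asserted, not its magnitude.
* Partial correlation given age residualises both variables on
  {1, age, age^2} and uses a t reference with n - 4 degrees of freedom.
* Normality: Kolmogorov–Smirnov with the Lilliefors correction (parameters
  are estimated from the sample); the uncorrected KS p-value is available
  behind a flag. Two-sided p-values throughout, no multiple-testing
  correction.
* `variance_decomposition_oracle` evaluates all population expectations in
  closed form from the model constants and exact truncated-normal age
  moments (Var(a^2) = E[a^4] - E[a^2]^2, Cov(a, a^2) = E[a^3] - E[a]E[a^2]),
  giving an independent benchmark for Monte-Carlo output; it refuses
  degenerate presets (zero variances).

Calibration is anchored at population level; cohort-averaged OLS R^2 at
n = 24 carries a small (~+0.02) finite-sample inflation that stays well
inside the reported tolerances.

## Reproducibility and problem sizes

All randomness descends from one seed. Batch runs give cohort k the
generator `default_rng([seed, k])`; within a study a single generator is
consumed in a fixed stage order, so identical configurations produce
identical numeric content. Replicate summaries use 200 cohorts per preset
(bedrest cohorts run the full signal pipeline at 30 s / 1 kHz per subject;
athlete cohorts run the device protocol only) and 50 entered-age runs —
sizes at which the Monte-Carlo error of every reported mean is an order of
magnitude below its tolerance, while a full recomputation stays in the
minutes range on one CPU.

## Known limitations

* The device surrogate is a calibrated stand-in, not a reconstruction of
  the proprietary algorithm; only its population behaviour (age/MAP
  dependence, repeatability) is meaningful.
* Marginal SDs of estimated PWV are under-dispersed relative to the printed
  cohorts (see above).
* The entered-age grid defaults to 30–80 in decades; the study text is
  ambiguous between 20–80 and 30–80, and 20–80 is available via
  configuration.
* Waveforms are morphologically idealised; detector thresholds are tuned to
  this family and carry no clinical-robustness claim.
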