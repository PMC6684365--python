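# Methods

## Scope and model overview

The package implements a four-route occupational SHS exposure assessment:
minute-resolution area PM₂.₅ from two-channel particle counts, time-averaged
passive airborne nicotine, short mobile PM₂.₅ measurements, and pre/post-shift
salivary cotinine. The routes are deliberately redundant: PM₂.₅ is sensitive
but not specific to SHS (hence the matched ambient-station comparison),
nicotine is specific but a single integrated value per site, and cotinine
integrates each worker's actual intake.

## Count-to-mass conversion

The counter reports particles >0.5 µm and >2.5 µm per 0.01 ft³; their
difference estimates the 0.5–2.5 µm band in which SHS aerosol concentrates.
The band count maps to mass through a monotone piecewise-linear function
anchored at 0 → 0 with a per-device multiplicative chamber factor. The
shipped default (0.010 µg/m³ per count up to 10 000 counts, 0.008 beyond,
device factor 1.0) is a package default of realistic magnitude
(≈3 000 counts ↔ ≈30 µg/m³) chosen because the published SHS-aerosol
conversion it stands in for is defined only up to calibration data that are
not distributed with any dataset; every cross-prison statistic the package
reproduces operates on already-converted values or on synthetic data pushed
through the same mapping in both directions, and is therefore independent of
these coefficients. Both breakpoints and slopes are configuration, not code.
Channel inversions (large > small) are clamped to zero with a logged
warning, not treated as errors: they occur at very clean-air counts.

## Exposure statistics

Time-fraction statistics use observed minutes only — missing minutes are
excluded from denominators, never imputed. Exceedance uses strict `>`
(a literal reading of "exceed"); the day window is the half-open
[07:00, 23:00) so day and night tile the clock exactly once. Cross-prison
pooling is the column-wise median with the mean-of-central-pair convention
for even counts (this convention is what reproduces the printed nicotine
median of 0.32 µg/m³ from 14 values). GM/GSD are exp of the mean and of the
sample SD (n−1) of natural logs, the standard occupational-hygiene
convention; GSD of a single value is reported as NaN. Report tables round PM
to one decimal; all comparisons in tests use unrounded values.

## Nicotine QC

Processing order: tamper exclusion → field blanks routed to a blank report
(any detectable blank raises a contamination alarm) → duplicate pairs
averaged arithmetically, with each member's agreement reported as % absolute
deviation from the pair mean → ½-LOD substitution (0.016 µg/m³) for
non-detects → one value per prison → cross-prison median. More than two
monitors at a site is rejected: only duplicate pairs are defined. The
configuration validator accepts a half-LOD within half a unit of the printed
last digit of LOD/2, because the assay convention reports 0.016 for
0.031/2. The filter-mass-to-concentration step of the passive sampler is out
of scope — inputs are already µg/m³, as laboratories report them.

## Cotinine pipeline

Eligibility applies, in order: questionnaire flags (smoker, nicotine-product
user, smoking cohabitant, smoking vehicle), sample validity (both samples
present and valid, post time strictly after pre), then the smoker cut-off
(pre or post strictly > 5 ng/ml; equality retained). Each record is tallied
under the first rule it fails so retained + tallies always equals the input
count.

Elimination is single-compartment first-order with default half-life 16 h,
consistent with population salivary-cotinine kinetics; it is configurable
and, at the cohort level, cancels out of the conversion chain because the
median increment is already elimination-corrected. Elapsed time is computed
per participant from recorded sample times; the cohort-level conversion uses
a representative 8-h shift.

The increment-to-air chain assumes the shift increment ΔC (ng/ml) arises
from breathing air at constant nicotine concentration N (µg/m³) for t hours:

    ΔC = N · BR · t · f_abs · f_conv · ρ / V_d

with defaults BR = 0.77 m³/h (light occupational activity), f_abs = 0.71
(fraction of inhaled nicotine absorbed), f_conv = 0.78 (fraction of absorbed
nicotine metabolised to cotinine), V_d = 61.6 l (0.88 l/kg × 70 kg) and
ρ = 1.0 (saliva:plasma cotinine ratio). Inverting for N and multiplying by
the SHS PM:nicotine ratio (10) gives the SHS-PM₂.₅ shift equivalent; the
chain is linear in ΔC and maps 0 → 0. All constants ship as configuration
with these documented defaults; elimination of newly formed cotinine within
the shift is neglected (a second-order effect over 8 h relative to the 16-h
half-life, well inside the chain's parameter uncertainty).

The measurable sub-sample keeps workers whose pre-shift sample was above
the 0.1 ng/ml LOD *and* whose zero-intake projected post-shift value is
above the LOD — otherwise the assay cannot resolve a change. Sub-sample
increments use measured post-shift values as reported; a censored post-shift
value has no reported number, so it enters through the same ½-LOD
convention (0.05 ng/ml) used everywhere else. Summary tables impute ½ LOD
for all censored values, matching the national-survey comparability
convention.

## Synthetic-data generator

The simulator emulates the features the study describes, not any real
prison: smoking events arrive as a Poisson process (defaults 2/h in the
07:00–23:00 window, 0.2/h at night), each adding a log-normal peak increment
(GM 17 µg/m³, GSD 2) that decays exponentially at 1/h (air-exchange
removal), over a 6.6 µg/m³ ambient baseline with 2 µg/m³ Gaussian
observation noise, floored at zero. These defaults put simulated 6-day
means inside the reported ≈10–140 µg/m³ per-prison range — a plausibility
anchor, not a fit. Counts are generated by inverting the configured
calibration and quantising, so conversion round-trips are exact to half a
slope unit. Nicotine is the SHS-PM mean divided by 10 plus assay noise,
censored at 0.031 µg/m³.

Cotinine cohorts draw pre-shift values log-normally (GM 0.16, GSD 2.5
ng/ml, the scale of the reported post-shift distribution), apply elimination
over the shift, add uptake with a coefficient that is the exact inverse of
the configured conversion chain (so pipeline recovery of a constant
generating exposure is well-posed by construction), add absolute assay noise
of 0.02 ng/ml (~8% CV at typical levels, realistic for LC-MS/MS), floor at
zero and censor below 0.1 ng/ml. The default cohort appends 3 invalid-sample
and 12 over-cut-off records to the 407 analysable workers, mirroring the
study's recruitment layout. All generators are pure functions of
(scenario, seed).

What passing tests do **not** show about real data: the generator has no
within-day occupancy structure beyond the two-level event rate, no
between-prison heterogeneity unless scenarios are varied explicitly, no
correlated assay drift, and no nicotine losses in storage/transport — the
study itself flagged its low absolute nicotine values as probably reflecting
such losses, and this package treats reported values as ground truth while
surfacing the PM:nicotine relationship so the anomaly stays visible.

## Numerical and design choices

- Timestamps are naive local clock time; the statistics only ever compare
  within-site clock windows.
- Readers reject invalid input (line-numbered errors, duplicate-timestamp
  and negativity checks) rather than coercing; below-LOD tokens stay
  censored statuses, never numbers. Write∘read is the identity on every
  format, with floats serialised via `repr` for exactness.
- Median convention throughout: mean of the two central order statistics for
  even n (numpy's default).
- R² is from the ordinary least-squares fit of nicotine on PM (equivalently
  squared Pearson correlation); tests cross-check against an independent
  correlation oracle.
- The zero-exposure centring check uses a test cohort with pre-shift levels
  well above the assay LOD so that the known, tiny censoring asymmetry
  (≈0.001 ng/ml, a fiftieth of the LOD) does not confound the question it
  asks — whether projection and differencing introduce spurious signal.
- Problem sizes in the property-based checks (200-worker cohorts × 1000
  replicates for centring; 100 seeds × 3 exposures at full 422-record scale
  for recovery; 100 seeded 6-day series for the day/night ordering) were
  chosen to give Monte-Carlo error comfortably inside the asserted bounds
  while keeping the default suite fast.

## Known limitations

- The default count→mass coefficients are plausible, not chamber-derived;
  deployments must supply their own calibration for absolute accuracy.
- The conversion chain is a single-compartment steady-uptake model; it is
  accurate at the cohort median level it is applied to, not for
  individual-level dose reconstruction.
- Duplicate handling is defined for pairs only; ambient matching assumes the
  station's native (hourly) resolution without interpolation.
- The measurable sub-sample conditions on pre-shift detectability and so
  systematically excludes the least-exposed workers; its PM equivalent
  describes that sub-population.
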