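# Methods

This note records the models, conventions and numerical choices behind
`coralproxy`, and what the synthetic validation does and does not show.

## Coordinate systems and the age model

Depth is measured in mm below the living surface (0 = tissue surface at
collection; increasing downcore, i.e. back in time). Calendar time is a
monthly grid; continuous time is the month ordinal plus 0.5, so "the
middle of the month" (nominally the 15th) is the reference instant for
resampling and for tie-point dates.

An age model is a piecewise-linear map through tie points — (depth,
calendar month) anchors pairing a skeletal Sr/Ca extremum with an SST
extremum. Constant growth is assumed between consecutive anchors; above
the shallowest anchor the first segment's rate is extrapolated but capped
at the collection date, below the deepest the last segment's rate is
extrapolated. The map is strictly monotone by construction and inversion
(time→depth) is exact.

### Extrema detection

Annual Sr/Ca extrema are picked on a centred moving-average presmooth of
the profile. The default window is six months of mean growth (≈ 4.8 mm at
9.6 mm/yr): a symmetric moving average introduces no phase shift, so the
extremal *positions* are preserved, while a narrower (≈ 1 month) window
leaves enough analytical noise near the flat parts of the seasonal cycle
to create spurious extrema. Candidate peaks must additionally clear a
prominence of 20 % of the smoothed profile's robust (5th–95th percentile)
range, and be separated by at least `min_separation_mm` (default 4.8 mm,
half a mean year). Plateaus resolve to their midpoint.

### Tie-point dating

Extrema of both kinds are merged, sorted by depth, and walked from the
core top: each extremum receives the newest season of its kind strictly
older than the previously assigned date. When extrema alternate cleanly
this is identical to pairing the i-th maximum from the top with the i-th
coolest observed month counting back from collection; unlike independent
per-kind rank pairing it stays consistent when an edge-truncated extremum
(e.g. the most recent summer, partly cut off at the living surface) is
missing. Within the instrumental span the coolest/warmest month of each
season is taken from the SST record (searched within ±2 months of the
climatological month); before it, fixed climatological months are used
(February/August by default, configurable per site). If a season that
should be instrumental cannot be dated from the SST record, the
chronology fails loudly rather than guessing.

## Gaussian decomposition

The low-pass filter is Gaussian in frequency, centred at zero, with
half-amplitude at the bandwidth: `W(f) = exp(−ln2 (f/bw)²)`. Frequencies
are in cycles per day with a month of 365/12 days, which makes the default
bandwidth 0.00137 cpd the frequency of a two-year period — the split
between "multidecadal" (>2 yr) and "seasonal/event" (<2 yr) variability.
The series is mean-removed, mirror-padded by one series length on each
side, FFT-transformed, windowed, inverse-transformed, trimmed, and the
mean restored. The detrended (notch) series is defined as input minus
low-pass, so complementarity is exact to rounding. Mean removal before
transforming keeps the notch output free of DC leakage.

Numerical properties, verified by the test suite on a 46-year monthly
series: the measured amplitude response matches `W(f)` to within 0.01 for
periods from 6 months to 20 years; the filter is linear to 1e-9; and for
inputs with zero slope at the series ends the mirror padding keeps the
endpoint error below 5 % of the amplitude. A cosine truncated mid-phase
carries an additional, unavoidable edge transition (largest, ~0.3–0.5 of
the amplitude, for periods near the two-year cutoff where `W ≈ 0.5`);
users should treat the first/last year of the low-pass series with
caution, as with any finite-record filter.

Tissue-layer exclusion removes the youngest n months before filtering
(the living-tissue zone carries anomalously high trace-element values);
the helper `tissue_layer_months` converts a thickness to whole months
(4.1 mm at 9.6 mm/yr → 5.125 → 5 months).

## Mean seasonal cycle and high-peaks

The MSC is the per-calendar-month mean (with standard error and count) of
the detrended series. A month is a high-peak *candidate* when its
detrended value exceeds the overall MSC mean plus `k_sigma` standard
deviations of the residuals about the MSC. `k_sigma = 0` — the literal
"exceeds the MSC mean" rule — is the default; on noisy data it flags many
months, so the robustness parameter is exposed (the synthetic validation
uses `k_sigma = 3` when scoring recall of injected spikes). Runs of
consecutive candidates collapse to the single highest month (ties break
earlier), so no two reported peaks are adjacent.

Event matching is greedy by event date: each catalogue event claims the
first unclaimed peak with a lag of 0..`max_lag_months` (default 4)
months, reflecting delayed estuarine Ba²⁺ desorption from stored sediment
and possible growth pauses after severe floods. Unmatched events and
peaks are both reported. Period counts split at January of the boundary
year (default 1996).

## SiZer

For each time point t and bandwidth h, the derivative of the underlying
trend is estimated by Gaussian-kernel weighted local linear regression
(weights `exp(−(x−t)²/2h²)`); the slope variance uses the weighted
sandwich form with the residual variance estimated from the weighted
residual sum of squares, and the effective sample size is `(Σw)²/Σw²`.
Cells with ESS < 5 are "insufficient data"; otherwise the cell is
significantly increasing/decreasing when the pointwise two-sided Gaussian
interval at `alpha` (default 0.05) excludes zero. Pointwise (not
simultaneous) quantiles are used deliberately: simpler, and the measured
type-I cell fraction on white noise is ≈ 0.04 at `alpha` = 0.05.

The bandwidth grid defaults to 21 log-spaced values over 2–25 years for a
~46-year annual series. Shift points are found per bandwidth row as
transitions from significant increase to significant decrease (or the
reverse) with only not-significant cells between, attributed to the
interval from the last year of the old trend to the first year of the
new. Same-direction transitions with overlapping intervals across
bandwidths are clustered into one shift point whose interval is the
intersection (the years every supporting bandwidth brackets) and whose
bandwidth list is the union. If clusters of opposite directions overlap
in time the record cannot be split there; both are flagged ambiguous and
excluded from the default output. A shift is therefore localised to an
interval, not a year: kernel smoothing displaces any scalar crossing-year
estimate by O(h/4) for asymmetric trends, while the interval brackets the
true break — on tent-shaped test series (break at year 28 of 46, signal
5× noise) the interval of the dominant cluster brackets the break year
(±1 yr) with ≥ 3 supporting bandwidths in ≥ 90 % of seeded replicates.

## Growth and calcification

Extension for year Y is the distance between the winter tie points
(Sr/Ca maxima) of Y and Y+1, labelled with the calendar year containing
the interval's summer midpoint. Annual density is the time-average of the
dated density-profile samples within each complete calendar year
(depth-averaging differs negligibly under near-uniform growth; the
time-average convention is fixed here). Calcification is
extension(cm) × density, and the identity
`calcification / density × 10 = extension` holds exactly for every
emitted record. Per-period associations with the annual-mean low-pass
Ba/Ca are reported as Pearson r/p/n plus the OLS slope ± SE.

## Ba–salinity mixing

Dissolved Ba mixes quasi-conservatively between a high-Ba river endmember
(desorption from suspended sediment peaks at low salinity) and a low-Ba
marine endmember; an OLS line of Ba (nmol/kg) on practical salinity gives
both endmembers (evaluation at salinity 0 and 35). Skeletal Ba/Ca converts
to seawater Ba with a partition coefficient of 1 and seawater Ca fixed at
10.28 mmol/kg (the salinity-35 reference): the unit product
µmol/mol × mmol/kg lands exactly on nmol/kg, so 3.8 µmol/mol ↔
39.06 nmol/kg and the conversion round-trips to machine precision.

## The synthetic core

The simulator emulates the statistical structure of a ~46-year subtropical
bay record; its defaults are the study conditions for all validation:

| parameter | default | rationale |
| --- | --- | --- |
| span | 552 months ending October 2014 | 46 full years of growth |
| mean extension | 9.6 mm/yr, lognormal σ = 0.08 | typical massive-coral growth; ~8 % interannual spread |
| sampling interval | 0.25 mm (≈ 0.3 months) | microsampling design |
| SST | 25 ± 3.8 °C seasonal, noise σ = 0.3 °C | subtropical NW-Pacific bay; warmest August, coolest February |
| Sr/Ca | 10.5 − 0.06·SST mmol/mol | standard *Porites* thermometer slope |
| Mg/Ca | 1.2 + 0.13·SST mmol/mol | positive thermometer |
| Ba/Ca baseline | 3.8 µmol/mol | gives ~39 nmol/kg seawater Ba |
| trend knots | (1968, −0.15) (1980, +0.30) (1995, −0.30) (2014, +0.35) | rise → fall → rise with the decline→rise shift at 1995 |
| seasonal Ba amplitude | 0.12 µmol/mol, peak September | typhoon-season sediment pulse; order of the observed MSC range |
| spikes | 8 events, 0.9–1.5 µmol/mol, lags 0–4 months, decay 2 months | flood-analogue pulses incl. 1977/1990/1991/2010-style events |
| density | 1.25 ± 0.08 g/cm³ seasonal | typical *Porites* densities |
| analytical RSD | 2.24 % Ba/Ca, 0.17 % Sr/Ca, 0.73 % Mg/Ca | instrument-level 1σ uncertainties |

Growth is uniform within the year by default (a winter-slowdown profile is
available to stress-test the constant-growth assumption of the age
model). Proxies are mapped to depth by inverting the cumulative growth
curve; the Ba forcing and density are evaluated as continuous functions
of time at each sample's exact age (identical to the monthly truth at
month midpoints), Sr/Ca and Mg/Ca interpolate the monthly (noisy) SST.
Analytical noise is multiplicative Gaussian at the configured RSDs, drawn
from a random stream separate from the growth/environment stream so
noise-on and noise-off runs of the same seed are directly comparable.
Spikes have a one-month linear onset ramp followed by exponential decay;
a zero decay degenerates to a single-month impulse.

The simulator does **not** emulate: dating error from missed or double
annual bands, diagenesis, smoothing by bioturbation or by the drill's
finite bit, SST-dependent Ba partitioning, or mechanistic
mangrove-trapping/tidal dynamics (the seasonal term and spikes are
phenomenological). Passing the validation therefore demonstrates that the
*algorithms* recover known truth under realistic noise — not that any
particular field record satisfies the assumptions.

## Validation problem sizes

The standard validation uses 20 seeded replicates of the full 46-year
core (~1760 samples each) for chronology and peak recovery, 20 replicates
for the SiZer type-I and tent-recovery checks, and 20–100 replicates for
regression-recovery rates; the whole suite runs in well under a minute.
Stochastic recovery criteria are stated as success fractions over the
replicates (e.g. ≥ 18/20 within 2 SE) because single-draw 2σ checks fail
by construction ~5–10 % of the time.

## Known limitations

* Tie-date accuracy under default noise is ±1 month; individual annual
  extensions inherit ~0.3 mm jitter from the SST-noise-displaced coolest
  month, so per-year extensions are only sampling-interval-accurate
  (0.25 mm) on noise-free input — per-core mean extension is accurate to
  well under 2 % either way.
* The monthly resampling attenuates sub-monthly structure: spike peak
  values are chord-interpolated and can lose ~10 % of their height at
  0.25 mm sampling; peak *timing* is preserved to ±1 month.
* The first/last year of filtered output carries edge effects (see the
  decomposition section).
* Greedy event matching is order-dependent when several events compete
  for one peak; the unmatched lists make this auditable.
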