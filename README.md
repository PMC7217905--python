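# coralproxy

Analysis toolkit for multidecadal records of terrigenous sediment load and
growth stress archived in massive coral skeletons (*Porites*-type cores).

Massive corals deposit annual density bands and record the chemistry of the
water they grew in. Two ratios carry most of the signal used here:

* **Sr/Ca** (mmol/mol) varies inversely and linearly with sea surface
  temperature (SST), so its downcore maxima/minima mark winters/summers and
  anchor a depth-to-time **age model**;
* **Ba/Ca** (µmol/mol) tracks dissolved barium in seawater, which in
  river-fed bays is dominated by Ba²⁺ desorbed from suspended fluvial
  sediment — making skeletal Ba/Ca a proxy for sediment load from land use,
  floods and coastal works.

The package implements the full chain a sclerochronologist needs to turn
depth-resolved microsampled profiles into interpreted time series:

1. **chronology** — Sr/Ca extrema detection, tie points against
   instrumental SST extrema (climatological February/August before the
   instrumental era), a piecewise-linear age model assuming constant growth
   between anchors, and monthly resampling of any proxy profile.
2. **decomposition** — Gaussian frequency-domain filtering with half
   amplitude at bandwidth 0.00137 cycles/day (the 2-year period):
   `W(f) = exp(−ln2 · (f/bw)²)` gives the low-pass (>2 yr, multidecadal)
   component; its exact complement (the notch / "detrended" series) keeps
   seasonal and event-scale variability. Includes tissue-layer exclusion,
   the mean seasonal cycle (MSC) climatology, and annual means.
3. **event detection** — "high-peaks": months where the detrended Ba/Ca
   exceeds the MSC mean (plus an optional `k·σ` margin), runs collapsed to
   their highest month, then matched against a documented-event catalogue
   with lags of 0–4 months (delayed estuarine Ba desorption, growth pauses).
4. **sizer** — a reimplementation of SiZer (SIgnificant ZERo crossings of
   derivatives): Gaussian-kernel local linear regression of the annual
   low-pass series over a bandwidth grid, pointwise classification of the
   derivative sign, and extraction of trend-shift intervals (e.g. the
   change from a multidecadal decline to a rise).
5. **growth** — annual extension (distance between successive Sr/Ca
   maxima, mm/yr), annual mean density (g/cm³) from a calibrated density
   profile, calcification = extension(cm) × density (g·cm⁻²·yr⁻¹), and
   per-period regressions of growth on the low-pass Ba/Ca.
6. **mixing** — conservative Ba–salinity endmember mixing regression on
   water samples, and conversion between skeletal Ba/Ca and seawater Ba
   (partition coefficient ≈ 1, seawater Ca 10.28 mmol/kg:
   3.8 µmol/mol ↔ 39.06 nmol/kg).
7. **synthetic** — a forward simulator of a virtual ~46-year core
   (9.6 mm/yr mean growth, 0.25 mm sampling ≈ 0.3 months) with known truth:
   chronology, a rise→fall→rise multidecadal Ba forcing with a shift year,
   seasonal cycles, lagged flood spikes, and instrument-level analytical
   noise (relative SD 2.24 % Ba/Ca, 0.17 % Sr/Ca, 0.73 % Mg/Ca). Every
   stage is validated against this truth.

## Worked example

```python
from coralproxy import chronology as ch
from coralproxy.decomposition import decompose, mean_seasonal_cycle, annual_means
from coralproxy.events import detect_high_peaks, count_peaks_by_period
from coralproxy.sizer import sizer_map, find_shift_points
from coralproxy.synthetic import SyntheticCoreConfig, simulate_core

cfg = SyntheticCoreConfig()
cores, truth = simulate_core(cfg, seed=1)

maxima = ch.detect_extrema(cores["sr_ca"], kind="maxima")
minima = ch.detect_extrema(cores["sr_ca"], kind="minima")
tiepoints = ch.build_tiepoints(maxima, minima, sst=truth.sst,
                               collection_date=cfg.collection)
model = ch.build_age_model(tiepoints, cfg.collection)
ba = ch.resample_monthly(cores["ba_ca"], model, units="umol/mol")

dec = decompose(ba)
msc = mean_seasonal_cycle(dec.detrended)
peaks = detect_high_peaks(dec.detrended, msc)
print("high-peaks (A, B):", count_peaks_by_period(peaks, boundary_year=1996))

shifts = find_shift_points(sizer_map(annual_means(dec.lowpass)))
for p in shifts:
    print(p.direction, p.interval, f"({len(p.bandwidths)} bandwidths)")
```

Output:

```
high-peaks (A, B): (49, 37)
increase_to_decrease (1977.0, 1979.0) (12 bandwidths)
decrease_to_increase (1993.0, 1997.0) (18 bandwidths)
```

The simulated forcing rises to ~1980, declines to 1995 and rises again;
the SiZer map recovers both turning points — the decline→rise shift
bracketing the true 1995 shift year — and the detrended series yields a
few dozen high-peaks per period, split at the January 1996 boundary.

The same pipeline runs from the shell:

```sh
coralproxy simulate --seed 1 --out-dir sim/
coralproxy run --config pipeline.json --out-dir out/   # full pipeline + summary.json
```

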