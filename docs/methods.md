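# Methods

This note documents the models, estimators and numerical choices behind
`ebossflux`, what the synthetic-data generator does and does not emulate,
and the package's known limitations.

## Signal model and conventions

A session is a uniformly sampled photodetector voltage series. All
voltages are held internally in millivolts (the digitiser spans
0–5000 mV over 2¹⁶ codes; integer-coded containers are converted on read
as `mv = code · range / 2¹⁶`). Timestamps are UTC; sample `i` maps to
`start_time + i / sample_rate`; indices are 0-based and every index
range is half-open. An insect transit multiplies the baseline by
`1 − ε(t)` where the fractional extinction ε is, for a single event,

    ε(t) = d_body · g(t) + d_wing · g(t) · p(t)

with `g` a unit-peak envelope and `p` a unit-peak periodic glint train.
Overlapping events add their extinctions (clipped below full occlusion).

## Detection

* **Filter.** 4th-order Butterworth band-pass, 10–900 Hz, applied
  forward–backward (zero phase) as second-order sections. The low edge
  removes baseline drift; the high edge removes wideband noise.
* **Polarity.** Insects decrease the voltage, so the filtered series is
  negated before thresholding; an upward excursion's main lobe then
  points away from the threshold and is not detected.
* **Smoothing.** A 1 ms centred moving average precedes thresholding.
  The averaging window is a package choice; it suppresses single-sample
  noise spikes without smearing millisecond glints below visibility.
* **Threshold.** Centred 5 s sliding mean plus 2.5 sliding standard
  deviations, computed exactly with cumulative sums (edge windows are
  clipped, not padded). Centred windows avoid threshold lag; the choice
  presumes offline processing.
* **Regions.** Above-threshold runs must last strictly more than 0.1 ms.
  Runs closer than 20 ms are merged, because one insect's wing glints
  cross the threshold many times within a single transit. At the 2.5σ
  multiplier a noise-only record necessarily yields crossings at roughly
  the Gaussian exceedance rate (~0.6% of samples); these false regions
  are expected and are removed by the harmonic test downstream.
* **Raw extraction.** Each region is cut out with symmetric context
  padding of `max(0.2 s, 2 × region duration)`. The padding scales with
  the region because the raw envelope of a slow transit is much wider
  than its band-passed excursion, and both the transit-width measurement
  and the baseline estimate need the full tails plus clean context
  beyond them.

## Harmonic classification and wingbeat estimation

The event segment's spectrum is computed after removing the segment mean,
applying a Hann window, and zero-padding fourfold (the quoted frequency
resolution is the native `sample_rate / segment length`; padded bins
interpolate). Before the transform the slowly varying transit envelope
is subtracted in the time domain, using a Gaussian smoother whose −6 dB
point sits at the search band's lower edge. A time-domain subtraction is
essential: for short events the windowed envelope's spectral line smears
far above any in-band cut, and at a 10 Hz cutoff against a 30.5 kHz rate
an IIR low-pass would contribute larger edge transients than the wing
signal itself.

The fundamental search band runs from `max(2/Δt, 10 Hz)` to a fixed
2 kHz ceiling: at least two full wingbeat periods must fit in the event,
and content below the detection band-pass could never have produced the
region in the first place. Candidate fundamentals are the in-band
spectral local maxima (quadratically interpolated). Each candidate is
scored by a harmonic comb of K = 5 teeth: power is integrated within
±8 bin spacings of k·f (capped at 0.45·f so adjacent windows never
overlap, clipped at the band edge), the per-bin noise floor — the median
in-band bin power divided by ln 2, the median-to-mean factor of
near-exponential noise bins — is subtracted from both the comb and the
in-band total, and the score is their ratio. The event is classified an
insect when three conditions hold:

1. score ≥ 0.3 (the acceptance ratio, calibrated on synthetic sweeps);
2. at least two comb teeth each carry ≥ 5% of the comb power, rise at
   least 10× above the noise floor, and coincide with an actual spectral
   local maximum — a single smooth lobe or a lucky noise bump is not a
   harmonic series;
3. the comb's excess over the floor exceeds 6 standard deviations of the
   summed floor (counting one independent bin per zero-padded group),
   and the comb windows cover at most half of the in-band bins (a comb
   that blankets the band has no contrast against it).

These guards were calibrated jointly on noise-free event sweeps,
noisy events at ten times the total noise, and threshold-selected
noise-only regions. The fundamental beats its subharmonic f/2 by
construction, since the comb at f/2 only collects a subset of the teeth
of f. Events too short for two periods under the ceiling are classified
non-insect with reason `empty_band`; envelope-only events fail on
in-band residual power (`no_wing_power`) or on the tooth tests.

**Wing/body separation.** The body component defaults to a rolling
median over one wingbeat period (evaluated on a quarter-period stride
and interpolated, then smoothed over one period). The glints are narrow
(≈10% duty cycle) one-sided excursions, so the window median tracks the
glint-free body level; a low-pass — also provided as `method='lowpass'` —
instead averages over the glints and inherits a bias of
`duty·mean(pulse)·d_wing/d_body` (a few percent of the depth) into the
body minimum. The wing component is always the residual, so the
decomposition is exactly additive. Fewer than four periods in the
segment flags the split as unreliable.

## Photometry

* **Baseline I₀**: median of the far half of the pre-event context. The
  near half can still sit in the raw envelope's tails (invisible to the
  band-passed detection series). Events at the record start fall back to
  post-event context and are flagged.
* **Body minimum I_B**: the body component at the event's own extinction
  peak, searched only inside the detected region so neighbouring events
  in the padding cannot capture the measurement.
* **Cross section**: σ_B = σ_pv (I₀ − I_B)/I₀, the flat-top relation;
  it is scale-invariant and inverse-consistent to machine precision.
  I_B > I₀ (negative extinction) and I_B ≤ 0 (occlusion beyond the
  model) are errors.
* **Transit time**: full width at 10% of peak of the body extinction
  profile, measured on the contiguous above-level run containing the
  event's peak, with linear interpolation of the flank crossings. The
  10% level is configurable; for a Gaussian envelope the width equals
  √(ln 10 / ln 2) ≈ 1.823 times the FWHM. Runs clipped by the record
  edge are flagged truncated.
* **Kurtosis**: Pearson convention (Gaussian = 3), treating the profile
  as an unnormalised density over time: μ₄/μ₂² of the sample-time
  variable weighted by extinction. Computed over the above-level run
  extended by one full width on each side — enough support to include
  the Gaussian tails without pulling in neighbours. Additive positive
  noise in the tails biases the statistic upward by a few tenths; the
  statistic is a shape descriptor, not a calibrated quantity.

## Mass calibration

The model chain — extinction vs geometric cross section (quasi-ballistic
transmittance), volume ∝ area^{3/2} (shape factor), mass ∝ volume
(volumetric mass density) — collapses, with all three factors treated as
constant across species, into m = η·σ^{3/2} with the single coefficient
η (mg/mm³). The factors are not separately identifiable from (σ, m)
pairs and are not reported.

Fitting is damped least squares (`scipy.optimize.least_squares`,
`method='lm'`) on per-specimen points by default; because the model is
linear in η the exact solution Σ m σ^{3/2} / Σ σ³ exists and serves as
an independent oracle the iterative fit must match to 10⁻¹⁰ relative. A
group-mean mode (means per specimen group, weighted by group size) is
provided because calibration plots are often drawn per group; which mode
a given published calibration used is generally not stated. R² is
computed against the mass mean (SS_tot about the mean) and adjusted for
the single fitted parameter; a free-exponent fit exists purely as a
diagnostic of the 3/2 law and is never used by the pipeline. The
published field constants η_wet = 0.157, η_dry = 0.075 ship as
`published_constants()` and are the pipeline default.

## Biomass density

ρ_b = Σ (Δtₙ/t_tot)·mₙ / ΔV over a window of length t_tot, with
ΔV = σ_pv × path length computed from geometry (Ø72 mm × 36 m →
0.1466 m³). Each transit contributes its mass weighted by the fraction
of the window it occupied, which makes the estimator an unbiased
occupancy estimate for stationary traffic (verified against a
time-integral oracle in the acceptance suite). Properties maintained:
non-negativity, linearity in mass, and additivity — the density over a
window equals the duration-weighted mean over any partition.

Binning assigns an event wholly to the bin containing its start time;
fractional apportioning across straddled bins is available as an option
(the difference is one transit time against the bin length). The 10 ms
hard transit cut-off gates both the event summaries and, by default, the
density sum; both behaviours are configurable since only the summary use
is unambiguous. Rolling averages are centred and unweighted with edge
bins using available support; diel profiles average bins by time-of-day
slot and require the bin length to divide 24 h.

The window length trades resolution against uncertainty: minute bins
resolve diel structure but fluctuate with Poisson arrivals, hour/day
bins are stable but average over it. The acceptance suite demonstrates
the monotone variance relationship on steady synthetic traffic.

## The synthetic generator

What it emulates: Gaussian transit envelopes with FWHM equal to the
ledger transit time (20 ms–1 s, log-uniform), chosen because real events
are Gaussian-like with shape kurtosis near 3; a flat-top envelope is
selectable for beam-filling crossings. Wing glints are raised-cosine
pulses of 10% duty cycle at the wingbeat frequency (50–500 Hz uniform) —
the true pulse shape is not documented, only that the dips are sharp.
Body extinction depths are log-uniform over 0.2–6% of the beam,
equivalent to dry masses from a couple to a few hundred mg under the
calibration law; the smallest events deliberately sit near the detection
floor, as real small insects do. Five independent Gaussian noise sources
(defaults 2.0, 1.5, 1.2, 0.8, 0.5 mV — plausible relative sizes for
acquisition card, ambient infrared, vibration, detector and laser noise,
not measured values) combine root-sum-square to ≈ 2.94 mV total.
Baseline drift is a random walk low-pass filtered below 0.01 Hz on a
coarse grid and rescaled to 1% RMS of the baseline — a few percent over
a few hours. Arrivals are homogeneous Poisson by default with an
optional time-varying rate for diel experiments. All randomness flows
from one seeded generator; identical seeds give bit-identical sessions.

What it does not emulate — and hence what passing tests do not show
about real data: diffraction and Mie structure of real insect bodies
(extinction here is purely geometric), the detector's 90 kHz bandwidth
roll-off, orientation changes between beam entry and exit, partially
entering trajectories as a geometry (a truncation flag exists, but no
trajectory model), weather-driven non-stationarity of the noise floor,
and species structure in the wingbeat/mass joint distribution.

## Numerical choices and degenerate inputs

Sliding statistics use cumulative sums with an offset subtraction for
variance stability and clip tiny negative variances to zero. Spectral
peak positions are refined by 3-point quadratic interpolation with the
shift clamped to one bin. Empty event tables yield zero density; zero
extinction yields σ_B = 0; a constant profile has undefined kurtosis and
raises. Threshold windows longer than the record, bands outside Nyquist,
and non-positive probed volumes raise parameter errors rather than
propagate.

Default problem sizes in the test and acceptance suites (sessions of
tens of seconds to a few simulated hours, 100–200 replicate draws) are
chosen so the whole suite documents the estimator's behaviour at
desk scale; all statistical tolerances were set from the corresponding
closed forms (Poisson standard errors, Gaussian exceedance rates) before
freezing.

## Known limitations

* Small insects below the detection threshold and transits too brief for
  two wingbeat periods are invisible; recall claims hold only above
  ~10× the total noise and with ≥ 3–4 periods in the beam.
* Partially entering specimens underestimate σ_B and hence mass; no
  correction is applied.
* The wet/dry mass of a specimen re-entering the beam is counted twice;
  the estimator has no track-level identity.
* The kurtosis statistic inflates slightly under additive noise because
  the profile is clipped at zero before weighting.
* The calibration treats σ as error-free; errors-in-variables are not
  modelled.
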