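# Methods

`fluxlens` implements the quantitative analysis around a CggR/FBP
transcription-factor biosensor for glycolytic flux in single yeast cells.
This note records the models, the numerical choices, what the synthetic
generators do and do not emulate, and the known limitations.

## Sensor biochemistry

**Melting-temperature extraction.** The melting temperature of a
thermal-shift curve is the temperature of the maximal first derivative of
fluorescence with respect to temperature, computed by centered finite
differences on the raw 0.5 °C grid with no pre-smoothing; the first and
last grid points are excluded and ties are broken toward the lowest
temperature. A curve whose derivative has no dynamic range (relative span
below 1e-9) is rejected as degenerate rather than assigned an arbitrary Tm.

**K_D from Tm shifts.** Ligand stabilization is modelled as a Hill-form
shift, `Tm(L) = Tm0 + ΔTm · Lⁿ/(K_Dⁿ + Lⁿ)`. The "cooperative binding"
family has no canonical printed form; the Hill parameterization is the
standard choice that contains one-site binding as the n = 1 special case.
Replicates are pooled into a single least-squares problem (per-replicate
scatter is visible in the data but the estimand is one K_D per variant).
Fitting is deterministic: a seedless multi-start grid over
K_D ∈ 10^[-2..2] mM (17 log-spaced points) × n ∈ {0.5, 1, 2, 4}, with the
two linear parameters (Tm0, ΔTm) profiled out in closed form at each grid
point, followed by bounded trust-region refinement from the best start.
The 95% K_D interval is asymptotic (from the fit covariance). A fitted
span indistinguishable from zero (|ΔTm| below twice its standard error, or
below 1 μ°C) flags the series as unbindable and the interval widens to the
full search range — K_D is unidentifiable without a thermal shift.

**Variant presets.** Wild-type CggR binds FBP with K_D = 1 mM; the point
mutants are stored as fold changes of that value (T151S ÷1.1, E269Q ÷1.5,
T152S ÷1.6, R250A ×1.5, T151V ×2.6). EMSA data show roughly 30% of the
repressor remains DNA-bound at saturating FBP, so the transfer function
floors occupancy at `residual_bound = 0.30`.

**Transfer function.** Promoter occupancy by the repressor is
`θ(FBP) = θ_max · (1 − (1 − residual_bound) · f_b(FBP))` with `f_b` the
Hill fraction bound and θ_max = 0.95 (near-complete repression at zero
FBP); reporter activity is `basal + (1 − basal) · (1 − θ)` with a 5%
basal leak. The output is strictly increasing in FBP, from
`basal + (1−basal)(1−θ_max)` at zero to
`basal + (1−basal)(1−θ_max·residual_bound)` at saturation. Inversion (for
ratio→FBP→flux) is by bisection on this monotone map to 1e-6 mM.

## FBP–flux bootstrap

Fluxes are condition-level summaries (mean ± sd of a sampled flux solution
space), while FBP is measured per replicate. Each bootstrap iteration
draws N measurement indices with replacement from the pooled FBP list and
pairs every drawn measurement with an independent normal draw from its
condition's flux (or growth-rate) distribution; Pearson's r is computed
per iteration. The default redraws target values every iteration; a
`redraw_targets=False` switch gives the classical pairs bootstrap instead,
since the source procedure can be read either way. Degenerate resamples
(zero variance in either coordinate) are discarded and counted, not
retried. Reported are the bootstrap mean r, the 2.5/97.5 percentile
interval, a normal-approximation p-value on the bootstrap distribution,
and the plug-in r (each measurement paired with its condition mean) —
the bootstrap mean carries a small O(1/N) resampling attenuation, so both
are useful. For small N with zero sds an exhaustive mode enumerates all
N^N resamples; it exists for exactness checks. The linear FBP→flux
calibration is weighted least squares (weights 1/sd², falling back to
unweighted when any sd is zero) on condition means, with the physiological
window 0.2–8 mM as the default fit range.

## Batch physiology

Under exponential growth with constant yields, biomass and metabolites
share one growth clock: `X(t) = X₀e^{μt}`,
`cᵢ(t) = cᵢ₀ ∓ (qᵢ/μ)X₀(e^{μt} − 1)` (− uptake, + product). All species
are fitted jointly with a shared μ by Levenberg–Marquardt, initialized
deterministically (μ, X₀ from log-linear biomass regression; qᵢ from the
concentration-vs-biomass slope, which is the yield). Unit weights by
default with a per-species override. Times are internally re-anchored to
the first sample, making μ and q invariant to time shifts. A molar-mass
table converts g/l-based rates to mmol·gDW⁻¹·h⁻¹.

## Cytometry readout and mixture detection

Event ratios are `(FL1 − bg₁)/(FL3 − bg₃)` with backgrounds taken as
channel medians of a non-fluorescent control; events whose corrected FL3
is ≤ 1 a.u. are excluded (the ratio diverges) and counted. No spectral
compensation is applied anywhere. Detection fits 1- and 2-component
Gaussian mixtures on ln(ratio) — the ratio itself is right-skewed — and
declares a subpopulation when the 2-component model wins by ≥ 10 BIC, the
minor weight is ≥ 0.5%, and the component means are ≥ 2 pooled sds apart.
EM details that matter: k-means-style initialization reliably misses a
small tail mode, so candidate fits are anchored at tail quantiles of the
log-ratio (plus one k-means++ start), screened at loose tolerance on a
seeded 20,000-event subsample (basin selection only), and the
best-likelihood candidate is refined on the full data to tol 1e-7 (capped
at 500 iterations) — the default sklearn tolerance (1e-3) stops EM after a
handful of iterations and leaves weight errors of several points. All of
this is deterministic for a fixed seed.

## Single-cell time-lapse pipeline

Per cell cycle — the half-open interval between consecutive cytokineses,
with exactly one budding inside and duration within [150, 300] min (closed
bounds); cycles violating any of these are dropped with a reason code:

1. **Volume.** Mother and bud are prolate spheroids, `V = (4/3)πRr²`
   (1 μm³ = 1 fl). The bud is zero before budding, linearly interpolated
   in time from zero at budding to its first segmentable measurement, then
   taken from measured radii and held at the last measured value beyond
   them (the hold only affects the padding window). Missing mother radii
   abort the cycle; a bud that is never segmentable stays at zero with a
   warning.
2. **Smoothing.** Volume and the two mean-fluorescence channels are
   smoothed by Gaussian-process regression — amplitude × RBF with the
   length scale bounded to [30, 48] min plus a white-noise kernel with
   free level, hyperparameters by marginal-likelihood maximization with 5
   seeded restarts. The fit includes 50 min of data on each side of the
   cycle; predictions cover only the cycle, on a dense ~1-min grid with
   exact endpoints (grid count = round(duration), so the realized step is
   within rounding of 1 min).
3. **Rates.** Abundances `A_X = V·F_X`; production rates
   `r_X = (t_{1/2}/ln 2)·A'' + A'` (first-order maturation; 20 min YFP,
   50 min mCherry), derivatives by centered finite differences on the
   dense grid with second-order one-sided endpoints. Derivatives are taken
   numerically on the GP posterior mean rather than analytically — at a
   1-min step the difference is negligible and the code stays simple.
4. **Normalization.** Each rate is detrended by the straight line through
   its values at the two cytokineses and min–max normalized to attain 0
   and 1 exactly; a rate that is flat after detrending (e.g. exactly
   linear) is degenerate and excludes the cycle.
5. **Uncoupling and alignment.** The uncoupling is the pointwise
   difference of the normalized rates (bounded in [−1, 1]). Each cycle's
   time axis maps piecewise-linearly onto phase through the three anchor
   events (cytokinesis → 0, budding → population-mean budding phase, next
   cytokinesis → 1); profiles are resampled by linear interpolation onto a
   common 100-point phase grid and averaged, with a 95% percentile
   bootstrap band from 5,000 resamplings of whole cycles. One top-level
   seed fans out deterministically (via spawned seed sequences) to the GP
   restarts and the bootstrap.

## Synthetic data

Every generator is a pure function of (config, seed) and returns ground
truth alongside the data.

**Cell traces.** Cycle durations are normal (mean 220, sd 35 min, clipped
to 155–295 so they span the analysis filter window, as real slow-growing
cells do); budding sits at phase 0.30 ± 0.06. The mother grows
exponentially and slowly (20% per cycle); each bud grows from zero at
budding to 55% of the mother's budding volume along a quintic smoothstep
(zero slope and curvature at both ends), then detaches at cytokinesis —
total volume is therefore C¹ along the trace, which matches mother+bud
trajectories at imaging resolution. FBP follows a circular Gaussian bump
on the phase axis, baseline 1 mM rising to 4 mM (the in-vivo oscillation
amplitude is not an established value; this fixture spans the
physiological window) with the peak at phase 0.95 by default. YFP is
produced per unit volume in proportion to the sensor transfer function at
the momentary FBP; mCherry constitutively; both pass through the two-pool
maturation ODE `dI/dt = p − kI, dA/dt = kI` integrated as concentrations
(so cytokinesis — a volume drop at constant concentration — needs no
special casing) with an RK4 that evaluates its time-varying coefficients
at stage midpoints. Observed fluorescence is the mature concentration plus
Gaussian noise (sd 2 a.u. on ~10²-scale signals); radii are back-computed
from volumes at a fixed 1.15 aspect ratio plus 0.03 μm noise; buds become
segmentable 12 min after budding. Events are reported exactly. An optional
`expression_amp` knob adds a shared cell-cycle expression modulation to
both channels; it defaults to off.

Not emulated: photobleaching, focal drift, segmentation error beyond
additive radius noise, mother/bud concentration gradients, and
event-detection error (budding/cytokinesis times are exact). Passing tests
therefore show that the pipeline recovers what this forward model encodes,
not that it is robust to segmentation failure modes.

**Cytometry.** Per-strain log-normal FL3 and log-normal ratio over a
log-normal autofluorescence floor; the WT/TM6 presets differ by 1.2
natural-log units in mean log-ratio with sd 0.35 (fixture constants chosen
so the two clouds separate the way distinct high-/low-flux strains do).
Mixture counts are exact, not binomial, so the nominal fraction is the
true fraction. **Thermal shift** uses the standard 10-concentration
protocol grid (0–36 mM), Tm noise sd 0.3 °C, 5 replicates, and logistic
raw melts. **Conditions** place six steady states on a line
(slope 1.4, intercept −0.2) across 0.2–8 mM with 53 pooled FBP
measurements (15% CV replicate scatter) and condition-level flux sds of
8% + 0.05 floor. **Batch** emulates the exponential/constant-yield model
exactly, with optional Gaussian noise.

## Known limitations

- The GP posterior mean carries curvature bias within roughly one length
  scale of the fit-window edges; with 50-min padding and the [30, 48]-min
  length-scale bounds this reaches the first/last ~quarter of a cycle. The
  production-rate formula multiplies the abundance's second derivative by
  t_{1/2}/ln 2, so the slow-maturing channel amplifies the shared bias
  ~2.5× more than the fast one, leaving a small systematic uncoupling
  residual (~±0.05) near phases 0/1 even for perfectly coupled channels.
  Peak localization is unaffected (the FBP-driven signal is much larger),
  but a zero-uncoupling control's confidence band does not always cover
  zero near the cycle edges. Treat profile features within ~0.1 of
  cytokinesis with caution.
- Mixture detection assumes two log-normal-ish modes; with more than two
  subpopulations the two-component fit reports a merged picture.
- The flux calibration is linear within 0.2–8 mM; extrapolation beyond the
  fitted window inherits no guarantee.
- Binary FCS containers are not parsed; cytometry events are exchanged as
  CSV (`sample_id,fl1,fl3`).

## Problem sizes used in the shipped checks

The shipped test-suite and acceptance runs use 10 cells × 3 cycles per
profile (≈30 cycles, matching the scale of a replicate experiment), 20
seeds for peak-recovery statistics, 200 simulations for K_D recovery, and
50 runs × 100,000 events per mixture fraction for detection power — sizes
at which the Monte-Carlo error of each summary is well below the margin it
is compared against.
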