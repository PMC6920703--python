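# fluxlens

Analysis stack for a transcription-factor biosensor that reports **glycolytic
flux in single yeast cells**. The sensor exploits the tight correlation
between glycolytic flux and the concentration of fructose-1,6-bisphosphate
(FBP): the *B. subtilis* repressor CggR binds a synthetic promoter and
silences a YFP reporter; FBP binding releases CggR, so YFP expression —
normalized by a constitutively expressed mCherry — tracks FBP and hence
flux. `fluxlens` implements the quantitative methods around such a sensor:

- **binding** — melting-temperature extraction from thermal-shift curves,
  Hill-form Tm-shift fits for the CggR–FBP dissociation constant
  (`Tm(L) = Tm0 + ΔTm · Lⁿ/(K_Dⁿ + Lⁿ)`), EMSA bound-fraction arithmetic,
  and the sensor transfer function (promoter activity vs FBP, with a
  residual DNA-bound floor at saturating ligand).
- **calibration** — the measurement-vs-distribution bootstrap of Pearson's
  *r* between pooled FBP measurements and condition-level flux (or growth)
  distributions, a weighted linear FBP→flux calibration, and numeric
  inversion of the transfer function to map sensor ratios to flux.
- **physiology** — joint exponential-growth / constant-yield fits of batch
  time courses: `X(t) = X₀e^{μt}`,
  `cᵢ(t) = cᵢ₀ ∓ (qᵢ/μ)·X₀·(e^{μt} − 1)`.
- **cytometry** — background-corrected FL1/FL3 (YFP/mCherry) event ratios
  and two-component Gaussian-mixture subpopulation detection on the
  log-ratio scale.
- **timelapse** — the single-cell pipeline from segmented mother/bud
  ellipse radii and fluorescence to maturation-corrected production rates
  `r_X = (t_{1/2}/ln 2)·A_X'' + A_X'` (first-order maturation, half-times
  20 min YFP / 50 min mCherry), and the cell-cycle-phase-aligned
  YFP–mCherry *uncoupling* profile with bootstrap confidence bands.
- **synthetic** — generators for every input (traces, cytometry mixtures,
  thermal shifts, condition tables, batch cultures) with known ground
  truth.
- **cli** — `fluxlens simulate|fit-binding|calibrate|rates|cytometry|timelapse`.

## Worked example

Simulate a two-strain flow-cytometry mixture with a 5% low-flux (TM6)
subpopulation, then detect it:

```python
from fluxlens.synthetic import SimConfig, simulate_cytometry
from fluxlens.cytometry import BackgroundModel, ratio_per_event, detect_subpopulations

cfg = SimConfig(seed=13)
sample, control, truth = simulate_cytometry(cfg, {"WT": 0.95, "TM6": 0.05},
                                            n_events=100_000)
bg = BackgroundModel.from_control(control)
ratios = ratio_per_event(sample, bg)
fit = detect_subpopulations(ratios.ratios, seed=1)
print(fit.detected, round(fit.minor_fraction, 4))
```

prints

```
True 0.0522
```

— the two-component model is decisively preferred (BIC margin, component
separation and minor-fraction floor all satisfied) and the minor-population
fraction is estimated at 5.22% against the true 5%.

The same end to end from the shell:

```sh
fluxlens simulate cytometry --seed 13 --out sim/
fluxlens cytometry --events sim/events.csv --control sim/control.csv --out out/
```

For the cell-cycle pipeline, `fluxlens simulate traces --n-cells 10 --seed 7
--out sim/` followed by `fluxlens timelapse --traces sim/traces.csv --events
sim/events.csv --seed 11 --out out/` writes the phase-aligned uncoupling
profile (`profile.csv`: phase, mean, ci_low, ci_high) and run metadata; the
profile's peak phase estimates where in the cell cycle FBP — and hence
glycolytic flux — is maximal.

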