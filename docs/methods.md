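# Methods

This note documents the models, estimators and design choices behind
`sdhscreen`, and what the synthetic-data generator does and does not
emulate.

## Biological setting

A haploid yeast strain lacking succinate dehydrogenase subunit 2
(*sdh2Δ*) cannot run the TCA cycle and therefore grows only
fermentatively. On a mixture of a fermentable carbon source (galactose)
and a non-fermentable one (glycerol), a wild-type-like strain shows
diauxic growth — a fast glycolytic phase, a pause, then a slower
respiratory phase — while the *sdh2Δ* strain stops at the diauxic
plateau. A third strain, *nhp6AΔ*, has wild-type physiology but carries
the same nourseothricin-resistance marker as the mutant; it is used to
exclude marker artifacts. The package analyses a three-stage screen for
compounds differentially toxic to the mutant: (I) endpoint growth
inhibition of the mutant in 384-well plates, (II) differential
growth-curve effects mutant vs. reference, (III) marker-strain
concordance.

## Growth model

Curves are modelled as a sum of logistic components,

    OD(t) = b + Σ_i K_i / (1 + exp(−r_i (t − m_i))),

one component per growth phase (at most two). The reported per-phase
parameters are the field-standard triple:

* saturation `S_i = K_i` (OD gained by the phase),
* maximal rate `R_i = r_i K_i / 4` (the steepest slope, OD/h — the
  absorbance-scale rate, not the specific growth rate in 1/h; the
  logistic shape rate `r_i` is also stored),
* lag `L_i = m_i − 2/r_i` (tangent-at-inflection intercept, clamped at
  0).

A sum of logistics was preferred over piecewise/segmented models because
it is continuous and differentiable and reproduces the plateaued diauxic
shape with a closed-form lag per phase.

**Segmentation and model selection.** The phase count is proposed from
the smoothed derivative (moving median then mean, 5-point windows): two
phases when two separated derivative maxima flank a valley below 0.3 of
the smaller maximum. Fitting is bounded nonlinear least squares
(`scipy.optimize.least_squares`), multi-started from the segmentation
guess plus 4 jittered starts (deterministic given `random_state`). In
`auto` mode both the one- and two-phase hypotheses are fitted and the
small-sample-corrected AIC decides, with a 2-point margin in favour of
the simpler model so that marginal RSS gains never add a phase. Curves
whose dynamic range is below 0.05 OD are declared "no growth" and not
fitted.

## Screening statistics

Percent inhibition places each compound well on a scale anchored by the
plate's own controls at the same read time:

    PI = 100 · (1 − (test − blank) / (control − blank)),

unclipped, so stimulated growth goes negative and below-blank readings
exceed 100. Assay quality uses the z-factor
`z = 1 − 3(σ_p + σ_n)/|µ_p − µ_n|` on control percent-inhibition values
with sample (n−1) standard deviations — control groups are small, so the
unbiased convention matters. z > 0.5 is treated as screenable.

Stage-I hit calling takes an explicit PI threshold and read time; there
is deliberately no default inside the pipeline run record, because any
threshold choice materially changes the funnel and must be auditable. A
suggested configuration is PI ≥ 50% at the 48 h read.

Dispensing arithmetic is exact mass balance: compound amount
= droplets × droplet volume × stock concentration, divided by the
cumulative volume at each stage. Both full accounting (droplet volume in
the denominator) and nominal protocol arithmetic (droplet volume
ignored) are reported; for the default protocol they differ by 0.5% or
less.

## Differential scoring

With S the total fitted saturation above baseline (the maximum culture
density reached across phases), and R, L from the glycolytic (first)
phase, the three differentials are ratio differences:

    ΔS = S_ref,drug/S_ref,ctrl − S_mut,drug/S_mut,ctrl
    ΔR = R_ref,drug/R_ref,ctrl − R_mut,drug/R_mut,ctrl
    ΔL = L_mut,drug/L_mut,ctrl − L_ref,drug/L_ref,ctrl

This form is unitless and strain-baseline-normalized, and the sign
convention is uniform: positive always means the mutant was hit harder.
A control lag of zero is replaced by a 0.25 h floor to keep the lag
ratio defined. Classification is by strict threshold exceedance per
metric (explicit thresholds, ties to nonselective); a score pushed past
threshold in both directions on different metrics is contradictory and
returns `indeterminate`. A compound tested at several concentrations is
reported differential if selective at one or more of them. S excludes
the blank baseline because drug effects act on growth, not on the
optical blank; including the baseline would only dilute the ratios.

## Dose–response and enzyme kinetics

IC50s come from the four-parameter log-logistic family
`bottom + (top − bottom)/(1 + (c/ic50)^hill)`, fitted by bounded least
squares on log-concentration with a multi-start grid of candidate IC50s
across the tested span (Hill slope free by default, fixable at 1).
Asymptote bounds are padded to 10× the observed response span because a
dilution series often covers only part of the transition. Flat
responses return `converged = False` with a `"flat"` diagnostic rather
than a number; IC50s outside the tested span are flagged extrapolated.
An optional case-resampling bootstrap (default 200 replicates) gives a
95% percentile CI.

Initial rates from A340 progress curves use an expanding-window
definition: OLS lines over windows anchored at the first point, keeping
the longest window with R² ≥ 0.98 (configurable); if none qualifies the
minimal window is used with a `curvature` flag. This is an objective
surrogate for by-eye linear-range selection; relaxing the floor can
only lengthen the window. Rates are invariant to constant absorbance
offsets. Per-concentration rates, normalized to the zero-inhibitor
mean, feed the log-logistic fit; with multiple assay runs, per-run
IC50s are fitted and their mean reported.

## Synthetic data: what it emulates, and what it does not

The generator is the package's test bed: every pipeline input can be
produced with known ground truth.

* **Strains.** Archetypes for the reference (two phases), mutant (phase
  1 only) and marker-control strains. Defaults: phase 1 lag 3 h, rate
  0.30 OD/h, saturation 0.8 OD; phase 2 lag 18 h, rate 0.10 OD/h,
  saturation 0.6 OD; baseline 0.05 OD — magnitudes typical of 96-well
  OD600 yeast growth on mixed media. Sampling every 6 min for 48 h.
* **Media.** `media_mix` is the fermentable fraction; 0 suppresses the
  glycolytic phase, 1 the respiratory phase. Phase-2 onset is
  constrained to at least 2 h after the phase-1 inflection, reproducing
  the diauxic pause without modelling substrate depletion.
* **Drugs.** Per-strain maximal multipliers on rate and saturation plus
  an additive lag, scaled by Hill occupancy `c^h/(c^h + EC50^h)`; zero
  dose is an exact identity on the ground truth.
* **Plates.** 384-well layout with columns 1/24 as no-compound controls
  and 2/23 as media blanks (320 compound wells); endpoint reads at 16 h
  and 48 h. 384-well wells are treated as hypoxic: only glycolytic
  physiology is expressed, and a compound's strongest per-strain effect
  applies — this is why compounds that preferentially inhibit the
  reference strain aerobically can still score as Stage-I hits on the
  mutant, as the real screen's two-step protocol anticipates. Control
  plates alternate rows of culture / culture+killer / media.
* **Enzyme assays.** First-order NADH depletion from A340 ≈ 0.65
  toward 0.05, 11 points over 20 min, initial slope
  `v0/(1 + (c/IC50)^h)`. The default uninhibited rate (0.005 A/min)
  keeps substrate consumption below ~20% over the read — standard
  initial-rate assay design — and the default absorbance noise
  (0.001 A) reflects the photometric repeatability of a modern reader.
* **Noise.** Additive Gaussian on OD (default sd 0.01) with no
  spatial/edge effects, drift, carryover or replicate-to-replicate
  systematic error. Consequently, passing recovery tests demonstrates
  estimator correctness and calibration under idealized instrument
  noise; they do not demonstrate robustness to spatial artifacts or
  media batch effects, which real screens must address separately.

Synthetic Stage-II effect classes use essentially saturating potencies
(EC50 1 µM, Hill 2) with saturation multipliers 0.2 (selective target
strain), 0.9 (non-target) and 0.3 (nonselective toxin), i.e.
well-separated effects relative to fit noise. End-to-end sizes in the
tests and acceptance script (320 compounds, 50 actives) were chosen so
a full run completes in minutes on one core while every stage still
exercises multi-plate, multi-class logic.

## Numerical choices and degenerate inputs

* All optimizers run with tight tolerances (1e−14) and fixed,
  seed-derived starts; results are deterministic given the seed.
* Growth fits clamp lags at 0; phases are reported in order of
  inflection time.
* `percent_inhibition` raises when the control mean does not exceed the
  blank mean (a failed plate), rather than returning nonsense.
* `z_factor` raises on equal control means (undefined separation).
* Flat growth curves (< 0.05 OD dynamic range) and flat dose–response
  data short-circuit with explicit diagnostics instead of forced fits.
* The IC50 ratio helper refuses non-converged fits.

## Known limitations

* At most two growth phases; no mechanistic (Monod/substrate) models.
* No spatial normalization (B-score etc.) — the analysed screen design
  relies on in-plate controls instead.
* The lag definition is logistic-specific; curves with strongly
  asymmetric phases may be better served by Gompertz-type components.
* Enzyme rate extraction assumes monotone-decreasing progress curves;
  increasing traces are flagged, not modelled.
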