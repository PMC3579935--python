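# sdhscreen

Analytics for three-stage differential growth-inhibition screening in a
succinate-dehydrogenase-deficient (*sdh2Δ*) yeast model.

Tumours of familial paraganglioma lose succinate dehydrogenase (SDH) and
survive on glycolysis alone. A haploid *sdh2Δ* yeast strain reproduces
that metabolic state and can be screened, against its wild-type parent,
for compounds that are *differentially* toxic to SDH-deficient cells.
`sdhscreen` implements the full analysis stack for such a screen, plus a
synthetic-data generator with known ground truth for validating every
estimator in the chain:

1. **Stage I — endpoint screening** (`sdhscreen.plates`): per-plate
   percent inhibition `PI = 100·(1 − (test − blank)/(control − blank))`,
   z-factor QC `z = 1 − 3(σ_p+σ_n)/|µ_p−µ_n|`, hit calling, and exact
   acoustic-dispensing mass balance.
2. **Stage II — growth-curve analysis** (`sdhscreen.growth`,
   `sdhscreen.differential`): mono-/biphasic (diauxic) fits of
   `OD(t) = b + Σ K_i/(1+e^{−r_i(t−m_i)})` reporting lag `L = m − 2/r`,
   maximal rate `R = rK/4` and saturation `S = K` per phase; then the
   differentials ΔS, ΔR, ΔL between mutant and reference strains with
   selective/nonselective calls.
3. **Stage III — confirmation** (`sdhscreen.differential.marker_concordance`,
   `sdhscreen.doseresponse`, `sdhscreen.enzyme`): marker-strain
   concordance checks, four-parameter log-logistic IC50 fits for
   whole-cell dose–response, and initial-rate extraction from NADH
   (A340) progress curves for enzyme-inhibition IC50s.

The growth, dose–response and initial-rate estimators are scikit-learn
style classes (`GrowthCurveModel`, `LogLogisticIC50`, `InitialRate`)
with `fit`/`predict` and trailing-underscore fitted attributes; the
module-level functions (`fit_growth`, `fit_ic50`, `initial_rate`, …) are
thin wrappers over them.

## Worked example

```python
import sdhscreen as s

# -- simulate a small screen of 64 compounds, 8 true inhibitors --------
reads, plate_map, truth = s.gen_screen_plate(
    n_compounds=64, hit_fraction=0.125, cfg=s.SimConfig(seed=3))
pi = s.summarize_plate(reads, plate_map)
hits = s.call_hits(pi, threshold=50.0, read_time_h=48.0)
print(len(hits), sorted(hits.compound_id)[:3])
# 8 ['C00005', 'C00011', 'C00012']   -- exactly the 8 seeded inhibitors

# -- fit a diauxic growth curve and read off the phase parameters ------
curve = s.gen_growth_curve(s.wild_type(), cfg=s.SimConfig(seed=3))
fit = s.fit_growth(curve.times_h, curve.od)
for p in fit.phases:
    print(f"lag {p.lag_h:.2f} h  rate {p.max_rate:.3f} OD/h  sat {p.saturation:.3f} OD")
# lag 2.99 h  rate 0.297 OD/h  sat 0.801 OD    (truth: 3.0, 0.30, 0.8)
# lag 17.97 h  rate 0.099 OD/h  sat 0.600 OD   (truth: 18.0, 0.10, 0.6)

# -- enzyme-inhibition IC50 at the standard assay design ---------------
from sdhscreen.enzyme import enzyme_inhibition_ic50
records = []
for run in (1, 2, 3):
    records += s.gen_enzyme_assay(3.8, replicates=4, run=run,
                                  cfg=s.SimConfig(noise_sd=0.001, seed=run))
ic50_fit, _ = enzyme_inhibition_ic50(records)
print(f"IC50 = {ic50_fit.ic50:.2f} µM")
# IC50 = 4.17 µM   (truth 3.8 µM; 8-point 5-fold series, 4 replicates, 3 runs)
```

The first block shows Stage-I hit calling recovering a seeded truth
table exactly; the second shows the two growth phases of a diauxic
curve recovered to within a percent; the third recovers an enzyme
IC50 from simulated NADH-depletion progress curves at the standard
8-point, five-fold, quadruplicate design.

The full three-stage pipeline is driven by one explicit config:

```bash
sdhscreen run --seed 1 --outdir out/
sdhscreen report --outdir out/
```

which prints the screening funnel (compounds screened → Stage-I hits →
differential → mutant-selective / reference-selective counts), per-plate
z-factors and the per-compound Δ-scores.

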