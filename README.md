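# epifract

Quantitative scoring of the morphologic complexity of stained epithelial
architecture, and its relation to patient survival.

Pathological grading of invasive breast carcinoma rests on a pathologist's
semi-quantitative reading of histological complexity, with well-documented
inter-observer variation. `epifract` implements an objective alternative for
pan-cytokeratin-stained tissue-microarray (TMA) cores: the **box-counting
fractal dimension** of the segmented epithelial outlines. For a structure
whose outline occupies N(s) boxes of edge s,

    FD = − d log N(s) / d log s,

estimated by ordinary least squares on the log–log box-count curve within a
calibrated 10–50 µm spatial scale window. Each core is background-corrected
against a blank field, binarized at a sweep of intensity thresholds, reduced
to outline images, and scored by the **global maximum** of the FD-versus-
threshold profile — a construction that is invariant to illumination and
stain intensity. A smooth outline (a circle) has FD ≈ 1; a crenellated one
(the Koch snowflake, FD = log 4/log 3 ≈ 1.2619) has FD > 1 despite the same
topological dimension.

Downstream, patients are represented by the maximum FD over their cores,
stratified into low / intermediate / high complexity by data-oriented
cutpoints (the upper quartile, then the median of the lower three-quarters),
and analyzed with Kaplan–Meier curves, logrank tests, Cox proportional-
hazards regression against standard clinicopathological covariates, ROC-AUC
of Cox-predicted event probabilities, predicted-mean imputation of missing
covariates, and split-sample cross-validation with a shrinkage coefficient.

The package is aimed at image-analysis and biostatistics researchers
evaluating morphometric biomarkers. No clinical imaging data are bundled: a
first-class `synthetic` module generates reference shapes with known
analytic dimension, pseudo-tissue images with a tunable complexity dial, and
survival cohorts with proportional-hazards structure.

## Worked example

```python
from epifract import (
    PipelineConfig, fd_profile, core_fd, render_fixture, render_pseudo_tissue,
    simulate_cohort, select_cutpoints, cox_fit, roc_auc, split_sample_cv,
)
from epifract.synthetic import FixtureSpec, CohortSpec
from epifract.cohort import records_to_frame

# 1. a shape of known dimension, through the full pipeline
image, analytic = render_fixture(FixtureSpec(shape="koch", order=5, image_size=2048))
profile = fd_profile(image)
print(f"koch fd={profile.max_fd.fd:.3f} (analytic {analytic:.4f}), "
      f"r2={profile.max_fd.r_squared:.3f}")
# koch fd=1.262 (analytic 1.2619), r2=0.998

# 2. a pseudo-stained core with its blank field
specimen, blank = render_pseudo_tissue(0.8, image_size=512, seed=1)
qc, prof = core_fd(specimen, blank, PipelineConfig())
print(f"stained={qc.stained_fraction:.2f} fd={prof.max_fd.fd:.3f}")
# stained=0.62 fd=1.432

# 3. a simulated cohort, categorized and related to survival
records, _ = simulate_cohort(CohortSpec(n_patients=379, seed=1))
df = records_to_frame(records)
fit = cox_fit(df, outcome="dss", covariates=["category"])
print(fit.hazard_ratios.round(2).to_dict())
# {'category_intermediate': 2.13, 'category_high': 3.13}
print(f"AUC={roc_auc(fit, df, 'dss', horizon=10.0):.2f}")
# AUC=0.63
report, _, _ = split_sample_cv(df, "dss", ["category"], 0.5, seed=17)
print(f"shrinkage={report.shrinkage:.3f} generalizable={report.generalizable}")
# shrinkage=0.059 generalizable=True
```

The hazard ratios say that, in this simulated cohort, patients in the
intermediate and high complexity strata die of their disease at 2.1× and
3.1× the rate of the low stratum; the shrinkage of 0.06 (< 0.10) indicates
the categorized score generalizes from the training half to the validation
half of the sample.

The same pipeline is scriptable from the shell:

```bash
epifract simulate fixtures --out fixtures/
epifract fd --input cores/ --blank blank.tif --calibration 1.06 --out fd.csv
epifract cohort --fd fd.csv --patients patients.csv --out cohort.csv --summary summary.json
epifract survival --cohort cohort.csv --outcome dss --model full --out report.json --cv
epifract run --out results/ --simulate 379 --seed 17     # end to end, synthetic
```

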