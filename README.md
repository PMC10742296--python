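# tilscore

Digital tumour-infiltrating-lymphocyte (TIL) scoring and survival analysis
for classified H&E nuclei maps, with nasopharyngeal carcinoma (NPC) as the
motivating disease setting.

Pathologists know that the abundance and placement of lymphocytes in and
around tumour regions carries prognostic information, but visual TIL
scoring is subjective. `tilscore` automates the downstream half of that
problem: given per-nucleus centroids (and optionally contours) already
classified as *tumour*, *lymphocyte* or *other* by an upstream segmentation
model, it

1. clusters tumour nuclei by spatial density (DBSCAN, `eps` = 200 px,
   `min_pts` = 10 at 0.255 µm/px),
2. builds each cluster's **inner region** and a 60-px **expansion ring**,
   defining the *intratumoural* and *stromal* compartments,
3. quantifies **12 digital TIL features** — for each location
   *L* ∈ {combined, intratumoural, stromal}:

   | family | definition |
   |---|---|
   | TIL ratio | N<sub>TIL</sub>(L) / N<sub>tumour</sub>(L) |
   | TIL density (cluster) | N<sub>TIL</sub>(L) / region area(L) |
   | TIL density (tumour) | N<sub>TIL</sub>(L) / Σ tumour-nucleus area(L) |
   | TIL area ratio | Σ TIL-nucleus area(L) / Σ tumour-nucleus area(L) |

   plus **9 nuclear-morphology features** (contour area, convex area,
   equivalent diameter, major/minor axis length, perimeter, bounding-box
   area, solidity, eccentricity) averaged over intratumoural tumour nuclei,
4. aggregates features per case (mean over a case's WSIs), and
5. runs the prognostic pipeline: Random Survival Forest (RSF) risk scores
   from a grid search over event-stratified 3-fold cross-validation,
   Harrell's C-index, a log-rank-optimal risk-score cutoff found in the
   discovery set (low risk = score ≤ cutoff), Kaplan–Meier curves with the
   log-rank test in the validation set, and univariate/multivariate Cox
   proportional-hazards tables (HR, Wald 95 % CI, p). Follow-up is
   right-censored at 60 months; four endpoints are supported (LRFS, DMFS,
   PFS, RRFS); EBV-DNA is grouped at 4000 copies/mL.

Because the clinical cohort this method targets is institutional, the
package ships a first-class **synthetic cohort generator** that emulates
clustered tumour point patterns with compartment-specific lymphocyte
rates, elliptical nucleus contours, clinical covariates drawn from the
reference cohort's category frequencies, and proportional-hazards survival
times linked (protectively) to TIL abundance.

## Worked example

```python
from tilscore import CohortConfig, gen_cohort, RunConfig
from tilscore.pipeline import run_all

cfg = CohortConfig(n_cases=80, n_multi_wsi=4, clusters_per_slide=(1, 2),
                   tumour_per_cluster=(25, 40), seed=11)
gen_cohort(cfg, out_dir="demo_cohort")

run_cfg = RunConfig(
    nuclei_dir="demo_cohort/nuclei",
    clinical_path="demo_cohort/clinical.csv",
    out_dir="demo_results",
    endpoints=("lrfs",),
    feature_sets=("til",),
    rsf_grid=({"n_estimators": 100, "min_samples_leaf": 10,
               "max_features": "sqrt"},),
    seed=0,
)
out = run_all(run_cfg)
print((out / "summary.md").read_text())
```

prints

```
# Run summary

## lrfs / til

- CV C-index: discovery 0.615 +/- 0.047, validation 0.566 +/- 0.054
- validation-set C-index: 0.658
- cutoff 12.42; log-rank chi2 3.89, p = 0.0486
```

Reading this: the RSF's cross-validated concordance on the 56-case
discovery set is modest (a C-index of 0.5 is chance, 1.0 perfect
ranking); scoring the held-out 24-case validation set with the
discovery-fit forest gives C = 0.658; splitting those cases at the
discovery-derived cutoff (12.42) separates their Kaplan–Meier curves with
log-rank p ≈ 0.049. At this small demo scale the planted protective TIL
effect is just detectable; the acceptance checks below use n = 300. The
output directory also holds per-case risk scores, KM curve points, Cox
tables, permutation feature importance and low-vs-high feature
comparisons as CSV, plus a JSON manifest of every seed and parameter.

The same stages are available from the shell:

```bash
til-score gen-cohort --out demo_cohort --n-cases 80 --seed 11
til-score run-all --nuclei-dir demo_cohort/nuclei \
    --clinical demo_cohort/clinical.csv --endpoint lrfs \
    --feature-set til --out demo_results
```

## Layout

- `src/tilscore/nuclei_io.py` — nuclei-map (GeoJSON/CSV) and clinical
  table readers/writers
- `src/tilscore/spatial_clustering.py` — DBSCAN, region geometry,
  compartment assignment
- `src/tilscore/til_quantification.py` — the 12 TIL + 9 morphology
  features and per-case aggregation
- `src/tilscore/survival_models.py` — RSF CV, C-index, cutoff, KM,
  log-rank, Cox
- `src/tilscore/synthetic_cohort.py` — synthetic nuclei maps, clinical
  covariates and survival times
- `src/tilscore/pipeline.py`, `cli.py` — orchestration and the
  `til-score` command
- `docs/methods.md` — model assumptions, parameter choices, limitations
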