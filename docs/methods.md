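# Methods

This note records the models, parameter choices and numerical conventions
behind `tilscore`, and what the synthetic-data tests do and do not show.

## Input contract

The package starts *after* nucleus detection/segmentation/classification:
its input is a classified nuclei map per whole-slide image (WSI) — one
record per nucleus with a centroid in pixel coordinates (origin top-left,
y down, 40× frame at 0.255 µm/px), a class in {tumour, lymphocyte, other},
and optionally a simple closed contour polygon and/or a precomputed area.
Upstream classifiers emit richer vocabularies ("neoplastic",
"inflammatory", …); a configurable alias map collapses them to the three
classes the method needs, and unknown labels fall back to "other" with a
logged count. A nucleus may carry an area without a contour; it then
contributes to count- and area-based TIL features but not to morphology,
and the exclusion is logged. Stored area and contour area must agree to
1 %.

## Tumour-cluster geometry

Tumour nuclei are clustered with DBSCAN, eps = 200 px, min_samples = 10,
where the neighbourhood count **includes the point itself** (the
convention of scikit-learn, which backs the implementation; the test
suite pins this down against a brute-force density-reachability oracle).
Each cluster's *inner region* is a polygon built from member centroids by
one of two selectable constructions:

- **closing** (default): union of 10-px (`r_pad`) discs around member
  centroids, morphologically closed (buffer +eps/2 then −eps/2). This
  follows concave cluster shapes and fills intra-cluster gaps up to the
  DBSCAN reachability scale. The exact region geometry for "cluster area"
  is not standardised anywhere; this is the package's own definition.
- **convex_hull**: convex hull of member centroids (buffered by `r_pad`
  when `r_pad` > 0). Kept because dilation of a convex polygon has the
  closed form A + P·r + πr², used as an analytic fixture.

The *expanded region* is the Minkowski dilation of the inner region by a
60-px disc (a shapely buffer with 16 segments per quadrant; the polygonal
disc approximation keeps area errors well under 0.5 %, and the expansion
of 60 px corresponds to 15.3 µm at 0.255 µm/px). The *outer ring* is
expanded minus inner.

Compartments are assigned by centroid: intratumoural iff the centroid
lies in (or on the boundary of — regions are closed) any inner region;
stromal iff not intratumoural but inside any expanded region; otherwise
outside. Tumour nuclei that are DBSCAN cluster members are intratumoural
by construction (matched back to their labels by exact centroid lookup,
so nucleus ordering is irrelevant). When expanded regions of different
clusters overlap, a nucleus is attributed to the cluster with the nearest
inner-region boundary, and all global region areas are union areas so
overlap is never double-counted.

A consequence of eps = 200 px with a 60-px ring worth stating: a tumour
nucleus inside a ring is almost always within eps of a core point and
therefore *joins* the cluster instead of remaining a ring resident.
Ring-resident (stromal) tumour nuclei are thus rare — they require sparse
cluster fringes held together by non-core members — and the stromal
features whose denominator is the stromal tumour count are frequently
zero-valued. Zero denominators are mapped to feature value 0 with a
per-slide QC flag (keeping the model input rectangular), never to missing
values.

## Features

The 12 TIL features are four families × three locations. Combined-location
features pool counts and areas across compartments (ratio of sums), never
average the two compartment ratios. "TIL density cluster" divides by
geometric region area (inner area, ring area, or expanded-union area for
the combined location); "TIL density tumour" divides by summed
tumour-nucleus area. Densities are canonical in px⁻²; a helper converts
to mm⁻² via the slide's µm/px. Nuclei assigned "outside" never contribute.

The 9 morphology features are measured per tumour-nucleus contour: area
by the shoelace formula, perimeter as polygon arc length, convex area
from the hull, equivalent diameter √(4A/π), axis-aligned bounding-box
area, solidity A/A_hull, and major/minor axis length and eccentricity
from the ellipse whose second central moments match the polygon region
(Green's-theorem closed forms; axis length = 4·√eigenvalue, the usual
region-props convention). Upstream classifiers often use an 11-feature
morphology set; the two dropped here are orientation (not a
size/irregularity measure) and radius (duplicates equivalent diameter).
Morphology is averaged over **intratumoural** tumour nuclei only; slides
without any contoured intratumoural tumour nucleus yield an all-missing
morphology vector, flagged, and per-case aggregation averages each
feature over the WSIs where it is available (unweighted mean; `n_wsis`
recorded).

## Survival pipeline

Endpoint times are right-censored at a 60-month horizon (events after the
horizon are recoded censored; an event exactly at 60 months stays an
event). EBV-DNA copies are grouped at 4000 copies/mL (low ≤ 4000).

Risk scores come from a Random Survival Forest (scikit-survival, log-rank
split rule) grid-searched over event-stratified 3-fold cross-validation;
the default grid is trees ∈ {200, 500} × min-leaf ∈ {5, 15} ×
features-per-split ∈ {√p, p/3} — a small standard grid, fully
overridable. The grid point with the best mean validation C-index wins,
and every case receives an **out-of-fold** score from that grid point;
out-of-fold scores (never refit-on-all scores) feed cutoff finding, which
prevents leakage. Harrell's C-index uses the classical conventions: a
pair is comparable when the shorter time carries an event (tied times
only when exactly one is an event); tied risks count ½.

The cutoff is the candidate midpoint between consecutive sorted unique
scores that minimises the two-group log-rank p-value, with each group
required to hold ≥ 10 % of cases (the "significance" method of common
cutoff-optimisation tools; the group floor prevents degenerate splits and
ties break toward the more balanced split). Low risk = score ≤ cutoff.
This optimal-cutoff scan is optimistic by construction; the null
calibration test documents that the *median-split* log-rank keeps its
nominal size, while the pipeline always evaluates the chosen cutoff on a
held-out validation set (30 % of cases, event-stratified).

Kaplan–Meier estimation and the two-group log-rank test are implemented
directly (plain risk-table arithmetic, hypergeometric variance); the test
suite requires agreement with lifelines to 1e-8. Cox proportional-hazards
fits use lifelines with declared reference levels (sex: female; T: 1;
N: 0; stage: I; EBV: low); univariate mode fits one covariate (with all
its dummy levels) at a time; non-convergence or separation yields flagged
rows rather than exceptions. Endpoint p-values are reported unadjusted by
default, with an optional Holm correction flag. Feature importance is
permutation importance: mean drop in out-of-fold validation C-index over
20 seeded permutations per feature, per fold.

Endpoints with fewer than 5 events are refused with a diagnostic (sparse
endpoints make every downstream quantity unstable). The low-vs-high group
feature comparison chooses Student's t versus Mann–Whitney U per feature
by a Shapiro normality pre-test at α = 0.05.

## Synthetic cohort generator

The generator's defaults encode the study conditions the package targets:
367 cases (18 with two WSIs, 385 WSIs total), clinical covariates drawn
from the reference cohort's category counts (e.g. male 260/367 = 70.84 %,
EBV-high 167/367 = 45.50 %, age ≈ N(45.64, 11.30)), covariates
independent of survival by default (matching the null covariate effects
a TIL-driven model assumes).

Per slide: 2–4 cluster centres placed uniformly with ≥ 1800-px
separation; 40–80 tumour nuclei per cluster, Gaussian scatter σ = 120 px.
Intratumoural TILs are Poisson with expected count (rate × tumour count),
each placed uniformly within 9 px of a random member tumour nucleus —
deliberately inside the `r_pad` disc, so a planted intratumoural TIL is
inside the inner region by construction and the rate-recovery tests
measure the pipeline, not placement leakage. Stromal TILs are pushed
15–55 px radially outward from random convex-hull vertices of the
*generating* scatter (never the recovered regions, keeping the generator
independent of the code under test); a few percent of them land outside
the recovered ring, and that recovery error is part of what the tests
measure. Default rates: intratumoural 0.5 / stromal 0.8 TILs per tumour
nucleus for low-risk cases, 0.15 / 0.25 for high-risk, with lognormal
(σ = 0.25) per-case jitter — order-of-magnitude choices reflecting that
TIL-rich cases fare better. Contours are rotated 32-gon ellipses;
high-risk tumour nuclei are ~20 % larger (420 vs 350 px²) and more
elongated (axis ratio 0.60 vs 0.75), the direction real high-risk
morphology shows. Background "other" nuclei are uniform (mean 150 per
slide).

Survival: event time ~ Exponential with hazard h₀·exp(β·z), h₀ = ln 2/36
per month (36-month median, matching the cohort's median follow-up),
z the standardised planted TIL ratio, β = −0.7 per SD (protective).
Censoring is independent U(0, u) with u calibrated by bisection so the
expected pre-horizon censoring fraction equals the configured 0.30, then
everything is clipped at 60 months. In the full cohort generator the
survival driver is the *planted* per-case TIL ratio (placed TILs /
placed tumour nuclei), again independent of the quantification code.

A feature-level sampler (`gen_case_features`) draws the same planted
counts/areas and evaluates the feature formulas directly, bypassing slide
geometry; large simulation batteries (hundreds of cohorts) use it, while
geometric recovery of the same rates is exercised separately through the
full DBSCAN → regions → compartments → features path.

What the generator does **not** emulate: stain/scanner variation and
segmentation error (upstream concerns), ragged real tumour fronts (its
Gaussian blobs make stromal *tumour* nuclei essentially absent, so the
three stromal features with tumour-count/area denominators are degenerate
in synthetic data even though they can be informative on real slides),
spatial correlation between TIL abundance and nucleus morphology, and
informative censoring. Passing tests therefore demonstrate correctness of
the pipeline's algorithms and calibration of its statistics under the
stated model — not clinical performance on real WSIs.

## Numerical choices and problem sizes

- shapely buffers use 16 segments per quadrant; closed-form geometry
  checks pass at 0.5 % and in practice agree to ~0.05 %.
- Closing-mode region areas are rotation-equivariant only to ~1e-4
  relative (point-buffer discs are discretised with axis-anchored
  vertices); convex-hull areas are exact under rigid motions.
- Boundary centroids count as inside (covers-semantics); ties between
  overlapping rings go to the nearest inner boundary.
- All stochastic steps take explicit integer seeds; cohort generation is
  a pure function of (config, seed), and run manifests record every seed
  and parameter.
- Simulation sizes in the test suite and acceptance script (e.g. n = 300
  cohorts, 25-seed medians, 100-slide rate recovery, a single-point RSF
  grid with 100 trees for batteries) are the package's chosen desk-scale
  defaults; larger grids and cohorts are configuration away.

## Known limitations

- The method inherits DBSCAN's parameter sensitivity; eps/min_pts were
  fixed upstream (200 px / 10) and are exposed but not auto-tuned.
- The optimal-cutoff procedure is optimistic on the discovery set by
  design; only validation-set statistics should be interpreted.
- Cox tables on small validation sets with rare events produce wide,
  unstable intervals (flagged, not suppressed).
- Real cohort results depend on upstream nucleus classification quality,
  which is outside this package's scope.
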