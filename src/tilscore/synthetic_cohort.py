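"""Synthetic cohort generator: nuclei maps + clinical table + survival times.

The real cohort behind this method is institutional and not public, so this
module generates data with the statistical structure the analysis assumes:

* Tumour nuclei form dense spatial clusters (Gaussian scatter about
  well-separated cluster centres on a virtual slide), the pattern DBSCAN is
  meant to recover.
* Lymphocytes are planted at compartment-specific Poisson rates (expected
  TILs per tumour nucleus): intratumoural TILs next to member tumour
  nuclei, stromal TILs just outside the cluster boundary (within the 60-px
  expansion band).
* Nucleus contours are rotated ellipses; high-risk cases get larger, more
  elongated tumour nuclei than low-risk cases.
* Survival follows a proportional-hazards model: exponential event times
  with hazard h0 * exp(beta * z), z the standardised planted TIL ratio and
  beta < 0 protective; censoring is independent uniform, calibrated to a
  target censoring fraction, then clipped at the 60-month horizon.

Stromal placement is relative to the *generating* cluster geometry, never
the recovered regions, so recovery error is part of what downstream tests
measure.  All sampling flows through one seeded generator: output is a pure
function of (config, seed).

``COHORT_MARGINS`` holds the category counts of the 367-case
nasopharyngeal-carcinoma cohort the defaults emulate; clinical covariates
are drawn from those margins, independent of survival by default.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .nuclei_io import (
    CLASS_LYMPHOCYTE,
    CLASS_OTHER,
    CLASS_TUMOUR,
    DEFAULT_MPP,
    ClinicalRecord,
    NucleusRecord,
    SlideNucleiMap,
    clinical_to_frame,
    write_nuclei_map,
)
from .survival_models import SurvivalData, censor_at
from .til_quantification import MORPH_FEATURE_NAMES, TIL_FEATURE_NAMES

# ---------------------------------------------------------------------------
# Reference cohort margins (category counts the generator defaults emulate)
# ---------------------------------------------------------------------------

COHORT_MARGINS: dict = {
    "n_collected": 378,          # cases with WSIs before exclusion
    "n_without_clinical": 11,    # excluded: WSIs but no clinical follow-up
    "n_cases": 367,
    "n_wsis": 385,
    "age_mean": 45.64,
    "age_sd": 11.30,
    "sex": {"male": 260, "female": 107},
    "t_stage": {1: 30, 2: 49, 3: 198, 4: 90},
    "n_stage": {0: 36, 1: 144, 2: 127, 3: 60},
    "stage": {"I": 8, "II": 30, "III": 194, "IV": 135},
    "ebv_group": {"low": 200, "high": 167},
}


def margin_percentages() -> dict[str, dict[str, float]]:
    """Category percentages recomputed from the margin counts."""
    out: dict[str, dict[str, float]] = {}
    n = COHORT_MARGINS["n_cases"]
    for var in ("sex", "t_stage", "n_stage", "stage", "ebv_group"):
        out[var] = {
            str(k): 100.0 * v / n for k, v in COHORT_MARGINS[var].items()
        }
    return out


RISK_GROUPS = ("low_risk", "high_risk")


class CohortGenError(ValueError):
    """Invalid generator configuration or output refusal."""


@dataclass
class CohortConfig:
    """Generator knobs; defaults are the study conditions the package targets.

    Rates are expected TILs per tumour nucleus by compartment and risk
    group; sizes/areas are px and px^2 at 0.255 um/px; hazards are per
    month.
    """

    n_cases: int = 367
    n_multi_wsi: int = 18            # cases contributing two WSIs (367+18=385)
    frac_high_risk: float = 0.5

    # slide geometry
    slide_size: tuple[float, float] = (10000.0, 10000.0)
    clusters_per_slide: tuple[int, int] = (2, 4)
    tumour_per_cluster: tuple[int, int] = (40, 80)
    cluster_sigma: float = 120.0     # Gaussian scatter of tumour nuclei, px
    cluster_min_sep: float = 1800.0  # min centre separation, px
    til_offset_max: float = 9.0      # intratumoural TIL offset from its tumour
                                     # neighbour; kept below the r_pad region pad
                                     # so infiltrating TILs sit inside the cluster
    stromal_offset: tuple[float, float] = (15.0, 55.0)  # px beyond the boundary

    # compartment TIL rates per risk group
    til_intra_rate: dict = field(
        default_factory=lambda: {"low_risk": 0.5, "high_risk": 0.15}
    )
    til_stromal_rate: dict = field(
        default_factory=lambda: {"low_risk": 0.8, "high_risk": 0.25}
    )
    rate_jitter_sd: float = 0.25     # lognormal sd of per-case rate multipliers

    # nucleus contours (rotated ellipses, 32 vertices)
    contours: bool = True
    contour_vertices: int = 32
    tumour_area_mean: dict = field(
        default_factory=lambda: {"low_risk": 350.0, "high_risk": 420.0}
    )
    tumour_area_sd: float = 60.0
    tumour_axis_ratio_mean: dict = field(
        default_factory=lambda: {"low_risk": 0.75, "high_risk": 0.60}
    )
    axis_ratio_sd: float = 0.08
    til_area_mean: float = 90.0
    til_area_sd: float = 15.0
    other_area_mean: float = 110.0
    other_area_sd: float = 20.0
    n_background_mean: float = 150.0  # uniform "other" nuclei per slide

    # survival model
    baseline_hazard: float = math.log(2) / 36.0  # median event time 36 months
    log_hr_per_sd: float = -0.7                  # protective TIL effect
    censor_rate: float = 0.3
    horizon: float = 60.0
    endpoints: tuple[str, ...] = ("lrfs", "dmfs", "pfs", "rrfs")

    seed: int = 0

    def validate(self) -> None:
        if any(r < 0 for r in self.til_intra_rate.values()):
            raise CohortGenError("til_intra_rate must be >= 0")
        if any(r < 0 for r in self.til_stromal_rate.values()):
            raise CohortGenError("til_stromal_rate must be >= 0")
        if self.baseline_hazard <= 0:
            raise CohortGenError("baseline_hazard must be > 0")
        if not math.isfinite(self.log_hr_per_sd):
            raise CohortGenError("log_hr_per_sd must be finite")
        if not 0 <= self.censor_rate < 1:
            raise CohortGenError("censor_rate must lie in [0, 1)")


# ---------------------------------------------------------------------------
# Nuclei-map generation
# ---------------------------------------------------------------------------


def _ellipse_contour(
    rng: np.random.Generator, area: float, axis_ratio: float, centre, n_vertices: int
) -> np.ndarray:
    """Rotated ellipse polygon with the given area and minor/major ratio."""
    q = min(max(axis_ratio, 0.1), 1.0)
    a = math.sqrt(area / (math.pi * q))  # semi-major
    b = q * a
    theta = rng.uniform(0, math.pi)
    t = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    xy = np.column_stack([a * np.cos(t), b * np.sin(t)])
    rot = np.array(
        [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
    )
    return xy @ rot.T + np.asarray(centre)


def _sample_centres(rng, n, size, min_sep) -> np.ndarray:
    margin = min_sep / 2.0
    for _ in range(2000):
        pts = rng.uniform([margin, margin], [size[0] - margin, size[1] - margin], (n, 2))
        if n == 1:
            return pts
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() >= min_sep:
            return pts
    raise CohortGenError("could not place cluster centres with the requested separation")


def _boundary_positions(rng, pts: np.ndarray, offset: tuple[float, float], k: int) -> np.ndarray:
    """k positions just outside the point cloud: random convex-hull vertex
    pushed radially outward by U(offset) px (plus a small tangential jitter)."""
    if k == 0:
        return np.empty((0, 2))
    centre = pts.mean(axis=0)
    try:
        hull_pts = pts[ConvexHull(pts).vertices]
    except Exception:  # degenerate (collinear) cluster
        hull_pts = pts
    picks = hull_pts[rng.integers(0, len(hull_pts), k)]
    vec = picks - centre
    norm = np.linalg.norm(vec, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    direction = vec / norm
    out = picks + direction * rng.uniform(offset[0], offset[1], (k, 1))
    return out + rng.normal(0, 2.0, out.shape)


def gen_nuclei_map(
    config: CohortConfig,
    risk_group: str = "low_risk",
    seed: int | np.random.Generator = 0,
    slide_id: str = "slide",
    til_intra_rate: float | None = None,
    til_stromal_rate: float | None = None,
) -> SlideNucleiMap:
    """Generate one slide's classified nuclei map.

    Per-case rate overrides (``til_intra_rate``/``til_stromal_rate``) take
    precedence over the group defaults in ``config``.
    """
    config.validate()
    if risk_group not in RISK_GROUPS:
        raise CohortGenError(f"unknown risk group {risk_group!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r_intra = config.til_intra_rate[risk_group] if til_intra_rate is None else til_intra_rate
    r_strom = config.til_stromal_rate[risk_group] if til_stromal_rate is None else til_stromal_rate

    n_clusters = int(rng.integers(config.clusters_per_slide[0], config.clusters_per_slide[1] + 1))
    exp_per_cluster = config.tumour_per_cluster[1] * (1 + r_intra + r_strom)
    if n_clusters * exp_per_cluster + config.n_background_mean > 1e6:
        raise CohortGenError("configuration implies more than 1e6 nuclei per slide")
    centres = _sample_centres(rng, n_clusters, config.slide_size, config.cluster_min_sep)

    records: list[NucleusRecord] = []

    def _add(cls: str, pos, area_mean, area_sd, axis_ratio_mean=0.85, tag="n"):
        area = max(float(rng.normal(area_mean, area_sd)), 20.0)
        q = float(rng.normal(axis_ratio_mean, config.axis_ratio_sd))
        contour = None
        stored_area = None
        if config.contours:
            contour = _ellipse_contour(rng, area, q, pos, config.contour_vertices)
        else:
            stored_area = area
        # the id tag records the planted compartment (ground truth for tests)
        records.append(
            NucleusRecord(
                id=f"{slide_id}-{tag}{len(records)}",
                x=float(pos[0]),
                y=float(pos[1]),
                cls=cls,
                contour=contour,
                area=stored_area,
            )
        )

    t_area = config.tumour_area_mean[risk_group]
    t_ratio = config.tumour_axis_ratio_mean[risk_group]
    for c in centres:
        n_t = int(rng.integers(config.tumour_per_cluster[0], config.tumour_per_cluster[1] + 1))
        pts = c + rng.normal(0, config.cluster_sigma, (n_t, 2))
        for p in pts:
            _add(CLASS_TUMOUR, p, t_area, config.tumour_area_sd, t_ratio)
        # intratumoural TILs: next to member tumour nuclei (uniform in a
        # disc of radius til_offset_max around a random member centroid)
        n_ti = rng.poisson(r_intra * n_t)
        base = pts[rng.integers(0, n_t, n_ti)]
        ang = rng.uniform(0, 2 * math.pi, n_ti)
        rad = config.til_offset_max * np.sqrt(rng.random(n_ti))
        offs = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        for p in base + offs:
            _add(CLASS_LYMPHOCYTE, p, config.til_area_mean, config.til_area_sd,
                 tag="til-i")
        # stromal TILs: just beyond the cluster boundary
        n_ts2 = rng.poisson(r_strom * n_t)
        for p in _boundary_positions(rng, pts, config.stromal_offset, n_ts2):
            _add(CLASS_LYMPHOCYTE, p, config.til_area_mean, config.til_area_sd,
                 tag="til-s")
    # background nuclei, uniform over the slide
    for _ in range(rng.poisson(config.n_background_mean)):
        pos = rng.uniform([0, 0], list(config.slide_size))
        _add(CLASS_OTHER, pos, config.other_area_mean, config.other_area_sd)

    return SlideNucleiMap(slide_id=slide_id, nuclei=records, mpp=DEFAULT_MPP)


# ---------------------------------------------------------------------------
# Feature-level cohort sampler (statistics without slide geometry)
# ---------------------------------------------------------------------------


def gen_case_features(
    config: CohortConfig, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample per-case feature rows from the generator's distributions.

    Draws the same planted counts and areas the slide generator would place
    (tumour nuclei per cluster, Poisson TIL counts per compartment, ellipse
    size statistics) and evaluates the 12 TIL feature formulas and 9
    morphology means on those planted quantities directly, bypassing slide
    geometry.  Used where thousands of cases are needed quickly; geometric
    recovery of the same rates is exercised separately.

    Returns (feature DataFrame indexed by case_id, risk-group array).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_cases
    groups = np.where(
        rng.random(n) < config.frac_high_risk, "high_risk", "low_risk"
    )
    rows = []
    for i in range(n):
        g = groups[i]
        jitter = rng.lognormal(0.0, config.rate_jitter_sd, 2)
        r_i = config.til_intra_rate[g] * jitter[0]
        r_s = config.til_stromal_rate[g] * jitter[1]
        n_clusters = int(rng.integers(config.clusters_per_slide[0],
                                      config.clusters_per_slide[1] + 1))
        n_tum_i = int(
            rng.integers(config.tumour_per_cluster[0],
                         config.tumour_per_cluster[1] + 1, n_clusters).sum()
        )
        n_tum_s = 0  # ring-resident tumour nuclei are geometrically impossible
        # at eps=200 with a 60-px ring: anything that close joins the cluster
        n_til_i = int(rng.poisson(r_i * n_tum_i))
        n_til_s = int(rng.poisson(r_s * n_tum_i))

        # region areas consistent with the scatter scale: the cluster mass
        # lies within ~2.2 sigma; the ring is a ~70 px band around it
        r_eff = 2.2 * config.cluster_sigma
        inner_area = n_clusters * math.pi * r_eff**2 * rng.lognormal(0, 0.1)
        ring_area = n_clusters * 2 * math.pi * r_eff * 70.0 * rng.lognormal(0, 0.1)

        t_area = float(rng.normal(config.tumour_area_mean[g],
                                  config.tumour_area_sd / math.sqrt(max(n_tum_i, 1))))
        til_area = config.til_area_mean
        tum_area_i = t_area * n_tum_i
        tum_area_s = t_area * n_tum_s
        til_area_i = til_area * n_til_i
        til_area_s = til_area * n_til_s

        def _div(a, b):
            return a / b if b > 0 else 0.0

        row = {
            "case_id": f"case{i:04d}",
            "til_ratio": _div(n_til_i + n_til_s, n_tum_i + n_tum_s),
            "intratumoural_til_ratio": _div(n_til_i, n_tum_i),
            "stromal_til_ratio": _div(n_til_s, n_tum_s),
            "til_density_cluster": _div(n_til_i + n_til_s, inner_area + ring_area),
            "intratumoural_til_density_cluster": _div(n_til_i, inner_area),
            "stromal_til_density_cluster": _div(n_til_s, ring_area),
            "til_density_tumour": _div(n_til_i + n_til_s, tum_area_i + tum_area_s),
            "intratumoural_til_density_tumour": _div(n_til_i, tum_area_i),
            "stromal_til_density_tumour": _div(n_til_s, tum_area_s),
            "til_area_ratio": _div(til_area_i + til_area_s, tum_area_i + tum_area_s),
            "intratumoural_til_area_ratio": _div(til_area_i, tum_area_i),
            "stromal_til_area_ratio": _div(til_area_s, tum_area_s),
        }
        q = float(np.clip(rng.normal(config.tumour_axis_ratio_mean[g],
                                     config.axis_ratio_sd / 3.0), 0.2, 0.98))
        a = math.sqrt(t_area / (math.pi * q))
        b = q * a
        solidity = float(np.clip(rng.normal(0.97, 0.01), 0.8, 1.0))
        row.update(
            {
                "contour_area": t_area,
                "convex_area": t_area / solidity,
                "equivalent_diameter": math.sqrt(4 * t_area / math.pi),
                "major_axis_length": 2 * a,
                "minor_axis_length": 2 * b,
                "perimeter": math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b))),
                "bounding_box_area": 4 * a * b,
                "solidity": solidity,
                "eccentricity": math.sqrt(1 - q**2),
            }
        )
        rows.append(row)
    df = pd.DataFrame(rows).set_index("case_id")
    return df[list(TIL_FEATURE_NAMES) + list(MORPH_FEATURE_NAMES)], groups


# ---------------------------------------------------------------------------
# Survival generation
# ---------------------------------------------------------------------------


def _calibrate_uniform_upper(hazards: np.ndarray, censor_rate: float) -> float:
    """Upper bound u of U(0, u) censoring achieving the target pre-horizon
    censoring fraction: solves mean_i (1 - exp(-h_i u)) / (h_i u) = rate."""

    def frac_censored(u: float) -> float:
        x = hazards * u
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-6, 1e7
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if frac_censored(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def gen_survival(
    til_ratio,
    config: CohortConfig,
    seed: int = 0,
    endpoint: str = "lrfs",
    case_ids=None,
) -> SurvivalData:
    """Proportional-hazards event times linked to the planted TIL ratio.

    ``til_ratio`` may be a numeric vector or a feature DataFrame (its
    ``til_ratio`` column is used).  Event time ~ Exponential with hazard
    ``h0 * exp(beta * z)``, z the standardised TIL ratio; censoring is
    independent U(0, u) with u calibrated to ``config.censor_rate``, then
    everything is right-censored at ``config.horizon`` months.
    """
    config.validate()
    if isinstance(til_ratio, pd.DataFrame):
        if case_ids is None:
            case_ids = til_ratio.index.to_numpy()
        til_ratio = til_ratio["til_ratio"].to_numpy()
    x = np.asarray(til_ratio, dtype=float)
    rng = np.random.default_rng(seed)
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    hazards = config.baseline_hazard * np.exp(config.log_hr_per_sd * z)
    t_event = rng.exponential(1.0 / hazards)
    if config.censor_rate > 0:
        u = _calibrate_uniform_upper(hazards, config.censor_rate)
        t_cens = rng.uniform(0, u, len(x))
    else:
        t_cens = np.full(len(x), np.inf)
    times = np.maximum(np.minimum(t_event, t_cens), 1e-3)
    events = (t_event <= t_cens).astype(int)
    if case_ids is None:
        case_ids = np.array([f"case{i:04d}" for i in range(len(x))])
    data = SurvivalData(np.asarray(case_ids), times, events, endpoint, config.horizon)
    return censor_at(data, config.horizon)


# ---------------------------------------------------------------------------
# Clinical covariates and the full cohort
# ---------------------------------------------------------------------------


def _sample_categorical(rng, counts: dict, n: int) -> np.ndarray:
    keys = list(counts.keys())
    p = np.array([counts[k] for k in keys], dtype=float)
    p /= p.sum()
    return rng.choice(np.array(keys, dtype=object), size=n, p=p)


def gen_clinical(
    config: CohortConfig,
    case_ids,
    survival: dict[str, SurvivalData],
    seed: int = 0,
) -> list[ClinicalRecord]:
    """Clinical covariates drawn from the reference margins, independent of
    survival (the default; matching the null covariate effects the survival
    model assumes)."""
    rng = np.random.default_rng(seed)
    n = len(case_ids)
    sex = _sample_categorical(rng, COHORT_MARGINS["sex"], n)
    t_stage = _sample_categorical(rng, COHORT_MARGINS["t_stage"], n)
    n_stage = _sample_categorical(rng, COHORT_MARGINS["n_stage"], n)
    stage = _sample_categorical(rng, COHORT_MARGINS["stage"], n)
    ebv = _sample_categorical(rng, COHORT_MARGINS["ebv_group"], n)
    age = rng.normal(COHORT_MARGINS["age_mean"], COHORT_MARGINS["age_sd"], n)
    records = []
    for i, cid in enumerate(case_ids):
        endpoints = {}
        for ep, data in survival.items():
            endpoints[ep] = (float(data.times[i]), int(data.events[i]))
        records.append(
            ClinicalRecord(
                case_id=str(cid),
                age=float(np.clip(age[i], 18, 90)),
                sex=str(sex[i]),
                t_stage=int(t_stage[i]),
                n_stage=int(n_stage[i]),
                stage=str(stage[i]),
                ebv_group=str(ebv[i]),
                endpoints=endpoints,
            )
        )
    return records


@dataclass
class SyntheticCohort:
    """Everything one run of the generator planted."""

    maps: dict[str, list[SlideNucleiMap]]      # case_id -> WSIs
    clinical: list[ClinicalRecord]
    survival: dict[str, SurvivalData]
    planted: pd.DataFrame                      # per-case planted truths
    config: CohortConfig


def gen_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> SyntheticCohort:
    """Generate the full cohort; optionally write it to disk.

    Cases are assigned risk groups and per-case TIL rates; each case gets
    one WSI (``n_multi_wsi`` cases get two).  Survival is linked to the
    *planted* per-case TIL ratio (placed TILs / placed tumour nuclei), so
    the generator stays independent of the quantification code.  On disk:
    one nuclei CSV per WSI, ``clinical.csv`` and a ``manifest.json`` of all
    planted parameters.
    """
    config.validate()
    root = np.random.default_rng(config.seed)
    n = config.n_cases
    case_ids = [f"case{i:04d}" for i in range(n)]
    groups = np.where(root.random(n) < config.frac_high_risk, "high_risk", "low_risk")
    multi = set(root.choice(n, size=min(config.n_multi_wsi, n), replace=False).tolist())

    maps: dict[str, list[SlideNucleiMap]] = {}
    planted_rows = []
    for i, cid in enumerate(case_ids):
        g = groups[i]
        jitter = root.lognormal(0.0, config.rate_jitter_sd, 2)
        r_i = config.til_intra_rate[g] * jitter[0]
        r_s = config.til_stromal_rate[g] * jitter[1]
        n_wsi = 2 if i in multi else 1
        case_maps = []
        n_til = n_tum = 0
        for w in range(n_wsi):
            smap = gen_nuclei_map(
                config, g, seed=root, slide_id=f"{cid}-wsi{w}",
                til_intra_rate=r_i, til_stromal_rate=r_s,
            )
            counts = smap.class_counts()
            n_til += counts[CLASS_LYMPHOCYTE]
            n_tum += counts[CLASS_TUMOUR]
            case_maps.append(smap)
        maps[cid] = case_maps
        planted_rows.append(
            {
                "case_id": cid, "risk_group": g,
                "til_intra_rate": r_i, "til_stromal_rate": r_s,
                "n_wsis": n_wsi,
                "planted_til_ratio": n_til / n_tum if n_tum else 0.0,
            }
        )
    planted = pd.DataFrame(planted_rows).set_index("case_id")

    survival = {
        ep: gen_survival(
            planted["planted_til_ratio"].to_numpy(),
            config,
            seed=int(root.integers(2**31)),
            endpoint=ep,
            case_ids=case_ids,
        )
        for ep in config.endpoints
    }
    clinical = gen_clinical(config, case_ids, survival, seed=int(root.integers(2**31)))

    cohort = SyntheticCohort(
        maps=maps, clinical=clinical, survival=survival,
        planted=planted, config=config,
    )
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir), overwrite)
    return cohort


def _write_cohort(cohort: SyntheticCohort, out_dir: Path, overwrite: bool) -> None:
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise CohortGenError(f"{out_dir} exists and is not empty; pass overwrite=True")
    nuclei_dir = out_dir / "nuclei"
    nuclei_dir.mkdir(parents=True, exist_ok=True)
    for case_maps in cohort.maps.values():
        for smap in case_maps:
            write_nuclei_map(smap, nuclei_dir / f"{smap.slide_id}.csv", "csv")
    clinical_to_frame(cohort.clinical).to_csv(out_dir / "clinical.csv", index=False)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cohort.config).items()
        },
        "planted": cohort.planted.reset_index().to_dict(orient="list"),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
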