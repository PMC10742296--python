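"""End-to-end orchestration: quantify -> aggregate -> model -> stratify.

``run_quantify`` turns a directory of classified nuclei maps into per-WSI
and per-case feature tables (12 TIL + 9 morphology columns) with a QC
report.  ``run_survival`` runs, per endpoint and feature set, the full
prognostic analysis: event-stratified discovery/validation split, RSF grid
search on 3-fold cross-validation, out-of-fold scoring, log-rank-optimal
cutoff from the discovery set, Kaplan-Meier/log-rank evaluation on the
validation set, univariate and multivariate Cox tables, RSF permutation
importance, and a low-vs-high feature comparison (Student's t or
Mann-Whitney U, chosen per feature by a Shapiro normality pre-test).
``run_all`` chains the two and writes a markdown summary plus a JSON run
manifest (seeds, parameters, cutoffs) sufficient to reproduce every output.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import nuclei_io, spatial_clustering, survival_models, til_quantification
from .nuclei_io import ENDPOINTS, SlideNucleiMap
from .survival_models import SurvivalData

logger = logging.getLogger("tilscore")

#: The seven feature-set rows the analysis compares.
FEATURE_SETS = (
    "clinical",
    "til",
    "morphology",
    "til+clinical",
    "til+morphology",
    "clinical+morphology",
    "all",
)

CLINICAL_FEATURE_COLUMNS = ("age", "sex", "t_stage", "n_stage", "stage", "ebv_group")


class PipelineError(RuntimeError):
    """A stage could not run (propagates a non-zero exit from the CLI)."""


@dataclass
class RunConfig:
    """Run parameters; defaults follow the published method where stated."""

    nuclei_dir: str = "nuclei"
    clinical_path: str = "clinical.csv"
    out_dir: str = "results"
    endpoints: tuple[str, ...] = ENDPOINTS
    feature_sets: tuple[str, ...] = ("til",)

    # clustering
    eps: float = spatial_clustering.DEFAULT_EPS
    min_pts: int = spatial_clustering.DEFAULT_MIN_PTS
    expansion_px: float = spatial_clustering.DEFAULT_EXPANSION
    region_method: str = "closing"
    r_pad: float = spatial_clustering.DEFAULT_R_PAD

    # survival modelling
    horizon: float = survival_models.DEFAULT_HORIZON
    folds: int = survival_models.DEFAULT_FOLDS
    validation_frac: float = survival_models.DEFAULT_VALIDATION_FRAC
    min_group_frac: float = survival_models.DEFAULT_MIN_GROUP_FRAC
    min_events: int = 5
    rsf_grid: tuple[dict, ...] | None = None
    importance_repeats: int = 20
    holm_adjust: bool = False
    seed: int = 0
    strict: bool = False

    def __post_init__(self):
        bad = set(self.endpoints) - set(ENDPOINTS)
        if bad:
            raise PipelineError(f"unknown endpoint(s) {sorted(bad)}")
        bad = set(self.feature_sets) - set(FEATURE_SETS)
        if bad:
            raise PipelineError(f"unknown feature set(s) {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        for key in ("endpoints", "feature_sets"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if isinstance(raw.get("rsf_grid"), list):
            raw["rsf_grid"] = tuple(raw["rsf_grid"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Quantification stage
# ---------------------------------------------------------------------------


def quantify_slide(smap: SlideNucleiMap, config: RunConfig) -> dict:
    """All 21 features plus QC flags for one slide."""
    tumour_xy = smap.coords(nuclei_io.CLASS_TUMOUR)
    labels = spatial_clustering.density_cluster(tumour_xy, config.eps, config.min_pts)
    partition = spatial_clustering.build_cluster_regions(
        tumour_xy, labels, config.expansion_px,
        region_method=config.region_method, r_pad=config.r_pad, eps=config.eps,
        min_pts=config.min_pts,
    )
    assignment = spatial_clustering.assign_compartments(partition, smap)
    til = til_quantification.compute_til_features(assignment, partition, smap)
    morph = til_quantification.slide_morphology_mean(partition, smap, assignment)
    row = {"slide_id": smap.slide_id, "n_clusters": partition.n_clusters}
    row.update(til.values)
    row.update(morph.values)
    row["qc_flags"] = "; ".join(til.qc_flags + (["no morphology"] if morph.missing else []))
    return row


def case_id_for_slide(slide_id: str) -> str:
    """Slide -> case mapping convention: strip a trailing ``-wsi<k>``."""
    if "-wsi" in slide_id:
        return slide_id.rsplit("-wsi", 1)[0]
    return slide_id


def run_quantify(
    config: RunConfig, maps: list[SlideNucleiMap] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Quantify every slide; aggregate per case.

    Returns (per-WSI table, per-case table, QC table).  Unreadable slides
    are listed in the QC table and skipped unless ``config.strict``.
    """
    t0 = time.time()
    qc_rows = []
    rows = []
    if maps is None:
        paths = sorted(Path(config.nuclei_dir).glob("*"))
        paths = [p for p in paths if p.suffix.lower() in (".csv", ".geojson", ".json")]
        if not paths:
            raise PipelineError(f"no nuclei maps found in {config.nuclei_dir}")
        maps = []
        for p in paths:
            try:
                maps.append(nuclei_io.read_nuclei_map(p))
            except nuclei_io.NucleiIOError as exc:
                if config.strict:
                    raise PipelineError(str(exc)) from exc
                qc_rows.append({"slide_id": p.stem, "issue": f"unreadable: {exc}"})
    for smap in maps:
        row = quantify_slide(smap, config)
        if row["qc_flags"]:
            qc_rows.append({"slide_id": smap.slide_id, "issue": row["qc_flags"]})
        rows.append(row)
    per_wsi = pd.DataFrame(rows)
    per_wsi.insert(0, "case_id", per_wsi["slide_id"].map(case_id_for_slide))
    per_case = til_quantification.aggregate_case(per_wsi)
    qc = pd.DataFrame(qc_rows, columns=["slide_id", "issue"])
    logger.info(
        "quantify: %d slides -> %d cases in %.1fs (%d QC rows)",
        len(per_wsi), len(per_case), time.time() - t0, len(qc),
    )
    return per_wsi, per_case, qc


# ---------------------------------------------------------------------------
# Survival stage
# ---------------------------------------------------------------------------


def _clinical_design(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix for the clinical feature set (dummy coding
    against the declared reference levels)."""
    design, _ = survival_models._expand_covariates(
        clinical[list(CLINICAL_FEATURE_COLUMNS)]
    )
    return design


def feature_matrix(
    feature_set: str, case_features: pd.DataFrame, clinical: pd.DataFrame
) -> pd.DataFrame:
    """Assemble the design matrix for one feature-set row."""
    til_cols = list(til_quantification.TIL_FEATURE_NAMES)
    morph_cols = list(til_quantification.MORPH_FEATURE_NAMES)
    parts = []
    if feature_set in ("til", "til+clinical", "til+morphology", "all"):
        parts.append(case_features[til_cols])
    if feature_set in ("morphology", "til+morphology", "clinical+morphology", "all"):
        parts.append(case_features[morph_cols])
    if feature_set in ("clinical", "til+clinical", "clinical+morphology", "all"):
        parts.append(_clinical_design(clinical))
    X = pd.concat(parts, axis=1)
    return X.fillna(0.0)


def _endpoint_data(clinical: pd.DataFrame, endpoint: str, horizon: float) -> SurvivalData:
    tcol, ecol = f"{endpoint}_months", f"{endpoint}_event"
    if tcol not in clinical.columns:
        raise PipelineError(f"clinical table lacks endpoint {endpoint}")
    data = SurvivalData(
        clinical["case_id"].to_numpy(),
        clinical[tcol].to_numpy(float),
        clinical[ecol].to_numpy(int),
        endpoint,
    )
    return survival_models.censor_at(data, horizon)


def group_comparison(
    X: pd.DataFrame, low_mask: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Low- vs high-risk per-feature comparison.

    Uses Student's t when both groups pass a Shapiro normality pre-test at
    ``alpha``, otherwise the Mann-Whitney U test.
    """
    rows = []
    for col in X.columns:
        a = X.loc[low_mask, col].to_numpy(float)
        b = X.loc[~low_mask, col].to_numpy(float)
        normal = False
        if len(a) >= 3 and len(b) >= 3 and a.std() > 0 and b.std() > 0:
            normal = (
                stats.shapiro(a).pvalue > alpha and stats.shapiro(b).pvalue > alpha
            )
        if normal:
            test, p = "t-test", stats.ttest_ind(a, b, equal_var=False).pvalue
        else:
            try:
                test, p = "mann-whitney", stats.mannwhitneyu(a, b).pvalue
            except ValueError:  # all values identical
                test, p = "mann-whitney", 1.0
        rows.append(
            {"feature": col, "test": test, "p_value": float(p),
             "mean_low": float(a.mean()), "mean_high": float(b.mean())}
        )
    return pd.DataFrame(rows)


@dataclass
class EndpointResult:
    """All survival outputs for one (endpoint, feature set) cell."""

    endpoint: str
    feature_set: str
    cv_summary: dict
    cutoff: float
    logrank_statistic: float
    logrank_p: float
    validation_cindex: float
    km_low: pd.DataFrame
    km_high: pd.DataFrame
    cox_univariate: pd.DataFrame
    cox_multivariate: pd.DataFrame
    importance: pd.DataFrame
    comparison: pd.DataFrame
    risk_scores: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run_survival_endpoint(
    config: RunConfig,
    feature_set: str,
    endpoint: str,
    case_features: pd.DataFrame,
    clinical: pd.DataFrame,
) -> EndpointResult:
    """The full prognostic analysis for one endpoint and feature set."""
    merged = clinical.merge(case_features, on="case_id", how="inner")
    if len(merged) < len(clinical):
        logger.warning(
            "%d clinical case(s) without features dropped", len(clinical) - len(merged)
        )
    data = _endpoint_data(merged, endpoint, config.horizon)
    if data.n_events < config.min_events:
        raise PipelineError(
            f"endpoint {endpoint}: only {data.n_events} events "
            f"(< {config.min_events}); analysis refused"
        )
    X = feature_matrix(feature_set, merged, merged)

    disc_idx, val_idx = survival_models.split_discovery_validation(
        data, config.validation_frac, config.seed
    )
    X_disc, X_val = X.iloc[disc_idx], X.iloc[val_idx]
    d_disc, d_val = data.subset(disc_idx), data.subset(val_idx)

    model = survival_models.fit_rsf_cv(
        X_disc, d_disc, folds=config.folds, grid=config.rsf_grid, seed=config.seed
    )
    final = survival_models.fit_rsf(X_disc, d_disc, model.best_params, config.seed)
    val_scores = final.predict(X_val.to_numpy(float))
    validation_cindex = survival_models.harrell_cindex(val_scores, d_val)

    cut = survival_models.find_cutoff(model.oof_scores, d_disc, config.min_group_frac)
    try:
        strat = survival_models.stratify(val_scores, d_val, cut.cutoff)
    except survival_models.SurvivalError as exc:
        raise PipelineError(
            f"endpoint {endpoint}/{feature_set}: discovery cutoff "
            f"{cut.cutoff:.4g} leaves an empty validation group ({exc}); "
            "more cases or a different seed are needed"
        ) from exc

    # Cox: clinical covariates + the RSF risk score on the validation set
    cox_cov = merged.iloc[val_idx][list(CLINICAL_FEATURE_COLUMNS)].copy()
    cox_cov["risk_score"] = val_scores
    cox_cov = cox_cov.reset_index(drop=True)
    d_val_r = SurvivalData(d_val.case_ids, d_val.times, d_val.events,
                           endpoint, data.censor_horizon)
    uni, _ = survival_models.cox_fit(cox_cov, d_val_r, "univariate")
    multi, _ = survival_models.cox_fit(cox_cov, d_val_r, "multivariate")
    uni_df = survival_models.cox_results_frame(uni)
    multi_df = survival_models.cox_results_frame(multi)
    if config.holm_adjust:
        for df in (uni_df, multi_df):
            mask = df["p_value"].notna()
            from statsmodels.stats.multitest import multipletests

            df.loc[mask, "p_holm"] = multipletests(
                df.loc[mask, "p_value"], method="holm"
            )[1]

    importance = survival_models.feature_importance(
        model, X_disc, d_disc, config.importance_repeats, config.seed
    )
    comparison = group_comparison(X_val.reset_index(drop=True),
                                  strat.low_mask)

    risk_scores = pd.DataFrame(
        {
            "case_id": np.concatenate([d_disc.case_ids, d_val.case_ids]),
            "split": ["discovery"] * len(d_disc) + ["validation"] * len(d_val),
            "risk_score": np.concatenate([model.oof_scores, val_scores]),
            "risk_group": np.concatenate(
                [
                    np.where(model.oof_scores <= cut.cutoff, "low", "high"),
                    np.where(strat.low_mask, "low", "high"),
                ]
            ),
        }
    )
    return EndpointResult(
        endpoint=endpoint,
        feature_set=feature_set,
        cv_summary={
            "mean_discovery_cindex": model.mean_discovery_cindex,
            "sd_discovery_cindex": float(model.fold_c_discovery.std()),
            "mean_validation_cindex": model.mean_validation_cindex,
            "sd_validation_cindex": float(model.fold_c_validation.std()),
            "best_params": model.best_params,
        },
        cutoff=cut.cutoff,
        logrank_statistic=strat.logrank_statistic,
        logrank_p=strat.logrank_p,
        validation_cindex=validation_cindex,
        km_low=strat.km_low.as_frame(),
        km_high=strat.km_high.as_frame(),
        cox_univariate=uni_df,
        cox_multivariate=multi_df,
        importance=importance,
        comparison=comparison,
        risk_scores=risk_scores,
        manifest={
            "endpoint": endpoint, "feature_set": feature_set,
            "seed": config.seed, "folds": config.folds,
            "validation_frac": config.validation_frac,
            "cutoff": cut.cutoff, "best_params": model.best_params,
            "n_cases": len(merged), "n_events": int(data.n_events),
        },
    )


def run_survival(
    config: RunConfig,
    case_features: pd.DataFrame,
    clinical: pd.DataFrame,
) -> list[EndpointResult]:
    """All selected endpoint x feature-set analyses; sparse endpoints are
    skipped with a logged diagnostic (or raised under ``strict``)."""
    results = []
    for endpoint in config.endpoints:
        for fs in config.feature_sets:
            try:
                results.append(
                    run_survival_endpoint(config, fs, endpoint, case_features, clinical)
                )
            except PipelineError as exc:
                if config.strict:
                    raise
                logger.warning("skipping %s/%s: %s", endpoint, fs, exc)
    return results


# ---------------------------------------------------------------------------
# Full run with on-disk outputs
# ---------------------------------------------------------------------------


def write_results(
    config: RunConfig,
    per_wsi: pd.DataFrame,
    per_case: pd.DataFrame,
    qc: pd.DataFrame,
    results: list[EndpointResult],
) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_wsi.to_csv(out / "features_per_wsi.csv", index=False)
    per_case.to_csv(out / "features_per_case.csv", index=False)
    qc.to_csv(out / "qc_report.csv", index=False)
    manifest: dict = {"config": asdict(config), "runs": []}
    summary_lines = ["# Run summary", ""]
    for r in results:
        tag = f"{r.endpoint}_{r.feature_set.replace('+', '_')}"
        r.km_low.to_csv(out / f"km_low_{tag}.csv", index=False)
        r.km_high.to_csv(out / f"km_high_{tag}.csv", index=False)
        r.cox_univariate.to_csv(out / f"cox_univariate_{tag}.csv", index=False)
        r.cox_multivariate.to_csv(out / f"cox_multivariate_{tag}.csv", index=False)
        r.importance.to_csv(out / f"importance_{tag}.csv", index=False)
        r.comparison.to_csv(out / f"group_comparison_{tag}.csv", index=False)
        r.risk_scores.to_csv(out / f"risk_scores_{tag}.csv", index=False)
        manifest["runs"].append(r.manifest)
        summary_lines += [
            f"## {r.endpoint} / {r.feature_set}",
            "",
            f"- CV C-index: discovery {r.cv_summary['mean_discovery_cindex']:.3f} "
            f"+/- {r.cv_summary['sd_discovery_cindex']:.3f}, "
            f"validation {r.cv_summary['mean_validation_cindex']:.3f} "
            f"+/- {r.cv_summary['sd_validation_cindex']:.3f}",
            f"- validation-set C-index: {r.validation_cindex:.3f}",
            f"- cutoff {r.cutoff:.4g}; log-rank chi2 {r.logrank_statistic:.2f}, "
            f"p = {r.logrank_p:.3g}",
            "",
        ]
    (out / "summary.md").write_text("\n".join(summary_lines))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out


def run_all(config: RunConfig, maps: list[SlideNucleiMap] | None = None) -> Path:
    """quantify + survival for all selected endpoints/feature sets."""
    per_wsi, per_case, qc = run_quantify(config, maps)
    clinical = nuclei_io.clinical_to_frame(
        nuclei_io.read_clinical_table(config.clinical_path)
    )
    results = run_survival(config, per_case, clinical)
    return write_results(config, per_wsi, per_case, qc, results)
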