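"""Risk scoring and survival statistics.

The prognostic pipeline: censor endpoints at a 60-month horizon, fit a
Random Survival Forest (RSF) by grid search over 3-fold cross-validation
stratified on the event indicator, score every case out-of-fold, pick the
risk-score cutoff that minimises the log-rank p-value between the resulting
low (score <= cutoff) and high (score > cutoff) groups, and report
Kaplan-Meier curves, the log-rank test and Cox proportional-hazards tables
(univariate and multivariate) with hazard ratios, Wald 95% CIs and p-values.

Harrell's C-index, the Kaplan-Meier estimator and the two-group log-rank
test are implemented directly (they are simple risk-table computations and
the C-index tie conventions need to be pinned down); the RSF comes from
scikit-survival and Cox fits from lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

logger = logging.getLogger("tilscore")

DEFAULT_HORIZON = 60.0  # months (5 years)
DEFAULT_FOLDS = 3
DEFAULT_VALIDATION_FRAC = 0.3
DEFAULT_MIN_GROUP_FRAC = 0.1

#: Reference level per categorical clinical covariate for Cox dummy coding.
COX_REFERENCE_LEVELS = {
    "sex": "female",
    "t_stage": 1,
    "n_stage": 0,
    "stage": "I",
    "ebv_group": "low",
}


class SurvivalError(ValueError):
    """Invalid survival-analysis input (no comparable pairs, bad split, ...)."""


# ---------------------------------------------------------------------------
# Survival data container and censoring
# ---------------------------------------------------------------------------


@dataclass
class SurvivalData:
    """Right-censored times (months) and event flags for one endpoint."""

    case_ids: np.ndarray
    times: np.ndarray
    events: np.ndarray
    endpoint: str = "lrfs"
    censor_horizon: float = DEFAULT_HORIZON

    def __post_init__(self):
        self.case_ids = np.asarray(self.case_ids)
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if np.any(self.times <= 0):
            raise SurvivalError("all survival times must be > 0")
        if not set(np.unique(self.events)) <= {0, 1}:
            raise SurvivalError("events must be 0/1")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def subset(self, idx) -> "SurvivalData":
        return SurvivalData(
            self.case_ids[idx], self.times[idx], self.events[idx],
            self.endpoint, self.censor_horizon,
        )

    def to_sksurv(self):
        return Surv.from_arrays(self.events.astype(bool), self.times)


def censor_at(data: SurvivalData, horizon: float = DEFAULT_HORIZON) -> SurvivalData:
    """Clip follow-up at ``horizon`` months; later events become censored.

    An event exactly at the horizon remains an event.
    """
    if horizon <= 0:
        raise SurvivalError("horizon must be > 0")
    times = np.minimum(data.times, horizon)
    events = np.where(data.times > horizon, 0, data.events)
    return SurvivalData(data.case_ids, times, events, data.endpoint, horizon)


# ---------------------------------------------------------------------------
# Harrell's C-index
# ---------------------------------------------------------------------------


def harrell_cindex(risk: np.ndarray, data: SurvivalData) -> float:
    """Harrell's concordance index between risk scores and outcomes.

    Pairs are comparable when the shorter time carries an event (for tied
    times, when exactly one of the two carries an event).  A pair is
    concordant when the higher risk goes with the shorter time (for tied
    times, with the event); tied risks count 1/2.
    """
    risk = np.asarray(risk, dtype=float)
    if len(risk) != len(data):
        raise SurvivalError("risk and survival data length mismatch")
    t, e = data.times, data.events
    n = len(t)
    ti = t[:, None]
    tj = t[None, :]
    ri = risk[:, None]
    rj = risk[None, :]
    ei = e[:, None].astype(bool)
    ej = e[None, :].astype(bool)

    # i indexes the earlier subject of the ordered pair
    earlier = (ti < tj) & ei
    tied_time = (ti == tj) & ei & ~ej
    comparable = earlier | tied_time
    comparable &= ~np.eye(n, dtype=bool)

    concordant = comparable & (ri > rj)
    tied_risk = comparable & (ri == rj)

    n_comp = comparable.sum()
    if n_comp == 0:
        raise SurvivalError("no comparable pairs")
    return float((concordant.sum() + 0.5 * tied_risk.sum()) / n_comp)


# ---------------------------------------------------------------------------
# Kaplan-Meier estimator and log-rank test
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit survival estimate: right-continuous step function."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t) -> np.ndarray:
        """S(t) evaluated at arbitrary times (S(0) = 1)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:  # no events: S(t) = 1 everywhere
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)

    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5 (inf if never reached)."""
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else float("inf")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival,
             "at_risk": self.at_risk, "events": self.n_events}
        )


def km_estimate(data: SurvivalData) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    if len(data) == 0:
        raise SurvivalError("empty survival data")
    t, e = data.times, data.events
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return KMCurve(
            times=np.array([]), survival=np.array([]),
            at_risk=np.array([], dtype=int), n_events=np.array([], dtype=int),
        )
    at_risk = np.array([(t >= et).sum() for et in event_times])
    d = np.array([((t == et) & (e == 1)).sum() for et in event_times])
    survival = np.cumprod(1.0 - d / at_risk)
    return KMCurve(times=event_times, survival=survival, at_risk=at_risk, n_events=d)


def logrank_test(group_a: SurvivalData, group_b: SurvivalData) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic with 1 df, two-tailed p).

    Observed-minus-expected events in group A over the pooled risk table
    with the hypergeometric variance.  Zero events overall gives (0, 1).
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise SurvivalError("both groups must be non-empty")
    t = np.concatenate([group_a.times, group_b.times])
    e = np.concatenate([group_a.events, group_b.events])
    g = np.concatenate([np.zeros(len(group_a)), np.ones(len(group_b))])
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return 0.0, 1.0
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        n1 = (at_risk & (g == 0)).sum()
        d = ((t == et) & (e == 1)).sum()
        d1 = ((t == et) & (e == 1) & (g == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Random Survival Forest with cross-validated grid search
# ---------------------------------------------------------------------------

#: Default hyperparameter grid: small and standard; the split rule is
#: scikit-survival's log-rank criterion.
DEFAULT_RSF_GRID = tuple(
    {"n_estimators": n, "min_samples_leaf": leaf, "max_features": mf}
    for n in (200, 500)
    for leaf in (5, 15)
    for mf in ("sqrt", 1.0 / 3.0)
)


@dataclass
class RiskModel:
    """Fitted RSF ensemble(s) with cross-validation diagnostics."""

    feature_names: list[str]
    best_params: dict
    fold_assignment: np.ndarray          # fold id per case
    oof_scores: np.ndarray               # out-of-fold risk score per case
    fold_c_discovery: np.ndarray
    fold_c_validation: np.ndarray
    cv_results: pd.DataFrame             # one row per grid point
    fold_models: list = field(default_factory=list, repr=False)
    seed: int = 0

    @property
    def mean_validation_cindex(self) -> float:
        return float(self.fold_c_validation.mean())

    @property
    def mean_discovery_cindex(self) -> float:
        return float(self.fold_c_discovery.mean())


def _stratified_event_folds(events: np.ndarray, folds: int, seed: int) -> np.ndarray:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(events), dtype=int)
    try:
        for k, (_, test_idx) in enumerate(skf.split(np.zeros(len(events)), events)):
            assignment[test_idx] = k
    except ValueError as exc:
        raise SurvivalError(
            f"cannot stratify {int(events.sum())} events into {folds} folds; "
            "use fewer folds"
        ) from exc
    return assignment


def fit_rsf(
    X: pd.DataFrame, data: SurvivalData, params: dict, seed: int = 0
) -> RandomSurvivalForest:
    """Fit one RSF on the full given data (log-rank split rule)."""
    model = RandomSurvivalForest(random_state=seed, n_jobs=1, **params)
    return model.fit(X.to_numpy(dtype=float), data.to_sksurv())


def fit_rsf_cv(
    X: pd.DataFrame,
    data: SurvivalData,
    folds: int = DEFAULT_FOLDS,
    grid: tuple[dict, ...] | None = None,
    seed: int = 0,
) -> RiskModel:
    """Grid-searched RSF on event-stratified k-fold cross-validation.

    Every case receives an out-of-fold risk score from the grid point with
    the best mean validation C-index; per-fold discovery and validation
    C-indices are recorded for that grid point.
    """
    if len(X) != len(data):
        raise SurvivalError("feature table and survival data length mismatch")
    if X.isna().any().any():
        raise SurvivalError("feature table contains missing values")
    grid = tuple(grid) if grid is not None else DEFAULT_RSF_GRID
    fold_assignment = _stratified_event_folds(data.events, folds, seed)
    for k in range(folds):
        if data.events[fold_assignment == k].sum() == 0:
            raise SurvivalError(
                f"fold {k} holds zero events; use fewer folds or more events"
            )

    Xa = X.to_numpy(dtype=float)
    rows = []
    per_grid_state = []
    for gi, params in enumerate(grid):
        oof = np.empty(len(data))
        c_disc = np.empty(folds)
        c_val = np.empty(folds)
        models = []
        for k in range(folds):
            tr = fold_assignment != k
            te = ~tr
            model = RandomSurvivalForest(random_state=seed, n_jobs=1, **params)
            model.fit(Xa[tr], data.subset(tr).to_sksurv())
            oof[te] = model.predict(Xa[te])
            c_disc[k] = harrell_cindex(model.predict(Xa[tr]), data.subset(tr))
            c_val[k] = harrell_cindex(oof[te], data.subset(te))
            models.append(model)
        rows.append({**{f"param_{k}": v for k, v in params.items()},
                     "mean_discovery_cindex": c_disc.mean(),
                     "mean_validation_cindex": c_val.mean()})
        per_grid_state.append((params, oof, c_disc, c_val, models))
    cv_results = pd.DataFrame(rows)
    best = int(cv_results["mean_validation_cindex"].idxmax())
    params, oof, c_disc, c_val, models = per_grid_state[best]
    return RiskModel(
        feature_names=list(X.columns),
        best_params=dict(params),
        fold_assignment=fold_assignment,
        oof_scores=oof,
        fold_c_discovery=c_disc,
        fold_c_validation=c_val,
        cv_results=cv_results,
        fold_models=models,
        seed=seed,
    )


def feature_importance(
    model: RiskModel,
    X: pd.DataFrame,
    data: SurvivalData,
    n_repeats: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation feature importance, ranked descending.

    Importance of a feature = mean drop in out-of-fold validation C-index
    when that feature is permuted in the validation fold, averaged over
    folds and ``n_repeats`` seeded permutations.
    """
    rng = np.random.default_rng(seed)
    Xa = X.to_numpy(dtype=float)
    base = np.empty(len(model.fold_models))
    for k, m in enumerate(model.fold_models):
        te = model.fold_assignment == k
        base[k] = harrell_cindex(m.predict(Xa[te]), data.subset(te))
    drops = np.zeros((len(X.columns), len(model.fold_models)))
    for j in range(len(X.columns)):
        for k, m in enumerate(model.fold_models):
            te = model.fold_assignment == k
            Xp = Xa[te].copy()
            acc = 0.0
            for _ in range(n_repeats):
                Xp[:, j] = rng.permutation(Xp[:, j])
                acc += base[k] - harrell_cindex(m.predict(Xp), data.subset(te))
            drops[j, k] = acc / n_repeats
    out = pd.DataFrame(
        {"feature": X.columns, "importance": drops.mean(axis=1)}
    ).sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Optimal cutoff (minimal log-rank p) and stratification
# ---------------------------------------------------------------------------


@dataclass
class CutoffResult:
    cutoff: float
    statistic: float
    p_value: float
    n_low: int
    n_high: int
    candidates: pd.DataFrame


def find_cutoff(
    risk: np.ndarray,
    data: SurvivalData,
    min_group_frac: float = DEFAULT_MIN_GROUP_FRAC,
) -> CutoffResult:
    """Log-rank-optimal cutoff on risk scores (Cutoff Finder style).

    Candidates are midpoints between consecutive sorted unique scores whose
    induced groups each hold at least ``min_group_frac`` of cases; the
    candidate with the smallest two-group log-rank p wins, ties broken
    toward the more balanced split.  Low risk = score <= cutoff.
    """
    risk = np.asarray(risk, dtype=float)
    uniq = np.unique(risk)
    if uniq.size < 2:
        raise SurvivalError("all risk scores identical; no cutoff exists")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n = len(risk)
    floor = max(min_group_frac * n, 1.0) if min_group_frac > 0 else 1.0
    rows = []
    for c in mids:
        low = risk <= c
        n_low, n_high = int(low.sum()), int((~low).sum())
        if n_low < floor or n_high < floor:
            continue
        stat, p = logrank_test(data.subset(low), data.subset(~low))
        rows.append({"cutoff": c, "n_low": n_low, "n_high": n_high,
                     "statistic": stat, "p_value": p})
    if not rows:
        raise SurvivalError("no cutoff satisfies the minimum group size")
    cand = pd.DataFrame(rows)
    best_p = cand["p_value"].min()
    at_best = cand[cand["p_value"] == best_p]
    balance = (at_best["n_low"] - at_best["n_high"]).abs()
    best = at_best.loc[balance.idxmin()]
    return CutoffResult(
        cutoff=float(best["cutoff"]),
        statistic=float(best["statistic"]),
        p_value=float(best["p_value"]),
        n_low=int(best["n_low"]),
        n_high=int(best["n_high"]),
        candidates=cand,
    )


@dataclass
class RiskStratification:
    """Low/high risk groups with their KM curves and log-rank test."""

    risk: np.ndarray
    cutoff: float
    low_mask: np.ndarray
    km_low: KMCurve
    km_high: KMCurve
    logrank_statistic: float
    logrank_p: float


def stratify(risk: np.ndarray, data: SurvivalData, cutoff: float) -> RiskStratification:
    """Split cases at the cutoff (low: score <= cutoff) and compare groups."""
    risk = np.asarray(risk, dtype=float)
    low = risk <= cutoff
    if low.all() or not low.any():
        raise SurvivalError("cutoff leaves one group empty")
    stat, p = logrank_test(data.subset(low), data.subset(~low))
    return RiskStratification(
        risk=risk,
        cutoff=cutoff,
        low_mask=low,
        km_low=km_estimate(data.subset(low)),
        km_high=km_estimate(data.subset(~low)),
        logrank_statistic=stat,
        logrank_p=p,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    """One covariate level: HR with Wald 95% CI and two-tailed p."""

    covariate: str
    level: str
    hr: float
    ci_lower: float
    ci_upper: float
    p_value: float
    reference: str | None = None
    converged: bool = True
    note: str = ""


def _expand_covariates(covariates: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Dummy-code categorical covariates against their reference levels.

    Returns the design frame and (column, covariate, level) descriptors.
    """
    cols = []
    design = pd.DataFrame(index=covariates.index)
    for name in covariates.columns:
        series = covariates[name]
        if name in COX_REFERENCE_LEVELS:
            ref = COX_REFERENCE_LEVELS[name]
            levels = [lv for lv in pd.unique(series) if lv != ref]
            try:
                levels = sorted(levels)
            except TypeError:
                levels = list(levels)
            for lv in levels:
                col = f"{name}_{lv}"
                design[col] = (series == lv).astype(float)
                cols.append((col, name, str(lv)))
        else:
            design[name] = series.astype(float)
            cols.append((name, name, ""))
    return design, cols


def cox_fit(
    covariates: pd.DataFrame,
    data: SurvivalData,
    mode: str = "multivariate",
) -> tuple[list[CoxResult], float]:
    """Cox PH regression: per-level HR, 95% CI, p, plus model C-index.

    ``univariate`` fits one covariate at a time (each with all its dummy
    levels); ``multivariate`` fits them jointly.  Non-convergence or
    separation yields flagged results instead of raising.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if mode not in ("univariate", "multivariate"):
        raise SurvivalError(f"unknown mode {mode!r}")
    base = pd.DataFrame(
        {"_time": data.times, "_event": data.events}, index=covariates.index
    )

    groups: list[list[str]]
    if mode == "univariate":
        groups = [[c] for c in covariates.columns]
    else:
        groups = [list(covariates.columns)]

    results: list[CoxResult] = []
    model_cindex = float("nan")
    for group in groups:
        design, cols = _expand_covariates(covariates[group])
        df = pd.concat([design, base], axis=1)
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            for col, cov, level in cols:
                results.append(
                    CoxResult(
                        covariate=cov, level=level,
                        hr=float("nan"), ci_lower=float("nan"),
                        ci_upper=float("nan"), p_value=float("nan"),
                        reference=str(COX_REFERENCE_LEVELS.get(cov)),
                        converged=False, note=f"fit failed: {exc}",
                    )
                )
            continue
        summ = cph.summary
        for col, cov, level in cols:
            row = summ.loc[col]
            results.append(
                CoxResult(
                    covariate=cov, level=level,
                    hr=float(row["exp(coef)"]),
                    ci_lower=float(row["exp(coef) lower 95%"]),
                    ci_upper=float(row["exp(coef) upper 95%"]),
                    p_value=float(row["p"]),
                    reference=str(COX_REFERENCE_LEVELS.get(cov))
                    if cov in COX_REFERENCE_LEVELS else None,
                )
            )
        linear_pred = design.to_numpy() @ cph.params_.to_numpy()
        model_cindex = harrell_cindex(linear_pred, data)
    return results, model_cindex


def cox_results_frame(results: list[CoxResult]) -> pd.DataFrame:
    """Cox table with covariate, level, HR, CI bounds and p columns."""
    return pd.DataFrame(
        [
            {
                "covariate": r.covariate, "level": r.level, "hr": r.hr,
                "ci_lower": r.ci_lower, "ci_upper": r.ci_upper,
                "p_value": r.p_value, "reference": r.reference,
                "converged": r.converged, "note": r.note,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Discovery / validation split
# ---------------------------------------------------------------------------


def split_discovery_validation(
    data: SurvivalData, frac: float = DEFAULT_VALIDATION_FRAC, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Event-stratified discovery/validation split (validation = ``frac``)."""
    if not 0 < frac < 1:
        raise SurvivalError("validation fraction must lie in (0, 1)")
    if data.n_events < 2 or data.n_events > len(data) - 2:
        raise SurvivalError("too few events (or censorings) to stratify")
    idx = np.arange(len(data))
    disc, val = train_test_split(
        idx, test_size=frac, random_state=seed, stratify=data.events
    )
    return np.sort(disc), np.sort(val)
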