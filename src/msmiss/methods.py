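"""Five strategies for partially observed confounders in MSM analyses.

Each strategy takes a masked :class:`~msmiss.panel.PanelData` and produces an
:class:`~msmiss.msm.MSMEstimate` through the standard weighting + MSM
pipeline:

* ``complete_case`` — drop every subject with any missing confounder cell;
* ``locf_impute`` — carry the most recent observed measurement forward
  (subjects missing a baseline measurement are dropped);
* ``mpa_weights`` — missingness pattern approach: person-time rows are
  grouped by which confounders are missing at that time, and the weight
  models within each pattern use only that pattern's observed confounders;
* ``mi_estimate`` — multiple imputation by chained equations with predictive
  mean matching, analysed per completed panel and pooled by Rubin's rules;
* ``ipmw_estimate`` — inverse-probability-of-missingness weighting: subjects
  are censored at the first missing confounder and the complete records are
  reweighted by the inverse probability of remaining uncensored.

Treatment and outcome are assumed fully observed (the simulator masks
confounders only); MPA enforces this explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyAnalysisError,
    EstimationError,
    UnsupportedMethodError,
)
from .msm import MSMEstimate, Z975, fit_msm
from .panel import CONFOUNDERS, PanelData
from .weights import (
    PooledLogit,
    TreatmentModels,
    WeightSet,
    _design,
    compute_stabilized_weights,
    fit_treatment_models,
    person_time_frame,
)


def _analyze(frame: pd.DataFrame, n_times: int, label: str, truncate: bool = False) -> MSMEstimate:
    """Standard pipeline on a complete frame: weights then weighted MSM."""
    models = fit_treatment_models(frame, n_times)
    w = compute_stabilized_weights(frame, models)
    if truncate:
        w = w.truncated()
    return fit_msm(frame, w, n_times, method=label)


def full_data(panel: PanelData, truncate: bool = False) -> MSMEstimate:
    """Reference analysis on the true (pre-missingness) values."""
    return _analyze(panel.true, panel.n_times, "full-data", truncate)


# ---------------------------------------------------------------------------
# complete case
# ---------------------------------------------------------------------------

def complete_case(panel: PanelData, truncate: bool = False) -> tuple[PanelData, MSMEstimate]:
    """Restrict to subjects with no missing confounder cell at any time."""
    complete = ~panel.mask_array().any(axis=(1, 2))
    if not complete.any():
        raise EmptyAnalysisError("complete-case: no subject has a complete record")
    sub = panel.subset(np.flatnonzero(complete))
    est = _analyze(sub.true, sub.n_times, "CC", truncate)
    return sub, est


# ---------------------------------------------------------------------------
# last observation carried forward
# ---------------------------------------------------------------------------

def locf_impute(panel: PanelData, truncate: bool = False) -> tuple[PanelData, MSMEstimate]:
    """Forward-fill each confounder from its most recent observed value.

    Subjects with a missing baseline measurement have nothing to carry
    forward and are dropped.  The filled panel is analysed as if complete;
    the reported SE does not account for the single imputation.
    """
    obs = panel.observed()
    baseline_ok = np.ones(panel.n, dtype=bool)
    for var in CONFOUNDERS:
        baseline_ok &= ~panel.mask[f"M_{var}_0"].to_numpy()
    if not baseline_ok.any():
        raise EmptyAnalysisError("LOCF: every subject is missing a baseline measurement")
    obs = obs.loc[baseline_ok].reset_index(drop=True)
    for var in CONFOUNDERS:
        for k in range(1, panel.n_times):
            col = obs[f"{var}_{k}"]
            obs[f"{var}_{k}"] = col.where(~col.isna(), obs[f"{var}_{k - 1}"])
    filled = PanelData.from_observed(obs, panel.n_times, panel.dgm)
    est = _analyze(filled.true, panel.n_times, "LOCF", truncate)
    est.n_effective = len(obs)
    return filled, est


# ---------------------------------------------------------------------------
# missingness pattern approach
# ---------------------------------------------------------------------------

@dataclass
class MPAResult:
    weights: WeightSet
    estimate: MSMEstimate
    patterns: pd.DataFrame  # pattern label, person-time rows, merged-into


def _pattern_labels(panel: PanelData) -> pd.Series:
    """Per person-time row, the frozenset of confounders missing at that time."""
    mask = panel.mask_array()  # (n, K, 2)
    labels = []
    for k in range(panel.n_times):
        for i in range(panel.n):
            missing = frozenset(
                var for j, var in enumerate(CONFOUNDERS) if mask[i, k, j]
            )
            labels.append(missing)
    return pd.Series(labels)


def mpa_weights(panel: PanelData, min_pattern_size: int = 50, truncate: bool = False) -> MPAResult:
    """Missingness pattern approach: pattern-specific weight models.

    Person-time rows are partitioned by the set of confounders missing at
    that time (at most 4 patterns with two confounders); each pattern gets
    its own pooled denominator model using only the observed confounders of
    the pattern.  The numerator (stabilization) model is fitted globally on
    treatment history alone: missingness indicators are themselves affected
    by past treatment, so a pattern-specific numerator would condition the
    pseudo-population treatment process on a post-treatment variable and
    bias the MSM.  Patterns with fewer rows than ``min_pattern_size`` are
    merged into the nearest coarser pattern (one more confounder treated as
    missing).  All subjects are retained.
    """
    for k in range(panel.n_times):
        if panel.true[f"A_{k}"].isna().any():
            raise UnsupportedMethodError(
                "MPA does not handle missing data on the exposure or outcome"
            )
    if panel.true["Y"].isna().any():
        raise UnsupportedMethodError(
            "MPA does not handle missing data on the exposure or outcome"
        )
    K = panel.n_times
    long = person_time_frame(panel.observed(), K)
    labels = _pattern_labels(panel)
    counts = labels.value_counts().to_dict()
    # merge sparse patterns into coarser ones (more covariates dropped)
    merged_into: dict[frozenset, frozenset] = {}
    full = frozenset(CONFOUNDERS)
    changed = True
    while changed:
        changed = False
        counts = labels.value_counts().to_dict()
        for pat, cnt in sorted(counts.items(), key=lambda kv: kv[1]):
            if cnt < min_pattern_size and pat != full:
                candidates = [
                    p for p in counts if p != pat and p.issuperset(pat)
                ] or [full]
                target = max(candidates, key=lambda p: counts.get(p, 0))
                labels = labels.where(labels != pat, target)
                merged_into[pat] = target
                changed = True
                break
    pattern_info = []
    n = panel.n
    p1_den = np.empty(len(long))
    X_num_all, names_num = _design(long, K, ("A_prev",))
    num = PooledLogit.fit(X_num_all, long["A"].to_numpy(), names_num, "MPA numerator")
    p1_num = num.predict_proba(X_num_all)
    for pat in labels.unique():
        rows = (labels == pat).to_numpy()
        sub = long.loc[rows]
        observed_covs = tuple(v for v in CONFOUNDERS if v not in pat)
        den_covs = observed_covs + ("A_prev",)
        X_den, names_den = _design(sub, K, den_covs)
        y = sub["A"].to_numpy()
        tag = "+".join(sorted(pat)) or "none"
        den = PooledLogit.fit(X_den, y, names_den, f"MPA pattern [{tag} missing] denominator")
        p1_den[rows] = den.predict_proba(X_den)
        pattern_info.append({"pattern": tag, "person_time_rows": int(rows.sum())})
    a_obs = long["A"].to_numpy()
    den_prob = np.where(a_obs == 1, p1_den, 1 - p1_den).reshape(K, n).T
    num_prob = np.where(a_obs == 1, p1_num, 1 - p1_num).reshape(K, n).T
    weights = WeightSet(panel.ids, num_prob, den_prob)
    if truncate:
        weights = weights.truncated()
    est = fit_msm(panel.true, weights, K, method="MPA")
    return MPAResult(weights, est, pd.DataFrame(pattern_info))


# ---------------------------------------------------------------------------
# multiple imputation
# ---------------------------------------------------------------------------

def _pmm_draw(
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    X_mis: np.ndarray,
    rng: np.random.Generator,
    donors: int = 5,
) -> np.ndarray:
    """Bayesian linear fit + predictive mean matching (type-1 matching).

    Parameters are drawn from their approximate posterior; each missing cell
    receives the observed value of a donor chosen at random among the
    ``donors`` observed rows with closest predicted mean.
    """
    n, p = X_obs.shape
    XtX = X_obs.T @ X_obs
    XtX_inv = np.linalg.pinv(XtX)
    beta_hat = XtX_inv @ (X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - p, 1)
    sigma2 = (resid @ resid) / stats.chi2.rvs(dof, random_state=rng)
    cov = 0.5 * (XtX_inv + XtX_inv.T) * sigma2
    jitter = 1e-12 * np.eye(p)
    beta_star = rng.multivariate_normal(beta_hat, cov + jitter, method="cholesky")
    yhat_obs = X_obs @ beta_hat
    yhat_mis = X_mis @ beta_star
    order = np.argsort(yhat_obs)
    sorted_hat = yhat_obs[order]
    pos = np.searchsorted(sorted_hat, yhat_mis)
    window = np.arange(-donors, donors)
    cand = np.clip(pos[:, None] + window[None, :], 0, n - 1)
    dist = np.abs(sorted_hat[cand] - yhat_mis[:, None])
    nearest = np.argpartition(dist, donors - 1, axis=1)[:, :donors]
    pick = nearest[np.arange(len(yhat_mis)), rng.integers(0, donors, len(yhat_mis))]
    donor_rows = cand[np.arange(len(yhat_mis)), pick]
    return y_obs[order][donor_rows]


def _imputation_design(work: pd.DataFrame, target: str, predictors: list[str]) -> np.ndarray:
    """Design matrix for one conditional model in the chained equations.

    Besides main effects of every other column, the model gets, for the
    target's own variable family (same confounder at the other time points),
    pairwise products and exact-equality indicators.  These carry the
    signal of sticky trajectories — e.g. when a confounder took the same
    value before and after a masked visit, the masked value almost surely
    repeated too — which no linear main-effects model can express and which
    predictive mean matching needs in its matching metric.
    """
    others = [p for p in predictors if p != target]
    cols = [np.ones(len(work))] + [work[p].to_numpy(dtype=float) for p in others]
    var = target.rsplit("_", 1)[0]
    family = [p for p in others if p.rsplit("_", 1)[0] == var]
    for i in range(len(family)):
        for j in range(i + 1, len(family)):
            a = work[family[i]].to_numpy(dtype=float)
            b = work[family[j]].to_numpy(dtype=float)
            cols.append(a * b)
            cols.append((a == b).astype(float))
    return np.column_stack(cols)


def chained_imputation(
    frame: pd.DataFrame,
    columns: list[str],
    rng: np.random.Generator,
    n_cycles: int = 5,
    donors: int = 5,
) -> pd.DataFrame:
    """One completed copy of ``frame`` by chained equations with PMM.

    Every partially observed column is regressed on all other columns
    (current working values) plus same-variable cross-time products and
    equality indicators; visit order is increasing missingness.  PMM
    guarantees imputed values lie in the observed support, so binary
    confounders stay binary without a separate logistic engine.
    """
    work = frame.copy()
    miss = {c: frame[c].isna().to_numpy() for c in columns}
    targets = [c for c in columns if miss[c].any()]
    for c in targets:
        if (~miss[c]).sum() == 0:
            raise EstimationError(f"imputation model for {c}: no observed values")
    targets.sort(key=lambda c: miss[c].mean())
    predictors = [c for c in frame.columns if c != "id"]
    # initialise missing cells with random observed values
    for c in targets:
        obs_vals = frame.loc[~miss[c], c].to_numpy()
        work.loc[miss[c], c] = rng.choice(obs_vals, miss[c].sum(), replace=True)
    for _ in range(n_cycles):
        for c in targets:
            X = _imputation_design(work, c, predictors)
            y = frame[c].to_numpy(dtype=float)
            m = miss[c]
            imputed = _pmm_draw(y[~m], X[~m], X[m], rng, donors)
            work.loc[m, c] = imputed
    return work


@dataclass
class ImputationResult:
    """M completed panels, their per-panel estimates, and the Rubin pool."""

    estimates: list[MSMEstimate]
    pooled: MSMEstimate
    within: np.ndarray  # W per coefficient
    between: np.ndarray  # B per coefficient
    total: np.ndarray  # T = W + (1 + 1/M) B per coefficient
    m: int
    completed: list[pd.DataFrame] | None = None


def rubin_pool(point_estimates, within_variances) -> dict:
    """Rubin's rules for combining M point estimates and within variances.

    Returns the pooled estimate, W, B, T = W + (1 + 1/M) B, the
    degrees of freedom of the t reference, and 95% CIs.
    """
    points = np.asarray(point_estimates, dtype=float)
    withins = np.asarray(within_variances, dtype=float)
    if points.shape != withins.shape or points.ndim not in (1, 2):
        raise EstimationError("rubin_pool: estimate and variance lists must align")
    M = points.shape[0]
    if M < 2:
        raise EstimationError("rubin_pool: at least 2 imputations are required")
    pooled = points.mean(axis=0)
    W = withins.mean(axis=0)
    B = points.var(axis=0, ddof=1)
    T = W + (1.0 + 1.0 / M) * B
    with np.errstate(divide="ignore", over="ignore"):
        r = (1.0 + 1.0 / M) * B / np.where(W == 0, np.inf, W)
        df = np.where(B > 0, (M - 1) * (1.0 + 1.0 / np.where(r == 0, np.inf, r)) ** 2, np.inf)
    tcrit = np.where(np.isinf(df), Z975, stats.t.ppf(0.975, np.where(np.isinf(df), 1, df)))
    half = tcrit * np.sqrt(T)
    return {
        "pooled": pooled,
        "W": W,
        "B": B,
        "T": T,
        "df": df,
        "ci_lower": pooled - half,
        "ci_upper": pooled + half,
    }


def mi_estimate(
    panel: PanelData,
    m: int = 10,
    seed: int = 0,
    n_cycles: int = 5,
    donors: int = 5,
    keep_completed: bool = False,
) -> ImputationResult:
    """Multiple imputation of missing confounders, pooled by Rubin's rules.

    Each imputation model conditions on V, all treatments, all confounders at
    all time points, and the outcome Y.  Each completed panel goes through
    the standard weighting + MSM pipeline.
    """
    if m < 2:
        raise EstimationError("mi_estimate: m must be >= 2")
    K = panel.n_times
    obs = panel.observed()
    conf_cols = [f"{var}_{k}" for k in range(K) for var in CONFOUNDERS]
    estimates = []
    completed = []
    if not panel.has_missing():
        est = _analyze(obs, K, "MI")
        estimates = [est] * m
        completed = [obs] * m
    else:
        for i in range(m):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5, i]))
            filled = chained_imputation(obs, conf_cols, rng, n_cycles, donors)
            estimates.append(_analyze(filled, K, "MI"))
            completed.append(filled)
    points = np.vstack([e.params for e in estimates])
    withins = np.vstack([np.diag(e.cov) for e in estimates])
    pool = rubin_pool(points, withins)
    W_cov = np.mean([e.cov for e in estimates], axis=0)
    if not panel.has_missing():
        # all completed panels are identical: between-imputation variance is 0
        pool["B"] = np.zeros_like(pool["B"])
        pool["T"] = pool["W"].copy()
        pool["pooled"] = estimates[0].params
        B_cov = np.zeros_like(W_cov)
    else:
        centered = points - pool["pooled"]
        B_cov = centered.T @ centered / (m - 1)
    T_cov = W_cov + (1.0 + 1.0 / m) * B_cov
    mean_df = float(np.mean(pool["df"])) if np.all(np.isfinite(pool["df"])) else np.inf
    pooled = MSMEstimate(
        beta_int=float(pool["pooled"][0]),
        betas=pool["pooled"][1:].copy(),
        cov=T_cov,
        variance_method="rubin",
        method="MI",
        n_effective=panel.n,
        weight_summary=estimates[0].weight_summary,
        ci_scale=float(stats.t.ppf(0.975, mean_df)) if np.isfinite(mean_df) else Z975,
    )
    return ImputationResult(
        estimates=estimates,
        pooled=pooled,
        within=pool["W"],
        between=pool["B"],
        total=pool["T"],
        m=m,
        completed=completed if keep_completed else None,
    )


# ---------------------------------------------------------------------------
# inverse-probability-of-missingness weighting
# ---------------------------------------------------------------------------

def ipmw_missing_weights(remain_num: np.ndarray, remain_den: np.ndarray) -> np.ndarray:
    """Cumulative stabilized missingness weight: prod_k num_k / den_k."""
    return np.prod(remain_num / remain_den, axis=1)


def ipmw_estimate(panel: PanelData, truncate: bool = False) -> tuple[WeightSet, MSMEstimate]:
    """Censor at the first missing confounder; reweight the complete records.

    Missingness is monotonized: a subject with any missing confounder at time
    k contributes no person-time from k onward, even if later values are
    observed.  The remain (uncensored) probability at time k is estimated as
    the product over confounders of per-cell logistic models
    ``P(cell observed at k | A_{k-1}, L1_{k-1}, L2_{k-1}, V)`` fitted among
    subjects still at risk (intercept only at k = 0, where no lagged values
    exist); being censored means *any* cell is missing, so the cell-level
    factorisation keeps the remain model correctly specified when each
    recording process is logistic.  The numerator uses past treatment only.
    The cumulative missingness weight multiplies the treatment weight and the
    MSM is fitted on subjects uncensored through the last time point.
    """
    K = panel.n_times
    n = panel.n
    mask_arr = panel.mask_array()  # (n, K, 2)
    any_missing = mask_arr.any(axis=2)  # (n, K)
    censor_time = np.where(any_missing.any(axis=1), any_missing.argmax(axis=1), K)
    uncensored = censor_time == K
    if not uncensored.any():
        raise EmptyAnalysisError("IPMW: no subject remains fully observed")
    df = panel.true
    remain_den = np.ones((n, K))
    remain_num = np.ones((n, K))
    for k in range(K):
        at_risk = censor_time >= k
        n_risk = int(at_risk.sum())
        cols = [np.ones(n_risk)]
        names = ["intercept"]
        if k > 0:
            prev = df.loc[at_risk]
            cols += [
                prev[f"A_{k - 1}"].to_numpy(dtype=float),
                prev[f"L1_{k - 1}"].to_numpy(dtype=float),
                prev[f"L2_{k - 1}"].to_numpy(dtype=float),
                prev["V"].to_numpy(dtype=float),
            ]
            names += [f"A_{k - 1}", f"L1_{k - 1}", f"L2_{k - 1}", "V"]
        X_den = np.column_stack(cols)
        X_num = X_den[:, :2] if k > 0 else X_den[:, :1]
        for j, var in enumerate(CONFOUNDERS):
            missing = mask_arr[at_risk, k, j].astype(float)
            if missing.max() == 0.0:
                continue  # this cell is never missing at k: factor 1
            den = PooledLogit.fit(
                X_den, missing, names, f"IPMW missingness model for {var} at k={k}"
            )
            num = PooledLogit.fit(
                X_num, missing, names[: X_num.shape[1]],
                f"IPMW missingness numerator for {var} at k={k}",
            )
            remain_den[at_risk, k] *= 1.0 - den.predict_proba(X_den)
            remain_num[at_risk, k] *= 1.0 - num.predict_proba(X_num)
    # treatment models on uncensored person-time rows (confounders observed)
    long = person_time_frame(df, K)
    contrib = np.concatenate([censor_time > k for k in range(K)])
    sub = long.loc[contrib]
    y = sub["A"].to_numpy()
    X_den, names_den = _design(sub, K, ("L1", "L2", "A_prev"))
    X_num, names_num = _design(sub, K, ("A_prev",))
    den_model = PooledLogit.fit(X_den, y, names_den, "IPMW treatment denominator")
    num_model = PooledLogit.fit(X_num, y, names_num, "IPMW treatment numerator")
    models = TreatmentModels(num_model, den_model, K)
    keep = np.flatnonzero(uncensored)
    sub_panel = panel.subset(keep)
    tw = compute_stabilized_weights(sub_panel.true, models)
    mw = ipmw_missing_weights(remain_num[keep], remain_den[keep])
    weights = WeightSet(sub_panel.ids, tw.num_prob, tw.den_prob, missing_factor=mw)
    if truncate:
        weights = weights.truncated()
    est = fit_msm(sub_panel.true, weights, K, method="IPMW")
    return weights, est


#: Dispatch table used by the experiment driver and the CLI.
def _run_cc(panel, truncate=False, **kw):
    return complete_case(panel, truncate)[1]


def _run_locf(panel, truncate=False, **kw):
    return locf_impute(panel, truncate)[1]


def _run_mpa(panel, min_pattern_size: int = 50, truncate=False, **kw):
    return mpa_weights(panel, min_pattern_size, truncate).estimate


def _run_mi(panel, m: int = 10, seed: int = 0, **kw):
    return mi_estimate(panel, m=m, seed=seed).pooled


def _run_ipmw(panel, truncate=False, **kw):
    return ipmw_estimate(panel, truncate)[1]


METHODS = {
    "full": lambda panel, truncate=False, **kw: full_data(panel, truncate),
    "cc": _run_cc,
    "locf": _run_locf,
    "mpa": _run_mpa,
    "mi": _run_mi,
    "ipmw": _run_ipmw,
}
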