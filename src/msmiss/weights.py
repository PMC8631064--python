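"""Stabilized inverse-probability-of-treatment weights.

Both weight models are pooled logistic regressions on stacked person-time
rows (one row per subject per time point) with time-specific intercepts:

* denominator: ``A_k ~ time + L1_k + L2_k + A_{k-1}``
* numerator:   ``A_k ~ time + A_{k-1}``

``A_{-1}`` is defined as 0 for every subject.  The per-time stabilized
factor is ``P_num(observed A_k) / P_den(observed A_k)`` and the analysis
weight is the cumulative product over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .errors import EstimationError, PositivityError
from .panel import PanelData

_PROB_EPS = 1e-10


def _frame(data) -> pd.DataFrame:
    if isinstance(data, PanelData):
        return data.true
    return data


def _n_times(data, n_times=None) -> int:
    if isinstance(data, PanelData):
        return data.n_times
    if n_times is None:
        k = 0
        while f"A_{k}" in data.columns:
            k += 1
        return k
    return n_times


class PooledLogit:
    """A pooled logistic fit on a person-time design, with column bookkeeping.

    Columns without variation in the fitting rows (e.g. ``A_prev`` in a
    design restricted to k = 0) are dropped before fitting and contribute
    zero to the linear predictor at prediction time.
    """

    def __init__(self, params: np.ndarray, kept: np.ndarray, names: list[str]):
        self.params = params
        self.kept = kept
        self.names = names

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray, names: list[str], context: str) -> "PooledLogit":
        ptp = X.max(axis=0) - X.min(axis=0)
        kept = np.flatnonzero((ptp > 0) | (np.arange(X.shape[1]) < 1))
        # always keep at least the first column (an intercept-like dummy)
        Xk = X[:, kept]
        try:
            res = sm.GLM(y, Xk, family=sm.families.Binomial()).fit(maxiter=100)
        except Exception as exc:  # separation raises PerfectSeparationError
            raise EstimationError(f"{context}: pooled logistic fit failed ({exc})") from exc
        if not res.converged:
            raise EstimationError(f"{context}: pooled logistic did not converge")
        if np.any(np.abs(res.params) > 30):
            j = int(np.argmax(np.abs(res.params)))
            raise EstimationError(
                f"{context}: quasi-separation on column {names[kept[j]]!r} "
                f"(|coefficient| = {abs(res.params[j]):.1f})"
            )
        return cls(np.asarray(res.params), kept, names)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(X[:, self.kept] @ self.params)


def person_time_frame(data, n_times: int | None = None) -> pd.DataFrame:
    """Stack a wide panel into person-time rows ``(id, k, A, L1, L2, A_prev)``."""
    df = _frame(data)
    K = _n_times(data, n_times)
    blocks = []
    for k in range(K):
        blocks.append(
            pd.DataFrame(
                {
                    "id": df["id"].to_numpy(),
                    "k": k,
                    "A": df[f"A_{k}"].to_numpy(dtype=float),
                    "L1": df[f"L1_{k}"].to_numpy(dtype=float),
                    "L2": df[f"L2_{k}"].to_numpy(dtype=float),
                    "A_prev": df[f"A_{k - 1}"].to_numpy(dtype=float) if k > 0 else 0.0,
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)


def _design(long: pd.DataFrame, K: int, covariates: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols = []
    names = []
    kvals = long["k"].to_numpy()
    for k in range(K):
        cols.append((kvals == k).astype(float))
        names.append(f"time_{k}")
    for c in covariates:
        cols.append(long[c].to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), names


@dataclass
class TreatmentModels:
    """Fitted numerator and denominator pooled treatment models."""

    numerator: PooledLogit
    denominator: PooledLogit
    n_times: int
    den_covariates: tuple[str, ...] = ("L1", "L2", "A_prev")
    num_covariates: tuple[str, ...] = ("A_prev",)

    def _probs(self, model: PooledLogit, covariates, data) -> np.ndarray:
        """(n, K) matrix of P(A_k = 1 | .) for each subject and time."""
        long = person_time_frame(data, self.n_times)
        X, _ = _design(long, self.n_times, covariates)
        p = model.predict_proba(X)
        return p.reshape(self.n_times, -1).T

    def prob_treated(self, data, which: str = "denominator") -> np.ndarray:
        model = self.denominator if which == "denominator" else self.numerator
        covs = self.den_covariates if which == "denominator" else self.num_covariates
        return self._probs(model, covs, data)


def fit_treatment_models(data, n_times: int | None = None) -> TreatmentModels:
    """Fit the stabilized-weight numerator and denominator models.

    The panel must have no missing values among the model covariates for the
    contributed person-time rows.
    """
    K = _n_times(data, n_times)
    long = person_time_frame(data, K)
    if long[["A", "L1", "L2", "A_prev"]].isna().any().any():
        raise EstimationError("treatment models: missing values among covariates")
    y = long["A"].to_numpy()
    X_den, names_den = _design(long, K, ("L1", "L2", "A_prev"))
    X_num, names_num = _design(long, K, ("A_prev",))
    den = PooledLogit.fit(X_den, y, names_den, "denominator model")
    num = PooledLogit.fit(X_num, y, names_num, "numerator model")
    return TreatmentModels(num, den, K)


@dataclass
class WeightSet:
    """Per-subject, per-time stabilized weight factors and cumulative products.

    ``num_prob``/``den_prob`` are probabilities of the *received* treatment.
    ``missing_factor`` optionally holds cumulative
    inverse-probability-of-missingness factors (IPMW) that multiply the
    treatment weight.
    """

    ids: np.ndarray
    num_prob: np.ndarray  # (n, K)
    den_prob: np.ndarray  # (n, K)
    missing_factor: np.ndarray | None = None  # (n,) cumulative, optional
    factor: np.ndarray = field(init=False)
    cum: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for name, p in (("numerator", self.num_prob), ("denominator", self.den_prob)):
            bad = (p <= _PROB_EPS) | (p >= 1 - _PROB_EPS) | ~np.isfinite(p)
            if bad.any():
                rows = np.argwhere(bad)[:20]
                raise PositivityError(
                    f"{name} probability numerically 0 or 1 for (subject, time) rows "
                    f"{[tuple(map(int, r)) for r in rows]}"
                )
        self.factor = self.num_prob / self.den_prob
        self.cum = np.cumprod(self.factor, axis=1)

    @property
    def final(self) -> np.ndarray:
        w = self.cum[:, -1]
        if self.missing_factor is not None:
            w = w * self.missing_factor
        return w

    def summary(self) -> dict:
        w = self.final
        return {
            "mean": float(w.mean()),
            "max": float(w.max()),
            "q99": float(np.quantile(w, 0.99)),
        }

    def truncated(self, lower: float = 0.01, upper: float = 0.99) -> "WeightSet":
        """Symmetric percentile truncation of the final weights (off by default)."""
        out = WeightSet(self.ids, self.num_prob, self.den_prob, self.missing_factor)
        w = out.final
        lo, hi = np.quantile(w, [lower, upper])
        scale = np.clip(w, lo, hi) / np.where(w == 0, 1.0, w)
        out.cum = out.cum * scale[:, None]
        return out


def compute_stabilized_weights(data, models: TreatmentModels) -> WeightSet:
    """Per-time stabilized factors and their cumulative products."""
    df = _frame(data)
    K = models.n_times
    a_obs = np.column_stack([df[f"A_{k}"].to_numpy(dtype=float) for k in range(K)])
    p1_den = models.prob_treated(data, "denominator")
    p1_num = models.prob_treated(data, "numerator")
    den = np.where(a_obs == 1, p1_den, 1 - p1_den)
    num = np.where(a_obs == 1, p1_num, 1 - p1_num)
    return WeightSet(df["id"].to_numpy(), num, den)


def _smd(x: np.ndarray, a: np.ndarray, w: np.ndarray) -> float:
    """Weighted standardized mean difference between treatment arms."""
    if (a == 1).sum() == 0 or (a == 0).sum() == 0:
        return float("nan")
    stats = []
    for arm in (1, 0):
        sel = a == arm
        ww = w[sel]
        xx = x[sel]
        m = np.average(xx, weights=ww)
        v = np.average((xx - m) ** 2, weights=ww)
        stats.append((m, v))
    (m1, v1), (m0, v0) = stats
    denom = np.sqrt((v1 + v0) / 2.0)
    if denom == 0:
        return 0.0 if m1 == m0 else float("inf")
    return (m1 - m0) / denom


def balance_diagnostics(data, weights: WeightSet, n_times: int | None = None) -> pd.DataFrame:
    """Weighted and unweighted confounder SMDs between arms at each time.

    The weighted columns use the cumulative *unstabilized* inverse
    probability weight through k (1 / product of denominator probabilities):
    in that pseudo-population treatment is sequentially randomized, so the
    marginal confounder distributions should balance between arms at every
    time point.  (Stabilized weights leave the association with past
    treatment in place by design, so their marginal SMDs need not vanish.)
    An empty treatment arm yields NaN, not an exception.
    """
    df = _frame(data)
    K = _n_times(data, n_times)
    unstab = np.cumprod(1.0 / weights.den_prob, axis=1)
    ones = np.ones(len(df))
    rows = []
    for k in range(K):
        a = df[f"A_{k}"].to_numpy(dtype=float)
        w = unstab[:, k]
        for var in ("L1", "L2"):
            x = df[f"{var}_{k}"].to_numpy(dtype=float)
            rows.append(
                {
                    "time": k,
                    "variable": var,
                    "smd_unweighted": _smd(x, a, ones),
                    "smd_weighted": _smd(x, a, w),
                }
            )
    return pd.DataFrame(rows)
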