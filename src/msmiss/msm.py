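"""Fitting the additive marginal structural model and regime contrasts.

The MSM is ``E[Y^a] = beta_int + sum_k beta_k a_k``, fitted by weighted
least squares of the observed outcome on the treatment history with the
stabilized weights.  The default variance is the heteroskedasticity-robust
sandwich treating the weights as known — conservative for stabilized
weights, with the nonparametric bootstrap (weights re-estimated inside each
resample) as the corrective option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import BootstrapError, EstimationError
from .panel import PanelData
from .weights import WeightSet, _frame, _n_times

Z975 = float(stats.norm.ppf(0.975))


@dataclass
class MSMEstimate:
    """Fitted marginal structural coefficients with provenance."""

    beta_int: float
    betas: np.ndarray  # (K,)
    cov: np.ndarray  # (K+1, K+1) including intercept
    variance_method: str = "sandwich"
    method: str = "full-data"
    n_effective: int = 0
    weight_summary: dict = field(default_factory=dict)
    ci_scale: float = Z975  # multiplier for the CI half-width (t for Rubin pooling)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.beta_int], self.betas])

    @property
    def conf_int(self) -> np.ndarray:
        p = self.params
        half = self.ci_scale * self.se
        return np.column_stack([p - half, p + half])

    def to_dict(self) -> dict:
        ci = self.conf_int
        return {
            "method": self.method,
            "variance_method": self.variance_method,
            "n_effective": int(self.n_effective),
            "beta_int": float(self.beta_int),
            "betas": [float(b) for b in self.betas],
            "se": [float(s) for s in self.se],
            "ci_lower": [float(x) for x in ci[:, 0]],
            "ci_upper": [float(x) for x in ci[:, 1]],
            "weight_summary": self.weight_summary,
        }


def fit_msm(
    data,
    weights: WeightSet | None = None,
    n_times: int | None = None,
    method: str = "full-data",
) -> MSMEstimate:
    """Weighted least squares of Y on (1, A_0, ..., A_{K-1})."""
    df = _frame(data)
    K = _n_times(data, n_times)
    X = np.column_stack(
        [np.ones(len(df))] + [df[f"A_{k}"].to_numpy(dtype=float) for k in range(K)]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError(
            "MSM design is rank deficient (degenerate treatment-regime distribution)"
        )
    y = df["Y"].to_numpy(dtype=float)
    if weights is None:
        w = np.ones(len(df))
        wsummary = {"mean": 1.0, "max": 1.0, "q99": 1.0}
    else:
        order = pd.Series(np.arange(len(weights.ids)), index=weights.ids)
        w = weights.final[order.loc[df["id"].to_numpy()].to_numpy()]
        wsummary = weights.summary()
    res = sm.WLS(y, X, weights=w).fit(cov_type="HC0")
    return MSMEstimate(
        beta_int=float(res.params[0]),
        betas=np.asarray(res.params[1:]),
        cov=np.asarray(res.cov_params()),
        variance_method="sandwich",
        method=method,
        n_effective=len(df),
        weight_summary=wsummary,
    )


def regime_contrast(
    est: MSMEstimate, regime_a: Sequence[int], regime_b: Sequence[int]
) -> tuple[float, float]:
    """Mean outcome contrast between two static regimes, with delta-method SE."""
    K = len(est.betas)
    a = np.asarray(regime_a, dtype=float)
    b = np.asarray(regime_b, dtype=float)
    if a.shape != (K,) or b.shape != (K,):
        raise EstimationError(f"regimes must have length {K}")
    d = np.concatenate([[0.0], a - b])
    effect = float(d @ est.params)
    se = float(np.sqrt(d @ est.cov @ d))
    return effect, se


def _resample(panel: PanelData, rng: np.random.Generator) -> PanelData:
    idx = rng.integers(0, panel.n, panel.n)
    true = panel.true.iloc[idx].reset_index(drop=True)
    mask = panel.mask.iloc[idx].reset_index(drop=True)
    true = true.copy()
    true["id"] = np.arange(len(true))
    return PanelData(true, mask, panel.n_times, panel.dgm)


def bootstrap_ci(
    panel: PanelData,
    pipeline: Callable[[PanelData], np.ndarray],
    B: int,
    seed: int,
    max_failure_rate: float = 0.05,
) -> dict:
    """Subject-level nonparametric bootstrap of a full analysis pipeline.

    ``pipeline`` maps a panel to a coefficient vector (re-estimating weights
    and any missing-data handling inside).  Returns percentile 95% intervals,
    the replicate draws, and the failure count.  Reproducible given ``seed``.
    """
    if B < 2:
        raise EstimationError("bootstrap: B must be >= 2")
    draws = []
    failures = 0
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4, b]))
        try:
            draws.append(np.asarray(pipeline(_resample(panel, rng)), dtype=float))
        except Exception:
            failures += 1
    if failures > max_failure_rate * B:
        raise BootstrapError(
            f"bootstrap unstable: {failures}/{B} replicates failed"
        )
    arr = np.vstack(draws)
    lower = np.percentile(arr, 2.5, axis=0)
    upper = np.percentile(arr, 97.5, axis=0)
    return {
        "ci_lower": lower,
        "ci_upper": upper,
        "draws": arr,
        "failures": failures,
        "B": B,
    }
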