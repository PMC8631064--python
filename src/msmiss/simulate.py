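"""Sequential simulation of longitudinal panels and missingness overlays.

The simulator draws, per subject, ``V -> L_0 -> A_0 -> L_1 -> A_1 -> ... -> Y``
with treatment-confounder feedback (earlier treatment enters later confounder
dynamics, current confounders enter the treatment model).  Missingness is
applied afterwards as an overlay that only sets flags — with one documented
exception: the DIFFERENTIAL mechanism interleaves mask and treatment draws so
that a confounder masked at time k is dropped from the time-k treatment
decision, which requires re-drawing treatments and everything downstream.

Seeding: one root seed per call; internal substreams keep data, masks, and
re-drawn trajectories independent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .config import DGMConfig, MissingnessConfig
from .errors import CalibrationError, ConfigurationError
from .panel import CONFOUNDERS, PanelData, mask_columns, wide_columns

_STREAM_DATA = 0
_STREAM_MASK = 1
_STREAM_REDRAW = 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


# ---------------------------------------------------------------------------
# full-data simulation
# ---------------------------------------------------------------------------

def _draw_l(config: DGMConfig, rng, l1_prev, l2_prev, a_prev):
    """One confounder transition step (sticky carry-over then fresh draw)."""
    n = len(l1_prev)
    carry1 = rng.random(n) < config.carryover
    if config.l1_continuous:
        fresh1 = (
            config.l1_intercept
            + config.l1_auto * l1_prev
            + config.l1_treat * a_prev
            + config.l1_sd * rng.standard_normal(n)
        )
    else:
        p1 = expit(config.l1_intercept + config.l1_auto * l1_prev + config.l1_treat * a_prev)
        fresh1 = (rng.random(n) < p1).astype(float)
    l1 = np.where(carry1, l1_prev, fresh1)
    carry2 = rng.random(n) < config.carryover
    fresh2 = (
        config.l2_intercept
        + config.l2_auto * l2_prev
        + config.l2_treat * a_prev
        + config.l2_sd * rng.standard_normal(n)
    )
    l2 = np.where(carry2, l2_prev, fresh2)
    return l1, l2


def _treat_prob(config: DGMConfig, k, l1, l2, a_prev, l1_obs=None, l2_obs=None):
    """Treatment probability at time k; observedness gates sever masked confounders."""
    lin = config.treat_intercepts[k] + config.treat_prev * a_prev
    lin = lin + config.treat_l1 * (l1 if l1_obs is None else l1 * l1_obs)
    lin = lin + config.treat_l2 * (l2 if l2_obs is None else l2 * l2_obs)
    return expit(lin)


def _outcome(config: DGMConfig, rng, v, l1s, l2s, a_s):
    y = config.out_intercept + config.out_v * v
    for k in range(config.n_times):
        y = y + config.out_treat[k] * a_s[k]
        y = y + config.out_l1[k] * l1s[k] + config.out_l2[k] * l2s[k]
    return y + config.out_sd * rng.standard_normal(len(v))


def _assemble(config, v, l1s, l2s, a_s, y, mask_arrays=None, dgm=None) -> PanelData:
    n = len(v)
    data = {"id": np.arange(n, dtype=int), "V": v}
    for k in range(config.n_times):
        data[f"L1_{k}"] = l1s[k]
        data[f"L2_{k}"] = l2s[k]
        data[f"A_{k}"] = a_s[k].astype(int)
    data["Y"] = y
    true = pd.DataFrame(data, columns=wide_columns(config.n_times))
    mcols = mask_columns(config.n_times)
    if mask_arrays is None:
        mask = pd.DataFrame(False, index=true.index, columns=mcols)
    else:
        mask = pd.DataFrame({c: mask_arrays[c] for c in mcols})
    return PanelData(true, mask, config.n_times, dgm or config)


def simulate_full_data(config: DGMConfig, n: int, seed: int) -> PanelData:
    """Simulate ``n`` complete subjects from the structural model.

    Identical ``(config, n, seed)`` triples give bit-identical panels; all
    missingness flags are 0.
    """
    if n < 1:
        raise ConfigurationError("n: must be >= 1")
    rng = _rng(seed, _STREAM_DATA)
    v = config.v_mean + config.v_sd * rng.standard_normal(n)
    if config.l1_continuous:
        l1 = config.l1_baseline_mean + config.l1_baseline_sd * rng.standard_normal(n)
    else:
        l1 = (rng.random(n) < config.l1_baseline_p).astype(float)
    l2 = config.l2_baseline_mean + config.l2_baseline_sd * rng.standard_normal(n)
    l1s, l2s, a_s = [], [], []
    a_prev = np.zeros(n)
    for k in range(config.n_times):
        if k > 0:
            l1, l2 = _draw_l(config, rng, l1s[-1], l2s[-1], a_prev)
        l1s.append(l1)
        l2s.append(l2)
        a = (rng.random(n) < _treat_prob(config, k, l1, l2, a_prev)).astype(float)
        a_s.append(a)
        a_prev = a
    y = _outcome(config, rng, v, l1s, l2s, a_s)
    return _assemble(config, v, l1s, l2s, a_s, y)


# ---------------------------------------------------------------------------
# missingness overlays
# ---------------------------------------------------------------------------

def _mechanism_linpred(mconfig: MissingnessConfig, df, k, obs_gate):
    """Linear predictor of the missingness model for cells at time k >= 1.

    Lagged confounders contribute only where they are themselves observed
    (``obs_gate``), so the probability of missingness depends on observed
    data alone and the mechanism is missing-at-random by construction.
    """
    lin = np.full(len(df), mconfig.intercept)
    s = mconfig.slopes()
    if "prev_treat" in s:
        lin = lin + s["prev_treat"] * df[f"A_{k - 1}"].to_numpy(dtype=float)
    if "prev_l1" in s:
        lin = lin + s["prev_l1"] * df[f"L1_{k - 1}"].to_numpy(dtype=float) * obs_gate["L1"]
    if "prev_l2" in s:
        lin = lin + s["prev_l2"] * df[f"L2_{k - 1}"].to_numpy(dtype=float) * obs_gate["L2"]
    if "outcome" in s:
        lin = lin + s["outcome"] * df["Y"].to_numpy(dtype=float)
    if "risk_factor" in s:
        lin = lin + s["risk_factor"] * df["V"].to_numpy(dtype=float)
    return lin


def maskable_cells(mconfig: MissingnessConfig, n_times: int) -> list[tuple[str, int]]:
    """(variable, time) cells the mechanism may mask.

    Only MCAR can mask baseline measurements; history-dependent mechanisms
    start at k = 1 because their predictors are lagged.
    """
    k0 = 0 if mconfig.mechanism == "MCAR" else 1
    return [(var, k) for k in range(k0, n_times) for var in mconfig.targets]


def realized_missingness(panel: PanelData, mconfig: MissingnessConfig) -> float:
    """Fraction of the mechanism's maskable cells that are flagged missing."""
    cells = maskable_cells(mconfig, panel.n_times)
    flags = np.concatenate(
        [panel.mask[f"M_{var}_{k}"].to_numpy() for var, k in cells]
    )
    return float(flags.mean())


def _require_dgm(panel: PanelData, mechanism: str) -> DGMConfig:
    if not isinstance(panel.dgm, DGMConfig):
        raise ConfigurationError(
            f"mechanism {mechanism} needs the panel's generating DGMConfig (panel.dgm)"
        )
    return panel.dgm


def apply_missingness(panel: PanelData, mconfig: MissingnessConfig, seed: int) -> PanelData:
    """Overlay one missingness mechanism on a fully observed panel.

    True values are retained alongside the flags.  Under DIFFERENTIAL the
    treatments (and their downstream confounder values and outcome) are
    re-drawn so that a confounder masked at k does not enter the time-k
    treatment decision; all other mechanisms only set flags.
    """
    if panel.has_missing():
        raise ConfigurationError("apply_missingness: panel already has missing values")
    if mconfig.mechanism == "DIFFERENTIAL":
        return _apply_differential(panel, mconfig, seed)
    rng = _rng(seed, _STREAM_MASK)
    df = panel.true
    n = panel.n
    K = panel.n_times
    masks = {c: np.zeros(n, dtype=bool) for c in mask_columns(K)}

    if mconfig.mechanism == "MCAR":
        p = expit(mconfig.intercept)
        for var, k in maskable_cells(mconfig, K):
            masks[f"M_{var}_{k}"] = rng.random(n) < p
    elif mconfig.mechanism == "CONSTANT":
        dgm = _require_dgm(panel, "CONSTANT")
        if dgm.carryover == 0.0:
            continuous = [v for v in mconfig.targets if v == "L2" or dgm.l1_continuous]
            if continuous:
                raise ConfigurationError(
                    "CONSTANT: carryover = 0 gives exact repeats probability zero "
                    f"for continuous confounder(s) {continuous}"
                )
        p = expit(mconfig.intercept)
        for var, k in maskable_cells(mconfig, K):
            repeat = (
                df[f"{var}_{k}"].to_numpy() == df[f"{var}_{k - 1}"].to_numpy()
            )
            masks[f"M_{var}_{k}"] = repeat & (rng.random(n) < p)
    else:  # MAR_AL / MAR_ALY / MAR_ALV
        for k in range(1, K):
            obs_gate = {
                var: 1.0 - masks[f"M_{var}_{k - 1}"].astype(float)
                for var in CONFOUNDERS
            }
            lin = _mechanism_linpred(mconfig, df, k, obs_gate)
            p = expit(lin)
            for var in mconfig.targets:
                masks[f"M_{var}_{k}"] = rng.random(n) < p
    mask = pd.DataFrame(masks)
    return PanelData(df.copy(), mask, K, panel.dgm)


def _apply_differential(panel: PanelData, mconfig: MissingnessConfig, seed: int) -> PanelData:
    """DIFFERENTIAL: per-time order L_k -> M_k -> A_k.

    The treatment model drops any confounder masked at k (the physician sees
    only recorded values), so among masked records the true confounder value
    is conditionally independent of the contemporaneous treatment.  V and the
    baseline confounders are kept from the input panel; treatments, later
    confounders, and the outcome are re-drawn.
    """
    config = _require_dgm(panel, "DIFFERENTIAL")
    rng_mask = _rng(seed, _STREAM_MASK)
    rng_data = _rng(seed, _STREAM_REDRAW)
    n = panel.n
    K = panel.n_times
    v = panel.true["V"].to_numpy(dtype=float)
    l1s = [panel.true["L1_0"].to_numpy(dtype=float)]
    l2s = [panel.true["L2_0"].to_numpy(dtype=float)]
    masks = {c: np.zeros(n, dtype=bool) for c in mask_columns(K)}
    a_s = []
    a_prev = np.zeros(n)
    for k in range(K):
        if k > 0:
            l1, l2 = _draw_l(config, rng_data, l1s[-1], l2s[-1], a_prev)
            l1s.append(l1)
            l2s.append(l2)
            frame = pd.DataFrame(
                {
                    f"A_{k - 1}": a_prev,
                    f"L1_{k - 1}": l1s[k - 1],
                    f"L2_{k - 1}": l2s[k - 1],
                }
            )
            obs_gate = {
                var: 1.0 - masks[f"M_{var}_{k - 1}"].astype(float)
                for var in CONFOUNDERS
            }
            lin = _mechanism_linpred(mconfig, frame, k, obs_gate)
            p_miss = expit(lin)
            for var in mconfig.targets:
                masks[f"M_{var}_{k}"] = rng_mask.random(n) < p_miss
        l1_obs = 1.0 - masks[f"M_L1_{k}"].astype(float)
        l2_obs = 1.0 - masks[f"M_L2_{k}"].astype(float)
        p_a = _treat_prob(config, k, l1s[k], l2s[k], a_prev, l1_obs, l2_obs)
        a = (rng_data.random(n) < p_a).astype(float)
        a_s.append(a)
        a_prev = a
    y = _outcome(config, rng_data, v, l1s, l2s, a_s)
    out = _assemble(config, v, l1s, l2s, a_s, y, masks, dgm=panel.dgm)
    out.true["id"] = panel.true["id"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_missingness(
    mconfig: MissingnessConfig,
    config: DGMConfig,
    target: float,
    seed: int,
    n_cal: int = 20_000,
) -> MissingnessConfig:
    """Adjust the mechanism intercept so realized missingness hits ``target``.

    Monotone root-finding on the intercept over one large simulated panel;
    slopes are untouched.  MCAR is solved analytically.
    """
    if not (0.0 < target < 1.0):
        raise ConfigurationError("target: must lie in (0, 1)")
    if mconfig.mechanism == "MCAR":
        return dataclasses.replace(
            mconfig, intercept=float(logit(target)), target_proportion=target
        )
    panel = simulate_full_data(config, n_cal, seed)

    def realized(intercept: float) -> float:
        trial = dataclasses.replace(mconfig, intercept=float(intercept))
        masked = apply_missingness(panel, trial, seed)
        return realized_missingness(masked, trial)

    lo, hi = -12.0, 12.0
    r_lo, r_hi = realized(lo), realized(hi)
    if not (r_lo <= target <= r_hi):
        raise CalibrationError(
            f"target {target:.3f} unreachable for {mconfig.mechanism}: "
            f"achievable range is [{r_lo:.3f}, {r_hi:.3f}]"
        )
    root = brentq(lambda x: realized(x) - target, lo, hi, xtol=1e-3)
    out = dataclasses.replace(mconfig, intercept=float(root), target_proportion=target)
    achieved = realized(out.intercept)
    if abs(achieved - target) > 0.02:
        raise CalibrationError(
            f"calibration landed at {achieved:.3f}, more than 2 points from {target:.3f}"
        )
    return out


_DEFAULT_SLOPES = {
    "MCAR": {},
    "CONSTANT": {},
    "MAR_AL": {"slope_prev_treat": 0.5, "slope_prev_l1": 0.7, "slope_prev_l2": 0.5},
    "MAR_ALY": {
        "slope_prev_treat": 0.5,
        "slope_prev_l1": 0.7,
        "slope_prev_l2": 0.5,
        "slope_outcome": 0.4,
    },
    "MAR_ALV": {
        "slope_prev_treat": 0.5,
        "slope_prev_l1": 0.7,
        "slope_prev_l2": 0.5,
        "slope_risk_factor": 0.7,
    },
    "DIFFERENTIAL": {"slope_prev_treat": 0.5, "slope_prev_l1": 0.7, "slope_prev_l2": 0.5},
}

_CALIBRATION_SEED = 731_001


def default_missingness(
    mechanism: str = "MAR_AL",
    target: float = 0.40,
    config: DGMConfig | None = None,
) -> MissingnessConfig:
    """The shipped scenario configuration: preset slopes, calibrated intercept.

    ``target=0.40`` is the main scenario; ``target=0.05`` the low-missingness
    secondary scenario.
    """
    if mechanism not in _DEFAULT_SLOPES:
        raise ConfigurationError(f"mechanism: unknown mechanism {mechanism!r}")
    if config is None:
        config = DGMConfig()
    raw = MissingnessConfig(mechanism=mechanism, **_DEFAULT_SLOPES[mechanism])
    return calibrate_missingness(raw, config, target, seed=_CALIBRATION_SEED)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class MissingnessSummary:
    per_cell: pd.DataFrame  # variable, time, proportion missing
    overall: float  # over all confounder cells
    patterns: pd.DataFrame  # pattern label, count

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"overall missing fraction {self.overall:.3f} over "
            f"{len(self.per_cell)} confounder cells; "
            f"{len(self.patterns)} distinct patterns"
        )


def missingness_summary(panel: PanelData) -> MissingnessSummary:
    """Per-cell missing proportions and missing-data pattern counts."""
    rows = []
    flags = []
    for k in range(panel.n_times):
        for var in CONFOUNDERS:
            f = panel.mask[f"M_{var}_{k}"].to_numpy()
            flags.append(f)
            rows.append({"variable": var, "time": k, "proportion": float(f.mean())})
    per_cell = pd.DataFrame(rows)
    overall = float(np.concatenate(flags).mean())
    cells = [f"{var}_{k}" for k in range(panel.n_times) for var in CONFOUNDERS]
    flag_mat = np.column_stack(flags)
    labels = [
        ",".join(c for c, m in zip(cells, row) if m) or "complete" for row in flag_mat
    ]
    patterns = (
        pd.Series(labels)
        .value_counts()
        .rename_axis("pattern")
        .reset_index(name="count")
    )
    return MissingnessSummary(per_cell, overall, patterns)
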