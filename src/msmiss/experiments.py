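"""Replicate simulations across method x mechanism scenarios.

``run_scenario`` simulates R independent replicates (per-replicate seed
substreams keyed by replicate index, so results are invariant to execution
order), overlays the scenario's missingness mechanism, analyses each
replicate with every requested method, and summarises bias, Monte Carlo
error, empirical and model-based SEs, and CI coverage against the oracle
truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DGMConfig, MissingnessConfig
from .errors import MsmissError, ScenarioInstabilityError
from .methods import METHODS
from .oracle import TrueEstimand, true_msm_coefficients
from .simulate import apply_missingness, simulate_full_data

METRICS = (
    "bias",
    "mc_se",
    "empirical_sd",
    "mean_model_se",
    "coverage",
    "mean_abs_bias",
)


@dataclass
class ScenarioSpec:
    """One simulation scenario: DGM, mechanism, methods, size, replications."""

    name: str
    dgm: DGMConfig
    missingness: MissingnessConfig | None  # None = full data only
    methods: tuple[str, ...]
    n: int = 10_000
    reps: int = 200
    seed: int = 0
    truth: TrueEstimand | None = None
    mi_imputations: int = 10
    oracle_n_mc: int = 400_000

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise MsmissError("reps: must be >= 1")
        if not self.methods:
            raise MsmissError("methods: must be non-empty")
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise MsmissError(f"unknown methods {unknown}; choose from {sorted(METHODS)}")


@dataclass
class SimulationSummary:
    """Per method x coefficient performance metrics plus raw replicate draws."""

    scenario: str
    truth: np.ndarray  # (K+1,) including intercept
    table: pd.DataFrame  # tidy: method, coefficient, metric, value
    abs_bias: pd.DataFrame  # one column per (method, coefficient), R rows
    failures: dict[str, int]
    reps: int
    estimates: dict[str, np.ndarray] | None = None  # per method: (R_ok, K+1) draws


def performance_metrics(
    estimates: np.ndarray,
    ci_lower: np.ndarray,
    ci_upper: np.ndarray,
    model_se: np.ndarray,
    truth: np.ndarray,
    method: str,
    coef_names: list[str],
) -> pd.DataFrame:
    """Bias, Monte Carlo SE, empirical SD, mean model SE, coverage.

    ``mc_se`` is the Monte Carlo standard error of the mean bias,
    empirical SD / sqrt(R).
    """
    R = estimates.shape[0]
    if R < 2:
        raise MsmissError("performance metrics need at least 2 successful replicates")
    bias = estimates.mean(axis=0) - truth
    sd = estimates.std(axis=0, ddof=1)
    cover = ((ci_lower <= truth) & (truth <= ci_upper)).mean(axis=0)
    mean_abs = np.abs(estimates - truth).mean(axis=0)
    rows = []
    values = {
        "bias": bias,
        "mc_se": sd / np.sqrt(R),
        "empirical_sd": sd,
        "mean_model_se": model_se.mean(axis=0),
        "coverage": cover,
        "mean_abs_bias": mean_abs,
    }
    for metric, vec in values.items():
        for j, cname in enumerate(coef_names):
            rows.append(
                {"method": method, "coefficient": cname, "metric": metric, "value": float(vec[j])}
            )
    return pd.DataFrame(rows)


def _coef_names(K: int) -> list[str]:
    return ["beta_int"] + [f"beta_{k}" for k in range(K)]


def run_scenario(spec: ScenarioSpec) -> SimulationSummary:
    """Run all replicates of a scenario and summarise against the truth."""
    truth = spec.truth
    if truth is None:
        truth = true_msm_coefficients(
            spec.dgm, "gformula_mc", n_mc=spec.oracle_n_mc, seed=spec.seed
        )
    truth_vec = truth.as_array()
    K = spec.dgm.n_times
    names = _coef_names(K)
    collected: dict[str, list] = {m: [] for m in spec.methods}
    failures = {m: 0 for m in spec.methods}
    for r in range(spec.reps):
        rep_seed = int(
            np.random.SeedSequence([spec.seed, 6, r]).generate_state(1, np.uint32)[0] % (2**31)
        )
        panel = simulate_full_data(spec.dgm, spec.n, rep_seed)
        if spec.missingness is not None:
            panel = apply_missingness(panel, spec.missingness, rep_seed)
        for m in spec.methods:
            try:
                est = METHODS[m](panel, m=spec.mi_imputations, seed=rep_seed)
            except MsmissError:
                failures[m] += 1
                continue
            ci = est.conf_int
            collected[m].append(
                (est.params, ci[:, 0], ci[:, 1], est.se)
            )
    tables = []
    abs_bias_cols = {}
    estimates = {}
    for m in spec.methods:
        if failures[m] > 0.10 * spec.reps:
            raise ScenarioInstabilityError(
                f"scenario {spec.name}: method {m} failed in {failures[m]}/{spec.reps} replicates"
            )
        params = np.vstack([c[0] for c in collected[m]])
        estimates[m] = params
        lo = np.vstack([c[1] for c in collected[m]])
        hi = np.vstack([c[2] for c in collected[m]])
        se = np.vstack([c[3] for c in collected[m]])
        tables.append(performance_metrics(params, lo, hi, se, truth_vec, m, names))
        for j, cname in enumerate(names):
            abs_bias_cols[f"{m}:{cname}"] = np.abs(params[:, j] - truth_vec[j])
    abs_bias = pd.DataFrame(
        {k: pd.Series(v) for k, v in abs_bias_cols.items()}
    )
    return SimulationSummary(
        scenario=spec.name,
        truth=truth_vec,
        table=pd.concat(tables, ignore_index=True),
        abs_bias=abs_bias,
        failures=failures,
        reps=spec.reps,
        estimates=estimates,
    )


def get_metric(summary: SimulationSummary, method: str, coefficient: str, metric: str) -> float:
    t = summary.table
    row = t[
        (t["method"] == method) & (t["coefficient"] == coefficient) & (t["metric"] == metric)
    ]
    if len(row) != 1:
        raise KeyError((method, coefficient, metric))
    return float(row["value"].iloc[0])


def export_results(summary: SimulationSummary, outdir) -> dict:
    """Write tidy metric and box-plot-ready absolute-bias CSVs."""
    import os

    os.makedirs(outdir, exist_ok=True)
    table = summary.table.copy()
    table.insert(0, "scenario", summary.scenario)
    summary_path = os.path.join(outdir, "summary.csv")
    table.to_csv(summary_path, index=False)
    abs_path = os.path.join(outdir, "absolute_bias.csv")
    summary.abs_bias.to_csv(abs_path, index=False)
    return {"summary": summary_path, "absolute_bias": abs_path}


def import_results(outdir) -> tuple[pd.DataFrame, pd.DataFrame]:
    import os

    table = pd.read_csv(os.path.join(outdir, "summary.csv"))
    abs_bias = pd.read_csv(os.path.join(outdir, "absolute_bias.csv"))
    return table, abs_bias
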