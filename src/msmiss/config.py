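"""Configuration of the data-generating and missingness mechanisms.

The structural model has, per subject: an independent baseline risk factor
``V`` (standard normal, affects the outcome only), two time-varying
confounders ``L1`` (binary by default) and ``L2`` (continuous), a binary
treatment ``A_k`` at each of ``n_times`` time points, and a continuous
end-of-study outcome ``Y``.  Generation order is
``V -> L_0 -> A_0 -> L_1 -> A_1 -> ... -> Y`` so that earlier treatment can
feed back into later confounders while each treatment responds to the current
confounder values.

Missingness mechanisms mask confounder cells only (never treatment or
outcome).  The internal flag convention is ``M = 1`` means *missing*.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, SchemaError

SCHEMA_VERSION = 1

#: The six missingness mechanisms.
MECHANISMS = ("MCAR", "MAR_AL", "MAR_ALY", "MAR_ALV", "CONSTANT", "DIFFERENTIAL")

#: Predictors (beyond the intercept) each mechanism's logistic model may use.
MECHANISM_PREDICTORS = {
    "MCAR": frozenset(),
    "MAR_AL": frozenset({"prev_treat", "prev_l1", "prev_l2"}),
    "MAR_ALY": frozenset({"prev_treat", "prev_l1", "prev_l2", "outcome"}),
    "MAR_ALV": frozenset({"prev_treat", "prev_l1", "prev_l2", "risk_factor"}),
    "CONSTANT": frozenset(),
    "DIFFERENTIAL": frozenset({"prev_treat", "prev_l1", "prev_l2"}),
}


def _as_tuple(value, n: int, name: str) -> tuple[float, ...]:
    """Broadcast a scalar to length ``n`` or validate a length-``n`` sequence."""
    if np.isscalar(value):
        return (float(value),) * n
    value = tuple(float(v) for v in value)
    if len(value) != n:
        raise ConfigurationError(f"{name}: expected length {n}, got {len(value)}")
    return value


def _check_finite(value, name: str) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ConfigurationError(f"{name}: non-finite coefficient")


@dataclass
class DGMConfig:
    """Full coefficient set for the structural (data-generating) model.

    ``carryover`` is the "sticky" probability pi with which a confounder at
    time k exactly repeats its value at k-1 instead of being redrawn from its
    dynamic model; it makes exact repeats possible for the continuous
    confounder, which the CONSTANT missingness mechanism requires.

    Setting ``l1_continuous=True`` switches L1 to a linear-Gaussian chain
    (the all-continuous variant for which a closed-form truth oracle exists).
    """

    n_times: int = 3
    # baseline risk factor V
    v_mean: float = 0.0
    v_sd: float = 1.0
    # confounder initialisation
    l1_baseline_p: float = 0.5
    l1_baseline_mean: float = 0.0  # used only when l1_continuous
    l1_baseline_sd: float = 1.0  # used only when l1_continuous
    l2_baseline_mean: float = 0.0
    l2_baseline_sd: float = 1.0
    # L1 dynamics: fresh logistic draw (binary) or linear-Gaussian (continuous)
    l1_intercept: float = -0.5
    l1_auto: float = 1.0
    l1_treat: float = 0.0
    l1_sd: float = 1.0  # used only when l1_continuous
    l1_continuous: bool = False
    # L2 dynamics: linear in previous L2 and previous treatment
    l2_intercept: float = 0.0
    l2_auto: float = 0.3
    l2_treat: float = 0.5
    l2_sd: float = 1.0
    # sticky carry-over probability (applies to both confounders)
    carryover: float = 0.5
    # treatment model: logistic in current L1, L2 and previous treatment
    treat_intercepts: Sequence[float] | float = (-0.35, -0.6, -0.7)
    treat_l1: float = 0.7
    treat_l2: float = 0.7
    treat_prev: float = 0.5
    # outcome model: linear in all treatments, all confounders, and V
    out_intercept: float = 1.0
    out_treat: Sequence[float] | float = 0.5
    out_l1: Sequence[float] | float = 0.5
    out_l2: Sequence[float] | float = 0.5
    out_v: float = 0.5
    out_sd: float = 1.0

    def __post_init__(self) -> None:
        if not isinstance(self.n_times, (int, np.integer)) or self.n_times < 2:
            raise ConfigurationError("n_times: must be an integer >= 2")
        self.n_times = int(self.n_times)
        for name in ("l1_baseline_p", "carryover"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name}: probability must lie in [0, 1]")
        for name in ("v_sd", "l1_baseline_sd", "l2_baseline_sd", "l1_sd", "l2_sd", "out_sd"):
            sd = getattr(self, name)
            if not (sd > 0 and math.isfinite(sd)):
                raise ConfigurationError(f"{name}: SD must be positive and finite")
        self.treat_intercepts = _as_tuple(self.treat_intercepts, self.n_times, "treat_intercepts")
        self.out_treat = _as_tuple(self.out_treat, self.n_times, "out_treat")
        self.out_l1 = _as_tuple(self.out_l1, self.n_times, "out_l1")
        self.out_l2 = _as_tuple(self.out_l2, self.n_times, "out_l2")
        for f in dataclasses.fields(self):
            if f.name == "l1_continuous":
                continue
            _check_finite(getattr(self, f.name), f.name)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("treat_intercepts", "out_treat", "out_l1", "out_l2"):
            d[key] = list(d[key])
        d["schema_version"] = SCHEMA_VERSION
        d["kind"] = "dgm"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DGMConfig":
        d = dict(d)
        kind = d.pop("kind", "dgm")
        version = d.pop("schema_version", SCHEMA_VERSION)
        if kind != "dgm":
            raise SchemaError(f"expected a dgm config, got kind={kind!r}")
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema_version {version}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown dgm config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "DGMConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class MissingnessConfig:
    """One missingness mechanism with its logistic coefficients.

    The cell-level missingness model is
    ``logit P(M = 1) = intercept + slopes . predictors`` where the allowed
    predictors depend on the mechanism (see :data:`MECHANISM_PREDICTORS`).
    For CONSTANT, ``expit(intercept)`` is the masking probability *given* the
    value exactly repeated the previous measurement (probability 0 otherwise).
    Slopes on predictors a mechanism does not use must be zero.
    """

    mechanism: str = "MAR_AL"
    intercept: float = 0.0
    slope_prev_treat: float = 0.0
    slope_prev_l1: float = 0.0
    slope_prev_l2: float = 0.0
    slope_outcome: float = 0.0
    slope_risk_factor: float = 0.0
    targets: tuple[str, ...] = ("L1", "L2")
    target_proportion: float | None = None

    _SLOPE_FIELDS = {
        "prev_treat": "slope_prev_treat",
        "prev_l1": "slope_prev_l1",
        "prev_l2": "slope_prev_l2",
        "outcome": "slope_outcome",
        "risk_factor": "slope_risk_factor",
    }

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(
                f"mechanism: {self.mechanism!r} not one of {MECHANISMS}"
            )
        self.targets = tuple(self.targets)
        if not self.targets or any(t not in ("L1", "L2") for t in self.targets):
            raise ConfigurationError("targets: must be a non-empty subset of ('L1','L2')")
        allowed = MECHANISM_PREDICTORS[self.mechanism]
        for predictor, fname in self._SLOPE_FIELDS.items():
            value = getattr(self, fname)
            _check_finite(value, fname)
            if predictor not in allowed and value != 0.0:
                raise ConfigurationError(
                    f"{fname}: mechanism {self.mechanism} does not admit this predictor"
                )
        _check_finite(self.intercept, "intercept")
        if self.target_proportion is not None and not (0.0 < self.target_proportion < 1.0):
            raise ConfigurationError("target_proportion: must lie in (0, 1)")

    def slopes(self) -> dict[str, float]:
        """Active predictor slopes for this mechanism."""
        return {
            p: getattr(self, f)
            for p, f in self._SLOPE_FIELDS.items()
            if p in MECHANISM_PREDICTORS[self.mechanism]
        }

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["targets"] = list(d["targets"])
        d["schema_version"] = SCHEMA_VERSION
        d["kind"] = "missingness"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MissingnessConfig":
        d = dict(d)
        kind = d.pop("kind", "missingness")
        version = d.pop("schema_version", SCHEMA_VERSION)
        if kind != "missingness":
            raise SchemaError(f"expected a missingness config, got kind={kind!r}")
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema_version {version}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown missingness config fields: {sorted(unknown)}")
        if "targets" in d:
            d["targets"] = tuple(d["targets"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "MissingnessConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_dgm() -> DGMConfig:
    """The default moderately-to-strongly confounded data-generating model."""
    return DGMConfig()


def linear_gaussian_dgm(**overrides) -> DGMConfig:
    """All-continuous linear-Gaussian variant (closed-form truth available)."""
    base = dict(
        l1_continuous=True,
        l1_intercept=0.0,
        l1_auto=0.7,
        l1_treat=0.4,
        l1_sd=1.0,
        l1_baseline_p=0.5,  # unused for continuous L1
    )
    base.update(overrides)
    return DGMConfig(**base)
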