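"""Wide-format longitudinal panel with true values and missingness masks.

A :class:`PanelData` holds two aligned data frames:

``true``
    the complete record: ``id, V, L1_0, L2_0, A_0, ..., L1_{K-1}, L2_{K-1},
    A_{K-1}, Y`` — always fully populated for simulated data;
``mask``
    one boolean column ``M_{var}_{k}`` per confounder cell, ``True`` (1)
    meaning the cell is *missing*.

``observed()`` materialises the analyst's view: the true frame with masked
confounder cells replaced by NaN.  Treatments and the outcome are never
masked by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

CONFOUNDERS = ("L1", "L2")


def wide_columns(n_times: int) -> list[str]:
    cols = ["id", "V"]
    for k in range(n_times):
        cols += [f"L1_{k}", f"L2_{k}", f"A_{k}"]
    cols.append("Y")
    return cols


def mask_columns(n_times: int) -> list[str]:
    return [f"M_{var}_{k}" for k in range(n_times) for var in CONFOUNDERS]


@dataclass
class PanelData:
    true: pd.DataFrame
    mask: pd.DataFrame
    n_times: int
    dgm: object | None = field(default=None, repr=False)  # generating DGMConfig, if known

    def __post_init__(self) -> None:
        expected = wide_columns(self.n_times)
        missing_cols = [c for c in expected if c not in self.true.columns]
        if missing_cols:
            raise SchemaError(f"panel is missing columns {missing_cols}")
        self.true = self.true.loc[:, expected].reset_index(drop=True)
        mcols = mask_columns(self.n_times)
        missing_cols = [c for c in mcols if c not in self.mask.columns]
        if missing_cols:
            raise SchemaError(f"mask frame is missing columns {missing_cols}")
        self.mask = self.mask.loc[:, mcols].reset_index(drop=True).astype(bool)
        if len(self.mask) != len(self.true):
            raise SchemaError("mask and true frames have different lengths")
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        ids = self.true["id"]
        if ids.duplicated().any():
            raise SchemaError("duplicate subject ids")
        for k in range(self.n_times):
            a = self.true[f"A_{k}"]
            if not a.isin([0, 1]).all():
                raise SchemaError(f"A_{k}: treatment values must be 0/1")
        if not np.isfinite(self.true["Y"].to_numpy(dtype=float)).all():
            raise SchemaError("Y: outcome must be finite")

    # -- views -------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.true)

    @property
    def ids(self) -> np.ndarray:
        return self.true["id"].to_numpy()

    def has_missing(self) -> bool:
        return bool(self.mask.to_numpy().any())

    def mask_array(self) -> np.ndarray:
        """Boolean array of shape (n, n_times, 2) ordered (k, [L1, L2])."""
        out = np.empty((self.n, self.n_times, len(CONFOUNDERS)), dtype=bool)
        for k in range(self.n_times):
            for j, var in enumerate(CONFOUNDERS):
                out[:, k, j] = self.mask[f"M_{var}_{k}"].to_numpy()
        return out

    def observed(self) -> pd.DataFrame:
        """The analyst's view: masked confounder cells set to NaN."""
        obs = self.true.copy()
        for k in range(self.n_times):
            for var in CONFOUNDERS:
                flag = self.mask[f"M_{var}_{k}"].to_numpy()
                col = obs[f"{var}_{k}"].to_numpy(dtype=float).copy()
                col[flag] = np.nan
                obs[f"{var}_{k}"] = col
        return obs

    def copy(self) -> "PanelData":
        return PanelData(self.true.copy(), self.mask.copy(), self.n_times, self.dgm)

    def subset(self, keep: np.ndarray) -> "PanelData":
        """Row subset by boolean mask or integer positions."""
        return PanelData(
            self.true.iloc[keep].reset_index(drop=True),
            self.mask.iloc[keep].reset_index(drop=True),
            self.n_times,
            self.dgm,
        )

    @classmethod
    def from_observed(cls, observed: pd.DataFrame, n_times: int, dgm=None) -> "PanelData":
        """Build a panel from an analyst's frame where NaN encodes missing.

        The "true" values of masked cells are unknown; they are stored as NaN
        and flagged, so only mask-aware consumers may touch them.
        """
        mask = pd.DataFrame(index=observed.index)
        for k in range(n_times):
            for var in CONFOUNDERS:
                mask[f"M_{var}_{k}"] = observed[f"{var}_{k}"].isna()
        return cls(observed.copy(), mask, n_times, dgm)

    def equals(self, other: "PanelData") -> bool:
        return (
            self.n_times == other.n_times
            and self.true.equals(other.true)
            and self.mask.equals(other.mask)
        )
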