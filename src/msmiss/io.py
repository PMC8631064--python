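"""Readers and writers for the package's CSV dialects and run manifests.

Wide dialect: one row per subject with columns
``id,V,L1_0,L2_0,A_0,...,L1_{K-1},L2_{K-1},A_{K-1},Y``; masked confounder
cells are written as empty strings (UTF-8, comma separator, ``.`` decimal).
Long dialect: one row per (id, k) with columns ``id,k,V,L1,L2,A,Y`` (V and Y
repeated on every row of a subject).
"""

from __future__ import annotations

import hashlib
import json
import os
import time

import pandas as pd

from .errors import SchemaError
from .panel import PanelData, wide_columns

MANIFEST_SCHEMA_VERSION = 1


def _n_times_from_columns(columns) -> int:
    k = 0
    while f"A_{k}" in columns:
        k += 1
    if k == 0:
        raise SchemaError("no treatment columns A_0, A_1, ... found")
    return k


def write_panel(panel: PanelData, path, dialect: str = "wide", write_true: bool = False) -> None:
    """Write the analyst's view; optionally a ``_true`` companion for audits."""
    obs = panel.observed()
    if dialect == "wide":
        obs.to_csv(path, index=False)
    elif dialect == "long":
        _to_long(obs, panel.n_times).to_csv(path, index=False)
    else:
        raise SchemaError(f"unknown dialect {dialect!r}")
    if write_true:
        root, ext = os.path.splitext(str(path))
        true_path = f"{root}_true{ext}"
        if dialect == "wide":
            panel.true.to_csv(true_path, index=False)
        else:
            _to_long(panel.true, panel.n_times).to_csv(true_path, index=False)


def _to_long(df: pd.DataFrame, K: int) -> pd.DataFrame:
    blocks = []
    for k in range(K):
        blocks.append(
            pd.DataFrame(
                {
                    "id": df["id"],
                    "k": k,
                    "V": df["V"],
                    "L1": df[f"L1_{k}"],
                    "L2": df[f"L2_{k}"],
                    "A": df[f"A_{k}"],
                    "Y": df["Y"],
                }
            )
        )
    return pd.concat(blocks, ignore_index=True).sort_values(["id", "k"], kind="stable").reset_index(drop=True)


def _from_long(df: pd.DataFrame) -> pd.DataFrame:
    required = {"id", "k", "V", "L1", "L2", "A", "Y"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"long dialect is missing columns {sorted(missing)}")
    K = int(df["k"].max()) + 1
    counts = df.groupby("id")["k"].nunique()
    if (counts != K).any():
        bad = counts[counts != K].index[0]
        raise SchemaError(f"subject {bad!r} does not have rows for all {K} time points")
    wide = df[df["k"] == 0][["id", "V", "Y"]].set_index("id")
    for k in range(K):
        sub = df[df["k"] == k].set_index("id")
        for var in ("L1", "L2", "A"):
            wide[f"{var}_{k}"] = sub[var]
    wide = wide.reset_index()
    return wide.loc[:, wide_columns(K)]


def read_panel(path, dialect: str = "wide") -> PanelData:
    """Read a panel; empty cells become missing flags; strict type checks."""
    df = pd.read_csv(path)
    if dialect == "long":
        df = _from_long(df)
    elif dialect != "wide":
        raise SchemaError(f"unknown dialect {dialect!r}")
    K = _n_times_from_columns(df.columns)
    expected = set(wide_columns(K))
    unknown = set(df.columns) - expected
    if unknown:
        raise SchemaError(f"unknown columns {sorted(unknown)}")
    missing = expected - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise SchemaError(f"duplicate subject id {dup!r}")
    for k in range(K):
        a = df[f"A_{k}"]
        if a.isna().any():
            row = int(a[a.isna()].index[0])
            raise SchemaError(f"missing treatment value in column A_{k}, row {row}")
        if not a.isin([0, 1]).all():
            row = int(a[~a.isin([0, 1])].index[0])
            raise SchemaError(f"non-binary treatment value in column A_{k}, row {row}")
    if df["Y"].isna().any():
        row = int(df["Y"][df["Y"].isna()].index[0])
        raise SchemaError(f"missing outcome value in column Y, row {row}")
    return PanelData.from_observed(df.loc[:, wide_columns(K)], K)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def config_hash(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def write_manifest(outdir, seed: int, configs: dict, counts: dict | None = None) -> str:
    """Write the results-directory manifest (configs + seed reproduce the run)."""
    from . import __version__

    os.makedirs(outdir, exist_ok=True)
    manifest = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "package": "msmiss",
        "version": __version__,
        "seed": int(seed),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "configs": configs,
        "config_hashes": {k: config_hash(v) for k, v in configs.items() if isinstance(v, dict)},
        "row_counts": counts or {},
    }
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
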