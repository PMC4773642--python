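"""Seedling architecture traits and extreme-phenotype pool construction.

Each seedling of the segregating progeny carries a trunk diameter (measured at
1 m height, in mm) and the mean internode length of five representative
one-year-old branches.  The per-seedling internode trait is the arithmetic mean
of the five branch means.  Pools are built by taking the seedlings with the
lowest and highest trait values; canopy-shape pool membership (ChiCa) is an
input label, not a computation.

Rounding to two decimals (half-up) is presentation only: full precision is
retained and propagated in every computation.
"""

from __future__ import annotations

import warnings
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "mean_internode_length",
    "round_half_up",
    "load_phenotypes",
    "write_phenotypes",
    "reference_phenotypes",
    "select_extreme_pools",
    "summarize_pools",
]

BRANCH_COLUMNS = [f"branch{i}_mm" for i in range(1, 6)]
REQUIRED_COLUMNS = ["seedling_id", "mother", "pollen_donor", "diameter_mm", *BRANCH_COLUMNS]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding, as used for the reported trait values."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def mean_internode_length(branch_means: Sequence[float]) -> float:
    """Arithmetic mean of exactly five per-branch mean internode lengths (mm).

    Returns the unrounded value; use :func:`round_half_up` for the 2-decimal
    reported form.
    """
    vals = [float(v) for v in branch_means]
    if len(vals) != 5:
        raise ValueError(f"expected exactly 5 branch means, got {len(vals)}")
    if any(v <= 0 for v in vals):
        raise ValueError("branch means must be positive")
    return float(np.mean(vals))


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    meas = df[["diameter_mm", *BRANCH_COLUMNS]].to_numpy(dtype=float)
    if not np.all(np.isfinite(meas)):
        raise ValueError("phenotype table contains missing measurements")
    if np.any(meas <= 0):
        raise ValueError("all phenotype measurements must be positive")
    # bare seedling ids recur across pools (and, in the published table, even
    # within one): rows are identified positionally, repeats only warn
    key = df[["mother", "pollen_donor", "seedling_id"]].astype(str)
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        warnings.warn(f"repeated seedling id {dup}; rows kept, identified by position",
                      stacklevel=2)
    df = df.copy()
    df["mean_internode_mm"] = df[BRANCH_COLUMNS].mean(axis=1)
    return df


def load_phenotypes(path: str | Path) -> pd.DataFrame:
    """Load a per-seedling phenotype TSV and derive the internode trait.

    The returned frame carries an unrounded ``mean_internode_mm`` column
    recomputed from the five branch means (any same-named input column is
    replaced by the recomputation).
    """
    df = pd.read_csv(path, sep="\t", dtype={"seedling_id": str, "mother": str, "pollen_donor": str})
    return _validate(df)


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    cols = list(REQUIRED_COLUMNS)
    if "pool" in df.columns:
        cols.append("pool")
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.2f")


def reference_phenotypes() -> pd.DataFrame:
    """The published 27-seedling phenotype table for the five study pools.

    Includes the reported 2-decimal ``mean_internode_mm`` column as
    ``reported_mean_internode_mm`` alongside the recomputed full-precision one.
    """
    ref = resources.files("olivearch.data") / "pool_seedling_phenotypes.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"seedling_id": str, "mother": str, "pollen_donor": str})
    df = df.rename(columns={"mean_internode_mm": "reported_mean_internode_mm"})
    return _validate(df)


def select_extreme_pools(
    table: pd.DataFrame,
    trait: str,
    k_low: int,
    k_high: int,
) -> tuple[list[int], list[int]]:
    """Row indices of the ``k_low`` lowest- and ``k_high`` highest-trait seedlings.

    ``trait`` is 'mean_internode' or 'diameter'.  Ties are broken by input row
    order (stable sort), so selection is deterministic.  The two pools are
    disjoint by construction; requesting more seedlings than exist is an error.
    """
    col = {"mean_internode": "mean_internode_mm", "diameter": "diameter_mm"}.get(trait)
    if col is None:
        raise ValueError(f"unknown trait {trait!r}; expected 'mean_internode' or 'diameter'")
    if k_low < 0 or k_high < 0:
        raise ValueError("pool sizes must be non-negative")
    n = len(table)
    if k_low + k_high > n:
        raise ValueError(f"requested {k_low}+{k_high} seedlings from a table of {n}")
    values = table[col].to_numpy(dtype=float)
    order = np.argsort(values, kind="stable")
    low = [int(i) for i in order[:k_low]]
    high = [int(i) for i in order[n - k_high:]]
    return low, sorted(high)


def assign_pools(
    table: pd.DataFrame,
    assignments: dict[str, Sequence[int]],
) -> pd.DataFrame:
    """Label rows with pool names from index lists; overlapping pools error."""
    df = table.copy()
    if "pool" not in df.columns:
        df["pool"] = ""
    seen: dict[int, str] = {}
    for pool, idx in assignments.items():
        for i in idx:
            if i in seen:
                raise ValueError(f"row {i} assigned to both {seen[i]!r} and {pool!r}")
            seen[int(i)] = pool
            df.iloc[int(i), df.columns.get_loc("pool")] = pool
    return df


def summarize_pools(table: pd.DataFrame) -> pd.DataFrame:
    """Per-pool mean +/- sd for diameter and internode traits.

    Single-member pools report sd 0 with ``degenerate=True``; empty pool labels
    are omitted.  Rows are sorted by pool name for determinism.
    """
    if "pool" not in table.columns:
        raise ValueError("phenotype table has no 'pool' column")
    df = table[table["pool"].astype(str).str.len() > 0]
    rows = []
    for pool, sub in df.groupby("pool", sort=True):
        n = len(sub)
        rows.append(
            {
                "pool": pool,
                "n": n,
                "diameter_mean_mm": float(sub["diameter_mm"].mean()),
                "diameter_sd_mm": float(sub["diameter_mm"].std(ddof=1)) if n > 1 else 0.0,
                "internode_mean_mm": float(sub["mean_internode_mm"].mean()),
                "internode_sd_mm": float(sub["mean_internode_mm"].std(ddof=1)) if n > 1 else 0.0,
                "degenerate": n == 1,
            }
        )
    return pd.DataFrame(rows, columns=[
        "pool", "n", "diameter_mean_mm", "diameter_sd_mm",
        "internode_mean_mm", "internode_sd_mm", "degenerate",
    ])
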