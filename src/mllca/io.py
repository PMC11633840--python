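"""Delimited-text ingestion and export of unit-level data tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import DataValidationError, ItemResponseData


def read_table(
    path,
    group_col: str = "group",
    item_cols=None,
    item_prefix: str = "item",
    z_low_cols=(),
    z_high_cols=(),
    sep: str = ",",
) -> ItemResponseData:
    """Read a unit-level table into an ItemResponseData.

    Item columns are either listed explicitly or auto-detected by prefix.
    Higher-level covariates must be constant within group; item values
    must be 0/1 with no missing cells.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if group_col not in df.columns:
        raise DataValidationError(f"missing required column {group_col!r}")
    if item_cols is None:
        item_cols = [c for c in df.columns if c.startswith(item_prefix)]
    missing = [c for c in list(item_cols) + list(z_low_cols) + list(z_high_cols)
               if c not in df.columns]
    if missing:
        raise DataValidationError(f"unknown columns: {missing}")
    if not item_cols:
        raise DataValidationError("no item columns found")
    items = df[list(item_cols)]
    if items.isna().any().any():
        rows = np.where(items.isna().any(axis=1))[0]
        raise DataValidationError(f"missing item values in rows {rows[:10].tolist()}")
    return ItemResponseData(
        items=items.to_numpy(),
        group_id=df[group_col].to_numpy(),
        z_low=df[list(z_low_cols)].to_numpy() if z_low_cols else None,
        z_high=df[list(z_high_cols)].to_numpy() if z_high_cols else None,
    )


def write_table(
    data: ItemResponseData,
    path,
    item_prefix: str = "item",
    sep: str = ",",
) -> pd.DataFrame:
    """Write the container back to a delimited table (1-based group labels)."""
    df = pd.DataFrame(
        data.items, columns=[f"{item_prefix}{h+1}" for h in range(data.n_items)]
    )
    df.insert(0, "group", data.group_labels[data.group_index])
    for k in range(data.p_low):
        df[f"z_low{k+1}"] = data.z_low[:, k]
    zh = data.z_high_per_unit()
    for k in range(data.p_high):
        df[f"z_high{k+1}"] = zh[:, k]
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return df


def export_assignments(path, data: ItemResponseData, post, w, sep: str = ","):
    """Audit table: unit, group, assigned class (1-based), posterior row."""
    T = post.post.shape[1]
    df = pd.DataFrame({
        "unit": np.arange(1, data.n_units + 1),
        "group": data.group_labels[data.group_index],
        "assigned": w.w.argmax(axis=1) + 1,
    })
    for t in range(T):
        df[f"post{t+1}"] = post.post[:, t]
    df.to_csv(path, sep=sep, index=False)
    return df
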