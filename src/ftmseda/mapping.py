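"""Formula-to-pathway mapping via local lookup tables.

Molecular formulas are matched by exact string against a user-supplied
mapping table with rows (formula, database, entry type, entry id, entry
name), where database is KEGG or MetaCyc and entry type is compound,
reaction, module or pathway.  Matching is by formula string only — isomers
share a formula, so a formula can legitimately map to many entries; a
per-(database, entry-type) cap (default 5) truncates long match lists,
taking entries in ascending entry-id order for determinism.

Results come in two layouts: long (one row per matched entry) and wide (one
row per peak, entries semicolon-joined per database/entry-type column).
The two layouts carry identical information.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .dataset import FTMSDataset, ValidationError

TABLE_COLUMNS = ("formula", "database", "entry_type", "entry_id", "entry_name")
DATABASES = ("KEGG", "MetaCyc")
ENTRY_TYPES = ("compound", "reaction", "module", "pathway")


def read_mapping_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a mapping CSV (columns as in TABLE_COLUMNS)."""
    df = pd.read_csv(path, dtype=str)
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"mapping table missing columns: {sorted(missing)}")
    key = ["formula", "database", "entry_type", "entry_id"]
    if df.duplicated(subset=key).any():
        raise ValidationError("mapping table has duplicate (formula, database, "
                              "entry_type, entry_id) rows")
    return df


def map_formulas(ds: FTMSDataset, table: pd.DataFrame,
                 max_records: int = 5, layout: str = "long") -> pd.DataFrame:
    """Map the dataset's peak formulas against a mapping table.

    Long layout: one row per (peak, matched entry) with columns mass_id,
    formula, database, entry_type, entry_id, entry_name.  Wide layout: one
    row per formula-assigned peak, one ``<db>:<type>`` id column and
    ``<db>:<type>:name`` column per combination present in the table,
    semicolon-joined.  At most ``max_records`` entries per (database,
    entry_type) per formula, in ascending entry-id order.
    """
    if max_records < 1:
        raise ValidationError("max_records must be >= 1")
    if layout not in ("long", "wide"):
        raise ValidationError("layout must be 'long' or 'wide'")
    if table.empty:
        warnings.warn("mapping table is empty; no formulas mapped")
    formulas = ds.mol_table.get("Formula")
    if formulas is None:
        raise ValidationError("dataset has no Formula column to map")
    peaks = pd.DataFrame({"mass_id": ds.mol_table.index,
                          "formula": formulas.to_numpy()}).dropna(subset=["formula"])
    merged = peaks.merge(table, on="formula", how="inner")
    merged = merged.sort_values(["mass_id", "database", "entry_type", "entry_id"],
                                kind="mergesort")
    merged["_rank"] = merged.groupby(["mass_id", "database", "entry_type"]).cumcount()
    long = merged[merged["_rank"] < max_records].drop(columns="_rank")
    long = long.reset_index(drop=True)
    if layout == "long":
        return long
    # wide: semicolon-join per (database, entry_type)
    wide = peaks.set_index("mass_id")[["formula"]].copy()
    for (db, et), sub in long.groupby(["database", "entry_type"]):
        ids = sub.groupby("mass_id")["entry_id"].agg(";".join)
        names = sub.groupby("mass_id")["entry_name"].agg(";".join)
        wide[f"{db}:{et}"] = ids.reindex(wide.index).fillna("")
        wide[f"{db}:{et}:name"] = names.reindex(wide.index).fillna("")
    return wide.reset_index()
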