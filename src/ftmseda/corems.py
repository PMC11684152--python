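"""Ingest of per-sample molecular-identification output (CoreMS-style).

Upstream formula-assignment tools emit one long-format CSV per sample, where
each row is a candidate molecular formula for a calibrated m/z: the peak
height, a confidence score in [0, 1], the assignment mass error in ppm, and
an optional isotope annotation.  A given (sample, m/z) can carry several
candidate rows.  The ingest path is:

1. :func:`read_corems` — concatenate the per-sample files, auto-detecting
   column names against a synonym list (user overrides win);
2. :func:`confidence_profile` / :func:`apply_confidence_filter` — choose and
   apply a confidence-score cut-off, trading retained peaks against mass
   error;
3. :func:`resolve_formulas` — keep exactly one candidate per (sample, m/z);
4. :func:`pivot_to_dataset` — pivot to the peak-table x molecular-table data
   model, merging peaks across samples by resolved formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import FTMSDataset, ProcessingStep, ValidationError, _now
from .formulas import ELEMENTS, parse_formula

#: Canonical internal column names.
CANONICAL = ("mz", "intensity", "formula", "confidence", "mass_error", "isotope")

#: Synonyms used for column auto-detection (case/sep-insensitive matching).
SYNONYMS: dict[str, tuple[str, ...]] = {
    "mz": ("calibrated m/z", "m/z", "mz", "calibrated mz", "calculated m/z"),
    "intensity": ("peak height", "intensity", "abundance", "height", "s/n"),
    "formula": ("molecular formula", "formula", "mol formula", "molecularformula"),
    "confidence": ("confidence score", "confidence", "score"),
    "mass_error": ("m/z error (ppm)", "mass error (ppm)", "m/z error", "mass error",
                   "error ppm", "ppm error"),
    "isotope": ("isotopologue", "is isotopologue", "isotope", "isotope type"),
}

#: Columns that must resolve for ingest to proceed.
REQUIRED = ("mz", "intensity", "formula", "confidence")


def _norm(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


@dataclass
class CoreMSRecords:
    """Long-format candidate-assignment records across samples."""

    data: pd.DataFrame  # columns: sample + CANONICAL
    resolved: bool = False
    provenance: list[ProcessingStep] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.data["sample"]))

    def _log(self, name: str, params: dict, before: int,
             timestamp: str | None = None) -> None:
        self.provenance.append(ProcessingStep(
            name=name, params=dict(params),
            n_peaks_before=before, n_peaks_after=self.n_records,
            n_samples_before=len(self.sample_ids), n_samples_after=len(self.sample_ids),
            timestamp=timestamp if timestamp is not None else _now(),
        ))


def read_corems(files: list[str | Path],
                column_map: dict[str, str] | None = None,
                sample_ids: list[str] | None = None) -> CoreMSRecords:
    """Read per-sample candidate-assignment CSV files into one record table.

    Sample identifiers default to the file names without extension.  Column
    names are auto-detected against the synonym list; entries in
    ``column_map`` (canonical name -> actual column) override detection.
    """
    if not files:
        raise ValidationError("at least one input file is required")
    files = [Path(f) for f in files]
    if sample_ids is not None and len(sample_ids) != len(files):
        raise ValidationError("sample_ids must match the number of files")
    frames = []
    for i, f in enumerate(files):
        df = pd.read_csv(f)
        colmap = _resolve_columns(df.columns, column_map or {})
        sub = pd.DataFrame(index=df.index)
        for canon in CANONICAL:
            sub[canon] = df[colmap[canon]] if canon in colmap else np.nan
        sub.insert(0, "sample", sample_ids[i] if sample_ids else f.stem)
        frames.append(sub)
    data = pd.concat(frames, ignore_index=True)
    data["mz"] = pd.to_numeric(data["mz"], errors="coerce")
    data["confidence"] = pd.to_numeric(data["confidence"], errors="coerce")
    if (data["mz"] <= 0).any() or data["mz"].isna().any():
        raise ValidationError("m/z values must be positive numbers")
    conf = data["confidence"]
    if conf.isna().any() or not np.isfinite(conf).all():
        raise ValidationError("confidence scores must be finite")
    if ((conf < 0) | (conf > 1)).any():
        raise ValidationError(
            "confidence scores outside [0, 1] found; this reader assumes the "
            "score is a probability-like value in [0, 1]"
        )
    recs = CoreMSRecords(data)
    recs._log("read_corems", {"files": [f.name for f in files]}, before=len(data))
    return recs


def _resolve_columns(columns, overrides: dict[str, str]) -> dict[str, str]:
    colmap: dict[str, str] = {}
    normed = {_norm(c): c for c in columns}
    for canon in CANONICAL:
        if canon in overrides:
            if overrides[canon] not in columns:
                raise ValidationError(
                    f"override column {overrides[canon]!r} for {canon!r} not in file"
                )
            colmap[canon] = overrides[canon]
            continue
        for syn in SYNONYMS[canon]:
            if _norm(syn) in normed:
                colmap[canon] = normed[_norm(syn)]
                break
    missing = [c for c in REQUIRED if c not in colmap]
    if missing:
        raise ValidationError(
            f"could not resolve required columns {missing}; "
            f"columns found: {list(columns)}; pass a column_map override"
        )
    return colmap


def confidence_profile(recs: CoreMSRecords,
                       thresholds: np.ndarray | list[float]) -> pd.DataFrame:
    """Retained-record counts and mass-error statistics over a threshold grid.

    For each threshold t, statistics are over records with score >= t; the
    retained count is monotone non-increasing in t.  Used to pick a cut-off
    that minimizes mass error while keeping as many peaks as possible.
    """
    thresholds = np.asarray(list(thresholds), dtype=float)
    if thresholds.size == 0:
        raise ValidationError("threshold grid is empty")
    if (thresholds < 0).any() or (thresholds > 1).any():
        raise ValidationError("thresholds must lie in [0, 1]")
    rows = []
    err = pd.to_numeric(recs.data["mass_error"], errors="coerce").abs()
    for t in thresholds:
        keep = recs.data["confidence"] >= t
        e = err[keep]
        rows.append({
            "threshold": t,
            "n_retained": int(keep.sum()),
            "mean_abs_mass_error": float(e.mean()) if keep.any() else np.nan,
            "max_abs_mass_error": float(e.max()) if keep.any() else np.nan,
        })
    return pd.DataFrame(rows)


def apply_confidence_filter(recs: CoreMSRecords, min_score: float,
                            timestamp: str | None = None) -> CoreMSRecords:
    """Drop candidate records with confidence score below ``min_score``."""
    if not 0 <= min_score <= 1:
        raise ValidationError("min_score must lie in [0, 1]")
    keep = recs.data["confidence"] >= min_score
    if not keep.any():
        raise ValidationError(
            f"confidence filter at {min_score} removes every record"
        )
    out = CoreMSRecords(recs.data[keep].reset_index(drop=True),
                        resolved=recs.resolved, provenance=list(recs.provenance))
    out._log("confidence_filter", {"min_score": min_score},
             before=recs.n_records, timestamp=timestamp)
    return out


def resolve_formulas(recs: CoreMSRecords, method: str = "max_confidence",
                     timestamp: str | None = None) -> CoreMSRecords:
    """Keep exactly one candidate formula per (sample, m/z).

    ``method`` picks the candidate with the highest confidence score
    (``max_confidence``) or the largest peak height (``max_peak_height``).
    Ties break deterministically: smallest absolute mass error first, then
    lexicographically smallest formula string.
    """
    if method == "max_confidence":
        crit = "confidence"
    elif method == "max_peak_height":
        crit = "intensity"
    else:
        raise ValidationError(f"unknown resolution method {method!r}")
    df = recs.data.copy()
    df["_abs_err"] = pd.to_numeric(df["mass_error"], errors="coerce").abs().fillna(np.inf)
    df["_crit"] = pd.to_numeric(df[crit], errors="coerce")
    # sort so the winner is first within each (sample, m/z) group
    df = df.sort_values(["sample", "mz", "_crit", "_abs_err", "formula"],
                        ascending=[True, True, False, True, True], kind="mergesort")
    best = df.drop_duplicates(subset=["sample", "mz"], keep="first")
    best = best.drop(columns=["_abs_err", "_crit"]).reset_index(drop=True)
    out = CoreMSRecords(best, resolved=True, provenance=list(recs.provenance))
    out._log("resolve_formulas", {"method": method},
             before=recs.n_records, timestamp=timestamp)
    return out


def pivot_to_dataset(recs: CoreMSRecords, missing_code: float = 0,
                     timestamp: str | None = None) -> FTMSDataset:
    """Pivot resolved records into the two-table data model.

    Peak identity across samples is the resolved formula string; a formula
    carrying an isotope annotation is a distinct peak from its monoisotopic
    form.  Peak-table cells hold peak heights; (sample, peak) pairs with no
    record are missing.  The molecular table carries the formula, parsed
    element counts, the isotope annotation, and the mean calibrated m/z as
    the peak mass.
    """
    if not recs.resolved:
        dup = recs.data.duplicated(subset=["sample", "mz"]).any()
        if dup:
            raise ValidationError("run resolve_formulas first: multi-candidate records remain")
    df = recs.data.copy()
    if df["formula"].isna().any():
        raise ValidationError("records without a candidate formula cannot be pivoted")
    iso = df["isotope"].fillna("").astype(str).replace({"0": "", "False": "", "nan": ""})
    df["peak_id"] = np.where(iso != "", df["formula"] + "|" + iso, df["formula"])
    # same-formula peaks within a sample (rare post-calibration) merge by summing
    peak_table = df.pivot_table(index="peak_id", columns="sample",
                                values="intensity", aggfunc="sum")
    peak_table.index.name = "Mass"
    peak_table.columns.name = None
    first = df.drop_duplicates("peak_id").set_index("peak_id")
    mol = pd.DataFrame(index=peak_table.index)
    mol["Formula"] = first["formula"]
    counts = {el: [] for el in ELEMENTS}
    for f in mol["Formula"]:
        parsed = parse_formula(f)
        for el in ELEMENTS:
            counts[el].append(float(parsed[el]))
    for el in ELEMENTS:
        mol[el] = counts[el]
    mol["Isotope"] = iso.groupby(df["peak_id"]).first().reindex(mol.index)
    mol["Mass"] = df.groupby("peak_id")["mz"].mean().reindex(mol.index)
    ds = FTMSDataset(peak_table, mol, data_scale="abundance",
                     missing_code=missing_code,
                     provenance=list(recs.provenance), missing_encoded=True)
    ds.log_step("pivot_to_dataset", {"n_records": recs.n_records},
                (ds.n_peaks, ds.n_samples), timestamp=timestamp)
    return ds
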