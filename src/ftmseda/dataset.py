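"""Core data model for formula-assigned FT-MS peak data.

The central container pairs two tables keyed on a shared mass identifier:

* the **peak table** — intensities with peaks (masses) as rows and samples as
  columns;
* the **molecular identification table** — one record per peak holding the
  molecular formula and/or the element counts C, H, N, O, S, P, an optional
  isotope annotation, and any calculated-property columns appended later.

Missing observations are encoded with a dedicated not-a-value sentinel (NaN),
never 0, so that presence/absence and intensity values cannot be conflated;
the raw code that denotes "not observed" in the input files (typically 0) is
kept as metadata and restored on export.  Every operation that changes the
data appends a :class:`ProcessingStep` to an append-only provenance log, which
later feeds the summary report.
"""

from __future__ import annotations

import copy
import datetime as _dt
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formulas import ELEMENTS, parse_formula

#: Recognized data scales for the peak table.
SCALES = ("abundance", "log2", "log10", "ln", "presence_absence")

#: Log transforms and their numpy implementations.
_LOG_FUNCS = {"log2": np.log2, "log10": np.log10, "ln": np.log}


class ValidationError(ValueError):
    """Raised when input tables violate the data-model invariants."""


@dataclass(frozen=True)
class ProcessingStep:
    """One entry of the provenance log."""

    name: str
    params: dict
    n_peaks_before: int
    n_peaks_after: int
    n_samples_before: int
    n_samples_after: int
    timestamp: str = ""

    def __post_init__(self):
        for v in (self.n_peaks_before, self.n_peaks_after,
                  self.n_samples_before, self.n_samples_after):
            if v < 0:
                raise ValidationError("provenance counts must be non-negative")


def _now() -> str:
    return _dt.datetime.now().isoformat(timespec="seconds")


@dataclass
class GroupDefinition:
    """Assignment of samples to experimental groups.

    A plain mapping ``sample_id -> group label``.  A sample belongs to at most
    one group per comparison; unassigned samples are simply absent from the
    mapping.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.mapping.items() if g == group]

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.samples_in(g)) for g in self.groups()}

    def validate_against(self, ds: "FTMSDataset") -> None:
        unknown = [s for s in self.mapping if s not in ds.peak_table.columns]
        if unknown:
            raise ValidationError(
                f"group mapping refers to samples absent from the data: {unknown}"
            )


class FTMSDataset:
    """Paired peak-intensity and molecular-identification tables.

    Parameters
    ----------
    peak_table:
        DataFrame of intensities, index = mass identifiers (strings),
        columns = sample identifiers.
    mol_table:
        DataFrame indexed identically, with element-count columns
        C,H,N,O,S,P (NaN where no formula is assigned) and, when available,
        a ``Formula`` string column and a ``Mass`` column in Da.
    data_scale:
        One of ``abundance, log2, log10, ln, presence_absence``.
    missing_code:
        The raw value that encodes "not observed" in the input (default 0).
    """

    def __init__(
        self,
        peak_table: pd.DataFrame,
        mol_table: pd.DataFrame,
        data_scale: str = "abundance",
        missing_code: float = 0,
        provenance: list[ProcessingStep] | None = None,
        missing_encoded: bool = False,
    ):
        if data_scale not in SCALES:
            raise ValidationError(f"unknown data scale {data_scale!r}; expected one of {SCALES}")
        self.peak_table = peak_table
        self.mol_table = mol_table
        self.data_scale = data_scale
        self.missing_code = missing_code
        self.provenance: list[ProcessingStep] = list(provenance or [])
        self.missing_encoded = missing_encoded
        self._validate()

    # ------------------------------------------------------------------ utils
    @property
    def n_peaks(self) -> int:
        return self.peak_table.shape[0]

    @property
    def n_samples(self) -> int:
        return self.peak_table.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.peak_table.columns)

    @property
    def mass_ids(self) -> list[str]:
        return list(self.peak_table.index)

    def has_formula(self) -> pd.Series:
        """Boolean per peak: a molecular formula (C and H counts) is recorded."""
        c = pd.to_numeric(self.mol_table.get("C"), errors="coerce")
        h = pd.to_numeric(self.mol_table.get("H"), errors="coerce")
        return (c.notna() & h.notna()).rename("has_formula")

    def masses(self) -> pd.Series:
        """Numeric peak mass in Da.

        Uses the ``Mass`` column when present, otherwise interprets the mass
        identifiers themselves as masses; identifiers that are not numeric
        yield NaN.
        """
        for col in ("Mass", "Mass_Da"):
            if col in self.mol_table.columns:
                return pd.to_numeric(self.mol_table[col], errors="coerce").rename("Mass")
        return pd.to_numeric(
            pd.Series(self.mol_table.index, index=self.mol_table.index), errors="coerce"
        ).rename("Mass")

    def observed_mask(self) -> pd.DataFrame:
        """Boolean mask of observed (non-missing) cells; requires encoded missing."""
        if not self.missing_encoded:
            raise ValidationError("call encode_missing first")
        return self.peak_table.notna()

    def log_step(self, name: str, params: dict, before: tuple[int, int],
                 timestamp: str | None = None) -> None:
        self.provenance.append(
            ProcessingStep(
                name=name,
                params=dict(params),
                n_peaks_before=before[0],
                n_peaks_after=self.n_peaks,
                n_samples_before=before[1],
                n_samples_after=self.n_samples,
                timestamp=timestamp if timestamp is not None else _now(),
            )
        )

    def copy(self) -> "FTMSDataset":
        new = FTMSDataset.__new__(FTMSDataset)
        new.peak_table = self.peak_table.copy()
        new.mol_table = self.mol_table.copy()
        new.data_scale = self.data_scale
        new.missing_code = self.missing_code
        new.provenance = list(self.provenance)
        new.missing_encoded = self.missing_encoded
        return new

    def _validate(self) -> None:
        if self.peak_table.index.has_duplicates:
            dups = self.peak_table.index[self.peak_table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate mass identifiers in data file: {dups}")
        if self.mol_table.index.has_duplicates:
            dups = self.mol_table.index[self.mol_table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate mass identifiers in molecular file: {dups}")
        left = set(self.peak_table.index)
        right = set(self.mol_table.index)
        if left != right:
            only_data = sorted(left - right)[:10]
            only_mol = sorted(right - left)[:10]
            raise ValidationError(
                "mass identifiers differ between data and molecular files; "
                f"only in data file: {only_data}; only in molecular file: {only_mol}"
            )
        # keep row order aligned
        self.mol_table = self.mol_table.loc[self.peak_table.index]
        if {"C", "H"} - set(self.mol_table.columns):
            raise ValidationError("C and H are required")
        hf = self.has_formula()
        c = pd.to_numeric(self.mol_table["C"], errors="coerce")
        h = pd.to_numeric(self.mol_table["H"], errors="coerce")
        bad = hf & ((c < 1) | (h < 1))
        if bad.any():
            raise ValidationError(
                f"peaks with a recorded formula must have C >= 1 and H >= 1: "
                f"{list(self.mol_table.index[bad][:10])}"
            )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"FTMSDataset({self.n_peaks} peaks x {self.n_samples} samples, "
                f"scale={self.data_scale!r}, missing_encoded={self.missing_encoded})")


# --------------------------------------------------------------------------- io
def _build_mol_table(mol: pd.DataFrame, formula_col: str | None) -> pd.DataFrame:
    """Normalize a molecular-identification table to element-count columns."""
    out = mol.copy()
    has_counts = {"C", "H"}.issubset(out.columns)
    if formula_col is None:
        for cand in ("Formula", "MolecularFormula", "Molecular Formula", "MolForm"):
            if cand in out.columns:
                formula_col = cand
                break
    if formula_col is not None and formula_col in out.columns and not has_counts:
        counts = {el: [] for el in ELEMENTS}
        for val in out[formula_col]:
            if isinstance(val, str) and val.strip():
                parsed = parse_formula(val)
                for el in ELEMENTS:
                    counts[el].append(parsed[el])
            else:
                for el in ELEMENTS:
                    counts[el].append(np.nan)
        for el in ELEMENTS:
            out[el] = pd.array(counts[el], dtype="float64")
        out = out.rename(columns={formula_col: "Formula"})
    if {"C", "H"} - set(out.columns):
        raise ValidationError("C and H are required")
    for el in ELEMENTS:
        if el in out.columns:
            out[el] = pd.to_numeric(out[el], errors="coerce")
        else:
            out[el] = 0.0
    # rows without a formula: C/H NaN; rows with: fill remaining element NaNs with 0
    hf = out["C"].notna() & out["H"].notna()
    for el in ("N", "O", "S", "P"):
        out.loc[hf & out[el].isna(), el] = 0.0
    return out


def read_generalized_input(
    data_file: str | Path,
    molid_file: str | Path,
    mass_col: str,
    missing_code: float = 0,
    data_scale: str = "abundance",
    formula_col: str | None = None,
    timestamp: str | None = None,
) -> FTMSDataset:
    """Read the generalized two-file input (data file + molecular file).

    The data file holds one row per mass and one column per sample, plus the
    ``mass_col`` identifier column.  The molecular identification file holds
    the same masses with a formula string column and/or C,H,N,O,S,P counts
    (C and H are required).  Mass identifiers are read as strings to avoid
    floating-point key drift.
    """
    data_file, molid_file = Path(data_file), Path(molid_file)
    for f in (data_file, molid_file):
        if not f.exists():
            raise FileNotFoundError(f)
    # round_trip parsing keeps write->read lossless for observed intensities
    data = pd.read_csv(data_file, dtype={mass_col: str}, float_precision="round_trip")
    mol = pd.read_csv(molid_file, dtype={mass_col: str}, float_precision="round_trip")
    for name, df in (("data", data), ("molecular identification", mol)):
        if mass_col not in df.columns:
            raise ValidationError(f"mass column {mass_col!r} missing from {name} file")
    peak_table = data.set_index(mass_col)
    peak_table = peak_table.apply(pd.to_numeric, errors="coerce")
    mol_table = _build_mol_table(mol.set_index(mass_col), formula_col)
    ds = FTMSDataset(peak_table, mol_table, data_scale=data_scale,
                     missing_code=missing_code)
    ds.log_step(
        "upload",
        {
            "data_file": data_file.name,
            "molid_file": molid_file.name,
            "mass_col": mass_col,
            "missing_code": missing_code,
            "data_scale": data_scale,
        },
        (ds.n_peaks, ds.n_samples),
        timestamp=timestamp,
    )
    return ds


def write_generalized_output(
    ds: FTMSDataset,
    data_file: str | Path,
    molid_file: str | Path,
    mass_col: str = "Mass",
) -> None:
    """Write the dataset back to the two-file format.

    Missing cells are written as the dataset's raw missing code, so a
    read/write round trip is lossless for observed values.
    """
    peaks = ds.peak_table.copy()
    if ds.missing_encoded:
        peaks = peaks.fillna(ds.missing_code)
    peaks.rename_axis(mass_col).reset_index().to_csv(data_file, index=False)
    mol = ds.mol_table.copy()
    if mass_col in mol.columns:
        # numeric mass column cannot share a name with the identifier column
        mol = mol.rename(columns={mass_col: f"{mass_col}_Da"})
    mol.rename_axis(mass_col).reset_index().to_csv(molid_file, index=False)


# -------------------------------------------------------------- transformations
def encode_missing(ds: FTMSDataset, timestamp: str | None = None) -> FTMSDataset:
    """Replace cells equal to the raw missing code with the NaN sentinel.

    Idempotent: re-applying leaves the data unchanged.
    """
    out = ds.copy()
    before = (ds.n_peaks, ds.n_samples)
    if not out.missing_encoded:
        out.peak_table = out.peak_table.mask(out.peak_table == out.missing_code)
        out.missing_encoded = True
    out.log_step("encode_missing", {"missing_code": ds.missing_code}, before,
                 timestamp=timestamp)
    return out


def transform_scale(ds: FTMSDataset, target: str,
                    timestamp: str | None = None) -> FTMSDataset:
    """Transform the peak table to a new scale.

    Log targets (``log2``, ``log10``, ``ln``) require the current scale to be
    raw abundance — no double-log.  ``presence_absence`` maps observed cells
    to 1 and missing to 0.  Missing cells stay missing under log transforms.
    """
    if target not in SCALES:
        raise ValidationError(f"unknown target scale {target!r}")
    if not ds.missing_encoded:
        raise ValidationError("encode missing values before transforming the scale")
    out = ds.copy()
    before = (ds.n_peaks, ds.n_samples)
    if target == ds.data_scale:
        pass
    elif target in _LOG_FUNCS:
        if ds.data_scale != "abundance":
            raise ValidationError(
                f"log transform requires abundance-scale data, got {ds.data_scale!r}"
            )
        vals = out.peak_table
        nonpos = (vals <= 0).any().any()
        if nonpos:
            raise ValidationError(
                "non-positive observed intensities cannot be log transformed; "
                "check the missing-value code supplied at upload"
            )
        with np.errstate(invalid="ignore"):
            out.peak_table = pd.DataFrame(
                _LOG_FUNCS[target](vals.to_numpy(dtype=float)),
                index=vals.index, columns=vals.columns,
            )
    elif target == "presence_absence":
        # observed -> 1, missing -> 0; on this scale 0 is absent by construction
        out.peak_table = ds.peak_table.notna().astype(float)
    else:  # target == "abundance" from a transformed scale
        raise ValidationError(
            f"cannot transform {ds.data_scale!r} data back to abundance; "
            "reload the raw data instead"
        )
    out.data_scale = target
    out.log_step("transform_scale", {"target": target}, before, timestamp=timestamp)
    return out


def filter_isotopes(ds: FTMSDataset, isotope_col: str = "Isotope",
                    isotope_value=None, timestamp: str | None = None) -> FTMSDataset:
    """Remove isotope-flagged peaks (e.g. C13 forms) from both tables.

    ``isotope_value`` selects the flag value marking an isotopic peak; if
    None, any non-empty, non-zero value in ``isotope_col`` counts as flagged.
    """
    if isotope_col not in ds.mol_table.columns:
        raise ValidationError(f"isotope column {isotope_col!r} not in molecular table")
    col = ds.mol_table[isotope_col]
    if isotope_value is None:
        flagged = col.notna() & ~col.isin(["", 0, "0", False])
    else:
        flagged = col == isotope_value
    keep = ~flagged
    if not keep.any():
        raise ValidationError("empty dataset after filter: all peaks are isotope-flagged")
    out = ds.copy()
    before = (ds.n_peaks, ds.n_samples)
    out.peak_table = out.peak_table.loc[keep.to_numpy()]
    out.mol_table = out.mol_table.loc[keep.to_numpy()]
    out.log_step("filter_isotopes",
                 {"isotope_col": isotope_col, "isotope_value": isotope_value,
                  "removed": int(flagged.sum())},
                 before, timestamp=timestamp)
    return out


# ------------------------------------------------------------------- groups
def detect_groups(
    sample_names: Sequence[str],
    patterns: Sequence[tuple[str, str]],
    regex: bool = False,
    case_sensitive: bool = True,
) -> GroupDefinition:
    """Assign samples to groups by pattern-matching their names.

    Plain substring matching by default (first match in pattern order wins);
    regular expressions behind the ``regex`` flag.  Samples matching no
    pattern are left unassigned; if nothing matches at all a warning is
    issued and the mapping is empty.
    """
    if not patterns:
        raise ValidationError("at least one (pattern, group) pair is required")
    for pat, _ in patterns:
        if pat == "":
            raise ValidationError("empty pattern")
    mapping: dict[str, str] = {}
    for name in sample_names:
        hay = name if case_sensitive else name.lower()
        for pat, group in patterns:
            needle = pat if case_sensitive else pat.lower()
            hit = re.search(needle, hay) if regex else (needle in hay)
            if hit:
                mapping[name] = group
                break
    if not mapping:
        warnings.warn("no sample name matched any pattern; group mapping is empty")
    return GroupDefinition(mapping)


# ------------------------------------------------------------------ summaries
def summarize_dataset(ds: FTMSDataset) -> pd.DataFrame:
    """Per-sample summary: observed peak count and five-number statistics.

    Rows are samples; columns ``n_observed, min, q1, median, q3, max`` over
    observed (non-missing) intensities.  Samples with no observed peaks get
    NaN quantiles.
    """
    if not ds.missing_encoded:
        raise ValidationError("encode missing values before summarizing")
    rows = []
    for s in ds.sample_ids:
        vals = ds.peak_table[s].dropna()
        if len(vals):
            q = np.percentile(vals, [0, 25, 50, 75, 100])
        else:
            q = [np.nan] * 5
        rows.append({"sample": s, "n_observed": int(len(vals)),
                     "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]})
    return pd.DataFrame(rows).set_index("sample")
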