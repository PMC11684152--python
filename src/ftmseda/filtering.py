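"""Sequential peak and sample filters with per-step retention accounting.

Four predefined filter kinds plus custom filters, applied in order:

* ``sample_name`` — keep or remove sample columns by name;
* ``mass_range`` — keep peaks with mass inside [min, max];
* ``min_observed`` — keep peaks observed in at least k samples, optionally
  per group (a peak survives if ANY group meets the minimum);
* ``has_formula`` — keep peaks with an assigned molecular formula;
* ``custom`` — keep peaks whose value in any molecular-table or calculated
  column lies in an inclusive numeric range or a categorical keep-set.

Peak-level filters are set intersections, so the final peak set does not
depend on filter order; only the per-step retention counts do.  The chain
returns both the filtered dataset and a retention table, the data behind the
sequential filter bar chart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .dataset import FTMSDataset, GroupDefinition, ValidationError


@dataclass(frozen=True)
class FilterSpec:
    """Specification of one filter in a chain.

    kind: one of sample_name, mass_range, min_observed, has_formula, custom.
    Parameters by kind:
      sample_name  — ``keep`` or ``remove``: list of sample ids.
      mass_range   — ``min_mass``, ``max_mass`` (min < max, inclusive ends).
      min_observed — ``min_count`` (>= 1), ``per_group`` flag.
      has_formula  — no parameters.
      custom       — ``column`` plus either ``range=(lo, hi)`` (inclusive)
                     or ``categories``: set of values to keep.
    """

    kind: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind == "mass_range":
            lo, hi = self.params["min_mass"], self.params["max_mass"]
            if not lo < hi:
                raise ValidationError("mass_range requires min_mass < max_mass")
        elif self.kind == "min_observed":
            if int(self.params.get("min_count", 0)) < 1:
                raise ValidationError("min_observed requires min_count >= 1")
        elif self.kind == "custom":
            if "column" not in self.params:
                raise ValidationError("custom filter requires a target column")
            if ("range" in self.params) == ("categories" in self.params):
                raise ValidationError("custom filter takes exactly one of range/categories")
        elif self.kind == "sample_name":
            if ("keep" in self.params) == ("remove" in self.params):
                raise ValidationError("sample_name filter takes exactly one of keep/remove")
        elif self.kind != "has_formula":
            raise ValidationError(f"unknown filter kind {self.kind!r}")

    @property
    def name(self) -> str:
        if self.kind == "mass_range":
            return f"mass_range[{self.params['min_mass']},{self.params['max_mass']}]"
        if self.kind == "min_observed":
            suffix = "/group" if self.params.get("per_group") else ""
            return f"min_observed>={self.params['min_count']}{suffix}"
        if self.kind == "custom":
            return f"custom[{self.params['column']}]"
        return self.kind


def peak_mask(ds: FTMSDataset, spec: FilterSpec,
              groups: GroupDefinition | None = None) -> pd.Series:
    """Boolean keep-mask over peaks for a single peak-level filter.

    ``sample_name`` filters act on columns, not peaks, and return an
    all-True mask here.
    """
    idx = ds.peak_table.index
    if spec.kind == "sample_name":
        return pd.Series(True, index=idx)
    if spec.kind == "mass_range":
        m = ds.masses()
        return (m >= spec.params["min_mass"]) & (m <= spec.params["max_mass"])
    if spec.kind == "min_observed":
        k = int(spec.params["min_count"])
        obs = ds.observed_mask()
        if spec.params.get("per_group"):
            if groups is None or not groups.groups():
                raise ValidationError("per-group min_observed needs a group definition")
            counts = pd.DataFrame({
                g: obs[groups.samples_in(g)].sum(axis=1) for g in groups.groups()
            })
            return (counts >= k).any(axis=1)
        return obs.sum(axis=1) >= k
    if spec.kind == "has_formula":
        return ds.has_formula()
    if spec.kind == "custom":
        col = spec.params["column"]
        if col not in ds.mol_table.columns:
            raise ValidationError(f"custom filter column {col!r} not found; "
                                  "compute properties first or check the name")
        series = ds.mol_table[col]
        if "range" in spec.params:
            lo, hi = spec.params["range"]
            v = pd.to_numeric(series, errors="coerce")
            return (v >= lo) & (v <= hi)
        return series.isin(spec.params["categories"])
    raise ValidationError(f"unknown filter kind {spec.kind!r}")


def apply_filters(ds: FTMSDataset, specs: Sequence[FilterSpec],
                  groups: GroupDefinition | None = None,
                  timestamp: str | None = None) -> tuple[FTMSDataset, pd.DataFrame]:
    """Apply a filter chain in order; return the result and a retention table.

    The retention table has one row per filter: peaks before, peaks after,
    and peaks with an assigned formula after that step.  An empty dataset
    after any step is an error naming the filter.  The pre-filter dataset is
    kept on the result for :func:`reset_filters`.
    """
    current = ds.copy()
    original = ds
    rows = []
    for spec in specs:
        before = current.n_peaks
        nsamp_before = current.n_samples
        if spec.kind == "sample_name":
            if "keep" in spec.params:
                keep_cols = [s for s in current.sample_ids if s in set(spec.params["keep"])]
            else:
                keep_cols = [s for s in current.sample_ids
                             if s not in set(spec.params["remove"])]
            if not keep_cols:
                raise ValidationError(f"filter {spec.name!r} leaves no samples")
            current.peak_table = current.peak_table[keep_cols]
        else:
            mask = peak_mask(current, spec, groups).fillna(False).astype(bool)
            if not mask.any():
                raise ValidationError(f"empty dataset after filter {spec.name!r}")
            current.peak_table = current.peak_table.loc[mask.to_numpy()]
            current.mol_table = current.mol_table.loc[mask.to_numpy()]
        current.log_step(f"filter:{spec.name}", dict(spec.params),
                         (before, nsamp_before), timestamp=timestamp)
        rows.append({
            "filter": spec.name,
            "peaks_before": before,
            "peaks_after": current.n_peaks,
            "peaks_with_formula_after": int(current.has_formula().sum()),
        })
    retention = pd.DataFrame(rows, columns=["filter", "peaks_before", "peaks_after",
                                            "peaks_with_formula_after"])
    current._prefilter = original  # type: ignore[attr-defined]
    return current, retention


def reset_filters(ds: FTMSDataset, timestamp: str | None = None) -> FTMSDataset:
    """Return the dataset as it was before the last filter chain.

    Preprocessing (calculated-property columns, missing encoding, scale) is
    not undone — only peak/sample removal by filters.  On a dataset with no
    filters applied this is the identity.
    """
    original = getattr(ds, "_prefilter", None)
    out = (original or ds).copy()
    out.provenance = list(ds.provenance)
    out.log_step("reset_filters", {}, (ds.n_peaks, ds.n_samples), timestamp=timestamp)
    return out
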