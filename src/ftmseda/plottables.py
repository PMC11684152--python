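"""Plot-ready data tables for the standard displays.

Each builder returns a :class:`PlotTable`: a tidy DataFrame of points (or
curves) plus axis/legend metadata.  Rendering is a thin optional layer on
top (``ftmseda.render``); the tables themselves are the product, and every
row-count is derivable from the stated exclusion rules — points lacking a
required value are excluded, never zero-filled.

* van Krevelen — one point per formula-assigned peak at (O:C, H:C);
* Kendrick — (Kendrick mass, Kendrick defect);
* density — per-sample or per-group kernel-density curves of any computed
  variable over observed peaks, with an optional pooled "combined" curve;
* scatter — any two molecular/calculated columns;
* QC — per-sample boxplot statistics and observed-peak counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .dataset import FTMSDataset, GroupDefinition, ValidationError, summarize_dataset
from .compare import ComparisonResult

#: Grid size for kernel-density curves.
KDE_GRID = 512
#: Grid padding in units of the largest bandwidth, so curves integrate to ~1.
KDE_PAD_BW = 5.0


@dataclass
class PlotTable:
    """Tidy plot data plus display metadata."""

    kind: str
    data: pd.DataFrame
    x: str
    y: str
    color: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.data)


def _require(ds: FTMSDataset, cols: list[str], hint: str) -> None:
    missing = [c for c in cols if c not in ds.mol_table.columns]
    if missing:
        raise ValidationError(f"columns {missing} not available; {hint}")


def van_krevelen_table(ds: FTMSDataset, color_by: str | None = None,
                       comparison: ComparisonResult | None = None) -> PlotTable:
    """Van Krevelen scatter: O:C on x, H:C on y, one point per assigned peak.

    When a comparison is supplied its uniqueness label is attached per peak
    (rows labelled observed-in-both included; hide them downstream if
    desired).  Hover fields carry the formula and mass.
    """
    _require(ds, ["OtoC", "HtoC"], "run compute_properties with 'ratios' first")
    df = pd.DataFrame({
        "mass_id": ds.mol_table.index,
        "x": ds.mol_table["OtoC"].astype(float),
        "y": ds.mol_table["HtoC"].astype(float),
        "formula": ds.mol_table.get("Formula"),
        "mass": ds.masses(),
    }).dropna(subset=["x", "y"])
    if color_by is not None:
        _require(ds, [color_by], "unknown color column")
        df["color"] = ds.mol_table[color_by].reindex(df["mass_id"]).to_numpy()
    if comparison is not None:
        df["uniqueness"] = comparison.table["uniqueness"].reindex(df["mass_id"]).to_numpy()
    return PlotTable("van_krevelen", df.reset_index(drop=True), x="x", y="y",
                     color="color" if color_by else None,
                     meta={"xlabel": "O:C", "ylabel": "H:C", "color_by": color_by})


def kendrick_table(ds: FTMSDataset, color_by: str | None = None,
                   comparison: ComparisonResult | None = None) -> PlotTable:
    """Kendrick scatter: Kendrick mass on x, Kendrick defect on y."""
    _require(ds, ["KendrickMass", "KendrickDefect"],
             "run compute_properties with 'kendrick' first")
    df = pd.DataFrame({
        "mass_id": ds.mol_table.index,
        "x": ds.mol_table["KendrickMass"].astype(float),
        "y": ds.mol_table["KendrickDefect"].astype(float),
        "formula": ds.mol_table.get("Formula"),
        "mass": ds.masses(),
    }).dropna(subset=["x", "y"])
    if color_by is not None:
        _require(ds, [color_by], "unknown color column")
        df["color"] = ds.mol_table[color_by].reindex(df["mass_id"]).to_numpy()
    if comparison is not None:
        df["uniqueness"] = comparison.table["uniqueness"].reindex(df["mass_id"]).to_numpy()
    return PlotTable("kendrick", df.reset_index(drop=True), x="x", y="y",
                     color="color" if color_by else None,
                     meta={"xlabel": "Kendrick mass", "ylabel": "Kendrick defect",
                           "color_by": color_by})


def density_table(ds: FTMSDataset, variable: str,
                  by: str = "sample",
                  groups: GroupDefinition | None = None,
                  include_combined: bool = False) -> PlotTable:
    """Kernel-density curves of a calculated variable, per sample or group.

    Gaussian kernel with Silverman bandwidth, evaluated on a shared
    512-point grid spanning the pooled value range padded by five
    bandwidths (so each curve integrates to one on the grid).  Units with
    fewer than two distinct values are skipped with a warning.
    """
    _require(ds, [variable], "compute the property first")
    if by not in ("sample", "group"):
        raise ValidationError("by must be 'sample' or 'group'")
    values = pd.to_numeric(ds.mol_table[variable], errors="coerce")
    obs = ds.observed_mask()
    if by == "group":
        if groups is None or not groups.groups():
            raise ValidationError("group densities need a group definition")
        units = {g: obs[groups.samples_in(g)].any(axis=1) for g in groups.groups()}
    else:
        units = {s: obs[s] for s in ds.sample_ids}
    series = {}
    for name, mask in units.items():
        v = values[mask].dropna().to_numpy()
        if len(np.unique(v)) < 2:
            warnings.warn(f"density curve for {name!r} omitted: "
                          "fewer than two distinct values")
            continue
        series[name] = v
    if include_combined:
        pooled = np.concatenate(list(series.values())) if series else np.array([])
        if len(np.unique(pooled)) >= 2:
            series["combined"] = pooled
    if not series:
        raise ValidationError("no unit has enough values for a density curve")
    pooled = np.concatenate(list(series.values()))
    kdes = {name: gaussian_kde(v, bw_method="silverman") for name, v in series.items()}
    bw_max = max(k.covariance_factor() * np.std(v, ddof=1)
                 for k, v in zip(kdes.values(), series.values()))
    lo = pooled.min() - KDE_PAD_BW * bw_max
    hi = pooled.max() + KDE_PAD_BW * bw_max
    grid = np.linspace(lo, hi, KDE_GRID)
    frames = []
    for name, kde in kdes.items():
        frames.append(pd.DataFrame({"unit": name, "x": grid, "density": kde(grid)}))
    df = pd.concat(frames, ignore_index=True)
    return PlotTable("density", df, x="x", y="density", color="unit",
                     meta={"variable": variable, "by": by})


def scatter_table(ds: FTMSDataset, x: str, y: str,
                  color_by: str | None = None) -> PlotTable:
    """Custom scatter of any two molecular/calculated columns."""
    _require(ds, [x, y], "unknown scatter column")
    df = pd.DataFrame({
        "mass_id": ds.mol_table.index,
        "x": pd.to_numeric(ds.mol_table[x], errors="coerce"),
        "y": pd.to_numeric(ds.mol_table[y], errors="coerce"),
    }).dropna(subset=["x", "y"])
    if color_by is not None:
        _require(ds, [color_by], "unknown color column")
        df["color"] = ds.mol_table[color_by].reindex(df["mass_id"]).to_numpy()
    return PlotTable("scatter", df.reset_index(drop=True), x="x", y="y",
                     color="color" if color_by else None,
                     meta={"xlabel": x, "ylabel": y})


def qc_tables(ds: FTMSDataset, groups: GroupDefinition | None = None,
              scale: str | None = None,
              group_filter: list[str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quality-control tables: per-sample five-number summaries and counts.

    ``scale`` optionally re-expresses intensities (log2/log10/ln/
    presence_absence) before summarizing; ``group_filter`` restricts to
    samples belonging to the named groups.
    """
    from .dataset import transform_scale

    view = ds
    if scale is not None and scale != ds.data_scale:
        view = transform_scale(ds, scale)
    if group_filter:
        if groups is None:
            raise ValidationError("group_filter needs a group definition")
        keep = [s for g in group_filter for s in groups.samples_in(g)]
        view = view.copy()
        view.peak_table = view.peak_table[[s for s in view.sample_ids if s in keep]]
    summary = summarize_dataset(view)
    box = summary[["min", "q1", "median", "q3", "max"]].copy()
    if groups is not None:
        box["group"] = [groups.mapping.get(s) for s in box.index]
    counts = summary[["n_observed"]].copy()
    if groups is not None:
        counts["group"] = [groups.mapping.get(s) for s in counts.index]
    return box, counts
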