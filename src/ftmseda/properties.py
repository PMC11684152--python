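"""Chemical properties computed per peak from molecular formulas.

Given element counts C, H, N, O, S, P for each peak, this module computes the
quantities routinely used to characterize complex organic mixtures measured
by ultrahigh-resolution mass spectrometry:

* **Elemental ratios** — O:C, H:C, N:C, P:C and N:P; the O:C/H:C pair places
  each formula on the van Krevelen plane.
* **Kendrick mass and defect** — the observed mass rescaled so that the CH2
  unit weighs exactly 14 Da; members of a CH2 homologous series share the
  same defect.
* **NOSC** — the nominal oxidation state of carbon,
  ``NOSC = 4 - (4C + H - 3N - 2O - 2S + 5P) / C``, bounded in [-4, +4].
* **GFE** — the standard-state Gibbs free energy of the carbon oxidation
  half reaction, ``GFE = 60.3 - 28.5 * NOSC`` (kJ per mol C), the
  LaRowe–Van Cappellen linear relation.
* **AI / AI_mod and DBE** — Koch–Dittmar aromaticity indices and the
  double-bond equivalent (rings plus pi bonds).
* **Elemental-composition class** — the concatenation of element symbols
  present (e.g. "CHO", "CHNOS").
* **Compound class** — a biochemical-class label assigned from the peak's
  position in (O:C, H:C) space against a boundary table.

Every property is NaN for peaks without an assigned formula and wherever a
denominator is degenerate ("whenever applicable" semantics).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import FTMSDataset, ValidationError
from .formulas import ELEMENTS

#: Exact mass of the CH2 repeat unit (Da) and its nominal mass.
CH2_EXACT = 14.01565
CH2_NOMINAL = 14.0

#: LaRowe–Van Cappellen coefficients: GFE = GFE_INTERCEPT + GFE_SLOPE * NOSC.
GFE_INTERCEPT = 60.3
GFE_SLOPE = -28.5

#: Columns appended to mol_table by compute_properties, in order.
PROPERTY_COLUMNS = (
    "OtoC", "HtoC", "NtoC", "PtoC", "NtoP",
    "KendrickMass", "KendrickDefect",
    "NOSC", "GFE", "AI", "AImod", "DBE",
    "ElementalClass", "CompoundClass",
)


# ---------------------------------------------------------------- boundaries
@dataclass(frozen=True)
class ClassBoundary:
    """One axis-aligned rectangle in (O:C, H:C) space."""

    name: str
    ocmin: float
    ocmax: float
    hcmin: float
    hcmax: float
    precedence: int

    def contains(self, oc: float, hc: float) -> bool:
        # half-open: min-inclusive, max-exclusive
        return (self.ocmin <= oc < self.ocmax) and (self.hcmin <= hc < self.hcmax)


class BoundarySet:
    """Named compound-class regions in the van Krevelen plane.

    Each class is a rectangle ``[ocmin, ocmax) x [hcmin, hcmax)``; rectangles
    may overlap, and all classes containing a point are reported in
    precedence order, joined by ";".  A point outside every rectangle is
    labelled "Other".
    """

    def __init__(self, boundaries: list[ClassBoundary]):
        for b in boundaries:
            if not (b.ocmax > b.ocmin and b.hcmax > b.hcmin):
                raise ValidationError(f"boundary {b.name!r} has non-positive area")
        self.boundaries = sorted(boundaries, key=lambda b: b.precedence)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BoundarySet":
        df = pd.read_csv(path)
        required = {"class", "ocmin", "ocmax", "hcmin", "hcmax", "precedence"}
        if missing := required - set(df.columns):
            raise ValidationError(f"boundary table missing columns: {sorted(missing)}")
        return cls([
            ClassBoundary(str(r["class"]), float(r["ocmin"]), float(r["ocmax"]),
                          float(r["hcmin"]), float(r["hcmax"]), int(r["precedence"]))
            for _, r in df.iterrows()
        ])

    @classmethod
    def default(cls) -> "BoundarySet":
        with resources.as_file(
            resources.files("ftmseda.data") / "compound_class_boundaries.csv"
        ) as p:
            return cls.from_csv(p)

    def classify(self, oc: float, hc: float) -> str:
        if not (np.isfinite(oc) and np.isfinite(hc)):
            return ""
        hits = [b.name for b in self.boundaries if b.contains(oc, hc)]
        return ";".join(hits) if hits else "Other"


# -------------------------------------------------------------- scalar kernels
def elemental_ratios(counts: pd.DataFrame) -> pd.DataFrame:
    """Element-count ratios O:C, H:C, N:C, P:C and N:P per peak.

    ``counts`` must have columns C,H,N,O,S,P; rows with C NaN or C < 1 yield
    NaN ratios, and N:P is NaN whenever P < 1.
    """
    c = counts["C"].astype(float)
    valid = c >= 1
    out = pd.DataFrame(index=counts.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["OtoC"] = np.where(valid, counts["O"] / c, np.nan)
        out["HtoC"] = np.where(valid, counts["H"] / c, np.nan)
        out["NtoC"] = np.where(valid, counts["N"] / c, np.nan)
        out["PtoC"] = np.where(valid, counts["P"] / c, np.nan)
        p = counts["P"].astype(float)
        out["NtoP"] = np.where(valid & (p >= 1), counts["N"] / p, np.nan)
    return out


def kendrick(mass, defect: str = "ceiling"):
    """Kendrick mass and defect on the CH2 base.

    KM = mass * 14 / 14.01565.  With the default ``ceiling`` convention
    KMD = ceil(KM) - KM, lying in [0, 1); the ``round`` alternative uses the
    nearest integer, giving KMD in [-0.5, 0.5).
    """
    m = np.asarray(mass, dtype=float)
    if np.any(m[np.isfinite(m)] <= 0):
        raise ValidationError("Kendrick mass requires strictly positive masses")
    km = m * (CH2_NOMINAL / CH2_EXACT)
    if defect == "ceiling":
        kmd = np.ceil(km) - km
    elif defect == "round":
        kmd = np.round(km) - km
    else:
        raise ValidationError(f"unknown Kendrick defect convention {defect!r}")
    return km, kmd


def nosc_gfe(counts: pd.DataFrame) -> pd.DataFrame:
    """Nominal oxidation state of carbon and carbon-oxidation Gibbs energy."""
    c = counts["C"].astype(float)
    valid = c >= 1
    with np.errstate(divide="ignore", invalid="ignore"):
        nosc = 4.0 - (4 * c + counts["H"] - 3 * counts["N"]
                      - 2 * counts["O"] - 2 * counts["S"] + 5 * counts["P"]) / c
    nosc = pd.Series(np.where(valid, nosc, np.nan), index=counts.index, name="NOSC")
    gfe = GFE_INTERCEPT + GFE_SLOPE * nosc
    return pd.DataFrame({"NOSC": nosc, "GFE": gfe.rename("GFE")})


def ai_dbe(counts: pd.DataFrame, clamp: bool = True) -> pd.DataFrame:
    """Aromaticity index, modified aromaticity index, and DBE per peak.

    AI = (1 + C - O - S - 0.5 H) / (C - O - S - N - P); AI_mod halves the
    oxygen contribution.  By the usual convention a non-positive denominator
    or a negative value clamps the index to 0; pass ``clamp=False`` to emit
    NaN instead.
    """
    c = counts["C"].astype(float)
    valid = c >= 1
    out = pd.DataFrame(index=counts.index)
    out["DBE"] = np.where(valid, 1 + 0.5 * (2 * c - counts["H"] + counts["N"] + counts["P"]),
                          np.nan)
    for name, o_weight in (("AI", 1.0), ("AImod", 0.5)):
        o = o_weight * counts["O"]
        num = 1 + c - o - counts["S"] - 0.5 * counts["H"]
        den = c - o - counts["S"] - counts["N"] - counts["P"]
        with np.errstate(divide="ignore", invalid="ignore"):
            ai = num / den
        bad = (den <= 0) | (ai < 0)
        ai = np.where(bad, 0.0 if clamp else np.nan, ai)
        out[name] = np.where(valid, ai, np.nan)
    return out


def elemental_composition_class(counts: pd.DataFrame) -> pd.Series:
    """Concatenated symbols of elements present, fixed C,H,N,O,S,P order."""
    valid = (counts["C"] >= 1) & (counts["H"] >= 1)
    labels = []
    for _, row in counts.iterrows():
        if not (row["C"] >= 1 and row["H"] >= 1):
            labels.append(None)
            continue
        labels.append("".join(el for el in ELEMENTS if row[el] >= 1))
    return pd.Series(labels, index=counts.index, name="ElementalClass").where(valid)


def assign_compound_class(ratios: pd.DataFrame,
                          boundary_set: BoundarySet | None = None) -> pd.Series:
    """Compound-class label(s) from O:C/H:C position, ";"-joined by precedence."""
    bs = boundary_set or BoundarySet.default()
    labels = [
        bs.classify(oc, hc) or None
        for oc, hc in zip(ratios["OtoC"].astype(float), ratios["HtoC"].astype(float))
    ]
    return pd.Series(labels, index=ratios.index, name="CompoundClass")


# ------------------------------------------------------------- dataset surface
def compute_properties(ds: FTMSDataset,
                       calcs: tuple[str, ...] = ("ratios", "kendrick", "nosc_gfe",
                                                 "ai_dbe", "elcomp", "class"),
                       boundary_set: BoundarySet | None = None,
                       kendrick_defect: str = "ceiling",
                       timestamp: str | None = None) -> FTMSDataset:
    """Append calculated-property columns to the molecular table.

    ``calcs`` selects which property families to compute; ``class`` implies
    ``ratios``.  Peaks without a formula get NaN everywhere; Kendrick values
    additionally require a numeric mass.
    """
    out = ds.copy()
    counts = out.mol_table[list(ELEMENTS)].astype(float)
    done = []
    if "class" in calcs and "ratios" not in calcs:
        calcs = ("ratios",) + tuple(calcs)
    for calc in calcs:
        if calc == "ratios":
            out.mol_table[["OtoC", "HtoC", "NtoC", "PtoC", "NtoP"]] = elemental_ratios(counts)
        elif calc == "kendrick":
            masses = out.masses()
            km, kmd = kendrick(masses.where(masses > 0), defect=kendrick_defect)
            out.mol_table["KendrickMass"] = km
            out.mol_table["KendrickDefect"] = kmd
        elif calc == "nosc_gfe":
            out.mol_table[["NOSC", "GFE"]] = nosc_gfe(counts)
        elif calc == "ai_dbe":
            out.mol_table[["AI", "AImod", "DBE"]] = ai_dbe(counts)
        elif calc == "elcomp":
            out.mol_table["ElementalClass"] = elemental_composition_class(counts)
        elif calc == "class":
            ratios = out.mol_table[["OtoC", "HtoC"]]
            out.mol_table["CompoundClass"] = assign_compound_class(ratios, boundary_set)
        else:
            raise ValidationError(f"unknown property family {calc!r}")
        done.append(calc)
    out.log_step("compute_properties", {"calcs": done,
                                        "kendrick_defect": kendrick_defect},
                 (ds.n_peaks, ds.n_samples), timestamp=timestamp)
    return out


def property_summary(ds: FTMSDataset, prop: str, bins: int = 20) -> dict:
    """Distribution summary of a calculated property across samples.

    Returns per-sample and overall min/median/max over peaks observed in each
    sample, plus shared-range histogram bin edges and counts.  Requires the
    property column to exist and to be non-NaN for at least one peak.
    """
    if prop not in ds.mol_table.columns:
        raise ValidationError(f"property {prop!r} not computed; run compute_properties")
    values = pd.to_numeric(ds.mol_table[prop], errors="coerce")
    if values.notna().sum() == 0:
        raise ValidationError(f"property {prop!r} is missing for every peak")
    mask = ds.observed_mask()
    rows = []
    for s in ds.sample_ids:
        v = values[mask[s]].dropna()
        rows.append({
            "sample": s, "n": int(len(v)),
            "min": v.min() if len(v) else np.nan,
            "median": v.median() if len(v) else np.nan,
            "max": v.max() if len(v) else np.nan,
        })
    per_sample = pd.DataFrame(rows).set_index("sample")
    allv = values.dropna()
    hist, edges = np.histogram(allv, bins=bins)
    overall = {"n": int(len(allv)), "min": float(allv.min()),
               "median": float(allv.median()), "max": float(allv.max())}
    return {"per_sample": per_sample, "overall": overall,
            "hist_counts": hist, "hist_edges": edges}
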