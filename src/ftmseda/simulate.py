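"""Synthetic formula-assigned FT-MS datasets with known group structure.

The generator emulates the two input formats at the scale of a typical soil
organic-matter study — a few thousand peaks across two groups of samples —
with controllable presence/absence structure so that uniqueness tests can be
validated against a known truth table:

* molecular formulas are drawn by rejection sampling over C in [4, 40] with
  H:C in [0.2, 2.5] and O:C capped at 1.2, so the simulated peaks populate
  the realistic region of the van Krevelen plane; N, O, S, P enter with
  decreasing inclusion probabilities;
* peak masses are the monoisotopic masses of the generated formulas;
* intensities are log-normal;
* each peak is observed in a sample with a per-group presence probability:
  most peaks share one probability across groups (null peaks), a configured
  fraction differ between groups (true-difference peaks, flagged in the
  returned truth table).

No physical spectrum features (peak shape, resolution, m/z noise) are
simulated.  All randomness flows from the config seed: a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import FTMSDataset, GroupDefinition, ValidationError
from .formulas import ELEMENTS, format_formula, monoisotopic_mass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults: 2000 peaks, two groups of 10 samples, 90% of peaks
    formula-assigned, 15% of peaks truly different between groups with
    presence probabilities 0.9 vs 0.1, null-peak presence probability drawn
    uniformly from [0.4, 0.95] and shared by both groups, log-normal
    intensities (meanlog 16, sdlog 1 — arbitrary instrument units).
    """

    n_peaks: int = 2000
    samples_per_group: tuple[int, int] = (10, 10)
    group_names: tuple[str, str] = ("G1", "G2")
    frac_formula: float = 0.9
    frac_differential: float = 0.15
    diff_presence: tuple[float, float] = (0.9, 0.1)
    null_presence_range: tuple[float, float] = (0.4, 0.95)
    intensity_meanlog: float = 16.0
    intensity_sdlog: float = 1.0
    frac_isotope: float = 0.05
    # CoreMS mode
    candidates_per_peak: int = 3
    true_confidence: tuple[float, float] = (0.7, 0.99)
    decoy_confidence: tuple[float, float] = (0.1, 0.69)
    seed: int = 0

    def __post_init__(self):
        if self.n_peaks < 1 or min(self.samples_per_group) < 1:
            raise ValidationError("need at least one peak and one sample per group")
        for p in (self.frac_formula, self.frac_differential, self.frac_isotope,
                  *self.diff_presence, *self.null_presence_range):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must lie in [0, 1]")


def _draw_formulas(rng: np.random.Generator, n: int) -> list[dict[str, int]]:
    """Rejection-sample n distinct valence-plausible formulas."""
    seen: dict[str, dict[str, int]] = {}
    while len(seen) < n:
        c = int(rng.integers(4, 41))
        h = max(1, int(round(c * rng.uniform(0.2, 2.5))))
        o = int(rng.integers(0, c + 1)) if rng.random() < 0.85 else 0
        if o / c > 1.2:
            continue
        nn = int(rng.integers(0, 4)) if rng.random() < 0.4 else 0
        s = int(rng.integers(0, 3)) if rng.random() < 0.15 else 0
        p = int(rng.integers(0, 2)) if rng.random() < 0.1 else 0
        counts = {"C": c, "H": h, "N": nn, "O": o, "S": s, "P": p}
        seen.setdefault(format_formula(counts), counts)
    return list(seen.values())[:n]


def simulate_dataset(cfg: SimulationConfig | None = None
                     ) -> tuple[FTMSDataset, GroupDefinition, pd.DataFrame]:
    """Generate a synthetic dataset, its group definition, and a truth table.

    The truth table has one row per peak with the per-group presence
    probabilities and ``true_difference`` flagging peaks whose presence
    probabilities differ between the groups.  Missing cells are already
    encoded (NaN); the data scale is raw abundance.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n1, n2 = cfg.samples_per_group
    g1, g2 = cfg.group_names
    samples = ([f"{g1}_s{i + 1:02d}" for i in range(n1)]
               + [f"{g2}_s{i + 1:02d}" for i in range(n2)])
    groups = GroupDefinition({s: (g1 if i < n1 else g2)
                              for i, s in enumerate(samples)})

    formulas = _draw_formulas(rng, cfg.n_peaks)
    has_formula = rng.random(cfg.n_peaks) < cfg.frac_formula
    masses = np.array([monoisotopic_mass(f) for f in formulas])
    # unassigned peaks keep a mass (jittered) but lose the formula record
    mass_ids = np.array([f"{m:.5f}" for m in masses])
    # guard against duplicate mass ids after rounding
    ids_series = pd.Series(mass_ids)
    dup = ids_series.duplicated()
    while dup.any():
        masses[dup.to_numpy()] += 0.00001
        mass_ids = np.array([f"{m:.5f}" for m in masses])
        ids_series = pd.Series(mass_ids)
        dup = ids_series.duplicated()

    n_diff = int(round(cfg.frac_differential * cfg.n_peaks))
    diff_idx = rng.choice(cfg.n_peaks, size=n_diff, replace=False)
    is_diff = np.zeros(cfg.n_peaks, dtype=bool)
    is_diff[diff_idx] = True
    p_null = rng.uniform(*cfg.null_presence_range, size=cfg.n_peaks)
    p1 = np.where(is_diff, cfg.diff_presence[0], p_null)
    p2 = np.where(is_diff, cfg.diff_presence[1], p_null)
    # half of the differential peaks flip direction
    flip = is_diff & (rng.random(cfg.n_peaks) < 0.5)
    p1, p2 = np.where(flip, p2, p1), np.where(flip, p1, p2)

    present = np.empty((cfg.n_peaks, n1 + n2), dtype=bool)
    present[:, :n1] = rng.random((cfg.n_peaks, n1)) < p1[:, None]
    present[:, n1:] = rng.random((cfg.n_peaks, n2)) < p2[:, None]
    intensity = rng.lognormal(cfg.intensity_meanlog, cfg.intensity_sdlog,
                              size=present.shape)
    values = np.where(present, intensity, np.nan)
    peak_table = pd.DataFrame(values, index=pd.Index(mass_ids, name="Mass"),
                              columns=samples)

    mol = pd.DataFrame(index=peak_table.index)
    mol["Formula"] = [format_formula(f) if hf else np.nan
                      for f, hf in zip(formulas, has_formula)]
    for el in ELEMENTS:
        mol[el] = [float(f[el]) if hf else np.nan
                   for f, hf in zip(formulas, has_formula)]
    mol["Isotope"] = np.where(rng.random(cfg.n_peaks) < cfg.frac_isotope, "C13", "")
    mol["Mass"] = masses

    ds = FTMSDataset(peak_table, mol, data_scale="abundance", missing_code=0,
                     missing_encoded=True)
    ds.log_step("simulate", {"n_peaks": cfg.n_peaks, "seed": cfg.seed},
                (cfg.n_peaks, n1 + n2), timestamp="")
    truth = pd.DataFrame({
        "p_g1": p1, "p_g2": p2, "true_difference": is_diff,
        "has_formula": has_formula,
    }, index=peak_table.index)
    return ds, groups, truth


def simulate_corems_files(cfg: SimulationConfig | None = None,
                          out_dir: str | Path = ".") -> tuple[list[Path], pd.DataFrame]:
    """Write per-sample long-format candidate CSVs plus a truth sidecar.

    Each observed (sample, m/z) gets ``candidates_per_peak`` candidate
    formulas: the true one with the highest confidence score, plus decoys
    with lower scores and larger mass errors.  The returned truth table maps
    each m/z to its true formula, so that confidence filtering and formula
    resolution can be checked against construction.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed + 1)
    ds, groups, _ = simulate_dataset(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    obs = ds.peak_table.notna()
    masses = ds.masses()
    formulas = ds.mol_table["Formula"]
    assigned = formulas.notna()
    files = []
    truth_rows = []
    for sample in ds.sample_ids:
        rows = []
        for mass_id in ds.mass_ids:
            if not (obs.loc[mass_id, sample] and assigned.loc[mass_id]):
                continue
            mz = masses.loc[mass_id]
            height = ds.peak_table.loc[mass_id, sample]
            true_f = formulas.loc[mass_id]
            true_conf = rng.uniform(*cfg.true_confidence)
            rows.append((mz, height, true_f, true_conf, rng.normal(0, 0.1)))
            for k in range(cfg.candidates_per_peak - 1):
                decoy = _perturb_formula(true_f, rng)
                rows.append((mz, height, decoy,
                             rng.uniform(*cfg.decoy_confidence),
                             rng.normal(0, 0.5)))
        df = pd.DataFrame(rows, columns=["Calibrated m/z", "Peak Height",
                                         "Molecular Formula", "Confidence Score",
                                         "m/z Error (ppm)"])
        path = out_dir / f"{sample}.csv"
        df.to_csv(path, index=False)
        files.append(path)
    truth = pd.DataFrame({
        "mz": masses[assigned],
        "true_formula": formulas[assigned],
    })
    return files, truth.reset_index(drop=True)


def _perturb_formula(formula: str, rng: np.random.Generator) -> str:
    """A decoy candidate: the true formula with one element count nudged."""
    from .formulas import parse_formula

    counts = parse_formula(formula)
    el = ("H", "O", "N")[int(rng.integers(0, 3))]
    counts[el] = max(0, counts[el] + int(rng.choice([-2, -1, 1, 2])))
    if counts["H"] < 1:
        counts["H"] = counts["H"] + 2
    out = format_formula(counts)
    if out == formula:
        counts["H"] += 2
        out = format_formula(counts)
    return out
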