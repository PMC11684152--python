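"""Two-group uniqueness tests on peak presence/absence.

A peak is "unique" to a group when it is reliably observed there and absent
from the other group.  Two determinations are provided:

* **Presence/absence thresholds** — a peak is unique to group 1 when its
  observed proportion p1 is at least the presence threshold and p2 is at
  most the absence threshold (and symmetrically for group 2); observed in
  both when both proportions clear the presence threshold.

* **G-test** — a likelihood-ratio test of independence on the 2x2 table of
  (observed, missing) sample counts per group,

      G = 2 * sum O * ln(O / E),

  with expected counts from the table margins, divided by the Williams
  small-sample correction factor

      q = 1 + [(n/r1 + n/r2 - 1) * (n/c1 + n/c2 - 1)] / (6 n),

  and referred to a chi-square distribution with 1 degree of freedom.  Each
  group must contain at least three samples.  A peak observed in no sample
  or in every sample gives G = 0, p = 1 (degenerate margins).

Labels: ``unique_to_<G1>`` / ``unique_to_<G2>`` when the test rejects at
alpha and the better-observed group also clears the presence threshold;
``observed_in_both`` when the test does not reject and the peak appears in
both groups; otherwise ``insufficient``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import FTMSDataset, GroupDefinition, ValidationError

LABEL_BOTH = "observed_in_both"
LABEL_INSUFFICIENT = "insufficient"


@dataclass(frozen=True)
class ComparisonConfig:
    """Thresholds and significance level for a two-group comparison.

    The defaults — a peak must be seen in at least half the samples of one
    group (``pres_threshold`` 0.5) and never in the other
    (``absn_threshold`` 0) — are a deliberate, strict convention; loosen the
    absence threshold for noisier data.
    """

    pres_threshold: float = 0.5
    absn_threshold: float = 0.0
    alpha: float = 0.05
    method: str = "gtest"

    def __post_init__(self):
        if not 0 <= self.absn_threshold < self.pres_threshold <= 1:
            raise ValidationError(
                "need 0 <= absn_threshold < pres_threshold <= 1"
            )
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.method not in ("threshold", "gtest"):
            raise ValidationError(f"unknown comparison method {self.method!r}")


@dataclass
class ComparisonResult:
    """Per-peak uniqueness determination for one two-group comparison."""

    group1: str
    group2: str
    method: str
    config: ComparisonConfig
    table: pd.DataFrame  # per-peak columns; see threshold/gtest builders

    def label_counts(self) -> dict[str, int]:
        return self.table["uniqueness"].value_counts().to_dict()


def _group_presence(ds: FTMSDataset, groups: GroupDefinition,
                    g1: str, g2: str) -> tuple[pd.DataFrame, int, int]:
    groups.validate_against(ds)
    s1, s2 = groups.samples_in(g1), groups.samples_in(g2)
    if not s1 or not s2:
        raise ValidationError("both groups must contain at least one sample")
    obs = ds.observed_mask()
    out = pd.DataFrame(index=ds.peak_table.index)
    out["n_obs_g1"] = obs[s1].sum(axis=1).astype(int)
    out["n_obs_g2"] = obs[s2].sum(axis=1).astype(int)
    out["p_g1"] = out["n_obs_g1"] / len(s1)
    out["p_g2"] = out["n_obs_g2"] / len(s2)
    return out, len(s1), len(s2)


def _threshold_labels(p1, p2, n1obs, n2obs, g1, g2, cfg) -> np.ndarray:
    labels = np.full(len(p1), LABEL_INSUFFICIENT, dtype=object)
    labels[(p1 >= cfg.pres_threshold) & (p2 <= cfg.absn_threshold)] = f"unique_to_{g1}"
    labels[(p2 >= cfg.pres_threshold) & (p1 <= cfg.absn_threshold)] = f"unique_to_{g2}"
    labels[(p1 >= cfg.pres_threshold) & (p2 >= cfg.pres_threshold)] = LABEL_BOTH
    return labels


def threshold_uniqueness(ds: FTMSDataset, groups: GroupDefinition,
                         group1: str, group2: str,
                         cfg: ComparisonConfig | None = None) -> ComparisonResult:
    """Label peaks unique to either group by presence/absence proportions."""
    cfg = cfg or ComparisonConfig(method="threshold")
    tab, n1, n2 = _group_presence(ds, groups, group1, group2)
    tab["n_g1"], tab["n_g2"] = n1, n2
    tab["uniqueness"] = _threshold_labels(
        tab["p_g1"].to_numpy(), tab["p_g2"].to_numpy(),
        tab["n_obs_g1"].to_numpy(), tab["n_obs_g2"].to_numpy(),
        group1, group2, cfg)
    return ComparisonResult(group1, group2, "threshold", cfg, tab)


def gtest_statistics(a: np.ndarray, n1: int, b: np.ndarray, n2: int):
    """Vectorized Williams-corrected G statistics for 2x2 presence tables.

    ``a``/``b`` are observed-sample counts per peak in groups of size
    ``n1``/``n2``.  Returns (G, q, G_corrected, p).  Degenerate margins
    (a + b == 0 or a + b == n1 + n2) give G = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = float(n1 + n2)
    # 2x2 cells: observed / missing per group
    cells = np.stack([a, n1 - a, b, n2 - b], axis=-1)
    c1 = a + b            # column total: observed
    c2 = n - c1           # column total: missing
    e = np.stack([n1 * c1 / n, n1 * c2 / n, n2 * c1 / n, n2 * c2 / n], axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(cells > 0, cells * np.log(cells / e), 0.0)
    g = 2.0 * terms.sum(axis=-1)
    degenerate = (c1 == 0) | (c2 == 0)
    g = np.where(degenerate, 0.0, g)
    g = np.maximum(g, 0.0)  # guard tiny negative round-off
    with np.errstate(divide="ignore", invalid="ignore"):
        q = 1.0 + ((n / n1 + n / n2 - 1.0) * (n / c1 + n / c2 - 1.0)) / (6.0 * n)
    q = np.where(degenerate, 1.0, q)
    g_corr = g / q
    p = stats.chi2.sf(g_corr, df=1)
    p = np.where(degenerate, 1.0, p)
    return g, q, g_corr, p


def gtest_uniqueness(ds: FTMSDataset, groups: GroupDefinition,
                     group1: str, group2: str,
                     cfg: ComparisonConfig | None = None,
                     bh_adjust: bool = False) -> ComparisonResult:
    """Label peaks unique to either group with the Williams-corrected G-test.

    Requires at least three samples per group.  When ``bh_adjust`` is set, a
    Benjamini–Hochberg adjusted p-value column is appended (labels still use
    the raw p-values, matching the default no-correction behaviour).
    """
    cfg = cfg or ComparisonConfig(method="gtest")
    tab, n1, n2 = _group_presence(ds, groups, group1, group2)
    if n1 < 3 or n2 < 3:
        raise ValidationError(
            "the G-test requires that groups consist of at least three samples "
            f"each; got {n1} and {n2}"
        )
    g, q, g_corr, p = gtest_statistics(tab["n_obs_g1"].to_numpy(), n1,
                                       tab["n_obs_g2"].to_numpy(), n2)
    tab["n_g1"], tab["n_g2"] = n1, n2
    tab["G"], tab["williams_q"], tab["G_corrected"], tab["p_value"] = g, q, g_corr, p
    p1, p2 = tab["p_g1"].to_numpy(), tab["p_g2"].to_numpy()
    labels = np.full(len(tab), LABEL_INSUFFICIENT, dtype=object)
    signif = p <= cfg.alpha
    bigger1 = p1 > p2
    labels[signif & bigger1 & (p1 >= cfg.pres_threshold)] = f"unique_to_{group1}"
    labels[signif & ~bigger1 & (p2 > p1) & (p2 >= cfg.pres_threshold)] = f"unique_to_{group2}"
    labels[~signif & (p1 > 0) & (p2 > 0)] = LABEL_BOTH
    tab["uniqueness"] = labels
    if bh_adjust:
        tab["p_adjusted"] = _benjamini_hochberg(p)
    return ComparisonResult(group1, group2, "gtest", cfg, tab)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def comparison_csv(result: ComparisonResult) -> pd.DataFrame:
    """Flat per-peak table for export (mirrors the uniqueness-test download)."""
    out = result.table.copy()
    out.insert(0, "group2", result.group2)
    out.insert(0, "group1", result.group1)
    out.insert(0, "method", result.method)
    return out
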