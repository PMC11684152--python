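"""Sample ordination: pairwise distances and principal coordinate analysis.

PCoA (classical multidimensional scaling) embeds samples from a distance
matrix: the squared distances are double-centered, B = -1/2 J D^2 J, and the
eigendecomposition of B gives coordinates sqrt(lambda_i) * v_i.  Negative
eigenvalues — which arise for non-euclidean metrics such as Bray–Curtis —
are dropped from both the coordinates and the variance-explained (R^2)
denominator, so the reported R^2 per axis is the positive-eigenvalue
proportion.  Up to the first five axes are returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .dataset import FTMSDataset, ValidationError

#: Supported metrics and the scipy pdist names behind them.
METRICS = {
    "euclidean": "euclidean",
    "manhattan": "cityblock",
    "bray_curtis": "braycurtis",
    "jaccard_presence": "jaccard",
}

MAX_AXES = 5


def distance_matrix(ds: FTMSDataset, metric: str = "bray_curtis") -> pd.DataFrame:
    """Pairwise sample distances over the peak table.

    Missing cells count as zero abundance for abundance-based metrics;
    ``jaccard_presence`` works on presence/absence regardless of scale.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if ds.n_samples < 3:
        raise ValidationError("ordination needs at least three samples")
    if not ds.missing_encoded:
        raise ValidationError("encode missing values before computing distances")
    if metric == "jaccard_presence":
        x = ds.peak_table.notna().to_numpy(dtype=bool).T
    else:
        x = ds.peak_table.fillna(0.0).to_numpy(dtype=float).T
    d = squareform(pdist(x, metric=METRICS[metric]))
    return pd.DataFrame(d, index=ds.sample_ids, columns=ds.sample_ids)


@dataclass
class PCoAResult:
    """Sample coordinates on up to five principal coordinates."""

    coordinates: pd.DataFrame  # samples x axes (PCo1..PCo5)
    eigenvalues: np.ndarray    # all eigenvalues, descending
    r_squared: np.ndarray      # variance-explained per returned axis
    metric: str


def pcoa(dist: pd.DataFrame, metric: str = "unknown",
         n_axes: int = MAX_AXES) -> PCoAResult:
    """Classical scaling of a symmetric zero-diagonal distance matrix."""
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValidationError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = eigh((b + b.T) / 2)   # ascending
    evals, evecs = evals[::-1], evecs[:, ::-1]
    tol = max(abs(evals[0]), 1.0) * 1e-12
    pos = evals > tol
    if not pos.any():
        raise ValidationError("no positive eigenvalue: degenerate distance matrix")
    k = min(n_axes, int(pos.sum()))
    lam = evals[:k]
    coords = evecs[:, :k] * np.sqrt(lam)
    r2 = lam / evals[pos].sum()
    labels = (list(dist.index) if isinstance(dist, pd.DataFrame)
              else [f"s{i}" for i in range(n)])
    cdf = pd.DataFrame(coords, index=labels,
                       columns=[f"PCo{i + 1}" for i in range(k)])
    return PCoAResult(cdf, eigenvalues=evals, r_squared=r2, metric=metric)


def pcoa_table(result: PCoAResult) -> pd.DataFrame:
    """Coordinates plus an R^2 header row-friendly attribute table for export."""
    out = result.coordinates.copy()
    out.attrs["r_squared"] = list(map(float, result.r_squared))
    out.attrs["metric"] = result.metric
    return out
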