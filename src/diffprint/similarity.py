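"""Feature-wise distribution similarity between media.

For every fingerprint feature and every pair of class labels, four
metrics compare the per-class feature distributions:

* area overlap — integral of the pointwise minimum of the two Gaussian
  KDE curves on a shared grid (1 for identical distributions);
* symmetrized (Jeffreys) Kullback-Leibler divergence of the shared-bin
  probability histograms (0 for identical);
* cosine similarity of the histogram vectors (1 for identical);
* Euclidean distance between the histogram vectors (0 for identical).

Defaults: Scott's-rule KDE bandwidth on a 512-point grid padded by three
pooled bandwidths; 50 shared histogram bins over the pooled range; KL
smoothing epsilon 1e-10 with renormalization.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .types import FEATURE_NAMES

GRID_POINTS = 512
N_BINS = 50
KL_EPS = 1e-10
METRICS = ("area_overlap", "kl_divergence", "cosine_similarity",
           "euclidean_distance")


def kde_density(values_by_class: dict, grid: np.ndarray | None = None,
                grid_points: int = GRID_POINTS):
    """Gaussian KDEs of several samples evaluated on one shared grid.

    The grid spans the pooled range padded by three pooled (Scott)
    bandwidths.  Each returned density integrates to ~1 on the grid
    (trapezoid rule).  Zero-variance samples get a flagged delta-like
    density (narrow Gaussian spanning one grid cell).
    Returns ``(grid, {class: density})``.
    """
    for cls, v in values_by_class.items():
        if len(np.asarray(v)) < 5:
            raise ValueError(f"class {cls!r}: need >= 5 values for a KDE")
    samples = {c: np.asarray(v, dtype=float) for c, v in values_by_class.items()}
    bandwidths = [len(v) ** (-1 / 5) * v.std(ddof=1) for v in samples.values()]
    pad = 3.0 * max(max(bandwidths), 1e-12)
    lo = min(v.min() for v in samples.values()) - pad
    hi = max(v.max() for v in samples.values()) + pad
    if grid is None:
        grid = np.linspace(lo, hi, grid_points)
    elif grid[0] > lo or grid[-1] < hi:
        raise ValueError("grid too narrow for the pooled sample range")
    densities = {}
    for cls, v in samples.items():
        if v.std() == 0:
            # delta-like stand-in for a degenerate sample
            width = (grid[-1] - grid[0]) / len(grid)
            d = np.exp(-0.5 * ((grid - v[0]) / width) ** 2)
            densities[cls] = d / np.trapezoid(d, grid)
        else:
            densities[cls] = gaussian_kde(v)(grid)  # Scott's rule
    return grid, densities


def area_overlap(f1: np.ndarray, f2: np.ndarray, grid: np.ndarray) -> float:
    """Shared area under two densities: trapezoidal integral of min(f1, f2)."""
    return float(np.trapezoid(np.minimum(f1, f2), grid))


def _as_probability_histograms(values1, values2, bins: int = N_BINS):
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if len(v1) == 0 or len(v2) == 0:
        raise ValueError("empty sample")
    lo = min(v1.min(), v2.min())
    hi = max(v1.max(), v2.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, bins + 1)
    P = np.histogram(v1, bins=edges)[0].astype(float)
    Q = np.histogram(v2, bins=edges)[0].astype(float)
    return P / P.sum(), Q / Q.sum()


def histogram_vector_metrics(P: np.ndarray, Q: np.ndarray,
                             symmetric_kl: bool = True):
    """(KL, cosine, Euclidean) between two probability vectors.

    KL uses epsilon-smoothing (1e-10, renormalized) and is symmetrized
    (Jeffreys) by default so pair results are order-free.
    """
    Ps = (P + KL_EPS) / (P + KL_EPS).sum()
    Qs = (Q + KL_EPS) / (Q + KL_EPS).sum()
    kl_pq = float(np.sum(Ps * np.log(Ps / Qs)))
    kl = 0.5 * (kl_pq + float(np.sum(Qs * np.log(Qs / Ps)))) if symmetric_kl else kl_pq
    cos = float(P @ Q / (np.linalg.norm(P) * np.linalg.norm(Q)))
    eucl = float(np.linalg.norm(P - Q))
    return kl, cos, eucl


def histogram_metrics(values1, values2, bins: int = N_BINS,
                      symmetric_kl: bool = True):
    """(KL, cosine, Euclidean) between two samples on shared histogram bins."""
    P, Q = _as_probability_histograms(values1, values2, bins)
    return histogram_vector_metrics(P, Q, symmetric_kl)


def similarity_matrix(table: pd.DataFrame, label_col: str = "medium",
                      features: list | None = None, bins: int = N_BINS,
                      grid_points: int = GRID_POINTS,
                      include_self_pairs: bool = False) -> pd.DataFrame:
    """All four metrics for every feature x class pair.

    Returns a long-format DataFrame (feature, class_a, class_b,
    area_overlap, kl_divergence, cosine_similarity, euclidean_distance).
    Feature values that are NaN are dropped per class; features with
    fewer than 5 valid values in any class are skipped.  Self pairs
    (internal sanity controls) are included on request.
    """
    features = list(features or FEATURE_NAMES)
    classes = sorted(table[label_col].unique())
    pairs = list(combinations(classes, 2))
    if include_self_pairs:
        pairs = [(c, c) for c in classes] + pairs
    rows = []
    for feat in features:
        groups = {c: table.loc[table[label_col] == c, feat].dropna().to_numpy()
                  for c in classes}
        if any(len(v) < 5 for v in groups.values()):
            continue
        grid, dens = kde_density(groups, grid_points=grid_points)
        for a, b in pairs:
            kl, cos, eucl = histogram_metrics(groups[a], groups[b], bins)
            rows.append({
                "feature": feat, "class_a": a, "class_b": b,
                "area_overlap": area_overlap(dens[a], dens[b], grid),
                "kl_divergence": kl, "cosine_similarity": cos,
                "euclidean_distance": eucl,
            })
    return pd.DataFrame(rows)


def aggregate_similarity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean of each metric across features, per class pair."""
    agg = (matrix.groupby(["class_a", "class_b"])[list(METRICS)]
           .mean().reset_index())
    agg["n_features"] = (matrix.groupby(["class_a", "class_b"])
                         .size().to_numpy())
    return agg


def overlap_difference_ranking(matrix: pd.DataFrame, reference: str = "PNCM",
                               candidate_a: str = "PACM-HEC",
                               candidate_b: str = "PACM-PAA",
                               top_k: int = 5) -> pd.DataFrame:
    """Rank features by how much more a feature overlaps reference-vs-A
    than reference-vs-B.

    delta(feature) = overlap(reference, candidate_a)
                   - overlap(reference, candidate_b); the top_k largest
    positive deltas identify the features driving the reference's greater
    similarity to candidate_a.
    """
    def pair_overlap(a, b):
        mask = (((matrix["class_a"] == a) & (matrix["class_b"] == b))
                | ((matrix["class_a"] == b) & (matrix["class_b"] == a)))
        return matrix[mask].set_index("feature")["area_overlap"]

    ov_a = pair_overlap(reference, candidate_a)
    ov_b = pair_overlap(reference, candidate_b)
    delta = (ov_a - ov_b).dropna().sort_values(ascending=False)
    out = delta.head(top_k).rename("delta_overlap").reset_index()
    out["overlap_ref_a"] = ov_a[out["feature"]].to_numpy()
    out["overlap_ref_b"] = ov_b[out["feature"]].to_numpy()
    return out
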