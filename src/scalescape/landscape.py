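"""Fitness-landscape characterization by hierarchical clustering of scales.

Ensembles of scales selected at a common matching level <R> are clustered
agglomeratively under the correlation distance 1 - R (R = Pearson correlation
between two scales' 20 weights; distance in [0, 2]). Cutting the dendrogram
at a distance cutoff and counting flat clusters, per level, yields the
cluster-count landscape: a funnel-shaped fitness space shows many clusters
at weak matching levels collapsing to one basin near the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .mc import MCTrajectory, select_scale_at_level
from .scales import AffinityScale, scale_correlation

LINKAGES = ("average", "complete", "single")


def scale_distance(s1: AffinityScale, s2: AffinityScale) -> float:
    """Correlation distance 1 - R between two scales; lower = more similar."""
    return 1.0 - scale_correlation(s1, s2)


def distance_matrix(scales: Sequence[AffinityScale]) -> np.ndarray:
    """Condensed pairwise 1 - R distance matrix (scipy pdist layout)."""
    W = np.stack([s.vector for s in scales])
    Wc = W - W.mean(axis=1, keepdims=True)
    norms = np.sqrt((Wc * Wc).sum(axis=1))
    ok = norms > 1e-12
    norms = np.where(ok, norms, 1.0)
    corr = (Wc / norms[:, None]) @ (Wc / norms[:, None]).T
    corr[~ok, :] = 0.0
    corr[:, ~ok] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


def cluster_scales(
    scales: Sequence[AffinityScale], method: str = "average"
) -> np.ndarray:
    """Agglomerative clustering on 1 - R distances; returns a scipy linkage matrix.

    Average linkage is the default; the qualitative funnel picture is robust
    to the linkage choice but the absolute cluster counts are not, so the
    method is always carried in output metadata.
    """
    if len(scales) < 2:
        raise ValueError("need at least 2 scales to cluster")
    if method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    return linkage(distance_matrix(scales), method=method)


def n_clusters(dendrogram: np.ndarray, cutoff: float) -> int:
    """Number of flat clusters with all within-cluster merge heights <= cutoff."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    labels = fcluster(dendrogram, t=cutoff, criterion="distance")
    return int(labels.max())


@dataclass(frozen=True)
class LandscapeLevel:
    """Cluster counts for the scale ensemble selected at one matching level."""

    level: float
    n_scales: int
    cluster_counts: dict[float, int]


def landscape_table(
    trajectories: Sequence[MCTrajectory],
    levels: Sequence[float],
    cutoffs: Sequence[float],
    n_required: int = 1000,
    tolerance: float = 0.01,
    method: str = "average",
) -> pd.DataFrame:
    """Cluster-count landscape over (level, cutoff).

    Per level, one scale is taken from each independent run (the accepted
    scale with <R> closest to the level, within ``tolerance``); levels
    reached by fewer than ``n_required`` runs are dropped — fast-converging
    searches may simply never visit a weak matching level. Columns:
    level, n_scales, cutoff, n_clusters, linkage.
    """
    if not trajectories:
        raise ValueError("no trajectories")
    if not list(levels) or not list(cutoffs):
        raise ValueError("levels and cutoffs must be nonempty")
    rows = []
    for level in levels:
        scales = [
            s
            for t in trajectories
            if (s := select_scale_at_level(t, level, tolerance)) is not None
        ]
        if len(scales) < n_required:
            continue
        if len(scales) == 1:
            counts = {float(c): 1 for c in cutoffs}
        else:
            Z = cluster_scales(scales, method=method)
            counts = {float(c): n_clusters(Z, c) for c in cutoffs}
        for cutoff, count in counts.items():
            rows.append(
                {
                    "level": level,
                    "n_scales": len(scales),
                    "cutoff": cutoff,
                    "n_clusters": count,
                    "linkage": method,
                }
            )
    return pd.DataFrame(rows, columns=["level", "n_scales", "cutoff", "n_clusters", "linkage"])
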