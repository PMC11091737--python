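"""Outlier-array detection via inter-array correlation and hierarchical clustering.

Samples from the same tissue are expected to correlate above ~0.9 across
CpGs; arrays falling well below that are technical outliers. Clustering uses
average linkage (by default) on the dissimilarity d = 1 - correlation, with
a static branch cut to assign cluster labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .core import BetaMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterTree",
    "interarray_correlation",
    "cluster_samples",
    "static_cut",
    "flag_outliers",
    "MIN_SHARED_PROBES",
]

# Pairwise-complete correlations on fewer shared probes than this are too
# noisy to trust for QC decisions.
MIN_SHARED_PROBES = 1000


@dataclass
class ClusterTree:
    """Agglomeration order and heights from hierarchical clustering."""

    merges: np.ndarray  # scipy linkage matrix, (n-1, 4)
    sample_ids: list[str]
    linkage_name: str

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.sample_ids[i] for i in leaves_list(self.merges)]


def interarray_correlation(
    betas: BetaMatrix, min_shared: int = MIN_SHARED_PROBES
) -> pd.DataFrame:
    """Samples x samples Pearson correlation across CpGs.

    Missing betas are handled pairwise-complete; a pair sharing fewer than
    ``min_shared`` observed probes is an error (the estimate would be too
    noisy). A zero-variance sample is reported by name.
    """
    if betas.n_samples < 2:
        raise ValidationError("need at least 2 samples for inter-array correlation")
    values = betas.values
    has_missing = np.isnan(values).any()

    degenerate = []
    for j, sid in enumerate(betas.sample_ids):
        col = values[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0 or np.ptp(col) == 0:
            degenerate.append(sid)
    if degenerate:
        raise ValidationError(
            f"sample(s) with zero variance across probes (correlation undefined): {degenerate[:10]}"
        )

    frame = betas.to_frame()
    if has_missing:
        shared = (~frame.isna()).astype(int).T @ (~frame.isna()).astype(int)
        low = shared < min_shared
        np.fill_diagonal(low.values, False)
        if low.to_numpy().any():
            i, j = np.argwhere(low.to_numpy())[0]
            raise ValidationError(
                f"samples {frame.columns[i]!r} and {frame.columns[j]!r} share only "
                f"{shared.iloc[i, j]} observed probes (< {min_shared})"
            )
        corr = frame.corr(method="pearson", min_periods=min_shared)
    else:
        corr = pd.DataFrame(
            np.corrcoef(values, rowvar=False), index=frame.columns, columns=frame.columns
        )
    out = corr.to_numpy()
    np.fill_diagonal(out, 1.0)
    out = np.clip((out + out.T) / 2.0, -1.0, 1.0)
    return pd.DataFrame(out, index=frame.columns, columns=frame.columns)


def _dissimilarity(corr: pd.DataFrame) -> np.ndarray:
    mat = corr.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-12):
        raise ValidationError("correlation matrix must be square and symmetric")
    d = 1.0 - mat
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0
    return d


def cluster_samples(corr: pd.DataFrame, linkage_name: str = "average") -> ClusterTree:
    """Agglomerative clustering on d = 1 - correlation. Deterministic."""
    if linkage_name not in ("average", "complete", "single"):
        raise ValidationError(f"unsupported linkage {linkage_name!r}")
    d = _dissimilarity(corr)
    condensed = squareform(d, checks=False)
    merges = linkage(condensed, method=linkage_name)
    return ClusterTree(merges=merges, sample_ids=list(corr.index.astype(str)), linkage_name=linkage_name)


def static_cut(tree: ClusterTree, height: float, min_cluster_size: int = 1) -> dict[str, int]:
    """Cut the dendrogram at a fixed height.

    Clusters are the connected components merged strictly below the cut;
    components smaller than ``min_cluster_size`` get label 0 (outlier /
    unassigned). Surviving clusters are numbered 1, 2, ... in order of first
    appearance in the sample list.
    """
    if height < 0:
        raise ValidationError(f"cut height must be >= 0, got {height}")
    n = len(tree.sample_ids)
    # Union components over merges below the cut height.
    parent = list(range(2 * n - 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for idx, (a, b, h, _) in enumerate(tree.merges):
        node = n + idx
        if h <= height:
            parent[find(int(a))] = node
            parent[find(int(b))] = node
            parent[node] = node
    roots = [find(i) for i in range(n)]
    sizes: dict[int, int] = {}
    for r in roots:
        sizes[r] = sizes.get(r, 0) + 1
    labels: dict[str, int] = {}
    next_label = 1
    assigned: dict[int, int] = {}
    for sid, r in zip(tree.sample_ids, roots):
        if sizes[r] < min_cluster_size:
            labels[sid] = 0
        else:
            if r not in assigned:
                assigned[r] = next_label
                next_label += 1
            labels[sid] = assigned[r]
    return labels


def flag_outliers(
    betas: BetaMatrix,
    corr_threshold: float = 0.9,
    min_shared: int = MIN_SHARED_PROBES,
) -> pd.DataFrame:
    """Flag samples whose MEAN correlation to all other samples falls below
    the threshold. Returns a DataFrame (sample_id, mean_corr, max_corr)
    sorted ascending by mean_corr; empty when nothing is flagged."""
    if betas.n_samples < 3:
        raise ValidationError("need at least 3 samples to flag outliers")
    corr = interarray_correlation(betas, min_shared=min_shared)
    mat = corr.to_numpy()
    np.fill_diagonal(mat, np.nan)
    mean_corr = np.nanmean(mat, axis=0)
    max_corr = np.nanmax(mat, axis=0)
    flagged = pd.DataFrame(
        {"sample_id": corr.index, "mean_corr": mean_corr, "max_corr": max_corr}
    )
    flagged = flagged[flagged["mean_corr"] < corr_threshold]
    return flagged.sort_values("mean_corr").reset_index(drop=True)
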