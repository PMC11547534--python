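"""k-means (k = 2) separation of features into sulfated / non-sulfated.

Eight MS/MS-derived parameters per feature — the six diagnostic-channel
intensities plus IR and MA — are z-scored column-wise and clustered with
Lloyd's algorithm.  The cluster whose centroid has the larger mean of the
standardized IR and MA columns is labelled *sulfated* (cluster label 1);
the other is *non-sulfated* (label 2).  Features without any MS/MS
spectrum enter as all-zero rows so that downstream counts stay
well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fragment_annotation import DIAGNOSTIC_LABELS, SulfateProfile

__all__ = ["ParameterMatrix", "ClusterAssignment", "build_parameter_matrix", "kmeans_two"]

#: fixed column order of the parameter matrix
PARAMETER_COLUMNS: Tuple[str, ...] = DIAGNOSTIC_LABELS + ("IR", "MA")


@dataclass
class ParameterMatrix:
    """Standardized features x 8 matrix (zero mean / unit variance columns;
    constant columns are left at 0).  ``raw`` keeps the unstandardized
    values for reporting."""

    values: np.ndarray
    feature_ids: Tuple[str, ...]
    columns: Tuple[str, ...]
    raw: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.feature_ids), columns=list(self.columns))


def build_parameter_matrix(
    profiles: Mapping[str, Optional[SulfateProfile]],
    feature_ids: Sequence[str],
) -> ParameterMatrix:
    """Assemble and z-score the 8-parameter matrix.

    ``profiles`` maps feature ID to its :class:`SulfateProfile` (features
    missing from the mapping, or mapped to None, get all-zero rows).
    """
    raw = np.zeros((len(feature_ids), len(PARAMETER_COLUMNS)))
    for i, fid in enumerate(feature_ids):
        p = profiles.get(fid)
        if p is None:
            continue
        for j, lab in enumerate(DIAGNOSTIC_LABELS):
            raw[i, j] = p.channels.get(lab, 0.0)
        raw[i, -2] = p.ir
        raw[i, -1] = p.ma
    std = raw.std(axis=0, ddof=0)
    mean = raw.mean(axis=0)
    z = np.zeros_like(raw)
    nonconst = std > 0
    z[:, nonconst] = (raw[:, nonconst] - mean[nonconst]) / std[nonconst]
    return ParameterMatrix(z, tuple(feature_ids), PARAMETER_COLUMNS, raw)


@dataclass
class ClusterAssignment:
    """Per-feature cluster label (1 = sulfated, 2 = non-sulfated)."""

    labels: pd.Series  # feature_id -> 1 | 2
    centroids: np.ndarray  # 2 x 8, row 0 = sulfated centroid
    wcss: float

    @property
    def sulfated_ids(self) -> pd.Index:
        return self.labels.index[self.labels == 1]

    @property
    def non_sulfated_ids(self) -> pd.Index:
        return self.labels.index[self.labels == 2]


def kmeans_two(m: ParameterMatrix, seed: int = 1, restarts: int = 10) -> ClusterAssignment:
    """k-means with k=2 on the standardized parameter matrix.

    Lloyd's algorithm, best of ``restarts`` random initializations by
    within-cluster sum of squares, deterministic for a fixed seed.  The
    semantic labelling depends only on the centroids: the cluster with the
    larger mean standardized (IR + MA) is sulfated.
    """
    X = m.values
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("k-means needs at least 2 distinct rows")
    from sklearn.cluster import KMeans

    km = KMeans(
        n_clusters=2,
        n_init=restarts,
        init="random",
        algorithm="lloyd",
        random_state=seed,
    ).fit(X)
    ir_col = m.columns.index("IR")
    ma_col = m.columns.index("MA")
    score = km.cluster_centers_[:, [ir_col, ma_col]].mean(axis=1)
    sulfated_cluster = int(np.argmax(score))
    labels = np.where(km.labels_ == sulfated_cluster, 1, 2)
    centroids = km.cluster_centers_[[sulfated_cluster, 1 - sulfated_cluster]]
    return ClusterAssignment(
        labels=pd.Series(labels, index=list(m.feature_ids), name="cluster"),
        centroids=centroids,
        wcss=float(km.inertia_),
    )
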