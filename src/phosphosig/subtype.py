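"""Unsupervised two-group assignment of ER-negative tumors and the PCA view.

ER-negative breast tumors split into an ERBB2-enriched and a basal-like
enriched cluster under hierarchical clustering on an intrinsic probe list;
the molecular label is assigned afterwards by which cluster is richer in
clinically ERBB2-positive samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .errors import DegenerateDataError, ValidationError

MOLECULAR_ERBB2 = "molecular_ERBB2"
BASAL_LIKE = "basal_like"


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample_id -> cluster label (ints until labeled)
    merge_heights: np.ndarray
    erbb2_fractions: dict | None = None  # label -> fraction of clinical ERBB2+


def hierarchical_cluster_two_groups(matrix: pd.DataFrame, probe_list: list[str] | None = None) -> ClusterAssignment:
    """Complete-linkage euclidean clustering of sample columns, cut at k=2."""
    if probe_list is not None:
        missing = [p for p in probe_list if p not in matrix.index]
        if missing:
            raise ValidationError(f"probe list entries absent from matrix: {missing[:5]}")
        if not probe_list:
            raise ValidationError("probe list must be non-empty")
        matrix = matrix.loc[probe_list]
    if matrix.shape[1] < 3:
        raise ValidationError("clustering needs at least 3 samples")
    Z = linkage(matrix.values.T, method="complete", metric="euclidean")
    flat = fcluster(Z, t=2, criterion="maxclust")
    labels = pd.Series(flat, index=matrix.columns, name="cluster")
    return ClusterAssignment(labels=labels, merge_heights=Z[:, 2].copy())


def label_clusters_by_erbb2(assignment: ClusterAssignment, clinical: pd.DataFrame) -> ClusterAssignment:
    """Name the cluster richer in clinically ERBB2+ samples ``molecular_ERBB2``."""
    status = clinical.set_index("sample_id")["erbb2_status"]
    missing = [s for s in assignment.labels.index if s not in status.index]
    if missing:
        raise ValidationError(f"clinical table lacks samples: {missing[:5]}")
    status = status.reindex(assignment.labels.index)
    if (status == "pos").sum() == 0:
        raise ValidationError("no clinically ERBB2-positive samples to anchor the labeling")
    fractions = {}
    for cluster in sorted(assignment.labels.unique()):
        members = status[assignment.labels == cluster]
        fractions[cluster] = float((members == "pos").mean())
    clusters = sorted(fractions, key=lambda c: (-fractions[c], c))
    if len(clusters) == 2 and np.isclose(fractions[clusters[0]], fractions[clusters[1]]):
        raise DegenerateDataError(
            "both clusters have the same ERBB2+ fraction; assign labels manually"
        )
    mapping = {clusters[0]: MOLECULAR_ERBB2}
    for c in clusters[1:]:
        mapping[c] = BASAL_LIKE
    labeled = assignment.labels.map(mapping)
    labeled.name = "subtype"
    return ClusterAssignment(
        labels=labeled,
        merge_heights=assignment.merge_heights,
        erbb2_fractions={mapping[c]: f for c, f in fractions.items()},
    )


def pca_scores(matrix: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Sample scores on the top principal components of probe-centered data."""
    if matrix.shape[1] < 3:
        raise ValidationError("PCA view needs at least 3 samples")
    n_components = min(n_components, matrix.shape[1] - 1, matrix.shape[0])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix.values.T)  # samples x components; centers probes
    return pd.DataFrame(
        scores,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
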