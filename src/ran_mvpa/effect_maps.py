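"""SVM weight maps ("effect maps") and cluster-extent thresholding.

A linear SVM fit on the full sample yields one signed weight per voxel
feature; projecting the weights back to their (i, j, k) coordinates gives a
3D effect map whose sign convention follows the positive class (positive
weight = evidence for the positive class).  Clusters are extracted by
binarizing |w| at a magnitude cutoff, labeling connected components, and
keeping components at or above a minimum extent — by default |w| >= 0.02
and >= 50 voxels under 26-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.measure import label as cc_label
from sklearn.svm import SVC

from .atlas import VoxelFeatureMatrix
from .classify import SvmConfig

__all__ = [
    "ClusterThresholdConfig",
    "Cluster",
    "fit_weight_map",
    "threshold_clusters",
]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}  # face / edge / corner adjacency


@dataclass(frozen=True)
class ClusterThresholdConfig:
    """Magnitude and extent thresholds for weight-map clusters."""

    min_extent_voxels: int = 50
    min_abs_weight: float = 0.02
    connectivity: int = 26
    sign_separated: bool = False  # cluster positive and negative weights apart

    def __post_init__(self) -> None:
        if self.min_extent_voxels < 1:
            raise ValueError("min_extent_voxels must be >= 1")
        if self.min_abs_weight < 0:
            raise ValueError("min_abs_weight must be >= 0")
        if self.connectivity not in _CONNECTIVITY:
            raise ValueError("connectivity must be one of 6, 18, 26")


@dataclass(frozen=True)
class Cluster:
    """One surviving connected component of the thresholded weight map."""

    voxels: np.ndarray  # (n, 3) coordinates, lexicographic order
    size: int
    mean_weight: float
    peak_abs_weight: float
    peak_voxel: tuple[int, int, int]
    bounding_box: tuple[tuple[int, int], ...]  # per-axis (min, max) inclusive
    dominant_sign: int  # +1 / -1 by the sign of the summed weight


def fit_weight_map(
    voxel_feats: VoxelFeatureMatrix | np.ndarray,
    labels: Sequence[str] | np.ndarray,
    svm_config: SvmConfig | None = None,
    grid_shape: tuple[int, int, int] | None = None,
    coords: np.ndarray | None = None,
    positive_class: str | None = None,
) -> np.ndarray:
    """Full-sample linear SVM weight vector projected into voxel space.

    Every voxel outside the feature set is exactly 0.  The map is oriented
    so positive weights are associated with ``positive_class`` (default:
    the lexicographically last class, matching the survivor/control
    convention where "survivor" sorts after "control").
    """
    svm_config = svm_config or SvmConfig()
    if isinstance(voxel_feats, VoxelFeatureMatrix):
        X = voxel_feats.values
        coords = voxel_feats.coords
    else:
        X = np.asarray(voxel_feats, dtype=float)
        if coords is None:
            raise ValueError("coords are required with a bare feature array")
    if grid_shape is None:
        raise ValueError("grid_shape is required")
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 samples per class")
    if np.any(coords.max(axis=0) >= np.asarray(grid_shape)):
        raise ValueError("feature coordinates fall outside the grid")
    if positive_class is None:
        positive_class = str(classes[-1])
    clf = SVC(kernel="linear", C=svm_config.C)
    clf.fit(X, y)
    w = clf.coef_.ravel()
    # sklearn orients coef_ toward classes_[1]; flip if that is not the
    # requested positive class
    if str(clf.classes_[1]) != str(positive_class):
        w = -w
    wmap = np.zeros(grid_shape, dtype=float)
    wmap[coords[:, 0], coords[:, 1], coords[:, 2]] = w
    return wmap


def _component_clusters(
    weight_map: np.ndarray, mask: np.ndarray, config: ClusterThresholdConfig
) -> list[Cluster]:
    labeled = cc_label(mask, connectivity=_CONNECTIVITY[config.connectivity])
    out: list[Cluster] = []
    for lab in range(1, labeled.max() + 1):
        voxels = np.argwhere(labeled == lab)
        if voxels.shape[0] < config.min_extent_voxels:
            continue
        w = weight_map[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
        peak = int(np.argmax(np.abs(w)))
        out.append(
            Cluster(
                voxels=voxels,
                size=int(voxels.shape[0]),
                mean_weight=float(w.mean()),
                peak_abs_weight=float(np.abs(w[peak])),
                peak_voxel=tuple(int(c) for c in voxels[peak]),
                bounding_box=tuple(
                    (int(voxels[:, a].min()), int(voxels[:, a].max()))
                    for a in range(3)
                ),
                dominant_sign=1 if w.sum() >= 0 else -1,
            )
        )
    return out


def threshold_clusters(
    weight_map: np.ndarray,
    config: ClusterThresholdConfig | None = None,
) -> list[Cluster]:
    """Connected components of ``|w| >= min_abs_weight`` with sufficient extent.

    By default components are formed on the magnitude image, so a cluster
    may mix signs (its dominant sign is reported); ``sign_separated=True``
    clusters positive and negative weights independently.  Returned sorted
    by size, largest first; an empty list is a valid result.
    """
    config = config or ClusterThresholdConfig()
    wmap = np.asarray(weight_map, dtype=float)
    if wmap.ndim != 3:
        raise ValueError("weight map must be 3D")
    # a zero magnitude cutoff still restricts to the nonzero support
    cutoff = max(config.min_abs_weight, np.finfo(float).tiny)
    if config.sign_separated:
        clusters = _component_clusters(wmap, wmap >= cutoff, config)
        clusters += _component_clusters(wmap, wmap <= -cutoff, config)
    else:
        clusters = _component_clusters(wmap, np.abs(wmap) >= cutoff, config)
    return sorted(clusters, key=lambda c: c.size, reverse=True)
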