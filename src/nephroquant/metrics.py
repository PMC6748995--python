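"""Segmentation scoring against ground truth: bijective centroid matching."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

__all__ = ["MatchResult", "match_centroids", "label_centroids"]


@dataclass(frozen=True)
class MatchResult:
    n_true: int
    n_detected: int
    n_matched: int

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else 0.0

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else 0.0


def label_centroids(labels: np.ndarray) -> np.ndarray:
    """Centroids of labels 1..L as an (L, ndim) array, 0-based pixel coords."""
    n = int(labels.max())
    if n == 0:
        return np.empty((0, labels.ndim))
    return np.asarray(
        ndi.center_of_mass(labels > 0, labels, np.arange(1, n + 1))
    )


def match_centroids(
    detected: np.ndarray, truth: np.ndarray, radius: float
) -> MatchResult:
    """Greedy bijective nearest match of detected to true centroids.

    True centroids are matched to their nearest detected centroid in order of
    increasing distance; each detected centroid is used at most once and
    matches farther than ``radius`` are discarded.
    """
    detected = np.atleast_2d(np.asarray(detected, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if detected.shape[0] == 0 or truth.shape[0] == 0:
        return MatchResult(truth.shape[0], detected.shape[0], 0)
    tree = cKDTree(detected)
    k = min(detected.shape[0], 4)
    dists, idxs = tree.query(truth, k=k)
    dists = np.atleast_2d(dists.T).T
    idxs = np.atleast_2d(idxs.T).T
    candidates = sorted(
        (dists[i, j], i, idxs[i, j])
        for i in range(truth.shape[0])
        for j in range(dists.shape[1])
        if dists[i, j] <= radius
    )
    used_t: set[int] = set()
    used_d: set[int] = set()
    for d, ti, di in candidates:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
    return MatchResult(truth.shape[0], detected.shape[0], len(used_t))
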