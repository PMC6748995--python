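"""Per-nucleus marker quantification and k-means intensity thresholding.

The label mask from segmentation is mapped onto the raw marker channels to
produce one record per nucleus (centroid, size, per-channel mean intensity
and population SD). Per channel, a k-means clustering of the standardized
(mean, SD) intensity features — or mean only — determines the
negative-staining threshold: the cluster with the lowest mean-intensity
center is the negative class and the threshold tau is the midpoint (in raw
AU) between the highest mean intensity assigned to that cluster and the
lowest mean intensity assigned to the next cluster. Cells strictly above tau
are marker-positive; labeled-to-total ratios summarize positivity per image
or pooled across replicate images. The same machinery applied to an EdU
channel yields the proliferating-cell ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from sklearn.cluster import KMeans

from .simulate import ImageStack

__all__ = [
    "ThresholdModel",
    "RatioResult",
    "measure_nuclei",
    "fit_threshold",
    "classify_cells",
    "positive_ratio",
    "proliferation_ratio",
    "DEFAULT_CLASS_NAMES",
]

DEFAULT_CLASS_NAMES = ("negative", "low", "high", "very_high")


@dataclass(frozen=True)
class ThresholdModel:
    """Fitted k-means threshold model for one marker channel.

    ``centers`` are cluster centers in raw feature units, sorted ascending by
    the mean-intensity coordinate. The lowest ``n_negative`` clusters form
    the negative class: the negative/positive boundary sits at the widest
    gap between consecutive clusters' assigned mean intensities, so that a
    dominant unstained population split across several clusters still counts
    as negative. ``threshold`` (tau, AU) is the midpoint of that gap; it is
    ``None`` for a degenerate single-class fit, in which case every cell is
    negative.
    """

    channel: str
    k: int
    feature_mode: str  # "mean_sd" | "mean"
    centers: np.ndarray
    assignments: np.ndarray  # values in 1..k, aligned with the fitted table
    threshold: float | None
    class_names: tuple[str, ...]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    n_negative: int = 1

    @property
    def degenerate(self) -> bool:
        return self.threshold is None


@dataclass(frozen=True)
class RatioResult:
    """Labeled-to-total cell ratio for one channel and scope."""

    condition: str
    channel: str
    positive: int
    total: int

    def __post_init__(self) -> None:
        if not 0 <= self.positive <= self.total:
            raise ValueError("positive count must lie in [0, total]")
        if self.total == 0:
            raise ValueError("ratio undefined for zero nuclei")

    @property
    def ratio(self) -> float:
        return self.positive / self.total

    @property
    def percentage(self) -> float:
        return 100.0 * self.ratio


def measure_nuclei(image: ImageStack, mask: np.ndarray) -> pd.DataFrame:
    """Extract per-nucleus statistics from the raw marker channels.

    Returns one row per label: ``label``, ``size`` (pixels), centroid
    coordinates, and per marker channel ``<name>_mean`` / ``<name>_sd``
    (population SD, i.e. divisor n). Intensities are read from the raw,
    un-preprocessed channels.
    """
    mask = np.asarray(mask)
    if mask.shape != image.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    labels = np.unique(mask)
    labels = labels[labels > 0]
    coord_names = ("z", "y", "x")[-mask.ndim:]
    if labels.size == 0:
        cols = ["label", "size", *coord_names]
        for name in image.marker_names:
            cols += [f"{name}_mean", f"{name}_sd"]
        return pd.DataFrame(columns=cols)

    sizes = ndi.sum_labels(np.ones_like(mask, dtype=np.int64), mask, labels)
    centroids = np.asarray(ndi.center_of_mass(mask > 0, mask, labels))
    table = {"label": labels.astype(int), "size": sizes.astype(int)}
    table.update(dict(zip(coord_names, centroids.T)))
    for name in image.marker_names:
        ch = np.asarray(image[name], dtype=float)
        table[f"{name}_mean"] = ndi.mean(ch, mask, labels)
        table[f"{name}_sd"] = ndi.standard_deviation(ch, mask, labels)
    return pd.DataFrame(table)


def _kmeans_1d_exact(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact 1-D k-means by dynamic programming over sorted values.

    The squared-error-optimal partition of 1-D data is contiguous in sorted
    order, so an O(k n^2) DP finds the global optimum deterministically.
    Returns (assignments in 1..k ascending by cluster mean, centers).
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    c1 = np.concatenate([[0.0], np.cumsum(xs)])
    c2 = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # SSE of xs[i..j] inclusive, vectorized over start indices i
        s = c1[j + 1] - c1[i]
        q = c2[j + 1] - c2[i]
        m = j + 1 - i
        return q - s * s / m

    dp = np.full((k + 1, n), np.inf)
    split = np.zeros((k + 1, n), dtype=int)
    dp[1] = np.array([seg_cost(np.array([0]), j)[0] for j in range(n)])
    for m in range(2, k + 1):
        for j in range(m - 1, n):
            i = np.arange(m - 1, j + 1)
            total = dp[m - 1][i - 1] + seg_cost(i, j)
            best = int(np.argmin(total))
            dp[m][j] = total[best]
            split[m][j] = i[best]
    # backtrack cluster boundaries
    assign_sorted = np.zeros(n, dtype=int)
    j = n - 1
    for m in range(k, 0, -1):
        i = split[m][j] if m > 1 else 0
        assign_sorted[i : j + 1] = m
        j = i - 1
    assignments = np.empty(n, dtype=int)
    assignments[order] = assign_sorted
    centers = np.array([x[assignments == c].mean() for c in range(1, k + 1)])
    return assignments, centers


def fit_threshold(
    table: pd.DataFrame,
    channel: str,
    k: int = 3,
    seed: int = 0,
    feature_mode: str = "mean_sd",
    n_init: int = 10,
) -> ThresholdModel:
    """Fit the k-means negative-staining threshold for one channel.

    Features are the per-nucleus (mean, SD) intensity pairs — or the mean
    alone (``feature_mode="mean"``) — standardized to zero mean and unit
    variance before clustering so the two scales contribute comparably.
    Mean-only clustering is solved exactly (dynamic programming over sorted
    values); the joint mode uses multi-restart Lloyd iterations with a fixed
    seed.
    Clusters are sorted by their mean-intensity center; the negative class
    is the run of lowest clusters below the widest inter-cluster gap, and
    tau is the raw-AU midpoint of that gap (for two well-separated
    components this is simply the midpoint between the negative cluster's
    maximum and the next cluster's minimum). All-identical intensities
    yield a degenerate single-class model (tau undefined, everything
    negative) with a warning.
    """
    if feature_mode not in ("mean_sd", "mean"):
        raise ValueError(f"unknown feature_mode {feature_mode!r}")
    means = table[f"{channel}_mean"].to_numpy(dtype=float)
    n = means.size
    if feature_mode == "mean_sd":
        feats = np.column_stack([means, table[f"{channel}_sd"].to_numpy(float)])
    else:
        feats = means[:, None]

    class_names = tuple(DEFAULT_CLASS_NAMES[:k]) if k <= len(
        DEFAULT_CLASS_NAMES
    ) else tuple(
        ["negative"] + [f"class_{i}" for i in range(1, k)]
    )

    if np.ptp(means) == 0:
        warnings.warn(
            f"all {channel} intensities identical; single-class model, "
            "threshold undefined",
            stacklevel=2,
        )
        return ThresholdModel(
            channel=channel,
            k=1,
            feature_mode=feature_mode,
            centers=np.atleast_2d(feats[:1] if n else [0.0]),
            assignments=np.ones(n, dtype=int),
            threshold=None,
            class_names=("negative",),
            feature_mean=feats.mean(axis=0) if n else np.zeros(1),
            feature_sd=np.ones(feats.shape[1]),
        )

    n_distinct = np.unique(feats, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(
            f"{n_distinct} distinct feature points < k={k}: degenerate clustering"
        )

    f_mean = feats.mean(axis=0)
    f_sd = feats.std(axis=0)
    f_sd = np.where(f_sd > 0, f_sd, 1.0)

    if feats.shape[1] == 1:
        # 1-D squared error admits an exact, deterministic solution
        assignments, centers_1d = _kmeans_1d_exact(means, k)
        centers = centers_1d[:, None]
    else:
        z = (feats - f_mean) / f_sd
        km = KMeans(n_clusters=k, n_init=max(n_init, 10), random_state=seed)
        raw_assign = km.fit_predict(z)
        centers_raw = km.cluster_centers_ * f_sd + f_mean
        order = np.argsort(centers_raw[:, 0])
        rank = np.empty(k, dtype=int)
        rank[order] = np.arange(k)
        assignments = rank[raw_assign] + 1  # 1..k, 1 = negative
        centers = centers_raw[order]

    # negative/positive boundary: candidate cuts are midpoints between
    # consecutive cluster centers (mean-intensity coordinate); each candidate
    # snaps to the midpoint of the pooled-intensity gap that contains it, and
    # the boundary with the widest gap wins. For clean two-population data
    # this is exactly the midpoint between the negative cluster's maximum and
    # the next cluster's minimum; it stays robust when a dominant unstained
    # population is split across several clusters.
    tau, n_negative = None, k
    best_margin = -np.inf
    for c in range(k - 1):
        cut = 0.5 * (centers[c, 0] + centers[c + 1, 0])
        lower = means[means <= cut]
        upper = means[means > cut]
        if lower.size == 0 or upper.size == 0:
            continue
        margin = upper.min() - lower.max()
        if margin > best_margin:
            best_margin = margin
            tau = float(0.5 * (lower.max() + upper.min()))
            n_negative = c + 1
    if tau is None:
        warnings.warn(
            f"k-means put every {channel} nucleus in one class; threshold "
            "undefined",
            stacklevel=2,
        )
    return ThresholdModel(
        channel=channel,
        k=k,
        feature_mode=feature_mode,
        centers=centers,
        assignments=assignments,
        threshold=tau,
        class_names=class_names,
        feature_mean=f_mean,
        feature_sd=f_sd,
        n_negative=n_negative,
    )


def classify_cells(table: pd.DataFrame, model: ThresholdModel) -> pd.DataFrame:
    """Classify each nucleus of ``table`` against a fitted threshold model.

    Returns a copy of ``table`` with ``<channel>_class`` (cluster-derived
    intensity-class name) and ``<channel>_positive`` columns. A nucleus is
    positive iff its mean intensity is strictly above tau; a cell exactly at
    tau is negative. With a degenerate model everything is negative.
    """
    means = table[f"{model.channel}_mean"].to_numpy(dtype=float)
    out = table.copy()
    if model.degenerate:
        out[f"{model.channel}_class"] = "negative"
        out[f"{model.channel}_positive"] = False
        return out
    positive = means > model.threshold
    if len(model.assignments) == len(table):
        cls = np.asarray(model.class_names)[model.assignments - 1]
    else:  # model applied to a different table: assign by nearest boundary
        cls = np.where(positive, model.class_names[1], model.class_names[0])
    out[f"{model.channel}_class"] = cls
    out[f"{model.channel}_positive"] = positive
    return out


def positive_ratio(
    classified: pd.DataFrame | list[pd.DataFrame],
    channel: str,
    condition: str = "",
    scope: str = "pooled",
) -> RatioResult | list[RatioResult]:
    """Labeled-to-total cell ratio for a channel.

    ``scope="pooled"`` concatenates nuclei across the given replicate tables
    before dividing; ``scope="per_image"`` returns one ratio per table (the
    form that feeds between-condition t-tests on the means of the ratios).
    """
    tables = classified if isinstance(classified, list) else [classified]
    col = f"{channel}_positive"
    for t in tables:
        if col not in t.columns:
            raise KeyError(f"column {col} missing; run classify_cells first")
    if scope == "per_image":
        return [
            RatioResult(condition, channel, int(t[col].sum()), len(t))
            for t in tables
        ]
    total = sum(len(t) for t in tables)
    pos = sum(int(t[col].sum()) for t in tables)
    return RatioResult(condition, channel, pos, total)


def proliferation_ratio(
    table: pd.DataFrame,
    edu_channel: str = "EdU",
    model: ThresholdModel | None = None,
    k: int = 3,
    seed: int = 0,
    condition: str = "",
) -> RatioResult:
    """EdU-labeled-to-total ratio (proliferating-cell ratio).

    Identical machinery to marker positivity, applied to the EdU channel;
    fits a threshold model on the spot when none is supplied.
    """
    if f"{edu_channel}_mean" not in table.columns:
        raise KeyError(f"EdU channel {edu_channel!r} not present in table")
    if model is None:
        model = fit_threshold(table, edu_channel, k=k, seed=seed)
    classified = classify_cells(table, model)
    return positive_ratio(classified, edu_channel, condition=condition)
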