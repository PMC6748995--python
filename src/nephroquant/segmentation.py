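"""Nuclear segmentation: preprocessing, graph-cut binarization, watershed split.

The nuclear counterstain channel is background-subtracted and smoothed, then
binarized by exact minimization of a two-label Markov-random-field energy

    E(l) = sum_p U_p(l_p) + lambda * sum_{(p,q) adjacent} [l_p != l_q]

whose unary terms are negative log-likelihoods under a two-component Gaussian
intensity model fitted to the preprocessed pixel values. For two labels this
energy is submodular, so min-cut/max-flow yields the global optimum; the cut
is computed with ``scipy.sparse.csgraph.maximum_flow`` on integer-scaled
capacities. Touching nuclei are then separated by a distance-transform
watershed and small fragments are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import relabel_sequential, watershed

from .simulate import ImageStack

__all__ = [
    "GraphCutParams",
    "GaussianMixture1D",
    "preprocess",
    "fit_intensity_model",
    "min_cut_binary",
    "binary_energy",
    "graphcut_binarize",
    "split_and_label",
    "segment_nuclei",
]


@dataclass(frozen=True)
class GraphCutParams:
    """Settings for graph-cut binarization and nucleus splitting.

    ``lam`` is the dimensionless smoothness weight of the pairwise term;
    ``connectivity`` selects the neighbor system of the smoothness term
    (4 or 8 in 2D, 6 or 26 in 3D); ``min_nucleus_size`` removes fragments
    below that pixel count; splitting is distance-transform watershed by
    default and can be disabled (``split_method="none"``).
    """

    lam: float = 1.0
    connectivity: int | None = None  # None -> 4 (2D) / 6 (3D)
    min_nucleus_size: int = 20
    split_method: str = "watershed"  # "watershed" | "none"
    watershed_sigma: float = 0.5
    peak_min_distance: int = 3
    intensity_model: "GaussianMixture1D | None" = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("smoothness weight lam must be >= 0")
        if self.min_nucleus_size < 1:
            raise ValueError("min_nucleus_size must be >= 1")
        if self.split_method not in ("watershed", "none"):
            raise ValueError(f"unknown split_method {self.split_method!r}")

    def resolved_connectivity(self, ndim: int) -> int:
        if self.connectivity is not None:
            return self.connectivity
        return 4 if ndim == 2 else 6


@dataclass(frozen=True)
class GaussianMixture1D:
    """Two-component 1-D Gaussian mixture (background, foreground).

    Component 0 is background (lower mean), component 1 foreground; ties in
    ordering are broken by mean.
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]

    def neg_log_likelihood(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel unary costs (-log of weighted component densities)."""
        out = []
        for w, mu, sd in zip(self.weights, self.means, self.sds):
            sd = max(sd, 1e-9)
            out.append(
                0.5 * ((x - mu) / sd) ** 2
                + np.log(sd)
                + 0.5 * np.log(2 * np.pi)
                - np.log(max(w, 1e-12))
            )
        return out[0], out[1]


def preprocess(
    image: ImageStack, bg_radius: float = 40.0, smooth_sigma: float = 1.0
) -> ImageStack:
    """Background-subtract and smooth the nuclear channel.

    A morphological top-hat (grey opening with a flat square/cube structuring
    element of half-width ``bg_radius``) estimates and removes the local
    background, then a Gaussian of ``smooth_sigma`` suppresses noise. Marker
    channels pass through untouched: intensity measurements must come from
    raw marker data.
    """
    if bg_radius <= 0:
        raise ValueError("bg_radius must be positive")
    if "nuclear" not in image.channels:
        raise ValueError("nuclear channel required for preprocessing")
    nuc = np.asarray(image["nuclear"], dtype=float)
    size = 2 * int(round(bg_radius)) + 1
    background = ndi.grey_opening(nuc, size=(size,) * nuc.ndim)
    out = nuc - background
    if smooth_sigma > 0:
        out = ndi.gaussian_filter(out, smooth_sigma)
    channels = dict(image.channels)
    channels["nuclear"] = out
    return ImageStack(channels=channels, pixel_size_um=image.pixel_size_um)


def fit_intensity_model(
    values: np.ndarray, max_iter: int = 100, tol: float = 1e-6
) -> GaussianMixture1D:
    """Fit a two-component Gaussian mixture by EM.

    Initialization splits the data at the Otsu threshold and takes moment
    estimates per side; EM then runs to convergence (relative log-likelihood
    change below ``tol``) or ``max_iter`` iterations. Components are returned
    sorted by mean (higher mean = foreground). Raises ``ValueError`` on
    degenerate input (a single intensity mode cannot be split).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 4 or np.ptp(x) == 0:
        raise ValueError("degenerate intensity distribution (no spread)")
    t = threshold_otsu(x)
    lo, hi = x[x <= t], x[x > t]
    if lo.size < 2 or hi.size < 2:
        raise ValueError("degenerate intensity distribution (one-sided split)")
    w = np.array([lo.size, hi.size], dtype=float) / x.size
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.maximum([lo.std(), hi.std()], 1e-6 * max(np.ptp(x), 1.0))

    prev_ll = -np.inf
    for _ in range(max_iter):
        log_p = np.stack(
            [
                np.log(w[k])
                - 0.5 * ((x - mu[k]) / sd[k]) ** 2
                - np.log(sd[k])
                for k in range(2)
            ]
        )
        m = log_p.max(axis=0)
        lse = m + np.log(np.exp(log_p - m).sum(axis=0))
        ll = float(lse.sum())
        resp = np.exp(log_p - lse)
        nk = resp.sum(axis=1)
        if np.any(nk < 1e-9):
            raise ValueError("degenerate intensity distribution (empty component)")
        w = nk / x.size
        mu = (resp @ x) / nk
        var = (resp @ x**2) / nk - mu**2
        sd = np.sqrt(np.maximum(var, 1e-12))
        if abs(ll - prev_ll) <= tol * (1.0 + abs(ll)):
            break
        prev_ll = ll
    order = np.argsort(mu)  # lower mean = background
    if sd[order].min() < 1e-9:
        raise ValueError("degenerate intensity distribution (zero variance)")
    return GaussianMixture1D(
        weights=tuple(w[order]), means=tuple(mu[order]), sds=tuple(sd[order])
    )


def _adjacency_offsets(ndim: int, connectivity: int) -> list[tuple[int, ...]]:
    """Unique forward neighbor offsets for the requested connectivity."""
    axis = {2: (4, 8), 3: (6, 26)}[ndim]
    if connectivity not in axis:
        raise ValueError(f"connectivity {connectivity} invalid for {ndim}D")
    offsets: list[tuple[int, ...]] = []
    rng = [(-1, 0, 1)] * ndim
    from itertools import product

    for off in product(*rng):
        if all(o == 0 for o in off):
            continue
        # keep only one direction of each pair
        if off < tuple([0] * ndim):
            continue
        if connectivity == axis[0] and sum(abs(o) for o in off) != 1:
            continue
        offsets.append(off)
    return offsets


def _edge_pairs(shape: tuple[int, ...], connectivity: int) -> np.ndarray:
    """(n_edges, 2) array of flat pixel-index pairs for the pixel lattice."""
    idx = np.arange(int(np.prod(shape))).reshape(shape)
    pairs = []
    for off in _adjacency_offsets(len(shape), connectivity):
        src = idx[
            tuple(
                slice(max(-o, 0), s - max(o, 0)) for o, s in zip(off, shape)
            )
        ]
        dst = idx[
            tuple(
                slice(max(o, 0), s - max(-o, 0)) for o, s in zip(off, shape)
            )
        ]
        pairs.append(np.stack([src.ravel(), dst.ravel()], axis=1))
    if not pairs:
        return np.empty((0, 2), dtype=int)
    return np.concatenate(pairs, axis=0)


def binary_energy(
    labels: np.ndarray,
    unary_bg: np.ndarray,
    unary_fg: np.ndarray,
    lam: float,
    connectivity: int | None = None,
) -> float:
    """Evaluate the two-label MRF energy of a labeling (True = foreground)."""
    labels = np.asarray(labels, dtype=bool)
    conn = connectivity or (4 if labels.ndim == 2 else 6)
    u = np.where(labels, unary_fg, unary_bg).sum()
    pairs = _edge_pairs(labels.shape, conn)
    flat = labels.ravel()
    cuts = int(np.count_nonzero(flat[pairs[:, 0]] != flat[pairs[:, 1]]))
    return float(u + lam * cuts)


def min_cut_binary(
    unary_bg: np.ndarray,
    unary_fg: np.ndarray,
    lam: float,
    connectivity: int | None = None,
) -> np.ndarray:
    """Globally minimize the two-label MRF energy by min-cut/max-flow.

    Returns a boolean foreground mask of the same shape as the unary arrays.
    Capacities are normalized per pixel (subtracting the smaller unary, which
    shifts the energy by a constant) and scaled to integers; the scale is
    chosen so the max-flow value stays far below the int64 range while
    keeping quantization error negligible.
    """
    u0 = np.asarray(unary_bg, dtype=float)
    u1 = np.asarray(unary_fg, dtype=float)
    if u0.shape != u1.shape:
        raise ValueError("unary arrays must share a shape")
    shape = u0.shape
    n = u0.size
    if lam == 0:
        return (u1 < u0).reshape(shape)
    conn = connectivity or (4 if len(shape) == 2 else 6)

    base = np.minimum(u0, u1)
    c_bg = (u0 - base).ravel()  # pay when labeled background
    c_fg = (u1 - base).ravel()  # pay when labeled foreground
    # clip decisive unaries: beyond ~1000x the total pairwise influence the
    # label is forced anyway, and a smaller range preserves scaling precision
    clip = max(1e4, 1e3 * lam * 2 * len(shape))
    c_bg = np.minimum(c_bg, clip)
    c_fg = np.minimum(c_fg, clip)
    pairs = _edge_pairs(shape, conn)

    # the solver arithmetic must stay within int32: bound both the largest
    # single capacity and the achievable flow value, with ample headroom
    cut_bound = min(c_bg.sum(), c_fg.sum()) + lam * len(pairs) + 1.0
    max_single = max(c_bg.max(), c_fg.max(), lam, 1.0)
    scale = min(1e6, 2.0**30 / max(cut_bound, 8.0 * max_single))
    cap_bg = np.round(c_bg * scale).astype(np.int32)
    cap_fg = np.round(c_fg * scale).astype(np.int32)
    lam_i = np.int32(round(lam * scale))

    # node 0 = source (foreground terminal), node n+1 = sink (background)
    src, snk = n, n + 1
    rows = np.concatenate(
        [np.full(n, src), np.arange(n), pairs[:, 0], pairs[:, 1]]
    )
    cols = np.concatenate(
        [np.arange(n), np.full(n, snk), pairs[:, 1], pairs[:, 0]]
    )
    # cutting source->p means p is background: pay c_bg; p->sink cut when
    # p is foreground: pay c_fg
    data = np.concatenate(
        [cap_bg, cap_fg, np.full(len(pairs), lam_i), np.full(len(pairs), lam_i)]
    )
    keep = data > 0
    graph = sparse.csr_matrix(
        (data[keep], (rows[keep], cols[keep])), shape=(n + 2, n + 2)
    )
    result = maximum_flow(graph, src, snk)
    residual = graph - result.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reach = breadth_first_order(
        residual, src, directed=True, return_predecessors=False
    )
    fg = np.zeros(n + 2, dtype=bool)
    fg[reach] = True
    return fg[:n].reshape(shape)


def graphcut_binarize(
    image: ImageStack | np.ndarray, params: GraphCutParams = GraphCutParams()
) -> np.ndarray:
    """Binarize the (preprocessed) nuclear channel by graph cut.

    A two-component Gaussian intensity model is fitted to the pixel values
    (unless supplied in ``params``); its negative log-likelihoods are the
    unary costs. On a degenerate intensity distribution the method falls back
    to a plain Otsu threshold with a warning.
    """
    nuc = np.asarray(
        image["nuclear"] if isinstance(image, ImageStack) else image, dtype=float
    )
    model = params.intensity_model
    if model is None:
        try:
            model = fit_intensity_model(nuc)
        except ValueError as exc:
            warnings.warn(
                f"intensity model degenerate ({exc}); falling back to Otsu",
                stacklevel=2,
            )
            if np.ptp(nuc) == 0:
                return np.zeros(nuc.shape, dtype=bool)
            return nuc > threshold_otsu(nuc)
    u_bg, u_fg = model.neg_log_likelihood(nuc)
    return min_cut_binary(
        u_bg, u_fg, params.lam, params.resolved_connectivity(nuc.ndim)
    )


def _label_structure(ndim: int, connectivity: int) -> np.ndarray:
    rank = 1 if connectivity in (4, 6) else ndim
    return ndi.generate_binary_structure(ndim, rank)


def split_and_label(
    mask: np.ndarray, params: GraphCutParams = GraphCutParams()
) -> np.ndarray:
    """Label connected components and split touching nuclei by watershed.

    Seeds are the regional maxima of the Gaussian-smoothed Euclidean distance
    transform (at least one seed per component); the watershed floods the
    negated distance map within the mask. Fragments below
    ``min_nucleus_size`` pixels are removed and labels are relabeled to a
    contiguous 1..L range. An empty mask yields an all-zero label image.
    """
    mask = np.asarray(mask, dtype=bool)
    structure = _label_structure(mask.ndim, params.resolved_connectivity(mask.ndim))
    comp, n_comp = ndi.label(mask, structure=structure)
    if n_comp == 0:
        return np.zeros(mask.shape, dtype=np.int32)

    if params.split_method == "watershed":
        dist = ndi.distance_transform_edt(mask)
        if params.watershed_sigma > 0:
            dist = ndi.gaussian_filter(dist, params.watershed_sigma)
        coords = peak_local_max(
            dist,
            min_distance=params.peak_min_distance,
            labels=comp,
            exclude_border=False,
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        # guarantee a seed in components where no peak survived
        seeded = set(np.unique(comp[markers > 0]))
        missing = [c for c in range(1, n_comp + 1) if c not in seeded]
        next_id = len(coords) + 1
        for c in missing:
            pos = np.unravel_index(
                np.argmax(np.where(comp == c, dist, -1.0)), mask.shape
            )
            markers[pos] = next_id
            next_id += 1
        labels = watershed(-dist, markers, mask=mask)
    else:
        labels = comp

    sizes = np.bincount(labels.ravel())
    too_small = sizes < params.min_nucleus_size
    too_small[0] = False
    if too_small.any():
        labels[too_small[labels]] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_nuclei(
    image: ImageStack,
    params: GraphCutParams = GraphCutParams(),
    bg_radius: float = 40.0,
    smooth_sigma: float = 1.0,
) -> np.ndarray:
    """Full nuclear segmentation: preprocess -> graph cut -> split & label."""
    pre = preprocess(image, bg_radius=bg_radius, smooth_sigma=smooth_sigma)
    mask = graphcut_binarize(pre, params)
    return split_and_label(mask, params)
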