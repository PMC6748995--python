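"""Synthetic fluorescence images and cytometry event tables with ground truth.

The generator emulates the data substrate of the sphere-culture quantification
pipeline: spherical clusters of nuclei rendered into a nuclear-counterstain
channel, per-nucleus marker brightness drawn from a two-component (negative /
positive) intensity mixture, an optional EdU channel marking a proliferating
subpopulation, optical blur (Gaussian PSF) and Poisson + Gaussian noise.
Every draw is recorded in a :class:`GroundTruth` table so that downstream
segmentation and classification can be scored against what was actually
sampled, not the nominal parameters.

A second generator produces single-detector flow-cytometry event tables as a
two-component log-normal mixture (live / dead populations of a Sytox
dead-cell stain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.special import erfc

__all__ = [
    "IntensityModel",
    "NoiseModel",
    "SphereImageParams",
    "EventTableParams",
    "ImageStack",
    "GroundTruth",
    "generate_sphere_image",
    "generate_event_table",
    "render_nuclei",
]


@dataclass(frozen=True)
class IntensityModel:
    """Per-nucleus brightness distribution in arbitrary units (AU).

    ``mean`` and ``sd`` are the arithmetic mean and standard deviation of the
    distribution; for ``lognormal`` they are converted internally to the
    log-scale (mu, sigma) parameterization.
    """

    mean: float
    sd: float
    distribution: str = "lognormal"  # "lognormal" | "normal"

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd < 0:
            raise ValueError("intensity mean must be > 0 and sd >= 0")
        if self.distribution not in ("lognormal", "normal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        if self.sd == 0:
            return np.full(n, self.mean, dtype=float)
        if self.distribution == "normal":
            return np.clip(rng.normal(self.mean, self.sd, n), 0.0, None)
        cv2 = (self.sd / self.mean) ** 2
        sigma = math.sqrt(math.log1p(cv2))
        mu = math.log(self.mean) - 0.5 * sigma**2
        return rng.lognormal(mu, sigma, n)


@dataclass(frozen=True)
class NoiseModel:
    """Shot + read noise: Poisson with ``gain`` photons/AU, then Gaussian read
    noise of SD ``read_sd`` AU. ``gain = 0`` disables the Poisson stage."""

    gain: float = 1.0
    read_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.gain < 0 or self.read_sd < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def enabled(self) -> bool:
        return self.gain > 0 or self.read_sd > 0

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = image
        if self.gain > 0:
            out = rng.poisson(np.clip(out, 0, None) * self.gain) / self.gain
        if self.read_sd > 0:
            out = out + rng.normal(0.0, self.read_sd, out.shape)
        return np.clip(out, 0.0, None)


@dataclass(frozen=True)
class SphereImageParams:
    """Parameters of one synthetic sphere-culture image (2D section by
    default; any shape of length 3 is rendered as a 3D stack).

    Defaults approximate a cross-section through a handful of spheres with
    roughly 200 nuclei in total, the scale at which the quantification
    pipeline operates per image.
    """

    image_shape: tuple[int, ...] = (384, 384)
    n_spheres: int = 6
    nuclei_per_sphere: int | tuple[int, int] = (28, 36)
    nucleus_radius: tuple[float, float] = (4.5, 0.5)  # (mean, SD) px
    sphere_radius: float = 58.0
    marker_names: tuple[str, ...] = ("SIX2",)
    positive_fraction: float | dict[str, float] = 0.5
    intensity_neg: IntensityModel = field(
        default_factory=lambda: IntensityModel(50.0, 15.0)
    )
    intensity_pos: IntensityModel = field(
        default_factory=lambda: IntensityModel(400.0, 80.0)
    )
    edu_fraction: float | None = None
    nuclear_amplitude: float = 300.0
    background_level: float = 20.0
    psf_sigma: float = 1.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    min_separation: float = 2.8  # center-to-center, in units of mean radius
    touching_fraction: float = 0.0  # fraction of nuclei allowed to violate it
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = list(self._positive_fractions().values())
        if self.edu_fraction is not None:
            fracs.append(self.edu_fraction)
        fracs.append(self.touching_fraction)
        for f in fracs:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {f} outside [0, 1]")
        if self.nucleus_radius[0] <= 0 or self.sphere_radius <= 0:
            raise ValueError("radii must be positive")
        if self.n_spheres < 0:
            raise ValueError("n_spheres must be >= 0")
        lo, hi = self._nuclei_range()
        if lo < 0 or hi < lo:
            raise ValueError("invalid nuclei_per_sphere")
        if self.intensity_pos.mean <= self.intensity_neg.mean:
            raise ValueError("intensity_pos mean must exceed intensity_neg mean")
        if len(self.image_shape) not in (2, 3):
            raise ValueError("image_shape must be 2D or 3D")

    def _nuclei_range(self) -> tuple[int, int]:
        if isinstance(self.nuclei_per_sphere, (int, np.integer)):
            return int(self.nuclei_per_sphere), int(self.nuclei_per_sphere)
        lo, hi = self.nuclei_per_sphere
        return int(lo), int(hi)

    def _positive_fractions(self) -> dict[str, float]:
        if isinstance(self.positive_fraction, dict):
            return {m: float(self.positive_fraction[m]) for m in self.marker_names}
        return {m: float(self.positive_fraction) for m in self.marker_names}


@dataclass(frozen=True)
class EventTableParams:
    """Two-population (live/dead) Sytox intensity mixture on log10 scale.

    Sytox is a cell-impermeant dead-cell stain, so the dead population sits at
    the higher log-intensity mode. Default separation is well above three
    combined SDs, matching a clean single-stain acquisition.
    """

    n_events: int = 10_000
    dead_fraction: float = 0.2
    log_intensity_live: tuple[float, float] = (2.0, 0.15)  # (mean, SD) log10 AU
    log_intensity_dead: tuple[float, float] = (3.2, 0.20)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction outside [0, 1]")
        if self.log_intensity_dead[0] <= self.log_intensity_live[0]:
            raise ValueError(
                "dead mean log-intensity must exceed live mean (dead-cell stain)"
            )
        if self.log_intensity_live[1] < 0 or self.log_intensity_dead[1] < 0:
            raise ValueError("log-intensity SDs must be >= 0")


@dataclass
class ImageStack:
    """Multi-channel intensity image with channel roles.

    ``channels`` maps role names ("nuclear", marker names, "EdU") to arrays
    that all share one (2D or 3D) shape. Axis order is (z,)y,x, 0-based.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def marker_names(self) -> list[str]:
        return [c for c in self.channels if c != "nuclear"]

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]


@dataclass
class GroundTruth:
    """Realized per-nucleus sample underlying one generated image.

    ``nuclei`` has one row per rendered nucleus: ``nucleus_id``, ``sphere_id``,
    centroid coordinates, ``radius``, and per channel a boolean class column
    (``<marker>_positive``, ``edu_positive``) plus the drawn brightness
    (``<channel>_brightness``). Class fractions are the empirical fractions of
    this realized sample.
    """

    nuclei: pd.DataFrame
    marker_names: tuple[str, ...]
    has_edu: bool = False

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    def positive_fraction(self, channel: str) -> float:
        col = "edu_positive" if channel == "EdU" else f"{channel}_positive"
        if self.n_nuclei == 0:
            return float("nan")
        return float(self.nuclei[col].mean())

    def positive_count(self, channel: str) -> int:
        col = "edu_positive" if channel == "EdU" else f"{channel}_positive"
        return int(self.nuclei[col].sum())

    def centroids(self) -> np.ndarray:
        cols = [c for c in ("z", "y", "x") if c in self.nuclei.columns]
        return self.nuclei[cols].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# placement and rendering


def _sphere_centers(
    shape: tuple[int, ...], n: int, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Dart-throw sphere centers, preferring non-overlapping spheres."""
    lo = np.full(len(shape), radius)
    hi = np.asarray(shape, dtype=float) - radius
    if np.any(hi < lo):  # image smaller than one sphere: just center it
        lo = hi = np.asarray(shape, dtype=float) / 2.0
    centers: list[np.ndarray] = []
    for _ in range(n):
        best, best_d = None, -1.0
        for _attempt in range(300):
            c = rng.uniform(lo, hi)
            if not centers:
                best = c
                break
            d = min(np.linalg.norm(c - p) for p in centers)
            if d >= 2.05 * radius:
                best = c
                break
            if d > best_d:
                best, best_d = c, d
        centers.append(best)
    return np.asarray(centers).reshape(n, len(shape))


def _place_nuclei(
    center: np.ndarray,
    n: int,
    sphere_radius: float,
    radii: np.ndarray,
    min_sep: float,
    touching_fraction: float,
    rng: np.random.Generator,
    existing: np.ndarray | None = None,
) -> np.ndarray:
    """Place n nucleus centers inside a sphere by rejection sampling.

    Best-candidate (blue-noise) sampling: each nucleus picks, out of a batch
    of uniform candidates, the one farthest from all previously placed
    nuclei, accepting early once the separation is met. This degrades
    gracefully at high densities instead of jamming. A ``touching_fraction``
    share of nuclei instead deliberately lands within touching range
    (< 2 radii) of an existing nucleus.
    """
    ndim = center.size
    pts: list[np.ndarray] = []
    prior = (
        np.asarray(existing).reshape(-1, ndim)
        if existing is not None and len(existing)
        else np.empty((0, ndim))
    )

    def _candidate() -> np.ndarray:
        u = rng.normal(size=ndim)
        u /= max(np.linalg.norm(u), 1e-12)
        r = sphere_radius * rng.random() ** (1.0 / ndim)
        return center + u * min(r, max(sphere_radius - radii.mean(), 0.0))

    for i in range(n):
        if not pts and not len(prior):
            pts.append(_candidate())
            continue
        arr = np.concatenate([prior, np.asarray(pts).reshape(-1, ndim)])
        if len(pts) and rng.random() < touching_fraction:
            # park next to a random existing nucleus, inside touching range
            anchor = pts[rng.integers(len(pts))]
            u = rng.normal(size=ndim)
            u /= max(np.linalg.norm(u), 1e-12)
            pts.append(anchor + u * rng.uniform(1.2, 1.9) * radii[i])
            continue
        best, best_d = None, -1.0
        for _attempt in range(60):
            c = _candidate()
            d = float(np.min(np.linalg.norm(arr - c, axis=1)))
            if d >= min_sep:
                best = c
                break
            if d > best_d:
                best, best_d = c, d
        pts.append(best)
    return np.asarray(pts).reshape(n, ndim)


def render_nuclei(
    shape: tuple[int, ...],
    centers: np.ndarray,
    radii: np.ndarray,
    values: np.ndarray,
    soft_edge_sigma: float = 0.0,
    combine: str = "max",
) -> np.ndarray:
    """Render disks/balls of given per-nucleus values into a float image.

    With ``soft_edge_sigma = 0`` each nucleus is a hard disk (every pixel with
    center within ``radius`` gets exactly ``value``); otherwise the edge rolls
    off as half an error function of the signed distance to the boundary.
    Overlaps combine by per-pixel max, which keeps values interpretable.
    """
    img = np.zeros(shape, dtype=float)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    radii = np.asarray(radii, dtype=float).ravel()
    values = np.asarray(values, dtype=float).ravel()
    pad = 3.0 * soft_edge_sigma + 1.0
    for c, r, v in zip(centers, radii, values):
        lo = np.maximum(np.floor(c - r - pad).astype(int), 0)
        hi = np.minimum(np.ceil(c + r + pad).astype(int) + 1, shape)
        if np.any(hi <= lo):
            continue
        grids = np.meshgrid(
            *[np.arange(a, b, dtype=float) for a, b in zip(lo, hi)], indexing="ij"
        )
        d = np.sqrt(sum((g - ci) ** 2 for g, ci in zip(grids, c)))
        if soft_edge_sigma > 0:
            profile = 0.5 * erfc((d - r) / (math.sqrt(2.0) * soft_edge_sigma))
        else:
            profile = (d <= r).astype(float)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        if combine == "max":
            np.maximum(img[sl], v * profile, out=img[sl])
        else:
            img[sl] += v * profile
    return img


def generate_sphere_image(
    params: SphereImageParams,
) -> tuple[ImageStack, GroundTruth]:
    """Generate one multi-channel sphere-culture image plus its ground truth.

    Channels: ``nuclear`` always; one channel per entry of
    ``params.marker_names``; ``EdU`` when ``params.edu_fraction`` is set.
    PSF blur and noise are applied last, to every channel. The returned
    :class:`GroundTruth` records the realized sample (classes actually drawn),
    which is the correct oracle for recovery tests.
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(int(s) for s in params.image_shape)
    ndim = len(shape)
    fractions = params._positive_fractions()
    lo, hi = params._nuclei_range()

    sphere_centers = _sphere_centers(
        shape, params.n_spheres, params.sphere_radius, rng
    )
    rows: list[dict] = []
    centers_all: list[np.ndarray] = []
    radii_all: list[float] = []
    mean_r = params.nucleus_radius[0]
    for s_id, s_center in enumerate(sphere_centers):
        n_nuc = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        if n_nuc == 0:
            continue
        radii = np.clip(
            rng.normal(params.nucleus_radius[0], params.nucleus_radius[1], n_nuc),
            0.5 * mean_r,
            2.0 * mean_r,
        )
        pts = _place_nuclei(
            s_center,
            n_nuc,
            params.sphere_radius,
            radii,
            params.min_separation * mean_r,
            params.touching_fraction,
            rng,
            existing=np.asarray(centers_all) if centers_all else None,
        )
        for i in range(n_nuc):
            row = {"sphere_id": s_id, "radius": float(radii[i])}
            row.update(dict(zip(("z", "y", "x")[-ndim:], pts[i])))
            rows.append(row)
            centers_all.append(pts[i])
            radii_all.append(float(radii[i]))

    truth = pd.DataFrame(rows)
    n_total = len(truth)
    truth.insert(0, "nucleus_id", np.arange(1, n_total + 1))

    # draw marker classes and brightness; render channels
    channels: dict[str, np.ndarray] = {}
    centers_arr = (
        np.asarray(centers_all) if n_total else np.empty((0, ndim))
    )
    radii_arr = np.asarray(radii_all)

    nuc_amp = np.full(n_total, params.nuclear_amplitude)
    nuc_amp = nuc_amp * rng.uniform(0.8, 1.2, n_total)  # staining variability
    channels["nuclear"] = params.background_level + render_nuclei(
        shape, centers_arr, radii_arr, nuc_amp, soft_edge_sigma=0.75
    )

    channel_fracs: list[tuple[str, float, str]] = [
        (m, fractions[m], f"{m}_positive") for m in params.marker_names
    ]
    if params.edu_fraction is not None:
        channel_fracs.append(("EdU", params.edu_fraction, "edu_positive"))
    for ch_name, frac, col in channel_fracs:
        positive = rng.random(n_total) < frac
        brightness = np.where(
            positive,
            params.intensity_pos.sample(rng, n_total),
            params.intensity_neg.sample(rng, n_total),
        )
        truth[col] = positive
        truth[f"{ch_name}_brightness"] = brightness
        channels[ch_name] = render_nuclei(
            shape, centers_arr, radii_arr, brightness, soft_edge_sigma=0.0
        )

    for name, img in channels.items():
        if params.psf_sigma > 0:
            img = ndi.gaussian_filter(img, params.psf_sigma)
        if params.noise.enabled:
            img = params.noise.apply(img, rng)
        channels[name] = img.astype(np.float32)

    gt = GroundTruth(
        nuclei=truth,
        marker_names=params.marker_names,
        has_edu=params.edu_fraction is not None,
    )
    return ImageStack(channels=channels), gt


def generate_event_table(
    params: EventTableParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a single-detector cytometry event table.

    Returns ``(events, truth)``: ``events`` has columns ``event_id`` and
    ``intensity`` (linear AU); ``truth`` additionally carries the true
    population label (``live`` / ``dead``) of every event.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_events
    dead = rng.random(n) < params.dead_fraction
    mu_l, sd_l = params.log_intensity_live
    mu_d, sd_d = params.log_intensity_dead
    log_i = np.where(
        dead, rng.normal(mu_d, sd_d, n), rng.normal(mu_l, sd_l, n)
    )
    events = pd.DataFrame(
        {"event_id": np.arange(1, n + 1), "intensity": 10.0**log_i}
    )
    truth = events.copy()
    truth["population"] = np.where(dead, "dead", "live")
    return events, truth


def with_seed(params: SphereImageParams, seed: int) -> SphereImageParams:
    """Copy params with a different seed (convenience for replicate images)."""
    return replace(params, seed=int(seed))
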