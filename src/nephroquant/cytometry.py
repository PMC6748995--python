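"""Live/dead viability estimation from single-detector Sytox event tables.

Sytox is a cell-impermeant nucleic-acid dye: only dead cells stain, so
events above the gate on the dead-stain detector are dead and viability is
the inverted dead-cell percentage, 100 - dead%. Flow intensities span
decades, so gating operates on log10 intensity; the default automatic gate
is Otsu's threshold (deterministic, parameter-free), with 2-means and fixed
thresholds as alternatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans

__all__ = ["ViabilitySummary", "gate_viability"]


@dataclass(frozen=True)
class ViabilitySummary:
    """Gating result for one event table."""

    n_events: int
    dead_fraction: float
    gate_log10: float
    method: str

    @property
    def dead_percent(self) -> float:
        return 100.0 * self.dead_fraction

    @property
    def viability_percent(self) -> float:
        return 100.0 - self.dead_percent


def _log_intensities(events: pd.DataFrame | np.ndarray, column: str) -> np.ndarray:
    if isinstance(events, pd.DataFrame):
        x = events[column].to_numpy(dtype=float)
    else:
        x = np.asarray(events, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("event table is empty")
    if np.any(x < 0):
        raise ValueError("intensities must be >= 0")
    return np.log10(np.maximum(x, 1e-12))


def _bimodal_enough(log_i: np.ndarray, gate: float) -> bool:
    """Sanity check for automatic gates: both sides populated and separated."""
    lo, hi = log_i[log_i <= gate], log_i[log_i > gate]
    if lo.size == 0 or hi.size == 0:
        return False
    spread = max(log_i.std(), 1e-12)
    return (hi.mean() - lo.mean()) >= 0.5 * spread


def gate_viability(
    events: pd.DataFrame | np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    column: str = "intensity",
) -> ViabilitySummary:
    """Gate a dead-cell-stain event table and summarize viability.

    ``method`` is ``"otsu"`` (default), ``"kmeans2"`` (2-means on log10
    intensity, gate at the midpoint of the two centers), or ``"fixed"``
    (honor ``threshold``, given in linear AU). Events with log10 intensity
    strictly above the gate are dead. An effectively unimodal distribution
    defeats automatic gating: a warning is issued and a fixed threshold is
    required.
    """
    log_i = _log_intensities(events, column)
    n = log_i.size

    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed gating requires a threshold (linear AU)")
        gate = float(np.log10(max(threshold, 1e-12)))
    elif method in ("otsu", "kmeans2"):
        if n < 2 or np.ptp(log_i) == 0:
            warnings.warn(
                "degenerate intensity distribution; automatic gating "
                "impossible — supply a fixed threshold",
                stacklevel=2,
            )
            if threshold is None:
                raise ValueError(
                    "automatic gate undefined on degenerate data; pass "
                    "method='fixed' with a threshold"
                )
            gate = float(np.log10(max(threshold, 1e-12)))
        elif method == "otsu":
            gate = float(threshold_otsu(log_i))
        else:
            km = KMeans(n_clusters=2, n_init=10, random_state=0)
            km.fit(log_i[:, None])
            centers = np.sort(km.cluster_centers_.ravel())
            gate = float(centers.mean())
        if method in ("otsu", "kmeans2") and not _bimodal_enough(log_i, gate):
            warnings.warn(
                "intensity distribution looks unimodal; automatic gate is "
                "unreliable — supply a fixed threshold",
                stacklevel=2,
            )
            if threshold is not None:
                gate = float(np.log10(max(threshold, 1e-12)))
                method = "fixed"
    else:
        raise ValueError(f"unknown gating method {method!r}")

    dead = int(np.count_nonzero(log_i > gate))
    return ViabilitySummary(
        n_events=n, dead_fraction=dead / n, gate_log10=gate, method=method
    )
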