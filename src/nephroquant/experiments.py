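"""Parameter-recovery experiments on synthetic data.

These runners exercise the full measurement chain — generate, segment,
measure, threshold, classify, ratio — against the generator's ground truth,
and are the package's standard way of validating that a known positive
fraction, proliferation ratio or viability survives the pipeline. Default
replication is 10 master seeds with 3 replicate images each at roughly 200
nuclei per image, the scale at which per-condition quantification operates.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Any

import numpy as np

from .cytometry import gate_viability
from .pipeline import derive_seed
from .quantify import classify_cells, fit_threshold, measure_nuclei, positive_ratio
from .segmentation import GraphCutParams, segment_nuclei
from .simulate import (
    EventTableParams,
    SphereImageParams,
    generate_event_table,
    generate_sphere_image,
)

__all__ = [
    "marker_recovery",
    "edu_recovery",
    "viability_recovery",
]


def _recover_one_image(
    params: SphereImageParams,
    channel: str,
    k: int,
    kmeans_seed: int,
    gc_params: GraphCutParams,
) -> tuple[int, int, int, int]:
    """(positive, total, true_positive, true_total) for one synthetic image."""
    image, truth = generate_sphere_image(params)
    labels = segment_nuclei(image, gc_params)
    table = measure_nuclei(image, labels)
    model = fit_threshold(table, channel, k=k, seed=kmeans_seed)
    classified = classify_cells(table, model)
    rr = positive_ratio(classified, channel)
    return rr.positive, rr.total, truth.positive_count(channel), truth.n_nuclei


def marker_recovery(
    fraction: float,
    channel: str = "SIX2",
    n_seeds: int = 10,
    images_per_seed: int = 3,
    base_seed: int = 0,
    k: int = 3,
    params: SphereImageParams | None = None,
) -> dict[str, Any]:
    """Recover a nominal marker-positive fraction through the full pipeline.

    Per master seed, ``images_per_seed`` replicate images are generated,
    segmented and classified; nuclei are pooled within a seed before the
    ratio, and the mean over seeds is reported. Returns recovered and
    realized-truth percentages plus replication sizes.
    """
    if params is None:
        params = SphereImageParams(
            marker_names=(channel,), positive_fraction=fraction
        )
    else:
        params = replace(
            params, marker_names=(channel,), positive_fraction=fraction
        )
    gc = GraphCutParams()
    recovered, truths, total_n = [], [], 0
    for s in range(n_seeds):
        pos = tot = true_pos = true_tot = 0
        for i in range(images_per_seed):
            img_seed = derive_seed(base_seed, f"marker:{channel}:{s}:{i}")
            p, t, tp, tn = _recover_one_image(
                replace(params, seed=img_seed),
                channel,
                k,
                derive_seed(base_seed, f"kmeans:{channel}:{s}:{i}"),
                gc,
            )
            pos += p
            tot += t
            true_pos += tp
            true_tot += tn
        recovered.append(100.0 * pos / tot)
        truths.append(100.0 * true_pos / true_tot)
        total_n += tot
    return {
        "nominal_percent": 100.0 * fraction,
        "recovered_percent": float(np.mean(recovered)),
        "recovered_sd": float(np.std(recovered, ddof=1)),
        "truth_percent": float(np.mean(truths)),
        "n_seeds": n_seeds,
        "n_nuclei": total_n,
    }


def edu_recovery(
    fraction: float,
    n_seeds: int = 10,
    images_per_seed: int = 3,
    base_seed: int = 0,
    k: int = 3,
) -> dict[str, Any]:
    """Recover a nominal EdU (proliferating) fraction; ratio scale in [0,1]."""
    gc = GraphCutParams()
    recovered, truths = [], []
    for s in range(n_seeds):
        pos = tot = 0
        true_pos = true_tot = 0
        for i in range(images_per_seed):
            img_seed = derive_seed(base_seed, f"edu:{s}:{i}")
            params = SphereImageParams(edu_fraction=fraction, seed=img_seed)
            image, truth = generate_sphere_image(params)
            labels = segment_nuclei(image, gc)
            table = measure_nuclei(image, labels)
            model = fit_threshold(
                table, "EdU", k=k, seed=derive_seed(base_seed, f"edu_km:{s}:{i}")
            )
            classified = classify_cells(table, model)
            rr = positive_ratio(classified, "EdU")
            pos += rr.positive
            tot += rr.total
            true_pos += truth.positive_count("EdU")
            true_tot += truth.n_nuclei
        recovered.append(pos / tot)
        truths.append(true_pos / true_tot)
    return {
        "nominal_ratio": fraction,
        "recovered_ratio": float(np.mean(recovered)),
        "recovered_sd": float(np.std(recovered, ddof=1)),
        "truth_ratio": float(np.mean(truths)),
        "n_seeds": n_seeds,
    }


def viability_recovery(
    viability_percent: float,
    n_events: int = 10_000,
    base_seed: int = 0,
    method: str = "otsu",
) -> dict[str, Any]:
    """Recover a nominal viability percentage from one gated event table."""
    params = EventTableParams(
        n_events=n_events,
        dead_fraction=1.0 - viability_percent / 100.0,
        seed=derive_seed(base_seed, f"viab:{viability_percent}"),
    )
    events, truth = generate_event_table(params)
    summary = gate_viability(events, method=method)
    return {
        "nominal_percent": viability_percent,
        "recovered_percent": summary.viability_percent,
        "truth_percent": 100.0 * float((truth["population"] == "live").mean()),
        "n_events": n_events,
    }
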