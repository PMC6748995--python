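"""End-to-end orchestration: simulate -> segment -> quantify -> compare.

A run is described by one config mapping (YAML/JSON on disk): synthetic
conditions with per-condition generator overrides, segmentation and
quantification parameter blocks, optional cytometry conditions and group
comparisons. All randomness derives from a single master seed; each stage
instance gets a deterministic sub-seed hashed from its name, so replicate
images and stages are decorrelated while the whole run reproduces exactly.
"""

from __future__ import annotations

import dataclasses
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .cytometry import gate_viability
from .quantify import classify_cells, fit_threshold, measure_nuclei, positive_ratio
from .segmentation import GraphCutParams, graphcut_binarize, preprocess, split_and_label
from .simulate import (
    EventTableParams,
    IntensityModel,
    NoiseModel,
    SphereImageParams,
    generate_event_table,
    generate_sphere_image,
)
from .stats import compare

__all__ = ["ConfigError", "StageError", "RunConfig", "run_pipeline", "derive_seed"]


class ConfigError(ValueError):
    """Invalid or unknown configuration key (message carries the key path)."""


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


_TOP_KEYS = {
    "seed",
    "conditions",
    "preprocess",
    "segmentation",
    "quantify",
    "cytometry",
    "comparisons",
}
_CONDITION_KEYS = {"name", "n_images", "image"}
_QUANTIFY_KEYS = {"k", "feature_mode", "channels", "edu"}
_COMPARISON_KEYS = {"a", "b", "channel", "test"}


def derive_seed(master: int, tag: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    return (int(master) * 1_000_003 + zlib.crc32(tag.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Resolved pipeline configuration (see module docstring for layout)."""

    seed: int = 0
    conditions: list[dict] = field(default_factory=list)
    preprocess: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    quantify: dict | None = None
    cytometry: list[dict] = field(default_factory=list)
    comparisons: list[dict] = field(default_factory=list)

    @classmethod
    def from_mapping(cls, raw: dict[str, Any]) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for i, cond in enumerate(raw.get("conditions", [])):
            bad = set(cond) - _CONDITION_KEYS
            if bad:
                raise ConfigError(
                    f"conditions[{i}]: unknown keys {sorted(bad)}"
                )
            if "name" not in cond:
                raise ConfigError(f"conditions[{i}].name missing")
        if raw.get("quantify") is not None:
            bad = set(raw["quantify"]) - _QUANTIFY_KEYS
            if bad:
                raise ConfigError(f"quantify: unknown keys {sorted(bad)}")
        for i, cmp_ in enumerate(raw.get("comparisons", [])):
            bad = set(cmp_) - _COMPARISON_KEYS
            if bad:
                raise ConfigError(f"comparisons[{i}]: unknown keys {sorted(bad)}")
        return cls(
            seed=int(raw.get("seed", 0)),
            conditions=list(raw.get("conditions", [])),
            preprocess=dict(raw.get("preprocess", {})),
            segmentation=dict(raw.get("segmentation", {})),
            quantify=raw.get("quantify"),
            cytometry=list(raw.get("cytometry", [])),
            comparisons=list(raw.get("comparisons", [])),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_mapping(raw)

    def to_mapping(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _image_params(overrides: dict, seed: int) -> SphereImageParams:
    kw = dict(overrides)
    for key in ("intensity_neg", "intensity_pos"):
        if key in kw and isinstance(kw[key], dict):
            kw[key] = IntensityModel(**kw[key])
    if "noise" in kw and isinstance(kw["noise"], dict):
        kw["noise"] = NoiseModel(**kw["noise"])
    for key in ("image_shape", "nuclei_per_sphere", "nucleus_radius", "marker_names"):
        if key in kw and isinstance(kw[key], list):
            kw[key] = tuple(kw[key])
    try:
        return SphereImageParams(seed=seed, **kw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"conditions[].image: {exc}") from exc


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the configured stages and return a self-contained report.

    The report embeds the resolved config and master seed; re-running from
    them reproduces every number. Quantification runs only when a
    ``quantify`` block is present (a simulate-only config yields ground-truth
    summaries and no comparisons).
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_mapping(config)
    t0 = time.time()
    report: dict[str, Any] = {
        "version": __version__,
        "master_seed": config.seed,
        "config": config.to_mapping(),
        "conditions": {},
        "viability": {},
        "comparisons": [],
    }

    gc_params = GraphCutParams(**config.segmentation) if config.segmentation else GraphCutParams()
    pre_kw = dict(config.preprocess)

    per_image_ratios: dict[str, dict[str, list[float]]] = {}
    for cond in config.conditions:
        name = cond["name"]
        n_images = int(cond.get("n_images", 1))
        cond_report: dict[str, Any] = {"images": []}
        for i in range(n_images):
            seed_i = derive_seed(config.seed, f"simulate:{name}:{i}")
            params = _image_params(dict(cond.get("image", {})), seed_i)
            try:
                image, truth = generate_sphere_image(params)
            except Exception as exc:  # pragma: no cover - config errors
                raise StageError(f"simulate[{name}/{i}]: {exc}") from exc
            img_report: dict[str, Any] = {
                "seed": seed_i,
                "true_nuclei": truth.n_nuclei,
                "true_fractions": {
                    ch: truth.positive_fraction(ch)
                    for ch in (
                        list(params.marker_names)
                        + (["EdU"] if params.edu_fraction is not None else [])
                    )
                },
            }
            if config.quantify is not None:
                try:
                    pre = preprocess(image, **pre_kw)
                    mask = graphcut_binarize(pre, gc_params)
                    labels = split_and_label(mask, gc_params)
                except Exception as exc:
                    raise StageError(f"segment[{name}/{i}]: {exc}") from exc
                try:
                    table = measure_nuclei(image, labels)
                    img_report["n_nuclei"] = len(table)
                    channels = config.quantify.get(
                        "channels", list(params.marker_names)
                    )
                    if config.quantify.get("edu") and params.edu_fraction is not None:
                        channels = list(channels) + ["EdU"]
                    for ch in channels:
                        model = fit_threshold(
                            table,
                            ch,
                            k=int(config.quantify.get("k", 3)),
                            seed=derive_seed(config.seed, f"kmeans:{name}:{i}:{ch}"),
                            feature_mode=config.quantify.get(
                                "feature_mode", "mean_sd"
                            ),
                        )
                        classified = classify_cells(table, model)
                        rr = positive_ratio(classified, ch, condition=name)
                        img_report.setdefault("ratios", {})[ch] = {
                            "positive": rr.positive,
                            "total": rr.total,
                            "ratio": rr.ratio,
                            "percentage": rr.percentage,
                            "threshold": model.threshold,
                        }
                        per_image_ratios.setdefault(name, {}).setdefault(
                            ch, []
                        ).append(rr.ratio)
                except Exception as exc:
                    raise StageError(f"quantify[{name}/{i}]: {exc}") from exc
            cond_report["images"].append(img_report)
        if name in per_image_ratios:
            cond_report["ratio_summary"] = {
                ch: {
                    "per_image": vals,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "n": len(vals),
                }
                for ch, vals in per_image_ratios[name].items()
            }
        report["conditions"][name] = cond_report

    for cyt in config.cytometry:
        name = cyt.get("name", f"events_{len(report['viability'])}")
        seed_c = derive_seed(config.seed, f"events:{name}")
        try:
            ev_params = EventTableParams(seed=seed_c, **cyt.get("events", {}))
            events, truth = generate_event_table(ev_params)
            summary = gate_viability(events, method=cyt.get("method", "otsu"))
        except (TypeError, ValueError) as exc:
            raise StageError(f"cytometry[{name}]: {exc}") from exc
        report["viability"][name] = {
            "seed": seed_c,
            "n_events": summary.n_events,
            "dead_percent": summary.dead_percent,
            "viability_percent": summary.viability_percent,
            "gate_log10": summary.gate_log10,
            "true_viability_percent": 100.0
            * float((truth["population"] == "live").mean()),
        }

    for cmp_ in config.comparisons:
        a, b, ch = cmp_["a"], cmp_["b"], cmp_.get("channel")
        try:
            va = per_image_ratios[a][ch]
            vb = per_image_ratios[b][ch]
        except KeyError as exc:
            raise StageError(
                f"compare[{a} vs {b}]: missing per-image ratios for {exc}"
            ) from exc
        gc = compare(
            va, vb, variant=cmp_.get("test", "independent"),
            condition_a=a, condition_b=b,
        )
        report["comparisons"].append(
            {
                "a": a,
                "b": b,
                "channel": ch,
                "variant": gc.variant,
                "mean_a": gc.summary_a.mean,
                "sd_a": gc.summary_a.sd,
                "n_a": gc.summary_a.n,
                "mean_b": gc.summary_b.mean,
                "sd_b": gc.summary_b.sd,
                "n_b": gc.summary_b.n,
                "t": gc.t,
                "df": gc.df,
                "p": gc.p,
                "significant": gc.significant,
                "fold_change": gc.fold_change,
            }
        )

    report["runtime_s"] = round(time.time() - t0, 3)
    return report


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, default=float))
    return path
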