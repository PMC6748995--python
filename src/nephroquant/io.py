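"""Reading and writing the pipeline's on-disk formats.

Images travel as multi-channel TIFF (channel-first) with a JSON sidecar
recording channel roles and pixel size; label masks as 16-bit TIFF; tables
(ground truth, nuclei, events) as CSV; threshold models and summaries as
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .quantify import ThresholdModel
from .simulate import ImageStack

__all__ = [
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "write_threshold_model",
    "read_threshold_model",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(image: ImageStack, path: str | Path) -> Path:
    """Write an ImageStack as channel-first TIFF plus a JSON sidecar."""
    path = Path(path)
    names = list(image.channels)
    stack = np.stack([image.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(path, stack)
    meta = {"channels": names, "pixel_size_um": image.pixel_size_um}
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_image(path: str | Path) -> ImageStack:
    path = Path(path)
    stack = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    names = meta["channels"]
    if stack.shape[0] != len(names):
        raise ValueError(
            f"TIFF has {stack.shape[0]} channels but sidecar lists {len(names)}"
        )
    channels = {n: np.asarray(stack[i]) for i, n in enumerate(names)}
    return ImageStack(channels=channels, pixel_size_um=meta.get("pixel_size_um"))


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    if mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; uint16 TIFF insufficient")
    tifffile.imwrite(path, np.asarray(mask).astype(np.uint16))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_threshold_model(model: ThresholdModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "channel": model.channel,
        "k": model.k,
        "feature_mode": model.feature_mode,
        "centers": np.asarray(model.centers).tolist(),
        "assignments": np.asarray(model.assignments).tolist(),
        "threshold": model.threshold,
        "class_names": list(model.class_names),
        "feature_mean": np.asarray(model.feature_mean).tolist(),
        "feature_sd": np.asarray(model.feature_sd).tolist(),
        "n_negative": model.n_negative,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_threshold_model(path: str | Path) -> ThresholdModel:
    d = json.loads(Path(path).read_text())
    return ThresholdModel(
        channel=d["channel"],
        k=d["k"],
        feature_mode=d["feature_mode"],
        centers=np.asarray(d["centers"], dtype=float),
        assignments=np.asarray(d["assignments"], dtype=int),
        threshold=d["threshold"],
        class_names=tuple(d["class_names"]),
        feature_mean=np.asarray(d["feature_mean"], dtype=float),
        feature_sd=np.asarray(d["feature_sd"], dtype=float),
        n_negative=int(d.get("n_negative", 1)),
    )


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
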