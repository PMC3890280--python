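"""File formats: field images, label rasters, masks, manifests, sidecars.

Everything on disk is plain and interoperable: 8-bit RGB TIFF/PNG images,
16-bit single-channel TIFF instance rasters, 0/255 8-bit PNG masks, CSV
manifests and JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .segmentation import FieldImage
from .synthetic import GroundTruth

MANIFEST_COLUMNS = ["animal_id", "condition", "field_index", "image_path", "labels_path"]


def write_image(path: str | Path, image: FieldImage) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels, photometric="rgb")
    else:
        iio.imwrite(path, image.pixels)


def read_image(path: str | Path, **metadata) -> FieldImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    px = np.asarray(iio.imread(path))
    if px.ndim == 3 and px.shape[2] == 4:  # tolerate RGBA PNGs
        px = px[..., :3]
    return FieldImage(px, **metadata)


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label raster not found: {path}")
    return tifffile.imread(path).astype(np.int32)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def write_ground_truth_sidecar(path: str | Path, gt: GroundTruth) -> None:
    """JSON summary of one field's ground truth (fractions + per-fiber types)."""
    payload = {
        "true_total_fraction": gt.true_total_fraction,
        "true_type1_fraction": gt.true_type1_fraction,
        "true_type2b_fraction": gt.true_type2b_fraction,
        "n_fibers": int(len(gt.fiber_types)),
        "fiber_types": {str(k): v for k, v in gt.fiber_types.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, allow_nan=True))


def write_manifest(path: str | Path, rows: list[dict]) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks required columns: {sorted(missing)}")
    if "labels_path" not in df.columns:
        df["labels_path"] = None
    return df
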