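"""File adapters: multichannel TIFF, validated CSV tables, report JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthgen import CHANNEL_ORDER

FOCI_COLUMNS = ["model", "condition", "organoid", "nucleus",
                "cyca2_positive", "focus_count"]


class TableFormatError(ValueError):
    pass


def write_image_tiff(path, image: np.ndarray, channels=CHANNEL_ORDER):
    """Write a (C, H, W) stack as a multi-page TIFF, one page per channel,
    channel order recorded in the page description."""
    if image.ndim != 3 or image.shape[0] != len(channels):
        raise ValueError(f"expected ({len(channels)}, H, W), got {image.shape}")
    meta = json.dumps({"channels": list(channels)})
    tifffile.imwrite(str(path), image, description=meta)


def read_image_tiff(path, expected_channels=CHANNEL_ORDER):
    """Read a multi-page TIFF back to (C, H, W); validates the channel count
    and, when present, the recorded channel order."""
    with tifffile.TiffFile(str(path)) as tf:
        img = tf.asarray()
        desc = tf.pages[0].description
    if img.ndim == 2:
        img = img[None]
    if img.shape[0] != len(expected_channels):
        raise TableFormatError(
            f"{path}: expected {len(expected_channels)} channels, "
            f"got {img.shape[0]}")
    if desc:
        try:
            recorded = json.loads(desc).get("channels")
        except json.JSONDecodeError:
            recorded = None
        if recorded and tuple(recorded) != tuple(expected_channels):
            raise TableFormatError(
                f"{path}: channel order {recorded} != expected "
                f"{list(expected_channels)}")
    return img


def write_ground_truth_json(path, gt):
    """Ground-truth sidecar for a generated image (counts and positions;
    the label map travels with the TIFF, not the JSON)."""
    payload = {
        "condition": gt.condition,
        "pixel_size_um": gt.pixel_size_um,
        "cyca2_positive_labels": sorted(gt.cyca2_positive_labels),
        "foci_per_nucleus": {str(k): v for k, v in gt.foci_per_nucleus.items()},
        "foci_positions": {str(k): v for k, v in gt.foci_positions.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_foci_csv(path, table: pd.DataFrame):
    missing = [c for c in FOCI_COLUMNS if c not in table.columns]
    if missing:
        raise TableFormatError(f"FociTable missing columns {missing}")
    table[FOCI_COLUMNS].to_csv(path, index=False)


def read_foci_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FOCI_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    for i, row in df.iterrows():
        if row["focus_count"] < 0 or int(row["focus_count"]) != row["focus_count"]:
            # header is line 1, data starts at line 2
            raise TableFormatError(
                f"{path}: line {i + 2}: focus_count must be a non-negative "
                f"integer, got {row['focus_count']!r}")
    df["cyca2_positive"] = df["cyca2_positive"].astype(bool)
    df["focus_count"] = df["focus_count"].astype(int)
    return df


def read_variants(path) -> pd.DataFrame:
    """Variant table from TSV/CSV with gene, vaf, oncogenic, inactivating."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("gene", "vaf", "oncogenic", "inactivating"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col!r}")
    bad = df.index[(df.vaf < 0) | (df.vaf > 1)]
    if len(bad):
        raise TableFormatError(
            f"{path}: line {bad[0] + 2}: VAF outside [0, 1]")
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj


def report_write(path, report: dict):
    Path(path).write_text(json.dumps(_jsonable(report), indent=1, sort_keys=True))
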