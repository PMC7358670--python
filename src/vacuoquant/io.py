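"""Shared readers and writers.

All tabular outputs are UTF-8 comma-separated CSV with a mandatory header
row and '.' decimals; percentages are always stored on the 0-100 scale.
Every writer embeds the package version and the parameters that produced the
file: CSV files carry ``#``-prefixed metadata comment lines before the
header (the paired readers skip them), JSON files carry a ``meta`` object.
Images travel as single-channel 8-bit grayscale TIFFs named
``<cell_id>_CD4.tif`` / ``<cell_id>_LAMP1.tif`` with masks as 0/255
``<cell_id>_MASK.tif``; coordinates are row-major, 0-based.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synth import CellImagePair, SeverityClass

__version__ = "0.1.0"

__all__ = [
    "write_table",
    "read_table",
    "write_json",
    "read_json",
    "save_image_pair",
    "load_image_pair",
    "save_mask",
    "load_yaml",
    "jsonable",
]


def jsonable(obj):
    """Recursively convert package objects to JSON/YAML-safe primitives."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return jsonable(dataclasses.asdict(obj))
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, Mapping):
        return {str(jsonable(k)): jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _meta_lines(meta: Mapping | None) -> str:
    lines = [f"# vacuoquant {__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}={json.dumps(jsonable(v), sort_keys=True)}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_meta_lines(meta))
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj, path: str | Path, meta: Mapping | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"meta": {"package": f"vacuoquant {__version__}", **jsonable(meta or {})},
               "data": jsonable(obj)}
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def save_image_pair(pair: CellImagePair, out_dir: str | Path,
                    with_mask: bool = True) -> list[Path]:
    """Write one cell's channels (and true mask) as 8-bit grayscale TIFFs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for suffix, arr in (("CD4", pair.cd4_channel), ("LAMP1", pair.lamp1_channel)):
        p = out_dir / f"{pair.cell_id}_{suffix}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.uint8))
        paths.append(p)
    if with_mask and pair.true_mask is not None:
        p = out_dir / f"{pair.cell_id}_MASK.tif"
        tifffile.imwrite(p, (pair.true_mask.astype(np.uint8) * 255))
        paths.append(p)
    return paths


def save_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, mask.astype(np.uint8) * 255)
    return path


def load_image_pair(
    cell_id: str,
    in_dir: str | Path,
    class_label: SeverityClass | str | None = None,
) -> CellImagePair:
    """Read a ``<cell_id>_CD4.tif`` / ``<cell_id>_LAMP1.tif`` pair back."""
    in_dir = Path(in_dir)
    cd4 = tifffile.imread(in_dir / f"{cell_id}_CD4.tif")
    lamp1 = tifffile.imread(in_dir / f"{cell_id}_LAMP1.tif")
    mask_path = in_dir / f"{cell_id}_MASK.tif"
    mask = tifffile.imread(mask_path) > 0 if mask_path.exists() else None
    return CellImagePair(
        cd4_channel=cd4,
        lamp1_channel=lamp1,
        true_mask=mask,
        true_mean_lamp1=float("nan"),
        cell_id=cell_id,
        class_label=SeverityClass.from_label(class_label)
        if class_label is not None
        else SeverityClass.CONTROL,
    )


def load_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}
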