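"""Readers and writers shared across the package.

Volumes travel either as multi-page TIFF (one lateral ``(slow, fast)`` page
per time sample, float32, metadata in the image description) or as raw
little-endian float32 with a JSON sidecar describing shape, axis order and
sampling.  Readers validate headers against the data and refuse to coerce
mismatches silently.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .geometry import ScanGeometry
from .register import PointPairs
from .volume import PAVolume

__all__ = [
    "read_volume",
    "write_volume",
    "load_geometry",
    "save_geometry",
    "read_image",
    "write_image",
    "read_pairs",
    "write_pairs",
]

_AXIS_ORDER = "fast,slow,time"


def _meta(vol: PAVolume) -> dict:
    return {
        "shape": list(vol.shape),
        "dtype": "float32",
        "axis_order": _AXIS_ORDER,
        "step_fast_um": vol.step_fast_um,
        "step_slow_um": vol.step_slow_um,
        "sample_rate_hz": vol.sample_rate_hz,
        "endianness": "little",
    }


def write_volume(vol: PAVolume, path: str | Path) -> None:
    """Write a volume as .tif (multi-page) or .raw (+ .json sidecar)."""
    path = Path(path)
    data = np.asarray(vol.data, dtype="<f4")
    if path.suffix.lower() in (".tif", ".tiff"):
        pages = data.transpose(2, 1, 0)  # (time, slow, fast)
        tifffile.imwrite(path, pages, metadata={"swmpam": _meta(vol)})
    elif path.suffix.lower() == ".raw":
        data.tofile(path)
        path.with_suffix(".json").write_text(json.dumps(_meta(vol), indent=2))
    else:
        raise ValueError(f"unsupported volume suffix {path.suffix!r}")


def _check_meta(meta: dict, n_values: int) -> dict:
    shape = tuple(int(s) for s in meta["shape"])
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"invalid shape {shape} in header")
    if meta.get("axis_order", _AXIS_ORDER) != _AXIS_ORDER:
        raise ValueError(f"unsupported axis order {meta.get('axis_order')!r}")
    if int(np.prod(shape)) != n_values:
        raise ValueError(
            f"header shape {shape} does not match data size {n_values}")
    return meta


def read_volume(path: str | Path) -> PAVolume:
    """Read a volume written by :func:`write_volume`; lossless for float32."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            pages = tf.asarray()
            shaped = tf.shaped_metadata
        if not shaped or "swmpam" not in shaped[0]:
            raise ValueError(f"{path} carries no volume header")
        meta = shaped[0]["swmpam"]
        if pages.ndim == 2:
            pages = pages[None]
        data = pages.transpose(2, 1, 0)
        _check_meta(meta, data.size)
        if tuple(meta["shape"]) != data.shape:
            raise ValueError(f"TIFF pages {data.shape} disagree with header {meta['shape']}")
    elif path.suffix.lower() == ".raw":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        raw = np.fromfile(path, dtype="<f4")
        _check_meta(meta, raw.size)
        data = raw.reshape(tuple(meta["shape"]))
    else:
        raise ValueError(f"unsupported volume suffix {path.suffix!r}")
    return PAVolume(data,
                    step_fast_um=float(meta.get("step_fast_um", 4.0)),
                    step_slow_um=float(meta.get("step_slow_um", 6.0)),
                    sample_rate_hz=float(meta.get("sample_rate_hz", 50e6)))


def load_geometry(path: str | Path) -> ScanGeometry:
    """Load scan geometry from YAML/JSON; missing keys take the defaults."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ValueError("geometry file must contain a mapping")
    known = set(ScanGeometry.__dataclass_fields__)
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown geometry keys: {sorted(unknown)}")
    return ScanGeometry.from_dict(cfg)


def save_geometry(geometry: ScanGeometry, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(geometry.to_dict()))


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image as float in [0, 1]."""
    img = np.asarray(iio.imread(path)).astype(float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() > 1.0:
        img = img / (65535.0 if img.max() > 255 else 255.0)
    return img


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] (grayscale) or uint8 (RGB) image as 8-bit."""
    image = np.asarray(image)
    if image.dtype != np.uint8:
        image = np.clip(image, 0.0, 1.0)
        image = (image * 255.0 + 0.5).astype(np.uint8)
    iio.imwrite(Path(path), image)


def write_pairs(pairs: PointPairs, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["src_row", "src_col", "dst_row", "dst_col", "origin"])
        for (sr, sc), (dr, dc), o in zip(pairs.src, pairs.dst, pairs.origin):
            w.writerow([sr, sc, dr, dc, o])


def read_pairs(path: str | Path) -> PointPairs:
    src, dst, origin = [], [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            src.append((float(row["src_row"]), float(row["src_col"])))
            dst.append((float(row["dst_row"]), float(row["dst_col"])))
            origin.append(row.get("origin", "manual") or "manual")
    return PointPairs(src=np.array(src).reshape(-1, 2),
                      dst=np.array(dst).reshape(-1, 2), origin=origin)
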