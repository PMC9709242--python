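"""Readers and writers: TIFF/PNG rasters, CSV tables, YAML run configuration,
and the plain-text run log.

Images round-trip losslessly at native bit depth; intensities are never
rescaled on read.  RGB files are refused unless the caller supplies an
explicit plane -> channel-role mapping.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image as _PILImage

from .core import CHANNEL_ROLES, ChannelStack, Image2D, LabelMap, RunConfig

__all__ = [
    "read_image",
    "read_rgb_stack",
    "write_image",
    "read_labels",
    "write_labels",
    "export_table",
    "read_table",
    "save_config",
    "load_config",
    "write_run_log",
]

_RGB_PLANE = {"R": 0, "G": 1, "B": 2}


def _infer_bit_depth(arr: np.ndarray) -> int | str:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    return "float"


def _read_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return tifffile.imread(path)
    if suffix == ".png":
        return np.asarray(_PILImage.open(path))
    raise ValueError(f"unsupported raster format {suffix!r} (expected TIFF or PNG)")


def read_image(
    path: str | Path,
    channel_role: str = "generic",
    pixel_size_um: float | None = None,
) -> Image2D:
    """Read a single-plane grayscale TIFF or PNG at native bit depth.

    Fails on RGB input: a colour file carries no reliable channel identity,
    so it must go through :func:`read_rgb_stack` with an explicit mapping.
    """
    arr = _read_raster(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path} is multi-plane/RGB; use read_rgb_stack() with an explicit "
            "plane->role mapping instead of guessing channel identity"
        )
    return Image2D(pixels=arr, bit_depth=_infer_bit_depth(arr), pixel_size_um=pixel_size_um,
                   channel_role=channel_role)


def read_rgb_stack(
    path: str | Path,
    mapping: Mapping[str, str],
    pixel_size_um: float | None = None,
) -> ChannelStack:
    """Split an RGB raster into a :class:`ChannelStack`.

    ``mapping`` sends colour planes to channel roles, e.g.
    ``{"R": "red", "G": "green"}``.  Unmapped planes are dropped.
    """
    arr = _read_raster(path)
    if arr.ndim != 3 or arr.shape[-1] < 3:
        raise ValueError(f"{path} is not an RGB raster (shape {arr.shape})")
    if not mapping:
        raise ValueError("empty plane->role mapping")
    channels: dict[str, Image2D] = {}
    for plane, role in mapping.items():
        if plane not in _RGB_PLANE:
            raise ValueError(f"unknown colour plane {plane!r} (use R/G/B)")
        if role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {role!r}")
        plane_arr = arr[..., _RGB_PLANE[plane]]
        channels[role] = Image2D(pixels=plane_arr, bit_depth=_infer_bit_depth(plane_arr),
                                 pixel_size_um=pixel_size_um, channel_role=role)
    return ChannelStack(channels=channels)


def write_image(image: Image2D, path: str | Path) -> Path:
    """Write an image losslessly at its native bit depth (TIFF or PNG)."""
    path = Path(path)
    arr = image.pixels
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif suffix == ".png":
        if arr.dtype not in (np.uint8, np.uint16):
            raise ValueError("PNG output supports 8/16-bit integer rasters only")
        _PILImage.fromarray(arr).save(path)
    else:
        raise ValueError(f"unsupported output format {suffix!r}")
    return path


def write_labels(labels: LabelMap, path: str | Path) -> Path:
    """Save a label map as 16-bit TIFF (errors above 65535 objects)."""
    if labels.n_objects > np.iinfo(np.uint16).max:
        raise ValueError("too many objects for a 16-bit label TIFF")
    tifffile.imwrite(Path(path), labels.labels.astype(np.uint16))
    return Path(path)


def read_labels(path: str | Path) -> LabelMap:
    arr = tifffile.imread(Path(path))
    return LabelMap.from_array(arr.astype(np.int32))


def _records_to_frame(records: Iterable) -> pd.DataFrame:
    records = list(records)
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
            rows.append(dataclasses.asdict(rec))
        elif isinstance(rec, Mapping):
            rows.append(dict(rec))
        else:
            raise TypeError(f"cannot tabulate record of type {type(rec)}")
    if rows:
        schema = set(rows[0])
        for r in rows[1:]:
            if set(r) != schema:
                raise ValueError("records do not share a schema")
        if not schema:
            raise ValueError("records have an empty schema")
    return pd.DataFrame(rows)


def export_table(records, path: str | Path, columns: Sequence[str] | None = None) -> Path:
    """Write records (dataclasses, dicts, or a DataFrame) to CSV.

    Output always has a header row and dot-decimal numbers regardless of
    locale.  An empty record list needs ``columns`` to emit a header-only
    file.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = _records_to_frame(records)
    if frame.empty:
        if columns is None and frame.columns.empty:
            raise ValueError("empty record list: pass columns= to write a header-only CSV")
        if columns is not None:
            frame = pd.DataFrame(columns=list(columns))
    frame.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path


def load_config(path: str | Path) -> RunConfig:
    with open(Path(path)) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def write_run_log(config: RunConfig, path: str | Path, extra: Mapping | None = None) -> Path:
    """Write the full effective RunConfig (plus optional free-form notes) as a
    plain-text log so every run is reproducible from its artefacts."""
    path = Path(path)
    lines = [
        f"# spermaquant run log ({_dt.datetime.now().isoformat(timespec='seconds')})",
        "# coordinates: (row, col), 0-based, origin top-left",
        yaml.safe_dump(config.to_dict(), sort_keys=True).rstrip(),
    ]
    if extra:
        lines.append(yaml.safe_dump({"notes": dict(extra)}, sort_keys=True).rstrip())
    path.write_text("\n".join(lines) + "\n")
    return path
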