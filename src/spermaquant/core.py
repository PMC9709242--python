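"""Core raster containers shared by every assay pipeline.

Conventions used throughout the package:

* coordinates are ``(row, col)``, 0-based, origin at the top-left pixel;
* pixel intensities are native values straight off the file — nothing is
  rescaled or normalised on read, so thresholds always operate on the values
  the microscope produced;
* channel identity (``brightfield``/``green``/``red``/``generic``) is
  declared by the caller, never guessed from file metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "CHANNEL_ROLES",
    "Image2D",
    "ChannelStack",
    "LabelMap",
    "RunConfig",
]

CHANNEL_ROLES = ("brightfield", "green", "red", "generic")

#: allowed bit-depth declarations; "float" marks synthetic / computed rasters
BIT_DEPTHS = (8, 16, "float")


@dataclass
class Image2D:
    """A single-channel 2-D intensity raster with calibration metadata.

    Parameters
    ----------
    pixels:
        2-D array of finite, non-negative intensities.  The dtype is
        whatever the source provided (uint8/uint16/float); values are never
        auto-normalised.
    bit_depth:
        8, 16, or ``"float"``.
    pixel_size_um:
        Physical pixel pitch in micrometres, or ``None`` when the
        acquisition calibration is unknown.
    channel_role:
        One of :data:`CHANNEL_ROLES`.
    """

    pixels: np.ndarray
    bit_depth: int | str = "float"
    pixel_size_um: float | None = None
    channel_role: str = "generic"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError(f"pixels must be a 2-D raster, got shape {self.pixels.shape}")
        if self.bit_depth not in BIT_DEPTHS:
            raise ValueError(f"bit_depth must be one of {BIT_DEPTHS}, got {self.bit_depth!r}")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(f"channel_role must be one of {CHANNEL_ROLES}, got {self.channel_role!r}")
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive or None")
        arr = self.pixels
        if np.issubdtype(arr.dtype, np.floating):
            if not np.all(np.isfinite(arr)):
                raise ValueError("pixel values must be finite")
            if arr.min() < 0:
                raise ValueError("pixel values must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def astype_float(self) -> np.ndarray:
        """Pixels as float64 (no rescaling)."""
        return self.pixels.astype(np.float64, copy=False)

    def with_pixels(self, pixels: np.ndarray, bit_depth: int | str | None = None) -> "Image2D":
        return Image2D(
            pixels=pixels,
            bit_depth=self.bit_depth if bit_depth is None else bit_depth,
            pixel_size_um=self.pixel_size_um,
            channel_role=self.channel_role,
        )


@dataclass
class ChannelStack:
    """A set of same-sized :class:`Image2D` rasters keyed by channel role."""

    channels: Mapping[str, Image2D]

    def __post_init__(self) -> None:
        self.channels = dict(self.channels)
        if not self.channels:
            raise ValueError("ChannelStack needs at least one channel")
        shapes = {img.shape for img in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"all channels must share dimensions, got {shapes}")
        for role in self.channels:
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")

    def __getitem__(self, role: str) -> Image2D:
        if role not in self.channels:
            raise KeyError(f"stack has no {role!r} channel (has {sorted(self.channels)})")
        return self.channels[role]

    def __contains__(self, role: str) -> bool:
        return role in self.channels

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class LabelMap:
    """Segmented objects: integer raster where 0 is background and objects
    are labelled 1..n_objects with no gaps."""

    labels: np.ndarray
    n_objects: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        present = np.unique(self.labels)
        expected = np.arange(0, self.n_objects + 1)
        # background may be absent only in the degenerate all-foreground case
        nonzero = present[present > 0]
        if not np.array_equal(nonzero, expected[1:]):
            raise ValueError(
                f"labels must be exactly 1..{self.n_objects}; found {nonzero[:10]}..."
            )

    @classmethod
    def from_array(cls, labels: np.ndarray) -> "LabelMap":
        """Build a LabelMap from any integer raster, relabelling objects
        sequentially so labels are exactly {0} U {1..n}."""
        labels = np.asarray(labels)
        values = np.unique(labels)
        values = values[values > 0]
        out = np.zeros_like(labels, dtype=np.int32)
        for new, old in enumerate(values, start=1):
            out[labels == old] = new
        return cls(labels=out, n_objects=len(values))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def object_labels(self) -> np.ndarray:
        return np.arange(1, self.n_objects + 1)


@dataclass
class RunConfig:
    """Every tunable used by any pipeline stage, with its effective value.

    ``params`` is a mapping of stage name -> {parameter: value}.  The full
    effective config (defaults merged with overrides) is logged by
    :func:`spermaquant.io.write_run_log` for every run — the package's
    reproducibility contract.
    """

    seed: int = 0
    params: dict = field(default_factory=dict)
    output_dir: str = "."

    def stage(self, name: str, defaults: Mapping | None = None) -> dict:
        """Effective parameters for one stage: defaults overlaid with any
        user overrides, and written back so the run log is complete."""
        merged = dict(defaults or {})
        merged.update(self.params.get(name, {}))
        self.params[name] = merged
        return merged

    def to_dict(self) -> dict:
        return {"seed": int(self.seed), "params": self.params, "output_dir": str(self.output_dir)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        return cls(
            seed=int(d.get("seed", 0)),
            params=dict(d.get("params", {})),
            output_dir=str(d.get("output_dir", ".")),
        )
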