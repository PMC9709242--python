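"""Redox-probe and whole-animal reporter intensity quantification.

Per-spermatid redox readout: the mean fluorescence under each (ellipse)
label from the Triangle-threshold mask.  Whole-animal reporters follow the
adjusted/relative convention: adjusted = animal mean grey value minus the
average of all background readings, then each adjusted value is divided by
the control-group mean so the control group's mean relative intensity is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import Image2D, LabelMap

__all__ = [
    "ReporterMeasurement",
    "redox_mean_intensity",
    "reporter_adjusted",
    "reporter_relative",
    "polygon_roi_mean",
]


@dataclass
class ReporterMeasurement:
    animal_id: str
    mean_grey_animal: float
    mean_grey_background: float
    adjusted_intensity: float
    relative_intensity: float | None = None
    negative_adjusted: bool = False       # background exceeded the animal
    roi_provenance: str = "manual"        # "manual" polygon or "auto" mask


def redox_mean_intensity(image: Image2D, cells: LabelMap) -> dict[int, float]:
    """Mean probe fluorescence per segmented spermatid.

    Background area around the field does not enter any label, so the means
    are invariant to padding the image.
    """
    if cells.shape != image.shape:
        raise ValueError("cell labels do not match image geometry")
    index = cells.object_labels()
    if len(index) == 0:
        return {}
    means = ndi.mean(image.astype_float(), labels=cells.labels, index=index)
    out = {}
    for label, m in zip(index, means):
        if not np.isfinite(m):
            raise ValueError(f"empty label {label}")
        out[int(label)] = float(m)
    return out


def reporter_adjusted(animal_mask_mean: float, background_means: list[float]) -> tuple[float, bool]:
    """Adjusted intensity = animal mean - mean(background readings).

    Returns ``(adjusted, negative_flag)``; a negative value (background
    brighter than the animal) is returned as-is but flagged.
    """
    if not background_means:
        raise ValueError("need at least one background reading")
    adjusted = float(animal_mask_mean) - float(np.mean(background_means))
    return adjusted, adjusted < 0


def reporter_relative(
    adjusted_values: dict[str, float],
    control_group_ids: list[str],
) -> dict[str, float]:
    """Relative intensity per animal: adjusted / control-group mean adjusted.

    The control group's own mean relative intensity is 1 by construction;
    re-normalising against the same control leaves values unchanged, and
    scaling every adjusted value by a constant leaves them unchanged too.
    """
    missing = [a for a in control_group_ids if a not in adjusted_values]
    if missing or not control_group_ids:
        raise ValueError(f"control group empty or missing animals: {missing}")
    control_mean = float(np.mean([adjusted_values[a] for a in control_group_ids]))
    if control_mean <= 0:
        raise ValueError(f"control-group mean adjusted intensity must be > 0, got {control_mean}")
    return {a: float(v) / control_mean for a, v in adjusted_values.items()}


def polygon_roi_mean(image: Image2D, vertices: np.ndarray) -> float:
    """Mean intensity inside a polygon ROI given as (row, col) vertices —
    the manual-selection route for whole-animal measurements."""
    from skimage import draw as skdraw

    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[0] < 3 or vertices.shape[1] != 2:
        raise ValueError("polygon needs >= 3 (row, col) vertices")
    rr, cc = skdraw.polygon(vertices[:, 0], vertices[:, 1], shape=image.shape)
    if rr.size == 0:
        raise ValueError("polygon covers no pixels")
    return float(image.astype_float()[rr, cc].mean())


def auto_animal_mask(image: Image2D) -> LabelMap:
    """Automatic worm mask: Otsu threshold, keep the largest component.

    Offered for synthetic tests and quick passes; the provenance field of
    the resulting measurements should record "auto"."""
    from skimage import filters as skfilters

    pixels = image.astype_float()
    if np.ptp(pixels) == 0:
        raise ValueError("constant image: no animal to mask")
    mask = pixels > skfilters.threshold_otsu(pixels)
    lab, n = ndi.label(mask, structure=ndi.generate_binary_structure(2, 2))
    if n == 0:
        raise ValueError("no foreground found")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    keep = int(np.argmax(sizes))
    return LabelMap((lab == keep).astype(np.int32), 1)
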