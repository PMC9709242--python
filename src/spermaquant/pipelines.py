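"""End-to-end assay drivers: one call per figure-level analysis.

Each driver wires the module stages together in the order the assays used
them, collects per-object tables (so every summary row traces back to the
objects behind it), and echoes the full effective RunConfig into a run log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters as skfilters
from skimage import morphology as skmorph

from .core import ChannelStack, Image2D, LabelMap, RunConfig
from .mitochondria import (MitoParams, count_mitochondria_per_cell,
                           detect_mitochondria, jc1_ratio,
                           measure_mitochondria, preprocess_mito, size_filter)
from .morphometry import (ActivationRules, AssaySummary, classify_activation,
                          measure_labels, records_to_frame,
                          summarize_activation)
from .segmentation import MaskingParams, binary_watershed, segment_jc1_cells
from .synth import generate_preset

__all__ = [
    "ActivationResult",
    "Jc1Result",
    "segment_activation_field",
    "run_activation_assay",
    "run_jc1_assay",
    "run_group_summary",
]


@dataclass
class ActivationResult:
    summary: AssaySummary
    cells: pd.DataFrame                      # per-cell morphometry + class
    labels: list[LabelMap] = field(default_factory=list)
    config: RunConfig | None = None


@dataclass
class Jc1Result:
    ratios: pd.DataFrame
    mito_morphometry: pd.DataFrame           # per mitochondrion, per channel
    counts: pd.DataFrame                     # per cell x channel
    cell_labels: LabelMap | None = None
    config: RunConfig | None = None


ACTIVATION_SEG_DEFAULTS = {
    "min_object_px": 120,       # well below one spermatid (~450 px at r=12)
    "use_watershed": False,     # dissected fields are sparse; splitting a
                                # pseudopod-bearing cell would corrupt shape
    "watershed_min_distance": 10,
}


def segment_activation_field(image: Image2D, config: RunConfig | None = None) -> LabelMap:
    """Whole-cell mask for dissected-spermatid fields: Otsu threshold, fill
    holes, size filter, connected components (watershed optional)."""
    config = config or RunConfig()
    params = config.stage("activation_segmentation", ACTIVATION_SEG_DEFAULTS)
    pixels = image.astype_float()
    if np.ptp(pixels) == 0:
        return LabelMap(np.zeros(pixels.shape, np.int32), 0)
    mask = pixels > skfilters.threshold_otsu(pixels)
    mask = ndi.binary_fill_holes(mask)
    # 1-px opening strips single-pixel threshold artifacts at cell rims that
    # would otherwise bite into solidity; real protrusions are far wider
    mask = skmorph.opening(mask, footprint=skmorph.disk(1))
    mask = size_filter(mask, params["min_object_px"])
    if params["use_watershed"]:
        labels = binary_watershed(mask, params["watershed_min_distance"])
    else:
        labels, _ = ndi.label(mask, structure=ndi.generate_binary_structure(2, 2))
    return LabelMap.from_array(labels.astype(np.int32))


def run_activation_assay(
    inputs,
    config: RunConfig | None = None,
    rules: ActivationRules | None = None,
) -> ActivationResult:
    """Pronase activation assay: segment -> morphometry -> classify ->
    summarize.

    ``inputs`` is a preset name (synthetic field generated at the config
    seed), a single Image2D, or a list of Image2D.  Raises when no cells are
    found in any image.
    """
    config = config or RunConfig()
    rules = rules or ActivationRules()
    if isinstance(inputs, str):
        _, (image, _truth) = generate_preset(inputs, seed=config.seed)
        images = [image]
        config.stage("synthesis", {"preset": inputs, "seed": config.seed})
    elif isinstance(inputs, Image2D):
        images = [inputs]
    else:
        images = list(inputs)

    all_morphs, all_calls, labelmaps = [], [], []
    offset = 0
    for image in images:
        labels = segment_activation_field(image, config)
        labelmaps.append(labels)
        morphs = measure_labels(labels, image=image,
                                opening_radius_px=rules.opening_radius_px)
        calls = [classify_activation(m, rules) for m in morphs]
        for m in morphs:
            m.label += offset
        for c in calls:
            c.label += offset
        offset += labels.n_objects
        all_morphs.extend(morphs)
        all_calls.extend(calls)

    if not all_calls:
        raise ValueError("zero cells found in all images")
    summary = summarize_activation(all_calls)
    cells = records_to_frame(all_morphs, all_calls)
    config.stage("activation_rules", vars(rules))
    return ActivationResult(summary=summary, cells=cells, labels=labelmaps,
                            config=config)


def run_jc1_assay(
    inputs,
    config: RunConfig | None = None,
    masking: MaskingParams | None = None,
    mito_params: MitoParams | None = None,
) -> Jc1Result:
    """JC-1 assay chain: generous-green cell mask -> per-cell red:green
    ratios; per channel: preprocess -> detect -> measure + count.

    ``inputs`` is a preset name or a ChannelStack with red and green
    channels.
    """
    config = config or RunConfig()
    masking = masking or MaskingParams(method="generous_green")
    mito_params = mito_params or MitoParams()
    if isinstance(inputs, str):
        _, (stack, _truth) = generate_preset(inputs, seed=config.seed)
        config.stage("synthesis", {"preset": inputs, "seed": config.seed})
    else:
        stack = inputs
    if not isinstance(stack, ChannelStack):
        raise TypeError("run_jc1_assay needs a ChannelStack or preset name")
    for role in ("red", "green"):
        if role not in stack:
            raise ValueError(f"missing {role} channel")

    cells = segment_jc1_cells(stack, masking)
    ratio_records = jc1_ratio(stack, cells)
    ratios = pd.DataFrame([vars(r) for r in ratio_records], columns=[
        "cell_label", "total_red", "total_green", "mean_red", "mean_green",
        "red_green_ratio", "ratio_defined"])

    morph_frames, count_rows = [], []
    for role in ("red", "green"):
        pre = preprocess_mito(stack[role], mito_params)
        mito = detect_mitochondria(pre, mito_params, intensity=stack[role])
        morph_frames.append(measure_mitochondria(mito, image=stack[role],
                                                 cells=cells, channel=role))
        counts = count_mitochondria_per_cell(mito, cells, image=pre,
                                             params=mito_params)
        for cell, cnt in sorted(counts.items()):
            count_rows.append({"cell_label": cell, "channel": role, "count": cnt})

    config.stage("jc1_masking", vars(masking))
    config.stage("mitochondria", vars(mito_params))
    return Jc1Result(
        ratios=ratios,
        mito_morphometry=pd.concat(morph_frames, ignore_index=True),
        counts=pd.DataFrame(count_rows, columns=["cell_label", "channel", "count"]),
        cell_labels=cells,
        config=config,
    )


def run_group_summary(table: pd.DataFrame, group_column: str,
                      value_column: str) -> pd.DataFrame:
    """Mean +/- SEM (sample sd / sqrt(n)) and n per group.

    A single-value group reports SEM as nan and is flagged; an empty group
    column raises.
    """
    if group_column not in table.columns or value_column not in table.columns:
        raise ValueError("group or value column missing from table")
    rows = []
    for group, grp in table.groupby(group_column, sort=True):
        vals = grp[value_column].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"group {group!r} has no values")
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
        rows.append({"group": group, "mean": float(vals.mean()), "sem": sem,
                     "n": int(vals.size), "single_value": vals.size == 1})
    return pd.DataFrame(rows)
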