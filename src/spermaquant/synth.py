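"""Ground-truthed synthetic microscopy for every assay in the package.

The generator renders the image classes the real assays produce, with the
truth recorded object-by-object, so every downstream stage (segmentation,
morphometry, classification, mitochondrial pipelines, motility statistics)
can be validated without access to the original micrographs:

* Pronase activation fields — round spermatids, spermatids with a small
  protrusion, activated spermatozoa with a tapered pseudopod, and abnormal
  morphs (thin spiked protrusion, swollen at 1.5x area, or with an internal
  dark vacuole), over an uneven background.
* Two-channel JC-1 fields — mitochondria as anisotropic Gaussian blobs with
  per-mitochondrion red/green amplitudes; the green channel carries a diffuse
  cell-body signal so a generous green threshold captures whole spermatids.
  A "mutant" preset has larger/elongated mitochondria, a higher fraction of
  green-dominant (low membrane potential) mitochondria, and a wider per-cell
  red:green spread at the same mean.
* Single-channel reporter images — a worm-shaped region of known mean over a
  background of known mean.
* A uterus time-lapse — bright sperm puncta between a vulva and a
  spermatheca landmark, moving with configured speeds.

Class counts in activation fields are *stratified*: exactly the
largest-remainder rounding of mixture x n, never a binomial draw, so
fraction-recovery tests isolate classifier error from sampling error.
All randomness flows from one seeded generator; identical config + seed
gives byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw as skdraw

from .core import ChannelStack, Image2D
from .morphometry import ACTIVATION_CLASSES

__all__ = [
    "SynthesisConfig",
    "GroundTruth",
    "largest_remainder_counts",
    "synth_spermatid_field",
    "synth_jc1_field",
    "synth_reporter_animal",
    "synth_uterus_timelapse",
    "PRESETS",
    "preset",
    "generate_preset",
]

ABNORMAL_MORPHS = ("spiked", "swollen", "vacuolated")


@dataclass
class SynthesisConfig:
    """All tunables of the synthetic generator (defaults = study conditions).

    Geometry is in pixels; the assays' absolute spermatid size in um is not
    pinned down by the source data, so the default radius (12 px, ~5%
    coefficient of variation — spermatid size is tightly controlled) is a
    plausible placeholder, flagged as such in docs/methods.md.
    """

    seed: int = 0
    image_size: tuple[int, int] = (1280, 1280)
    n_cells: int = 200
    #: fractions over (spermatid, small_protrusion, spermatozoon, abnormal)
    class_mixture: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)
    cell_radius_px: tuple[float, float] = (12.0, 0.5)         # mean, sd
    cell_amp: tuple[float, float] = (120.0, 8.0)              # mean, sd
    #: pseudopod (length, width) as fractions of the cell diameter
    pseudopod: tuple[float, float] = (0.8, 0.35)
    small_protrusion_shape: tuple[float, float] = (0.35, 0.45)
    spike_shape: tuple[float, float] = (0.6, 0.20)
    swollen_area_factor: float = 1.5
    vacuole_radius_frac: float = 0.35
    vacuole_depth: float = 0.7        # fraction of cell amplitude removed
    touching_cell_fraction: float = 0.0
    # --- JC-1 fields ---
    jc1_cell_radius_px: tuple[float, float] = (16.0, 0.8)
    mito_per_cell: tuple[float, float] = (6.0, 1.0)           # mean, sd
    mito_radius_px: tuple[float, float] = (2.0, 0.2)          # minor sigma
    mito_elongation: tuple[float, float] = (1.2, 0.15)        # aspect ratio
    #: per-cell red:green ratio ~ LogNormal with this (mean, sigma)
    mmp_profile: tuple[float, float] = (2.0, 0.15)
    mito_green_amp: tuple[float, float] = (120.0, 10.0)
    green_body_amp: float = 20.0
    red_blob_factor: float = 8.0      # red amp of a high-MMP mito = k x green amp
    low_mmp_fraction: float = 0.0
    low_mmp_green_boost: float = 1.3
    # --- reporter animals ---
    worm_mean: float = 50.0
    worm_brightness_factor: float = 1.0
    background_mean: float = 10.0
    worm_radius_px: float = 14.0
    # --- uterus time-lapse ---
    n_sperm: int = 25
    n_frames: int = 10
    frame_interval_s: float = 30.0
    speed_px_per_s: tuple[float, float] = (0.15, 0.04)        # mean, sd
    axis_beta: tuple[float, float] = (1.0, 1.0)               # placement bias
    # --- shared rendering ---
    background: tuple[float, float] = (8.0, 4.0)              # level, gradient amp
    noise_gaussian_sd: float = 2.0
    noise_poisson: bool = False
    edge_sigma: float = 1.0
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        mix = np.asarray(self.class_mixture, dtype=float)
        if mix.shape != (4,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("class_mixture must be 4 non-negative fractions summing to 1")
        for name in ("touching_cell_fraction", "low_mmp_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")


@dataclass
class GroundTruth:
    """Per-object truth matching the rendered instance map."""

    cells: pd.DataFrame | None = None
    mitochondria: pd.DataFrame | None = None
    labels: np.ndarray | None = None          # instance map, 0 = background
    scene: "object | None" = None             # UterusScene for time-lapses
    tracks: pd.DataFrame | None = None
    info: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def largest_remainder_counts(fractions: Sequence[float], n: int) -> np.ndarray:
    """Integer counts summing to ``n``: floor(f*n) plus one unit to the
    largest fractional remainders (ties broken by position)."""
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    raw = f * n
    counts = np.floor(raw).astype(int)
    remainder = int(n - counts.sum())
    if remainder:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def _background_field(cfg: SynthesisConfig, shape: tuple[int, int]) -> np.ndarray:
    level, grad = cfg.background
    cols = np.linspace(-0.5, 0.5, shape[1])
    return level + grad * np.broadcast_to(cols, shape).copy()


def _finish_render(cfg: SynthesisConfig, rng: np.random.Generator,
                   scene: np.ndarray) -> np.ndarray:
    if cfg.edge_sigma > 0:
        scene = ndi.gaussian_filter(scene, sigma=cfg.edge_sigma)
    if cfg.noise_poisson:
        scene = rng.poisson(np.clip(scene, 0, None)).astype(float)
    if cfg.noise_gaussian_sd > 0:
        scene = scene + rng.normal(0.0, cfg.noise_gaussian_sd, size=scene.shape)
    return np.clip(scene, 0.0, None)


def _grid_positions(shape: tuple[int, int], half_extent: float, sep: float) -> np.ndarray:
    pitch = 2 * half_extent + sep
    margin = half_extent + 2
    rows = np.arange(margin, shape[0] - margin + 1e-9, pitch)
    cols = np.arange(margin, shape[1] - margin + 1e-9, pitch)
    if len(rows) == 0 or len(cols) == 0:
        return np.empty((0, 2))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


def _place_cells(rng: np.random.Generator, shape: tuple[int, int],
                 half_extents: np.ndarray, radii: np.ndarray,
                 touching_fraction: float) -> np.ndarray:
    """Non-overlapping centres on a jittered grid; a configured fraction of
    cells is re-placed tangent to a partner to form touching pairs."""
    n = len(half_extents)
    h_max = float(half_extents.max(initial=1.0))
    positions = _grid_positions(shape, h_max, sep=4.0)
    if len(positions) < n:
        raise ValueError(
            f"image {shape} too small to place {n} cells without exceeding "
            f"the overlap budget ({len(positions)} slots available)"
        )
    chosen = positions[rng.permutation(len(positions))[:n]]
    chosen = chosen + rng.uniform(-1.5, 1.5, size=chosen.shape)

    n_pairs = int(round(touching_fraction * n / 2.0))
    for k in range(n_pairs):
        a, b = 2 * k, 2 * k + 1
        if b >= n:
            break
        target = radii[a] + radii[b] - 1.0  # slight overlap -> one component
        for _ in range(24):
            theta = rng.uniform(0, 2 * np.pi)
            cand = chosen[a] + target * np.array([np.sin(theta), np.cos(theta)])
            if not (half_extents[b] + 2 <= cand[0] <= shape[0] - half_extents[b] - 2
                    and half_extents[b] + 2 <= cand[1] <= shape[1] - half_extents[b] - 2):
                continue
            others = np.delete(np.arange(n), [a, b])
            d = np.linalg.norm(chosen[others] - cand, axis=1)
            if np.all(d >= half_extents[others] + half_extents[b] + 2):
                chosen[b] = cand
                break
    return chosen


def _tapered_protrusion(mask: np.ndarray, center: tuple[float, float], r: float,
                        length: float, width: float, theta: float) -> None:
    """Rasterise a tapered protrusion onto a local boolean mask, attached to
    a circle of radius ``r`` at angle ``theta``."""
    u = np.array([np.sin(theta), np.cos(theta)])
    p = np.array([u[1], -u[0]])
    base = np.asarray(center) + (r - 2.0) * u
    tip = np.asarray(center) + (r + length) * u
    w0 = width / 2.0
    w1 = max(width * 0.30 / 2.0, 0.6)
    corners = np.array([
        base + w0 * p, base - w0 * p, tip - w1 * p, tip + w1 * p,
    ])
    rr, cc = skdraw.polygon(corners[:, 0], corners[:, 1], shape=mask.shape)
    mask[rr, cc] = True


def _cell_geometry(rng: np.random.Generator, cfg: SynthesisConfig, cls: str,
                   submorph: str | None, r: float) -> tuple[np.ndarray, dict]:
    """Local boolean mask for one cell (centred), plus rendering extras."""
    if cls == "abnormal" and submorph == "swollen":
        r_draw = r * np.sqrt(cfg.swollen_area_factor)
    else:
        r_draw = r
    length_frac = {"small_protrusion": cfg.small_protrusion_shape,
                   "spermatozoon": cfg.pseudopod,
                   "spiked": cfg.spike_shape}.get(submorph or cls, (0.0, 0.0))
    half = int(np.ceil(r_draw + 2 * r * length_frac[0])) + 4
    side = 2 * half + 1
    mask = np.zeros((side, side), dtype=bool)
    rr, cc = skdraw.disk((half, half), r_draw, shape=mask.shape)
    mask[rr, cc] = True
    extras: dict = {"half": half, "r_draw": r_draw}

    if length_frac[0] > 0:
        theta = rng.uniform(0, 2 * np.pi)
        _tapered_protrusion(mask, (half, half), r_draw,
                            length=2 * r * length_frac[0],
                            width=2 * r * length_frac[1], theta=theta)
        extras["protrusion_theta"] = theta
    if cls == "abnormal" and submorph == "vacuolated":
        off_theta = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(0.0, 0.3) * r
        v_center = (half + off * np.sin(off_theta), half + off * np.cos(off_theta))
        v_r = cfg.vacuole_radius_frac * r
        vrr, vcc = skdraw.disk(v_center, v_r, shape=mask.shape)
        extras["vacuole"] = (vrr, vcc)
    return mask, extras


# ---------------------------------------------------------------------------
# Pronase activation fields
# ---------------------------------------------------------------------------

def synth_spermatid_field(cfg: SynthesisConfig) -> tuple[Image2D, GroundTruth]:
    """Render a dissected-spermatid field with stratified class counts.

    Returns a brightfield-like image (bright cells on a dim, optionally
    graded background) and the ground truth: one row per cell with its true
    class, sub-morph, centroid and label, plus the instance map.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.image_size)
    counts = largest_remainder_counts(cfg.class_mixture, cfg.n_cells)

    classes: list[str] = []
    submorphs: list[str | None] = []
    for cls, cnt in zip(ACTIVATION_CLASSES, counts):
        for _ in range(cnt):
            classes.append(cls)
            if cls == "abnormal":
                submorphs.append(ABNORMAL_MORPHS[rng.integers(len(ABNORMAL_MORPHS))])
            elif cls in ("small_protrusion", "spermatozoon"):
                submorphs.append(cls)
            else:
                submorphs.append(None)
    order = rng.permutation(cfg.n_cells)
    classes = [classes[i] for i in order]
    submorphs = [submorphs[i] for i in order]

    radii = np.clip(rng.normal(*cfg.cell_radius_px, size=cfg.n_cells), 4.0, None)
    amps = np.clip(rng.normal(*cfg.cell_amp, size=cfg.n_cells), 10.0, None)
    geoms = [_cell_geometry(rng, cfg, classes[i], submorphs[i], radii[i])
             for i in range(cfg.n_cells)]
    half_extents = np.array([g[1]["half"] for g in geoms], dtype=float)
    draw_radii = np.array([g[1]["r_draw"] for g in geoms], dtype=float)
    centers = _place_cells(rng, shape, half_extents, draw_radii,
                           cfg.touching_cell_fraction)

    amp_canvas = np.zeros(shape, dtype=float)
    label_map = np.zeros(shape, dtype=np.int32)
    rows = []
    for i, ((mask, extras), center) in enumerate(zip(geoms, centers)):
        label = i + 1
        half = extras["half"]
        r0 = int(round(center[0])) - half
        c0 = int(round(center[1])) - half
        mrr, mcc = np.nonzero(mask)
        grr, gcc = mrr + r0, mcc + c0
        keep = (grr >= 0) & (grr < shape[0]) & (gcc >= 0) & (gcc < shape[1])
        grr, gcc = grr[keep], gcc[keep]
        amp_canvas[grr, gcc] = amps[i]
        label_map[grr, gcc] = label
        if "vacuole" in extras:
            vrr, vcc = extras["vacuole"]
            amp_canvas[vrr + r0, vcc + c0] = amps[i] * (1.0 - cfg.vacuole_depth)
        rows.append({
            "label": label, "true_class": classes[i],
            "submorph": submorphs[i] or "", "centroid_row": r0 + half,
            "centroid_col": c0 + half, "radius_px": radii[i], "amp": amps[i],
        })

    scene = _background_field(cfg, shape) + amp_canvas
    pixels = _finish_render(cfg, rng, scene)
    image = Image2D(pixels=pixels, bit_depth="float",
                    pixel_size_um=cfg.pixel_size_um, channel_role="brightfield")
    truth = GroundTruth(cells=pd.DataFrame(rows), labels=label_map,
                        info={"counts": dict(zip(ACTIVATION_CLASSES, counts.tolist()))})
    return image, truth


# ---------------------------------------------------------------------------
# JC-1 two-channel fields
# ---------------------------------------------------------------------------

def _gaussian_blob(box: np.ndarray, center: tuple[float, float],
                   sigma_u: float, sigma_v: float, theta: float,
                   amp: float) -> None:
    """Add an anisotropic Gaussian blob (truncated at 4 sigma) to ``box``."""
    extent = int(np.ceil(4 * sigma_u)) + 1
    r0 = max(int(center[0]) - extent, 0)
    r1 = min(int(center[0]) + extent + 1, box.shape[0])
    c0 = max(int(center[1]) - extent, 0)
    c1 = min(int(center[1]) + extent + 1, box.shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * np.sin(theta) + dc * np.cos(theta)
    v = dr * np.cos(theta) - dc * np.sin(theta)
    box[r0:r1, c0:c1] += amp * np.exp(-0.5 * (u ** 2 / sigma_u ** 2 +
                                              v ** 2 / sigma_v ** 2))


def synth_jc1_field(cfg: SynthesisConfig) -> tuple[ChannelStack, GroundTruth]:
    """Render a red/green JC-1 field of round spermatids with mitochondria.

    High-MMP mitochondria fluoresce in red at a fixed multiple
    (``red_blob_factor``) of their green amplitude — JC-1 aggregate emission
    tracks monomer loading — so red blobs are uniformly detectable across
    cells.  The drawn per-cell red:green ratio is realised by adjusting the
    diffuse green cell-body amplitude; ``true_ratio`` records the ratio of
    the noiseless per-cell channel integrals exactly.  Green-dominant
    (low-MMP) mitochondria contribute no red signal, so red-channel
    detections undercount exactly the low-MMP population.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.image_size)
    n = cfg.n_cells
    radii = np.clip(rng.normal(*cfg.jc1_cell_radius_px, size=n), 8.0, None)
    sig_v_mean = cfg.mito_radius_px[0]
    capacity = max(1.0, 0.6 * radii.min() ** 2 / sig_v_mean ** 2)
    if cfg.mito_per_cell[0] > capacity:
        raise ValueError(
            f"mito_per_cell mean {cfg.mito_per_cell[0]} exceeds cell capacity "
            f"(~{capacity:.1f} for radius {radii.min():.1f} px)"
        )

    pad = 12.0  # blob tails + smoothing stay inside each cell's influence region
    half_extents = radii + pad
    centers = _place_cells(rng, shape, half_extents, radii,
                           cfg.touching_cell_fraction)

    green = np.zeros(shape, dtype=float)
    red = np.zeros(shape, dtype=float)
    label_map = np.zeros(shape, dtype=np.int32)
    ratio_mean, ratio_sigma = cfg.mmp_profile
    mu = np.log(ratio_mean) - 0.5 * ratio_sigma ** 2
    k = cfg.red_blob_factor

    cell_rows, mito_rows = [], []
    for i in range(n):
        label = i + 1
        r = radii[i]
        half = int(np.ceil(r + pad))
        side = 2 * half + 1
        high = np.zeros((side, side), dtype=float)
        low = np.zeros((side, side), dtype=float)
        drr, dcc = skdraw.disk((half, half), r, shape=high.shape)
        disk_area = float(len(drr))

        n_mito = max(1, int(round(rng.normal(*cfg.mito_per_cell))))
        ratio_c = float(np.exp(rng.normal(mu, ratio_sigma)))
        mitos = []
        placed: list[tuple[float, float, float]] = []   # (row, col, sigma_u)
        for _ in range(n_mito):
            sigma_v = float(np.clip(rng.normal(*cfg.mito_radius_px), 0.8, None))
            ar = float(np.clip(rng.normal(*cfg.mito_elongation), 1.0, None))
            sigma_u = ar * sigma_v
            sigma_u = min(sigma_u, (r - 2.0) / 2.0)  # keep the blob inside the cell
            ar = sigma_u / sigma_v
            theta = rng.uniform(0, 2 * np.pi)
            max_off = max(r - (1.5 * sigma_u + 1.0), 0.0)
            # keep mitochondria apart so they render as discrete organelles
            for _try in range(40):
                rho = np.sqrt(rng.uniform()) * max_off
                phi = rng.uniform(0, 2 * np.pi)
                center = (half + rho * np.sin(phi), half + rho * np.cos(phi))
                if all(np.hypot(center[0] - pr, center[1] - pc)
                       >= 1.8 * (sigma_u + ps) for pr, pc, ps in placed):
                    break
            placed.append((center[0], center[1], sigma_u))
            g_amp = float(np.clip(rng.normal(*cfg.mito_green_amp), 5.0, None))
            is_low = bool(rng.uniform() < cfg.low_mmp_fraction)
            if is_low:
                g_amp *= cfg.low_mmp_green_boost
                _gaussian_blob(low, center, sigma_u, sigma_v, theta, g_amp)
            else:
                _gaussian_blob(high, center, sigma_u, sigma_v, theta, g_amp)
            mitos.append({"cell_label": label, "row": center[0], "col": center[1],
                          "sigma_minor": sigma_v, "aspect_ratio": ar,
                          "theta": theta, "green_amp": g_amp, "low_mmp": is_low})

        # body dilution realises the drawn ratio: red = k*GH must satisfy
        # ratio_c = k*GH / (GH + GL + body); clamp body to stay non-negative
        gh = float(high.sum())
        gl = float(low.sum())
        body_amp = cfg.green_body_amp
        if gh > 0 and ratio_c > 0:
            body_amp = (gh * (k / ratio_c - 1.0) - gl) / disk_area
        body_amp = float(np.clip(body_amp, 2.0, None))
        body = np.zeros((side, side), dtype=float)
        body[drr, dcc] = body_amp
        g_total = float(body.sum() + gh + gl)
        true_ratio = k * gh / g_total if g_total > 0 else 0.0

        r0 = int(round(centers[i][0])) - half
        c0 = int(round(centers[i][1])) - half
        sl = (slice(r0, r0 + side), slice(c0, c0 + side))
        green[sl] += body + high + low
        red[sl] += k * high
        label_map[drr + r0, dcc + c0] = label
        for m in mitos:
            m["row"] += r0
            m["col"] += c0
            m["red_amp"] = k * m["green_amp"] if not m["low_mmp"] else 0.0
        mito_rows.extend(mitos)
        cell_rows.append({
            "label": label, "centroid_row": r0 + half, "centroid_col": c0 + half,
            "radius_px": r, "n_mito": n_mito,
            "n_low_mmp": sum(m["low_mmp"] for m in mitos),
            "true_ratio": true_ratio,
            "green_total_noiseless": g_total,
        })

    bg = _background_field(cfg, shape)
    green_img = _finish_render(cfg, rng, green + bg)
    red_img = _finish_render(cfg, rng, red + bg)
    stack = ChannelStack(channels={
        "green": Image2D(green_img, "float", cfg.pixel_size_um, "green"),
        "red": Image2D(red_img, "float", cfg.pixel_size_um, "red"),
    })
    truth = GroundTruth(cells=pd.DataFrame(cell_rows),
                        mitochondria=pd.DataFrame(mito_rows),
                        labels=label_map,
                        info={"measure_dilation_px": int(pad)})
    return stack, truth


# ---------------------------------------------------------------------------
# reporter animals
# ---------------------------------------------------------------------------

def synth_reporter_animal(cfg: SynthesisConfig) -> tuple[Image2D, GroundTruth]:
    """Render one worm-shaped region of known mean intensity over a known
    background.  Edges are left sharp so a zero-noise render recovers the
    configured means exactly under the truth mask."""
    rng = np.random.default_rng(cfg.seed)
    shape = (256, 512) if cfg.image_size == (1280, 1280) else tuple(cfg.image_size)
    h, w = shape
    margin = int(cfg.worm_radius_px) + 10
    xs = np.arange(margin, w - margin)
    s = (xs - xs[0]) / max(len(xs) - 1, 1)
    amp_wiggle = 0.18 * h
    ys = h / 2 + amp_wiggle * np.sin(2 * np.pi * (1.5 * s + rng.uniform()))
    taper = np.sqrt(np.clip(4 * s * (1 - s), 0.04, None))
    radii = cfg.worm_radius_px * taper

    mask = np.zeros(shape, dtype=bool)
    for x, y, r in zip(xs, ys, radii):
        rr, cc = skdraw.disk((y, x), max(r, 1.0), shape=shape)
        mask[rr, cc] = True

    worm_value = cfg.worm_mean * cfg.worm_brightness_factor
    scene = _background_field(cfg, shape)
    # centre the background so the *non-animal* region means exactly
    # background_mean on a noiseless render
    scene = scene - scene[~mask].mean() + cfg.background_mean
    scene[mask] = worm_value
    noiseless = scene.copy()
    if cfg.noise_poisson:
        scene = rng.poisson(np.clip(scene, 0, None)).astype(float)
    if cfg.noise_gaussian_sd > 0:
        scene = scene + rng.normal(0, cfg.noise_gaussian_sd, size=shape)
    pixels = np.clip(scene, 0, None)
    image = Image2D(pixels, "float", cfg.pixel_size_um, "green")
    truth = GroundTruth(
        labels=mask.astype(np.int32),
        info={
            "animal_mean": float(noiseless[mask].mean()),
            "background_mean": float(noiseless[~mask].mean()),
            "configured_animal_mean": worm_value,
            "configured_background_mean": cfg.background_mean,
            "brightness_factor": cfg.worm_brightness_factor,
        },
    )
    return image, truth


# ---------------------------------------------------------------------------
# uterus time-lapse
# ---------------------------------------------------------------------------

def synth_uterus_timelapse(cfg: SynthesisConfig):
    """Render a vulva->spermatheca scene with moving sperm puncta.

    Returns ``(frames, scene_truth, track_truth)``.  Each sperm moves in a
    straight line at its drawn speed, so the true per-track speed equals the
    configured draw exactly.
    """
    from .motility import UterusScene  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed)
    shape = (256, 512) if cfg.image_size == (1280, 1280) else tuple(cfg.image_size)
    h, w = shape
    vulva = np.array([h / 2.0, 60.0])
    spermatheca = np.array([h / 2.0, w - 60.0])
    axis = spermatheca - vulva
    axis_len = float(np.linalg.norm(axis))
    u = axis / axis_len
    perp = np.array([-u[1], u[0]])

    fr = rng.beta(*cfg.axis_beta, size=cfg.n_sperm)
    offsets = np.clip(rng.normal(0, 0.12 * h, size=cfg.n_sperm), -0.3 * h, 0.3 * h)
    starts = vulva[None, :] + fr[:, None] * axis[None, :] + offsets[:, None] * perp[None, :]
    speeds = np.clip(rng.normal(*cfg.speed_px_per_s, size=cfg.n_sperm), 0.0, None)

    duration = (cfg.n_frames - 1) * cfg.frame_interval_s
    dirs = np.zeros((cfg.n_sperm, 2))
    for i in range(cfg.n_sperm):
        for _ in range(64):
            theta = rng.uniform(0, 2 * np.pi)
            d = np.array([np.sin(theta), np.cos(theta)])
            end = starts[i] + speeds[i] * duration * d
            if 5 <= end[0] <= h - 5 and 5 <= end[1] <= w - 5:
                dirs[i] = d
                break
        else:
            speeds[i] = 0.0

    frames: list[Image2D] = []
    track_rows = []
    for f in range(cfg.n_frames):
        t = f * cfg.frame_interval_s
        scene = np.full(shape, 5.0)
        for i in range(cfg.n_sperm):
            pos = starts[i] + speeds[i] * t * dirs[i]
            _gaussian_blob(scene, tuple(pos), 1.5, 1.5, 0.0, 150.0)
            track_rows.append({"track": i, "frame": f, "t_seconds": t,
                               "row": pos[0], "col": pos[1]})
        if cfg.noise_gaussian_sd > 0:
            scene = scene + rng.normal(0, cfg.noise_gaussian_sd, size=shape)
        frames.append(Image2D(np.clip(scene, 0, None), "float",
                              cfg.pixel_size_um, "red"))

    tracks = pd.DataFrame(track_rows)
    zone = np.where(fr < 1 / 3, 1, np.where(fr < 2 / 3, 2, 3))
    scene_truth = GroundTruth(
        scene=UterusScene(vulva_point=tuple(vulva),
                          spermatheca_point=tuple(spermatheca),
                          sperm_points=[tuple(p) for p in starts]),
        info={"axis_fractions": fr.tolist(), "zones": zone.tolist()},
    )
    track_truth = GroundTruth(
        tracks=tracks,
        info={"true_speeds": speeds.tolist(),
              "frame_interval_s": cfg.frame_interval_s},
    )
    return frames, scene_truth, track_truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _lognormal_mu_kept_mean(mean: float, sigma: float) -> tuple[float, float]:
    return mean, sigma  # mmp_profile stores (mean, sigma); mu derived at draw


#: assay presets: name -> (assay kind, config overrides).  The activation
#: mixtures encode the published class fractions for wild-type, sdha-2
#: mutant, and AKA36 Pronase assays; the JC-1 pair encodes the wild-type
#: versus mutant mitochondrial contrasts (elongated/larger mitochondria,
#: excess low-MMP mitochondria, wider red:green spread at equal mean).
PRESETS: dict[str, tuple[str, dict]] = {
    "wt-pronase": ("spermatid_field", {
        "class_mixture": (0.09, 0.04, 0.85, 0.02)}),
    "mut-pronase": ("spermatid_field", {
        "class_mixture": (0.63, 0.09, 0.23, 0.05)}),
    "aka36-pronase": ("spermatid_field", {
        "class_mixture": (0.62, 0.12, 0.21, 0.05)}),
    "wt-jc1": ("jc1_field", {
        "image_size": (640, 640), "n_cells": 25,
        "touching_cell_fraction": 0.15,
        "jc1_cell_radius_px": (16.0, 0.8),
        "mito_elongation": (1.2, 0.15), "mito_radius_px": (2.0, 0.2),
        "mmp_profile": (2.0, 0.15), "low_mmp_fraction": 0.10,
        "mito_per_cell": (3.0, 0.8)}),
    "mut-jc1": ("jc1_field", {
        "image_size": (704, 704), "n_cells": 25,
        "touching_cell_fraction": 0.15,
        "jc1_cell_radius_px": (24.0, 1.0),
        "mito_elongation": (3.0, 0.4), "mito_radius_px": (2.2, 0.25),
        "mmp_profile": (2.0, 0.45), "low_mmp_fraction": 0.30,
        "mito_per_cell": (3.0, 0.8)}),
    "reporter": ("reporter_animal", {"image_size": (256, 512)}),
    "uterus": ("uterus_timelapse", {"image_size": (256, 512)}),
    "uterus-wt": ("uterus_timelapse", {
        "image_size": (256, 512), "axis_beta": (4.0, 1.5),
        "speed_px_per_s": (0.20, 0.05)}),
    "uterus-mut": ("uterus_timelapse", {
        "image_size": (256, 512), "axis_beta": (1.5, 4.0),
        "speed_px_per_s": (0.06, 0.02)}),
}

_SYNTH_OPS = {
    "spermatid_field": synth_spermatid_field,
    "jc1_field": synth_jc1_field,
    "reporter_animal": synth_reporter_animal,
    "uterus_timelapse": synth_uterus_timelapse,
}


def preset(name: str, seed: int = 0, **overrides) -> SynthesisConfig:
    """The SynthesisConfig for a named preset (overridable field by field)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    _, params = PRESETS[name]
    merged = {**params, **overrides, "seed": seed}
    return dataclasses.replace(SynthesisConfig(), **merged)


def generate_preset(name: str, seed: int = 0, **overrides):
    """Generate a preset's images + truth; returns (kind, outputs)."""
    kind, _ = PRESETS[name]
    cfg = preset(name, seed=seed, **overrides)
    return kind, _SYNTH_OPS[kind](cfg)
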