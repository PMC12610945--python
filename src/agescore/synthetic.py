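"""Ground-truthed synthetic study generator.

Emulates a two-condition (control vs. doxycycline-induced progerin
expression), three-timepoint (3/7/14 days) cell-culture study: for every
well it renders fluorescence scenes for the image-based aging markers
(DNA-damage foci, nuclear-stain intensities, morphology, puncta, spot
uptake, nucleocytoplasmic reporters) and draws the tabular assays (qPCR Ct
duplicates, ELISA duplicates, telomere-qPCR triplicates, wound-mask pairs).
Every planted quantity is recorded in a ground-truth sidecar so downstream
quantification can be tested exactly.

Measurement model
-----------------
* Nuclei are perturbed ellipses placed without overlap, rendered into a
  DAPI-like channel as ``background + per-nucleus level + Gaussian noise``.
* Foci / puncta are Gaussian spots whose in-window core (pixels inside the
  detection intensity window) covers at least the minimum component size.
  Spots occupy randomly chosen sites of a per-cell hexagonal lattice, which
  guarantees non-overlap so planted counts are an exact oracle; the planted
  count is capped at the number of available sites and the cap is what the
  ground truth records.
* Per-cell marker levels are log-normal around a condition×timepoint mean;
  a log-normal per-well multiplier (``dispersion``) supplies the
  biological between-well variability that the per-well statistics see.
* Noise is additive Gaussian everywhere (no shot noise, PSF or vignetting).
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.measure import regionprops

from .scene import Scene, write_scene

__all__ = [
    "EFFECT_KINDS",
    "StudyDesign",
    "MarkerEffectSpec",
    "SceneGeometry",
    "SceneGroundTruth",
    "StudyBundle",
    "generate_scene",
    "generate_study",
    "write_study",
    "reference_effect_preset",
    "null_effect_preset",
]

# Effect kinds and the artifact each one produces.
IMAGE_KINDS = frozenset(
    {
        "foci_rate",
        "channel_intensity",
        "nucleus_area",
        "nucleus_shape",
        "nc_shift",
        "puncta_rate",
        "spot_probability",
    }
)
TABLE_KINDS = frozenset({"secretion_level", "ct_shift", "ts_shift", "gap_closure_rate"})
EFFECT_KINDS = IMAGE_KINDS | TABLE_KINDS

# Spot (focus/punctum) rendering. Peak amplitudes sit inside the default
# detection window (20, 200); the in-window core of a sigma=1.1 Gaussian
# spot covers >= 9 px, comfortably above the 5 px minimum size.
SPOT_SIGMA = 1.1
SPOT_AMP_RANGE = (70.0, 150.0)
SPOT_PITCH = 6.0  # lattice pitch; keeps in-window cores 4-disconnected
SPOT_MARGIN = 3.0  # spot core must sit this far inside its compartment

PER_CELL_SIGMA = 0.15  # log-scale SD of per-cell marker levels
DAPI_CELL_SIGMA = 0.10
AREA_CELL_SIGMA = 0.10  # log-scale SD of per-cell nucleus area
CYTO_BASE_LEVEL = 30.0  # cytoplasm level for N/C reporter channels

# Tabular-assay baselines.
QPCR_TARGET_BASE_CT = 25.0
QPCR_REF_BASE_CT = 18.0
QPCR_TECH_SIGMA = 0.05  # cycles, technical replicate scatter
ELISA_TECH_CV = 0.02
TELOMERE_T_INTERCEPT = 14.0  # Ct at 1 unit input, telomere primer pair
TELOMERE_S_INTERCEPT = 22.0  # Ct at 1 unit input, single-copy gene
TELOMERE_CT_SIGMA = 0.05


@dataclass(frozen=True)
class StudyDesign:
    """Arms, timepoints and replication of the simulated study.

    Defaults mirror the progerin-induction design: a non-induced control
    arm and a doxycycline-induced arm, sampled after 3, 7 and 14 days,
    with at least 20 analyzed cells per well and wells as the biological
    replicate unit.
    """

    conditions: tuple[str, ...] = ("-DOX", "+DOX")
    timepoints_days: tuple[int, ...] = (3, 7, 14)
    wells_per_arm: int = 6
    cells_per_well: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) < 2:
            raise ValueError("need a control and at least one treated condition")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if self.wells_per_arm < 2:
            raise ValueError(
                "wells_per_arm must be >= 2: per-well statistics need replication"
            )
        if self.cells_per_well < 20:
            raise ValueError(
                "cells_per_well must be >= 20 (minimum analyzed cells per replicate)"
            )

    @property
    def control_condition(self) -> str:
        return self.conditions[0]


@dataclass(frozen=True)
class MarkerEffectSpec:
    """Planted effect for one marker.

    ``control_param`` and ``aged_param`` are on the natural scale of the
    effect kind (mean foci per nucleus, mean intensity, mean area in px,
    target form factor, N/C ratio, pg/mL, Ct shift in cycles, T/S ratio,
    percent gap closure, or spot probability).  ``aged_param`` may be a
    mapping ``{timepoint_days: value}`` for time-varying effects.
    ``dispersion`` is the between-well variability: log-scale SD of a
    per-well multiplier for multiplicative kinds, and an additive SD on
    the natural scale for ``ct_shift`` (cycles) and ``gap_closure_rate``
    (percentage points).
    """

    marker_name: str
    effect_kind: str
    control_param: float
    aged_param: float | Mapping[int, float]
    dispersion: float = 0.10
    compartment: str = "nucleus"  # "nucleus" or "cell"; channel_intensity only

    def __post_init__(self) -> None:
        if self.effect_kind not in EFFECT_KINDS:
            raise ValueError(
                f"unknown effect_kind {self.effect_kind!r}; one of {sorted(EFFECT_KINDS)}"
            )
        if not self.dispersion > 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")
        if self.compartment not in ("nucleus", "cell"):
            raise ValueError("compartment must be 'nucleus' or 'cell'")

    def param_for(self, condition: str, timepoint_days: int, design: StudyDesign) -> float:
        """Planted parameter for one study arm and timepoint."""
        if condition == design.control_condition:
            return float(self.control_param)
        if isinstance(self.aged_param, Mapping):
            try:
                return float(self.aged_param[timepoint_days])
            except KeyError:
                raise ValueError(
                    f"effect spec for {self.marker_name!r} has no aged_param for "
                    f"timepoint {timepoint_days} d"
                ) from None
        return float(self.aged_param)

    def validate_against(self, design: StudyDesign) -> None:
        for cond in design.conditions:
            for tp in design.timepoints_days:
                self.param_for(cond, tp, design)


@dataclass(frozen=True)
class SceneGeometry:
    """Canvas and nucleus geometry of a synthetic scene."""

    shape: tuple[int, int] = (300, 300)
    nucleus_radius_px: float = 12.0
    radius_jitter_px: float = 1.2
    margin_px: int = 20
    min_gap_px: int = 4
    background_level: float = 8.0
    noise_sigma: float = 1.5
    nucleus_level: float = 120.0
    cytoplasm_width_px: int = 6
    boundary_amplitude: float = 0.04
    max_place_tries: int = 5000


@dataclass
class SceneGroundTruth:
    """Everything planted into one scene, keyed by cell label."""

    labels: np.ndarray  # cell ids, 1..n
    nucleus_masks: np.ndarray  # label image
    cytoplasm_masks: np.ndarray  # label image (ring around each nucleus)
    per_cell_area_px: np.ndarray
    per_cell_foci_counts: dict[str, np.ndarray] = field(default_factory=dict)
    per_cell_channel_means: dict[str, np.ndarray] = field(default_factory=dict)
    per_cell_target_form_factor: np.ndarray | None = None
    per_cell_puncta_counts: dict[str, np.ndarray] = field(default_factory=dict)
    per_cell_phagocytic: dict[str, np.ndarray] = field(default_factory=dict)
    per_cell_nc_ratio: dict[str, np.ndarray] = field(default_factory=dict)
    background_level: float = 0.0


# ---------------------------------------------------------------------------
# nucleus shapes


_N_BOUNDARY = 64


def _ellipse_base(rng: np.random.Generator, radius: float, axis_ratio: float) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, _N_BOUNDARY, endpoint=False)
    a = radius / math.sqrt(axis_ratio)
    b = radius * math.sqrt(axis_ratio)
    t = theta - rng.uniform(0, np.pi)
    return a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)


def _perturbation_profile(rng: np.random.Generator) -> np.ndarray:
    """Unit-norm mixture of low-order harmonics (3..6) of the boundary."""
    theta = np.linspace(0.0, 2.0 * np.pi, _N_BOUNDARY, endpoint=False)
    weights = rng.normal(size=4)
    weights /= np.linalg.norm(weights) + 1e-12
    phases = rng.uniform(0, 2 * np.pi, size=4)
    pert = np.zeros(_N_BOUNDARY)
    for h, (w, ph) in enumerate(zip(weights, phases), start=3):
        pert += w * np.cos(h * theta + ph)
    return pert


def _boundary_radii(
    rng: np.random.Generator, radius: float, amplitude: float, axis_ratio: float
) -> np.ndarray:
    """Radial boundary samples of a perturbed ellipse."""
    base = _ellipse_base(rng, radius, axis_ratio)
    if amplitude > 0:
        base = base * (1.0 + amplitude * _perturbation_profile(rng))
    return np.maximum(base, 2.0)


def _render_nucleus(
    radii: np.ndarray, center: tuple[float, float], shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    theta = np.linspace(0.0, 2.0 * np.pi, len(radii), endpoint=False)
    rr = center[0] + radii * np.sin(theta)
    cc = center[1] + radii * np.cos(theta)
    return draw_polygon(rr, cc, shape=shape)


def _measure_form_factor(radii: np.ndarray, radius: float) -> float:
    """Form factor of a rendered boundary, measured off-canvas."""
    size = int(4 * radius + 10)
    mask = np.zeros((size, size), dtype=np.uint8)
    rr, cc = _render_nucleus(radii, (size / 2, size / 2), (size, size))
    mask[rr, cc] = 1
    prop = regionprops(mask)[0]
    perim = prop.perimeter_crofton
    if perim == 0:
        return 1.0
    return float(4.0 * np.pi * prop.area / perim**2)


def _calibrated_boundary(
    rng: np.random.Generator, radius: float, target_ff: float, tol: float = 0.01
) -> np.ndarray:
    """Bisect the boundary-perturbation amplitude until the rendered form
    factor matches ``target_ff`` (digital measurement, Crofton perimeter).

    One random harmonic profile is drawn and only its amplitude is scaled,
    so the form factor is monotone in the bisection variable.
    """
    base = _ellipse_base(rng, radius, axis_ratio=1.0)
    profile = _perturbation_profile(rng)
    circle = np.maximum(base, 2.0)
    if _measure_form_factor(circle, radius) <= target_ff + tol:
        return circle
    lo, hi = 0.0, 0.8
    best = circle
    for _ in range(14):
        mid = 0.5 * (lo + hi)
        radii = np.maximum(base * (1.0 + mid * profile), 2.0)
        ff = _measure_form_factor(radii, radius)
        best = radii
        if abs(ff - target_ff) < tol:
            return radii
        if ff > target_ff:
            lo = mid
        else:
            hi = mid
    return best


# ---------------------------------------------------------------------------
# placement and spots


def _place_nuclei(
    rng: np.random.Generator, geometry: SceneGeometry, radii_px: np.ndarray
) -> np.ndarray:
    """Non-overlapping centers, all fully interior. Returns (n, 2) array."""
    h, w = geometry.shape
    n = len(radii_px)
    centers: list[tuple[float, float]] = []
    order = np.argsort(radii_px)[::-1]  # place large nuclei first
    placed_r: list[float] = []
    for idx in order:
        r = radii_px[idx]
        m = geometry.margin_px + r
        for _ in range(geometry.max_place_tries):
            y = rng.uniform(m, h - m)
            x = rng.uniform(m, w - m)
            ok = all(
                (y - cy) ** 2 + (x - cx) ** 2
                >= (r + pr + geometry.min_gap_px) ** 2
                for (cy, cx), pr in zip(centers, placed_r)
            )
            if ok:
                centers.append((y, x))
                placed_r.append(r)
                break
        else:
            density = float(np.pi * np.sum(radii_px**2)) / float(h * w)
            raise RuntimeError(
                f"failed to place {n} nuclei on a {h}x{w} canvas "
                f"(nucleus area fraction {density:.2f}); enlarge the canvas "
                "or reduce cells_per_well"
            )
    out = np.empty((n, 2))
    for pos, idx in enumerate(order):
        out[idx] = centers[pos]
    return out


def _spot_sites(
    rng: np.random.Generator, region_mask: np.ndarray, margin: float, pitch: float
) -> np.ndarray:
    """Hexagonal-lattice candidate sites whose surroundings lie inside the
    region by at least ``margin`` pixels.  Random lattice offset per call."""
    sl = ndimage.find_objects(region_mask.astype(np.int8))
    if not sl or sl[0] is None:
        return np.empty((0, 2), dtype=int)
    pad = int(margin) + 1
    y0 = max(0, sl[0][0].start - pad)
    x0 = max(0, sl[0][1].start - pad)
    sub = region_mask[y0 : sl[0][0].stop + pad, x0 : sl[0][1].stop + pad]
    dist = ndimage.distance_transform_edt(sub)
    ys, xs = np.nonzero(dist >= margin)
    ys = ys + y0
    xs = xs + x0
    if len(ys) == 0:
        return np.empty((0, 2), dtype=int)
    oy, ox = rng.uniform(0, pitch, size=2)
    dy = pitch * math.sqrt(3) / 2
    row = np.round((ys - oy) / dy).astype(int)
    col = np.round((xs - ox - (row % 2) * pitch / 2) / pitch).astype(int)
    snap_y = oy + row * dy
    snap_x = ox + (row % 2) * pitch / 2 + col * pitch
    on_lattice = (np.abs(ys - snap_y) < 0.5) & (np.abs(xs - snap_x) < 0.5)
    sites = np.column_stack([ys[on_lattice], xs[on_lattice]])
    rng.shuffle(sites)
    return sites


def _add_spot(img: np.ndarray, y: int, x: int, amp: float, sigma: float) -> None:
    r = int(math.ceil(3.5 * sigma))
    h, w = img.shape
    y0, y1 = max(0, y - r), min(h, y + r + 1)
    x0, x1 = max(0, x - r), min(w, x + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * sigma**2)
    )


def _plant_spots(
    rng: np.random.Generator,
    channel: np.ndarray,
    region_mask: np.ndarray,
    requested: int,
) -> int:
    """Plant ``requested`` non-overlapping spots, capped at available sites.

    Returns the number actually planted (the ground truth)."""
    sites = _spot_sites(rng, region_mask, SPOT_MARGIN, SPOT_PITCH)
    k = min(requested, len(sites))
    for y, x in sites[:k]:
        amp = rng.uniform(*SPOT_AMP_RANGE)
        _add_spot(channel, int(y), int(x), amp, SPOT_SIGMA)
    return k


def _lognormal_mean(rng: np.random.Generator, mean: float, sigma: float, size=None):
    """Log-normal draws with expectation ``mean``."""
    return mean * np.exp(rng.normal(0.0, sigma, size=size) - 0.5 * sigma**2)


# ---------------------------------------------------------------------------
# scene generation


def generate_scene(
    n_cells: int,
    effects: list[MarkerEffectSpec] | MarkerEffectSpec,
    seed: int,
    geometry: SceneGeometry = SceneGeometry(),
    condition: str = "-DOX",
    timepoint_days: int = 3,
    design: StudyDesign | None = None,
    well_id: str = "",
) -> tuple[Scene, SceneGroundTruth]:
    """Render one well: a DAPI channel plus one channel per image effect.

    Identical ``(parameters, seed)`` produce bit-identical output.  The
    returned ground truth records the nucleus/cytoplasm label images and
    every planted per-cell value.
    """
    if isinstance(effects, MarkerEffectSpec):
        effects = [effects]
    design = design or StudyDesign()
    for eff in effects:
        if eff.effect_kind not in IMAGE_KINDS:
            raise ValueError(
                f"effect kind {eff.effect_kind!r} produces a table, not a scene"
            )
    rng = np.random.default_rng(seed)
    h, w = geometry.shape

    # --- nucleus sizes (a nucleus_area effect overrides the geometry default)
    area_eff = next((e for e in effects if e.effect_kind == "nucleus_area"), None)
    if area_eff is not None:
        mean_area = area_eff.param_for(condition, timepoint_days, design)
        well_mult = _lognormal_mean(rng, 1.0, area_eff.dispersion)
        areas = _lognormal_mean(rng, mean_area * well_mult, AREA_CELL_SIGMA, n_cells)
        radii = np.sqrt(areas / np.pi)
    else:
        radii = geometry.nucleus_radius_px + rng.uniform(
            -geometry.radius_jitter_px, geometry.radius_jitter_px, n_cells
        )

    shape_eff = next((e for e in effects if e.effect_kind == "nucleus_shape"), None)
    target_ff = None
    if shape_eff is not None:
        target_ff = shape_eff.param_for(condition, timepoint_days, design)

    centers = _place_nuclei(rng, geometry, radii)

    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    target_ffs = np.empty(n_cells) if target_ff is not None else None
    for i in range(n_cells):
        if target_ff is not None:
            ff_i = float(np.clip(target_ff + rng.normal(0, 0.01), 0.3, 1.0))
            radii_b = _calibrated_boundary(rng, radii[i], ff_i)
            target_ffs[i] = ff_i
        else:
            radii_b = _boundary_radii(
                rng, radii[i], geometry.boundary_amplitude, rng.uniform(0.8, 1.0)
            )
        rr, cc = _render_nucleus(radii_b, tuple(centers[i]), (h, w))
        nucleus_labels[rr, cc] = i + 1

    # cytoplasm: fixed-width ring around each nucleus, nearest-nucleus tie-break
    dist, (iy, ix) = ndimage.distance_transform_edt(
        nucleus_labels == 0, return_indices=True
    )
    ring = (dist > 0) & (dist <= geometry.cytoplasm_width_px)
    cyto_labels = np.zeros_like(nucleus_labels)
    cyto_labels[ring] = nucleus_labels[iy[ring], ix[ring]]

    gt = SceneGroundTruth(
        labels=np.arange(1, n_cells + 1),
        nucleus_masks=nucleus_labels,
        cytoplasm_masks=cyto_labels,
        per_cell_area_px=np.bincount(nucleus_labels.ravel(), minlength=n_cells + 1)[1:],
        per_cell_target_form_factor=target_ffs,
        background_level=geometry.background_level,
    )

    channels: dict[str, np.ndarray] = {}
    bg = geometry.background_level
    noise = geometry.noise_sigma

    # --- DAPI
    def _paint(levels: np.ndarray, labels: np.ndarray) -> np.ndarray:
        lut = np.zeros(n_cells + 1)
        lut[1:] = levels
        return lut[labels]

    dapi = np.full((h, w), bg, dtype=np.float64)
    dapi_levels = _lognormal_mean(rng, geometry.nucleus_level, DAPI_CELL_SIGMA, n_cells)
    dapi += _paint(dapi_levels, nucleus_labels)
    dapi += rng.normal(0.0, noise, (h, w))
    channels["dapi"] = dapi

    # --- marker channels
    for eff in effects:
        kind = eff.effect_kind
        if kind in ("nucleus_area", "nucleus_shape"):
            continue  # expressed through the DAPI geometry
        param = eff.param_for(condition, timepoint_days, design)
        ch = np.full((h, w), 0.0 if kind == "foci_rate" else bg, dtype=np.float64)

        if kind == "foci_rate":
            # faint nuclear counterstain keeps foci on a realistic pedestal
            # while staying below the detection window's lower bound
            ch[nucleus_labels > 0] += bg
            well_rate = param * _lognormal_mean(rng, 1.0, eff.dispersion)
            counts = np.zeros(n_cells, dtype=int)
            for i in range(n_cells):
                k = int(rng.poisson(well_rate))
                counts[i] = _plant_spots(rng, ch, nucleus_labels == i + 1, k)
            gt.per_cell_foci_counts[eff.marker_name] = counts

        elif kind == "channel_intensity":
            well_mult = _lognormal_mean(rng, 1.0, eff.dispersion)
            levels = _lognormal_mean(rng, param * well_mult, PER_CELL_SIGMA, n_cells)
            ch += _paint(levels, nucleus_labels)
            if eff.compartment == "cell":
                ch += _paint(levels, cyto_labels)
            gt.per_cell_channel_means[eff.marker_name] = levels

        elif kind == "nc_shift":
            well_mult = _lognormal_mean(rng, 1.0, eff.dispersion)
            cyto_levels = _lognormal_mean(rng, CYTO_BASE_LEVEL, PER_CELL_SIGMA, n_cells)
            ratios = np.full(n_cells, param * well_mult)
            ch += _paint(cyto_levels, cyto_labels)
            ch += _paint(ratios * cyto_levels, nucleus_labels)
            gt.per_cell_nc_ratio[eff.marker_name] = ratios
            gt.per_cell_channel_means[eff.marker_name] = cyto_levels

        elif kind == "puncta_rate":
            well_rate = param * _lognormal_mean(rng, 1.0, eff.dispersion)
            counts = np.zeros(n_cells, dtype=int)
            for i in range(n_cells):
                k = int(rng.poisson(well_rate))
                counts[i] = _plant_spots(rng, ch, cyto_labels == i + 1, k)
            gt.per_cell_puncta_counts[eff.marker_name] = counts

        elif kind == "spot_probability":
            p = float(np.clip(param * _lognormal_mean(rng, 1.0, eff.dispersion), 0, 1))
            positive = rng.random(n_cells) < p
            counts = np.zeros(n_cells, dtype=int)
            for i in range(n_cells):
                if positive[i]:
                    k = 1 + int(rng.poisson(0.8))
                    counts[i] = _plant_spots(rng, ch, cyto_labels == i + 1, k)
            planted_positive = counts > 0
            gt.per_cell_phagocytic[eff.marker_name] = planted_positive
            gt.per_cell_puncta_counts[eff.marker_name] = counts

        ch += rng.normal(0.0, noise, (h, w))
        channels[eff.marker_name] = ch

    scene = Scene(
        channels=channels,
        pixel_size_um=None,
        well_id=well_id,
        condition=condition,
        timepoint_days=timepoint_days,
    )
    return scene, gt


# ---------------------------------------------------------------------------
# study generation


@dataclass
class SceneEntry:
    marker_name: str
    condition: str
    timepoint_days: int
    well_id: str
    seed: int
    scene: Scene
    ground_truth: SceneGroundTruth | None = None


@dataclass
class WoundEntry:
    marker_name: str
    condition: str
    timepoint_days: int
    well_id: str
    gap_mask_first: np.ndarray
    gap_mask_last: np.ndarray
    planted_closure_percent: float


@dataclass
class StudyBundle:
    """All artifacts of one simulated study, in memory.

    ``scenes`` holds one entry per well per image marker.  Tabular assays
    are long-format DataFrames with one row per technical replicate.
    """

    design: StudyDesign
    effects: list[MarkerEffectSpec]
    scenes: list[SceneEntry]
    qpcr: pd.DataFrame | None
    elisa: pd.DataFrame | None
    telomere_runs: pd.DataFrame | None
    telomere_standard: pd.DataFrame | None
    wounds: list[WoundEntry]
    manifest: dict


def _wells(design: StudyDesign):
    for cond in design.conditions:
        for tp in design.timepoints_days:
            for w in range(design.wells_per_arm):
                yield cond, tp, f"{cond}_{tp}d_w{w + 1}"


def _make_wound_pair(
    rng: np.random.Generator, closure_percent: float, width: int = 100, shape=(80, 260)
) -> tuple[np.ndarray, np.ndarray]:
    """Vertical-gap mask pair; last-day gap width set by percent closure."""
    h, w = shape
    c = w // 2
    first = np.zeros(shape, dtype=bool)
    first[:, c - width // 2 : c + width // 2] = True
    remaining = max(0, int(round(width * (1.0 - closure_percent / 100.0))))
    last = np.zeros(shape, dtype=bool)
    if remaining > 0:
        last[:, c - remaining // 2 : c - remaining // 2 + remaining] = True
    return first, last


def generate_study(
    design: StudyDesign,
    effects: list[MarkerEffectSpec],
    geometry: SceneGeometry = SceneGeometry(),
) -> StudyBundle:
    """Simulate the full study: scenes for image markers, tables for assays.

    One scene is rendered per well per image-based marker (the well is the
    statistical unit downstream).  qPCR Ct values come in technical
    duplicates, ELISA in duplicates, telomere qPCR in triplicates with a
    shared standard dilution series.  Deterministic in ``design.seed``.
    """
    names = [e.marker_name for e in effects]
    if len(set(names)) != len(names):
        raise ValueError("duplicate marker names in effect list")
    for eff in effects:
        eff.validate_against(design)

    root = np.random.default_rng(design.seed)
    scenes: list[SceneEntry] = []
    wounds: list[WoundEntry] = []
    qpcr_rows: list[dict] = []
    elisa_rows: list[dict] = []
    telo_rows: list[dict] = []
    manifest_entries: list[dict] = []

    image_effects = [e for e in effects if e.effect_kind in IMAGE_KINDS]
    # nucleus_area / nucleus_shape markers get their own DAPI-only scene
    for eff in image_effects:
        for cond, tp, well in _wells(design):
            seed = int(root.integers(2**31))
            scene, gt = generate_scene(
                design.cells_per_well,
                [eff],
                seed,
                geometry=geometry,
                condition=cond,
                timepoint_days=tp,
                design=design,
                well_id=well,
            )
            scenes.append(SceneEntry(eff.marker_name, cond, tp, well, seed, scene, gt))
            manifest_entries.append(
                {"kind": "scene", "marker": eff.marker_name, "condition": cond,
                 "timepoint_days": tp, "well_id": well, "seed": seed}
            )

    for eff in effects:
        kind = eff.effect_kind
        if kind == "ct_shift":
            for cond, tp, well in _wells(design):
                shift = eff.param_for(cond, tp, design)
                sample_effect = root.normal(0.0, 0.08)  # RNA input, cancels in dCt
                dct_noise = root.normal(0.0, eff.dispersion)
                for rep in (1, 2):
                    qpcr_rows.append(
                        {"sample_id": well, "condition": cond, "timepoint_days": tp,
                         "well_id": well, "gene": eff.marker_name, "tech_rep": rep,
                         "ct": QPCR_TARGET_BASE_CT + shift + sample_effect + dct_noise
                               + root.normal(0.0, QPCR_TECH_SIGMA)}
                    )
                for rep in (1, 2):
                    qpcr_rows.append(
                        {"sample_id": well, "condition": cond, "timepoint_days": tp,
                         "well_id": well, "gene": "GAPDH", "tech_rep": rep,
                         "ct": QPCR_REF_BASE_CT + sample_effect
                               + root.normal(0.0, QPCR_TECH_SIGMA)}
                    )
        elif kind == "secretion_level":
            for cond, tp, well in _wells(design):
                level = eff.param_for(cond, tp, design)
                conc = level * _lognormal_mean(root, 1.0, eff.dispersion)
                for rep in (1, 2):
                    elisa_rows.append(
                        {"sample_id": well, "condition": cond, "timepoint_days": tp,
                         "well_id": well, "analyte": eff.marker_name, "tech_rep": rep,
                         "value": conc * (1.0 + root.normal(0.0, ELISA_TECH_CV))}
                    )
        elif kind == "ts_shift":
            for cond, tp, well in _wells(design):
                tlr = eff.param_for(cond, tp, design)
                tlr_w = tlr * _lognormal_mean(root, 1.0, eff.dispersion)
                for rep in (1, 2, 3):
                    dna = 20.0 * _lognormal_mean(root, 1.0, 0.05)
                    telo_rows.append(
                        {"sample_id": well, "condition": cond, "timepoint_days": tp,
                         "well_id": well, "replicate": rep,
                         "t_ct": TELOMERE_T_INTERCEPT - math.log2(dna * tlr_w)
                                 + root.normal(0.0, TELOMERE_CT_SIGMA),
                         "s_ct": TELOMERE_S_INTERCEPT - math.log2(dna)
                                 + root.normal(0.0, TELOMERE_CT_SIGMA)}
                    )
        elif kind == "gap_closure_rate":
            for cond, tp, well in _wells(design):
                target = eff.param_for(cond, tp, design)
                closure = float(np.clip(target + root.normal(0.0, eff.dispersion), 0, 100))
                first, last = _make_wound_pair(root, closure)
                wounds.append(
                    WoundEntry(eff.marker_name, cond, tp, well, first, last, closure)
                )

    # shared telomere standard dilution series (strictly monotone by design)
    telomere_standard = None
    if telo_rows:
        conc = 100.0 / 2.0 ** np.arange(10)  # 100 .. 0.195, 2-fold steps
        telomere_standard = pd.DataFrame(
            {"concentration": conc,
             "t_ct": TELOMERE_T_INTERCEPT - np.log2(conc) + root.normal(0, 0.02, 10),
             "s_ct": TELOMERE_S_INTERCEPT - np.log2(conc) + root.normal(0, 0.02, 10)}
        )

    manifest = {
        "design": {
            "conditions": list(design.conditions),
            "timepoints_days": list(design.timepoints_days),
            "wells_per_arm": design.wells_per_arm,
            "cells_per_well": design.cells_per_well,
            "seed": design.seed,
        },
        "effects": [
            {"marker_name": e.marker_name, "effect_kind": e.effect_kind,
             "control_param": e.control_param,
             "aged_param": dict(e.aged_param) if isinstance(e.aged_param, Mapping)
                           else e.aged_param,
             "dispersion": e.dispersion, "compartment": e.compartment}
            for e in effects
        ],
        "artifacts": manifest_entries,
    }
    return StudyBundle(
        design=design,
        effects=list(effects),
        scenes=scenes,
        qpcr=pd.DataFrame(qpcr_rows) if qpcr_rows else None,
        elisa=pd.DataFrame(elisa_rows) if elisa_rows else None,
        telomere_runs=pd.DataFrame(telo_rows) if telo_rows else None,
        telomere_standard=telomere_standard,
        wounds=wounds,
        manifest=manifest,
    )


def write_study(bundle: StudyBundle, out_dir: str | Path) -> Path:
    """Write a study bundle to disk: scene TIFFs, assay CSVs, a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for se in bundle.scenes:
        rel = Path("scenes") / se.marker_name / f"{se.well_id}.tif"
        write_scene(se.scene, out / rel)
        tifffile.imwrite(
            out / rel.parent / f"{se.well_id}.nuclei.tif",
            se.ground_truth.nucleus_masks.astype(np.uint16),
        )
        entries.append(
            {"kind": "scene", "path": str(rel), "marker": se.marker_name,
             "condition": se.condition, "timepoint_days": se.timepoint_days,
             "well_id": se.well_id, "seed": se.seed}
        )
    for name in ("qpcr", "elisa", "telomere_runs", "telomere_standard"):
        df = getattr(bundle, name)
        if df is not None:
            df.to_csv(out / f"{name}.csv", index=False)
            entries.append({"kind": "table", "path": f"{name}.csv"})
    for we in bundle.wounds:
        rel = Path("wounds") / f"{we.well_id}.tif"
        (out / rel.parent).mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(
            out / rel,
            np.stack([we.gap_mask_first, we.gap_mask_last]).astype(np.uint8),
        )
        entries.append(
            {"kind": "wound_pair", "path": str(rel), "marker": we.marker_name,
             "condition": we.condition, "timepoint_days": we.timepoint_days,
             "well_id": we.well_id}
        )
    manifest = dict(bundle.manifest)
    manifest["artifacts"] = entries
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out


# ---------------------------------------------------------------------------
# presets


def reference_effect_preset() -> list[MarkerEffectSpec]:
    """Default ten-marker effect set for the progerin-induction study.

    Plants the qualitative pattern of the induced arm: DNA-damage foci up,
    H3K9Me3 down, SA-beta-Gal up, IL-6/IL-8 secretion up, Lamin B1 down at
    all timepoints; nucleus area up only at 14 days; telomere content, p16
    and p21 left unchanged.  Magnitudes are generator presets chosen to be
    unambiguous at 6 wells/arm, not estimates of the source data.
    """
    return [
        MarkerEffectSpec("gamma_h2ax", "foci_rate", 0.8, 6.0, dispersion=0.15),
        MarkerEffectSpec("h3k9me3", "channel_intensity", 60.0, 28.0, dispersion=0.10),
        MarkerEffectSpec("telomere", "ts_shift", 1.0, 1.0, dispersion=0.05),
        MarkerEffectSpec("p21", "ct_shift", 0.0, 0.0, dispersion=0.12),
        MarkerEffectSpec("p16", "ct_shift", 0.0, 0.0, dispersion=0.12),
        MarkerEffectSpec(
            "sa_bgal", "channel_intensity", 25.0, 70.0, dispersion=0.10,
            compartment="cell",
        ),
        MarkerEffectSpec("il6", "secretion_level", 15.0, 60.0, dispersion=0.12),
        MarkerEffectSpec("il8", "secretion_level", 40.0, 160.0, dispersion=0.12),
        MarkerEffectSpec("lamin_b1", "channel_intensity", 80.0, 35.0, dispersion=0.10),
        MarkerEffectSpec(
            "nucleus_area", "nucleus_area", 450.0,
            {3: 450.0, 7: 450.0, 14: 700.0}, dispersion=0.04,
        ),
    ]


def null_effect_preset() -> list[MarkerEffectSpec]:
    """The reference panel with every aged parameter equal to control."""
    out = []
    for eff in reference_effect_preset():
        out.append(replace(eff, aged_param=eff.control_param))
    return out
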