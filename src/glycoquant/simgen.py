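"""Synthetic ground-truth scene and gel generation.

Emulates multichannel confocal fields of epithelial-like cells fed a
clickable, UV-crosslinkable monosaccharide probe: a DAPI channel (nuclei),
a plasma-membrane marker channel, an antibody channel marking one nuclear
subcompartment (nucleolar dense fibrillar component, nuclear speckles, or
H3K9me3 heterochromatin), and the clicked probe channel itself.  Every
scene carries complete ground truth (label masks, configured enrichment
folds, true compartment means) so downstream segmentation and
quantification can be validated by parameter recovery.

Also generates synthetic SDS-PAGE gel images with known per-lane
integrated signals for densitometry recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .segmentation import ChannelStack

SUBCOMPARTMENT_KINDS = ("DFC", "NS", "heterochromatin")
CONDITIONS = ("plusUV", "minusUV", "untreated")

# Fixed stain levels for the marker channels (AU).  The analysis is
# invariant to these (thresholds are relative), so they are not exposed
# as parameters.
DAPI_LEVEL = 100.0
MEMBRANE_BACKGROUND = 2.0
MEMBRANE_BAND_LEVEL = 150.0
MARKER_BACKGROUND = 1.0
MARKER_NUCLEOPLASM_LEVEL = 20.0
MARKER_FOCUS_LEVEL = 100.0


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place the requested objects."""


@dataclass(frozen=True)
class NoiseParams:
    """Camera noise model: Poisson shot noise then additive Gaussian read noise.

    ``poisson_scale`` is the photon count per intensity AU (``inf`` disables
    shot noise); ``gaussian_sd`` is the read-noise standard deviation in AU.
    Defaults give SNR ~ 20 at the default nucleoplasm level of 100 AU.
    """

    poisson_scale: float = 4.0
    gaussian_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.poisson_scale <= 0 or self.gaussian_sd < 0:
            raise ValueError("noise parameters must be positive (poisson) / non-negative (gaussian)")


NO_NOISE = NoiseParams(poisson_scale=math.inf, gaussian_sd=0.0)


@dataclass(frozen=True)
class SubcompartmentSpec:
    """One subnuclear compartment to render.

    For DFC/NS, ``foci_per_nucleus`` disk-like foci with radii drawn from
    ``focus_radius_range`` are placed inside each nucleus.  Heterochromatin
    is rendered as a nuclear-rim band whose width is the lower bound of
    ``focus_radius_range``; ``foci_per_nucleus`` is ignored.
    """

    kind: str
    foci_per_nucleus: int = 3
    focus_radius_range: tuple[float, float] = (2.0, 4.0)

    def __post_init__(self) -> None:
        if self.kind not in SUBCOMPARTMENT_KINDS:
            raise ValueError(f"unknown subcompartment kind {self.kind!r}; expected one of {SUBCOMPARTMENT_KINDS}")
        lo, hi = self.focus_radius_range
        if not (0 < lo <= hi):
            raise ValueError("focus_radius_range must satisfy 0 < min <= max")


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic imaging field.

    Defaults describe the study conditions the package is validated under:
    9 well-separated cells per 512x512 field, nucleoplasm brighter than
    cytoplasm brighter than membrane, DFC enrichment fold 1.39, NS 1.22,
    no heterochromatin enrichment, SNR ~ 20.
    """

    image_height: int = 512
    image_width: int = 512
    n_cells: int = 9
    cell_radius_range: tuple[float, float] = (20.0, 30.0)
    nucleus_radius_range: tuple[float, float] = (9.0, 13.0)
    membrane_band_width: float = 3.0
    subcompartments: tuple[SubcompartmentSpec, ...] = (SubcompartmentSpec("DFC"),)
    base_levels: dict[str, float] = field(
        default_factory=lambda: {"pm": 40.0, "cytoplasm": 60.0, "nucleoplasm": 100.0}
    )
    enrichment_folds: dict[str, float] = field(
        default_factory=lambda: {"DFC": 1.39, "NS": 1.22, "heterochromatin": 1.0}
    )
    background_level: float = 2.0
    noise: NoiseParams = NoiseParams()
    minus_uv_retention: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 8 or self.image_width < 8:
            raise ValueError("field must be at least 8x8 pixels")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        c_lo, c_hi = self.cell_radius_range
        n_lo, n_hi = self.nucleus_radius_range
        if not (0 < c_lo <= c_hi) or not (0 < n_lo <= n_hi):
            raise ValueError("radius ranges must satisfy 0 < min <= max")
        if n_hi >= c_lo:
            raise ValueError("nucleus radii must be strictly smaller than cell radii")
        if self.membrane_band_width < 1:
            raise ValueError("membrane_band_width must be >= 1 pixel")
        if any(f < 0 for f in self.enrichment_folds.values()):
            raise ValueError("enrichment folds must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if not (0 <= self.minus_uv_retention <= 1):
            raise ValueError("minus_uv_retention must lie in [0, 1]")

    def without_noise(self) -> "FieldSpec":
        return replace(self, noise=NO_NOISE)


@dataclass
class CellGeometry:
    """Placement of one cell: axis-aligned ellipses for cell and nucleus."""

    center: tuple[float, float]            # (row, col)
    radii: tuple[float, float]             # (row semi-axis, col semi-axis)
    nucleus_center: tuple[float, float]
    nucleus_radii: tuple[float, float]
    foci: dict[str, list[tuple[float, float, float]]]  # kind -> [(row, col, radius)]


@dataclass
class FieldGeometry:
    spec: FieldSpec
    cells: list[CellGeometry]


@dataclass
class GroundTruth:
    """Generator-side masks and true parameters for recovery tests."""

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    pm_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    subcompartment_masks: dict[str, np.ndarray]
    true_folds: dict[str, float]
    true_compartment_means: dict[str, float]  # noise-free probe mean per compartment (raw AU)
    background_level: float


@dataclass
class SyntheticScene:
    channels: ChannelStack
    truth: GroundTruth
    time_min: float
    condition: str
    marker_kind: str | None


def _sample_radii(rng: np.random.Generator, radius_range: tuple[float, float]) -> tuple[float, float]:
    r = rng.uniform(*radius_range)
    ecc = rng.uniform(0.9, 1.1)
    return r * ecc, r / ecc


def sample_cell_layout(spec: FieldSpec, *, max_tries_per_cell: int = 400) -> FieldGeometry:
    """Place ``spec.n_cells`` non-overlapping cells by rejection sampling.

    Each nucleus lies fully inside its cell and each focus fully inside its
    nucleus; deterministic for a fixed ``spec.seed``.  Raises
    :class:`PlacementError` naming the achieved count if the budget runs out.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 101]))
    h, w = spec.image_height, spec.image_width
    gap = 3.0  # minimum boundary-to-boundary clearance between cells
    cells: list[CellGeometry] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, bounding radius)

    for i in range(spec.n_cells):
        for _ in range(max_tries_per_cell):
            ry, rx = _sample_radii(rng, spec.cell_radius_range)
            rb = max(ry, rx)
            if 2 * (rb + 1) >= min(h, w):
                continue
            cy = rng.uniform(rb + 1, h - 1 - rb - 1)
            cx = rng.uniform(rb + 1, w - 1 - rb - 1)
            if any(math.hypot(cy - py, cx - px) <= rb + pr + gap for py, px, pr in placed):
                continue
            cell = _sample_cell_interior(rng, spec, (cy, cx), (ry, rx))
            if cell is None:
                continue
            cells.append(cell)
            placed.append((cy, cx, rb))
            break
        else:
            raise PlacementError(
                f"placed only {len(cells)} of {spec.n_cells} cells after "
                f"{max_tries_per_cell} tries each; relax density or radii"
            )
    return FieldGeometry(spec=spec, cells=cells)


def _sample_cell_interior(
    rng: np.random.Generator,
    spec: FieldSpec,
    center: tuple[float, float],
    radii: tuple[float, float],
) -> CellGeometry | None:
    cy, cx = center
    ry, rx = radii
    nry, nrx = _sample_radii(rng, spec.nucleus_radius_range)
    slack = min(ry, rx) - max(nry, nrx) - 1.0
    if slack < 0:
        return None
    theta = rng.uniform(0, 2 * math.pi)
    rho = rng.uniform(0, slack)
    ncy, ncx = cy + rho * math.sin(theta), cx + rho * math.cos(theta)

    foci: dict[str, list[tuple[float, float, float]]] = {}
    existing: list[tuple[float, float, float]] = []
    for sub in spec.subcompartments:
        if sub.kind == "heterochromatin":
            foci[sub.kind] = []  # rendered as a rim band, no foci
            continue
        placed_foci: list[tuple[float, float, float]] = []
        for _ in range(sub.foci_per_nucleus):
            for _ in range(200):
                rf = rng.uniform(*sub.focus_radius_range)
                margin = min(nry, nrx) - rf - 0.5
                if margin <= 0:
                    continue
                th = rng.uniform(0, 2 * math.pi)
                rr = margin * math.sqrt(rng.uniform(0, 1))
                fy, fx = ncy + rr * math.sin(th), ncx + rr * math.cos(th)
                if any(math.hypot(fy - oy, fx - ox) <= rf + orad + 0.5 for oy, ox, orad in existing):
                    continue
                placed_foci.append((fy, fx, rf))
                existing.append((fy, fx, rf))
                break
            else:
                return None  # could not fit foci; resample the whole cell
        foci[sub.kind] = placed_foci
    return CellGeometry((cy, cx), (ry, rx), (ncy, ncx), (nry, nrx), foci)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float], radii: tuple[float, float]) -> np.ndarray:
    """Boolean raster of an axis-aligned ellipse, integer pixel centers."""
    cy, cx = center
    ry, rx = radii
    yy, xx = np.ogrid[0 : shape[0], 0 : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _render_truth(geometry: FieldGeometry) -> GroundTruth:
    spec = geometry.spec
    shape = (spec.image_height, spec.image_width)
    cell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    sub_masks = {sub.kind: np.zeros(shape, dtype=bool) for sub in spec.subcompartments}

    for k, cell in enumerate(geometry.cells, start=1):
        cmask = _ellipse_mask(shape, cell.center, cell.radii)
        nmask = _ellipse_mask(shape, cell.nucleus_center, cell.nucleus_radii)
        nmask &= cmask
        cell_labels[cmask] = k
        nucleus_labels[nmask] = k
        for sub in spec.subcompartments:
            if sub.kind == "heterochromatin":
                w = sub.focus_radius_range[0]
                inner = _ellipse_mask(
                    shape,
                    cell.nucleus_center,
                    (max(cell.nucleus_radii[0] - w, 1.0), max(cell.nucleus_radii[1] - w, 1.0)),
                )
                sub_masks[sub.kind] |= nmask & ~inner
            else:
                for fy, fx, rf in cell.foci.get(sub.kind, []):
                    sub_masks[sub.kind] |= _ellipse_mask(shape, (fy, fx), (rf, rf)) & nmask

    pm_mask = np.zeros(shape, dtype=bool)
    for k in range(1, len(geometry.cells) + 1):
        cmask = cell_labels == k
        dist = ndi.distance_transform_edt(cmask)
        pm_mask |= cmask & (dist <= spec.membrane_band_width)
    pm_mask &= nucleus_labels == 0  # nucleus wins ties over the membrane band
    cytoplasm_mask = (cell_labels > 0) & ~pm_mask & (nucleus_labels == 0)

    return GroundTruth(
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
        pm_mask=pm_mask,
        cytoplasm_mask=cytoplasm_mask,
        subcompartment_masks=sub_masks,
        true_folds={sub.kind: spec.enrichment_folds[sub.kind] for sub in spec.subcompartments},
        true_compartment_means={},
        background_level=spec.background_level,
    )


def apply_noise(raster: np.ndarray, noise: NoiseParams, seed: int | np.random.SeedSequence) -> np.ndarray:
    """Poisson shot noise at ``poisson_scale`` photons/AU, then Gaussian read
    noise, clipped at zero.  Deterministic per seed; the infinite-scale /
    zero-sd limit returns the input unchanged."""
    raster = np.asarray(raster, dtype=float)
    if np.any(raster < 0):
        raise ValueError("raster must be non-negative before noise")
    rng = np.random.default_rng(seed)
    out = raster
    if math.isfinite(noise.poisson_scale):
        out = rng.poisson(out * noise.poisson_scale).astype(float) / noise.poisson_scale
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def render_scene(
    geometry: FieldGeometry,
    spec: FieldSpec,
    time_min: float = 360.0,
    condition: str = "plusUV",
    uptake_rate: float = 1.0 / 360.0,
    marker_kind: str | None = None,
) -> SyntheticScene:
    """Render a scene from a sampled layout.

    The probe channel is ``background_level`` plus a compartment-dependent
    signal that scales linearly with time (``signal = uptake_rate * time_min
    * base_level``); −UV scenes retain ``minus_uv_retention`` of the +UV
    signal and untreated scenes carry background only.  Subcompartment
    pixels carry exactly ``fold ×`` the nucleoplasm signal, so the
    configured fold is recovered exactly on the background-corrected scale.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if time_min < 0:
        raise ValueError("time_min must be >= 0")
    truth = _render_truth(geometry)
    if marker_kind is None:
        marker_kind = spec.subcompartments[0].kind if spec.subcompartments else None

    scale = uptake_rate * time_min
    if condition == "minusUV":
        scale *= spec.minus_uv_retention
    elif condition == "untreated":
        scale = 0.0

    nucleus_support = truth.nucleus_labels > 0
    levels = spec.base_levels
    probe = np.full(truth.cell_labels.shape, spec.background_level, dtype=float)
    probe[truth.pm_mask] += scale * levels["pm"]
    probe[truth.cytoplasm_mask] += scale * levels["cytoplasm"]
    probe[nucleus_support] += scale * levels["nucleoplasm"]
    for kind, mask in truth.subcompartment_masks.items():
        fold = truth.true_folds[kind]
        probe[mask] = spec.background_level + scale * fold * levels["nucleoplasm"]

    dapi = np.where(nucleus_support, DAPI_LEVEL, 0.0)

    membrane_band = np.zeros_like(probe, dtype=bool)
    for k in range(1, len(geometry.cells) + 1):
        cmask = truth.cell_labels == k
        membrane_band |= cmask & (ndi.distance_transform_edt(cmask) <= spec.membrane_band_width)
    membrane = np.where(membrane_band, MEMBRANE_BACKGROUND + MEMBRANE_BAND_LEVEL, MEMBRANE_BACKGROUND)

    marker = np.full_like(probe, MARKER_BACKGROUND)
    marker[nucleus_support] = MARKER_NUCLEOPLASM_LEVEL
    if marker_kind is not None and marker_kind in truth.subcompartment_masks:
        marker[truth.subcompartment_masks[marker_kind]] = MARKER_FOCUS_LEVEL

    for comp, mask in (
        ("pm", truth.pm_mask),
        ("cytoplasm", truth.cytoplasm_mask),
        ("nucleus", nucleus_support),
        ("whole_cell", truth.cell_labels > 0),
    ):
        truth.true_compartment_means[comp] = float(probe[mask].mean()) if mask.any() else float("nan")

    channels = {"dapi": dapi, "membrane": membrane, "marker": marker, "probe": probe}
    cond_idx = CONDITIONS.index(condition)
    for i, name in enumerate(sorted(channels)):
        ss = np.random.SeedSequence([int(spec.seed), 977, cond_idx, int(round(time_min * 1000)), i])
        channels[name] = apply_noise(channels[name], spec.noise, ss)

    return SyntheticScene(
        channels=ChannelStack(channels),
        truth=truth,
        time_min=float(time_min),
        condition=condition,
        marker_kind=marker_kind,
    )


def generate_scene(
    spec: FieldSpec,
    time_min: float = 360.0,
    condition: str = "plusUV",
    uptake_rate: float = 1.0 / 360.0,
) -> SyntheticScene:
    """Convenience: sample a layout and render it in one call."""
    return render_scene(sample_cell_layout(spec), spec, time_min, condition, uptake_rate)


def generate_time_course(
    spec: FieldSpec,
    times: Sequence[float],
    uptake_rate: float = 1.0 / 360.0,
    condition: str = "plusUV",
    fields_per_time: int = 1,
) -> list[SyntheticScene]:
    """Independent fields at each labeling time; probe signal grows linearly
    as ``uptake_rate * t`` times the compartment base levels."""
    times = list(times)
    if any(t < 0 for t in times):
        raise ValueError("times must be >= 0")
    if sorted(times) != times:
        raise ValueError("times must be sorted ascending")
    scenes = []
    for i, t in enumerate(times):
        for j in range(fields_per_time):
            sub_seed = int(np.random.SeedSequence([int(spec.seed), 555, i, j]).generate_state(1)[0] % (2**31))
            sub = replace(spec, seed=sub_seed)
            scenes.append(render_scene(sample_cell_layout(sub), sub, t, condition, uptake_rate))
    return scenes


# ---------------------------------------------------------------------------
# Gel simulation


GEL_LANE_ROLES = ("ladder", "no_click", "untreated", "vehicle", "minusUV", "plusUV")


@dataclass(frozen=True)
class GelLaneSpec:
    role: str
    true_integrated_signal: float

    def __post_init__(self) -> None:
        if self.role not in GEL_LANE_ROLES:
            raise ValueError(f"unknown lane role {self.role!r}")
        if self.true_integrated_signal < 0:
            raise ValueError("true_integrated_signal must be >= 0")


@dataclass(frozen=True)
class GelSpec:
    """One synthetic fluorescence gel.

    ``band_layout`` entries are (migration position px, FWHM px, relative
    mass); the same layout is shared by all sample lanes so lane ratios are
    shape-independent.  Band supports are truncated at 3 sigma and must stay
    clear of the 5% edge windows used for baseline estimation.
    """

    lanes: tuple[GelLaneSpec, ...]
    lane_width: int = 16
    profile_length: int = 200
    band_layout: tuple[tuple[float, float, float], ...] = ((70.0, 8.0, 1.0), (110.0, 10.0, 0.6), (150.0, 8.0, 0.4))
    baseline_level: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lanes) == 0:
            raise ValueError("a gel needs at least one lane")
        if self.lane_width < 3 or self.profile_length < 20:
            raise ValueError("lane_width >= 3 and profile_length >= 20 required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        edge = 0.05 * self.profile_length
        for pos, fwhm, mass in self.band_layout:
            sigma = fwhm / 2.355
            if pos - 3 * sigma < edge or pos + 3 * sigma > self.profile_length - edge:
                raise ValueError("band support overlaps the baseline edge windows")
            if mass <= 0:
                raise ValueError("band relative mass must be > 0")


@dataclass
class SyntheticGel:
    raster: np.ndarray
    lane_columns: list[tuple[int, int]]       # (start, stop) column slices per lane
    lane_roles: list[str]
    true_signals: list[float]
    spec: GelSpec


def _band_kernel(length: int, layout: Sequence[tuple[float, float, float]]) -> np.ndarray:
    rows = np.arange(length, dtype=float)
    kernel = np.zeros(length)
    for pos, fwhm, mass in layout:
        sigma = fwhm / 2.355
        k = np.exp(-0.5 * ((rows - pos) / sigma) ** 2)
        k[np.abs(rows - pos) > 3 * sigma] = 0.0
        kernel += mass * k
    return kernel / kernel.sum()


def generate_gel(gelspec: GelSpec) -> SyntheticGel:
    """Render a multi-lane gel raster whose noise-free per-lane integrated
    signal above baseline equals each lane's configured truth exactly."""
    n = len(gelspec.lanes)
    gap = max(4, gelspec.lane_width // 3)
    width = n * gelspec.lane_width + (n + 1) * gap
    raster = np.full((gelspec.profile_length, width), gelspec.baseline_level, dtype=float)

    sample_kernel = _band_kernel(gelspec.profile_length, gelspec.band_layout)
    ladder_positions = np.linspace(0.15, 0.85, 6) * gelspec.profile_length
    ladder_kernel = _band_kernel(gelspec.profile_length, [(p, 4.0, 1.0) for p in ladder_positions])

    lane_columns, roles, truths = [], [], []
    for i, lane in enumerate(gelspec.lanes):
        start = gap + i * (gelspec.lane_width + gap)
        stop = start + gelspec.lane_width
        kernel = ladder_kernel if lane.role == "ladder" else sample_kernel
        raster[:, start:stop] += np.outer(kernel * lane.true_integrated_signal, np.ones(gelspec.lane_width))
        lane_columns.append((start, stop))
        roles.append(lane.role)
        truths.append(lane.true_integrated_signal)

    if gelspec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(gelspec.seed), 313]))
        raster = np.clip(raster + rng.normal(0.0, gelspec.noise_sd, raster.shape), 0.0, None)
    return SyntheticGel(raster=raster, lane_columns=lane_columns, lane_roles=roles, true_signals=truths, spec=gelspec)
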