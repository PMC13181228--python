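"""Three-compartment cell segmentation.

Nuclei are segmented from the DAPI channel (smooth, Otsu threshold, fill
holes, area filter, distance-transform watershed to split touching
nuclei).  Cells are grown from the nuclei by a seeded watershed on the
smoothed plasma-membrane marker, which acts as a ridge landscape.  Each
cell is then partitioned exactly into a plasma-membrane band (pixels
within a configurable distance of the cell boundary), the nucleus, and
the remaining cytoplasm.  Nucleus pixels always win ties over the
membrane band so nuclear measurements are never contaminated.

All thresholds are relative, so segmentation is invariant to a global
positive rescaling of the intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import relabel_sequential, watershed


@dataclass
class ChannelStack:
    """Named, co-registered 2-D intensity rasters (one per channel)."""

    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(r).shape for name, r in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, raster in self.channels.items():
            arr = np.asarray(raster, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"channel {name!r} has non-finite or negative intensities")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(f"channel {name!r} not in stack; available: {sorted(self.channels)}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.channels


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables for the nucleus/cell segmentation stages (pixel units)."""

    smoothing_sigma: float = 2.0
    min_nucleus_area: int = 50
    min_seed_separation: int = 10
    membrane_band_width: float = 3.0
    exclude_border_cells: bool = True

    def __post_init__(self) -> None:
        if self.smoothing_sigma <= 0 or self.min_nucleus_area <= 0 or self.min_seed_separation <= 0:
            raise ValueError("segmentation parameters must be strictly positive")
        if self.membrane_band_width < 1:
            raise ValueError("membrane_band_width must be >= 1 pixel")


@dataclass
class CompartmentMasks:
    """Exact three-way partition of every retained cell.

    Per cell k the plasma-membrane band, cytoplasm, and nucleus are pairwise
    disjoint and tile the cell-k support exactly; cell and nucleus label
    sets are identical.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    pm_mask: np.ndarray
    cytoplasm_mask: np.ndarray

    def labels(self) -> list[int]:
        return [int(k) for k in np.unique(self.cell_labels) if k != 0]


def _validate_raster(raster: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(raster, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 2-D raster")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains NaN or infinite values")
    return arr


def segment_nuclei(dapi: np.ndarray, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Label nuclei in a DAPI raster.

    Returns an int32 label raster with labels 1..K; objects smaller than
    ``min_nucleus_area`` are removed, and touching nuclei are split by a
    distance-transform watershed seeded at local maxima separated by at
    least ``min_seed_separation`` pixels.  A constant (e.g. all-zero)
    raster yields zero nuclei.
    """
    dapi = _validate_raster(dapi, "dapi")
    if dapi.max() == dapi.min():
        return np.zeros(dapi.shape, dtype=np.int32)
    smoothed = gaussian(dapi, sigma=params.smoothing_sigma, preserve_range=True)
    fg = smoothed > threshold_otsu(smoothed)
    fg = ndi.binary_fill_holes(fg)
    fg = remove_small_objects(fg, max_size=params.min_nucleus_area - 1)
    if not fg.any():
        return np.zeros(dapi.shape, dtype=np.int32)

    dist = ndi.distance_transform_edt(fg)
    blob_labels = cc_label(fg)
    coords = peak_local_max(
        dist, min_distance=params.min_seed_separation, labels=blob_labels, exclude_border=False
    )
    markers = np.zeros(dapi.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    labels = watershed(-dist, markers, mask=fg)

    # drop fragments below the area floor, then relabel 1..K
    areas = np.bincount(labels.ravel())
    small = np.flatnonzero(areas < params.min_nucleus_area)
    labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_cells(
    membrane: np.ndarray,
    nucleus_labels: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> np.ndarray:
    """Grow one cell per nucleus by seeded watershed on the membrane marker.

    The smoothed membrane intensity is treated as a ridge landscape; the
    cell foreground is the hole-filled thresholded membrane united with the
    nuclei.  Cell label k always contains nucleus label k (nuclei are
    clipped to their cell with a warning otherwise).
    """
    membrane = _validate_raster(membrane, "membrane")
    nucleus_labels = np.asarray(nucleus_labels)
    if membrane.shape != nucleus_labels.shape:
        raise ValueError("membrane and nucleus_labels shapes differ")
    if nucleus_labels.max() == 0:
        raise ValueError("no nuclei provided; run segment_nuclei first")

    smoothed = gaussian(membrane, sigma=params.smoothing_sigma, preserve_range=True)
    if smoothed.max() > smoothed.min():
        ridge = smoothed > threshold_otsu(smoothed)
    else:
        ridge = np.zeros(membrane.shape, dtype=bool)
    fg = ndi.binary_fill_holes(ridge) | (nucleus_labels > 0)
    cells = watershed(smoothed, markers=nucleus_labels, mask=fg).astype(np.int32)

    clipped = (nucleus_labels > 0) & (cells != nucleus_labels)
    if clipped.any():
        warnings.warn(
            f"{int(clipped.sum())} nucleus pixels fell outside their cell basin and were clipped",
            stacklevel=2,
        )
    return cells


def derive_compartments(
    cell_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> CompartmentMasks:
    """Partition every cell into membrane band / cytoplasm / nucleus.

    The membrane band is geometric: pixels of cell k whose Euclidean
    distance to the nearest non-cell-k pixel is at most
    ``membrane_band_width``, minus nucleus pixels.  Cells touching the
    image border are dropped when ``exclude_border_cells`` is set.
    """
    cell_labels = np.asarray(cell_labels).copy()
    nucleus_labels = np.asarray(nucleus_labels).copy()
    if cell_labels.shape != nucleus_labels.shape:
        raise ValueError("cell and nucleus label rasters differ in shape")
    cell_set = set(np.unique(cell_labels)) - {0}
    nuc_set = set(np.unique(nucleus_labels)) - {0}
    if cell_set != nuc_set:
        raise ValueError(f"cell/nucleus label sets differ: {sorted(cell_set ^ nuc_set)}")

    if params.exclude_border_cells:
        border = np.zeros(cell_labels.shape, dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        for k in sorted(set(np.unique(cell_labels[border])) - {0}):
            cell_labels[cell_labels == k] = 0
            nucleus_labels[nucleus_labels == k] = 0

    # nuclei must sit inside their cells for the partition to be exact
    stray = (nucleus_labels > 0) & (cell_labels != nucleus_labels)
    if stray.any():
        nucleus_labels[stray] = 0

    pm_mask = np.zeros(cell_labels.shape, dtype=bool)
    objects = ndi.find_objects(cell_labels)
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sl = tuple(slice(max(s.start - 1, 0), s.stop + 1) for s in sl)
        cmask = cell_labels[sl] == k
        dist = ndi.distance_transform_edt(cmask)
        pm_mask[sl] |= cmask & (dist <= params.membrane_band_width)
    pm_mask &= nucleus_labels == 0
    cytoplasm_mask = (cell_labels > 0) & ~pm_mask & (nucleus_labels == 0)

    return CompartmentMasks(
        cell_labels=cell_labels.astype(np.int32),
        nucleus_labels=nucleus_labels.astype(np.int32),
        pm_mask=pm_mask,
        cytoplasm_mask=cytoplasm_mask,
    )


def segment_field(
    stack: ChannelStack,
    params: SegmentationParams = SegmentationParams(),
    dapi_channel: str = "dapi",
    membrane_channel: str = "membrane",
) -> CompartmentMasks:
    """Full segmentation of one field: nuclei, cells, compartments."""
    nuclei = segment_nuclei(stack[dapi_channel], params)
    if nuclei.max() == 0:
        empty = np.zeros(stack.shape, dtype=np.int32)
        return CompartmentMasks(empty, empty.copy(), np.zeros(stack.shape, bool), np.zeros(stack.shape, bool))
    cells = segment_cells(stack[membrane_channel], nuclei, params)
    return derive_compartments(cells, nuclei, params)
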