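"""Nuclei-seeded cell segmentation for two-channel screening fields.

The classic high-content-screening recipe: nuclei are detected on the
nuclear-stain channel (smooth, top-hat background removal, Otsu threshold,
distance-transform watershed to split touching nuclei) and then used as
markers to grow per-cell cytoplasmic regions on the GFP channel (watershed
of the inverted smoothed GFP restricted to the GFP foreground, clipped to a
maximum radius around each seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import disk, white_tophat
from skimage.segmentation import expand_labels, relabel_sequential, watershed

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "LabelMaskPair",
    "segment_nuclei",
    "segment_cytoplasm",
    "correct_illumination",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the two-step segmentation.

    Defaults are tuned to the simulator's geometry (nuclei ~6 px radius,
    cytoplasm ~5 px annulus at 256x256 px per field) and are all overridable
    from the run configuration.
    """

    smooth_sigma: float = 1.5
    background_radius: int = 25
    min_nucleus_area: int = 20
    max_nucleus_area: int = 800
    min_seed_distance: int = 5
    cyto_max_radius: float = 12.0
    gfp_foreground_method: str = "halfmax"

    def __post_init__(self) -> None:
        if self.min_nucleus_area <= 0 or self.max_nucleus_area <= 0:
            raise ValueError("nucleus area bounds must be positive")
        if self.min_nucleus_area >= self.max_nucleus_area:
            raise ValueError(
                f"min_nucleus_area ({self.min_nucleus_area}) must be < "
                f"max_nucleus_area ({self.max_nucleus_area})"
            )
        if self.gfp_foreground_method not in ("otsu", "halfmax", "none"):
            raise ValueError(
                f"unknown gfp_foreground_method {self.gfp_foreground_method!r}"
            )


@dataclass
class LabelMaskPair:
    """Matched nucleus/cytoplasm label masks: identical label sets, disjoint
    per-cell regions, labels consecutive from 1."""

    nuclei: np.ndarray
    cytoplasm: np.ndarray

    def labels(self) -> np.ndarray:
        return np.unique(self.nuclei[self.nuclei > 0])

    def validate(self) -> None:
        if self.nuclei.shape != self.cytoplasm.shape:
            raise ValueError("mask shapes differ")
        nuc = set(np.unique(self.nuclei)) - {0}
        cyt = set(np.unique(self.cytoplasm)) - {0}
        if nuc != cyt:
            raise ValueError(f"label sets differ: {sorted(nuc ^ cyt)}")
        if np.any((self.nuclei > 0) & (self.cytoplasm > 0)):
            raise ValueError("nucleus and cytoplasm masks overlap")
        if nuc and sorted(nuc) != list(range(1, len(nuc) + 1)):
            raise ValueError("labels are not consecutive from 1")


def _check_raster(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty raster")
    img = img.astype(np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("raster contains non-finite pixels")
    return img


def segment_nuclei(dna: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Detect nuclei on the nuclear-stain channel.

    Pipeline: Gaussian smooth -> white top-hat background removal -> global
    Otsu threshold -> fill holes -> watershed on the distance transform,
    seeded at its regional maxima (minimum seed separation
    ``min_seed_distance``) so touching nuclei are split -> drop components
    outside the plausible area range -> relabel consecutively.

    An all-constant image yields zero labels (an empty field is not an
    error); non-finite pixels raise.
    """
    params = params or SegmentationParams()
    img = _check_raster(dna)

    smoothed = gaussian(img, sigma=params.smooth_sigma, preserve_range=True)
    footprint = disk(params.background_radius, decomposition="sequence")
    flat = white_tophat(smoothed, footprint=footprint)
    if flat.max() <= flat.min():
        return np.zeros(img.shape, dtype=np.int32)
    binary = flat > threshold_otsu(flat)
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)
    binary = ndi.binary_fill_holes(binary)

    distance = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        distance,
        min_distance=params.min_seed_distance,
        labels=binary,
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    # scan-order marker numbering keeps the flood deterministic
    order = np.lexsort((peaks[:, 1], peaks[:, 0])) if peaks.size else []
    for i, idx in enumerate(order, start=1):
        markers[peaks[idx, 0], peaks[idx, 1]] = i
    labels = watershed(-distance, markers, mask=binary)

    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero(
        (areas < params.min_nucleus_area) | (areas > params.max_nucleus_area)
    )
    labels[np.isin(labels, bad[bad > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def _gfp_foreground(img: np.ndarray, method: str) -> np.ndarray:
    """GFP foreground mask per the configured strategy.

    Thresholds are computed on the unsmoothed raster: the cell/background
    contrast is large against the pixel noise, and smoothing a cytoplasmic
    ring only a few pixels wide drags the threshold contour well outside the
    true boundary. ``otsu``: global Otsu. ``halfmax`` (default): Otsu to
    split classes, then threshold at the midpoint of the class medians (the
    half-maximum edge of a step). ``none``: everything is foreground.
    """
    if method == "none":
        return np.ones(img.shape, dtype=bool)
    if img.max() <= img.min():
        return np.ones(img.shape, dtype=bool)
    thr = threshold_otsu(img)
    if method == "halfmax":
        lo = np.median(img[img <= thr])
        hi = np.median(img[img > thr])
        thr = (lo + hi) / 2.0
    return img > thr


def segment_cytoplasm(
    gfp: np.ndarray,
    nuclei: np.ndarray,
    params: SegmentationParams | None = None,
) -> LabelMaskPair:
    """Grow per-cell regions on the GFP channel from nucleus seeds.

    The GFP foreground (per ``gfp_foreground_method``, union of the nucleus
    footprint) is partitioned by a watershed of the inverted smoothed GFP
    seeded at the nuclei; each region is clipped to within
    ``cyto_max_radius`` of its own seed (nearest-seed tie-break, so adjacent
    cells stay disjoint). The cytoplasm is the region minus the nucleus;
    cells left without any cytoplasm pixel are dropped from both masks.
    """
    params = params or SegmentationParams()
    img = _check_raster(gfp)
    nuclei = np.asarray(nuclei)
    if nuclei.shape != img.shape:
        raise ValueError(
            f"shape mismatch: gfp {img.shape} vs nuclei {nuclei.shape}"
        )
    if nuclei.max() == 0:
        empty = np.zeros(img.shape, dtype=np.int32)
        return LabelMaskPair(nuclei=empty, cytoplasm=empty.copy())

    smoothed = gaussian(img, sigma=params.smooth_sigma, preserve_range=True)
    foreground = _gfp_foreground(img, params.gfp_foreground_method)
    foreground |= nuclei > 0

    reached = watershed(-smoothed, nuclei.astype(np.int32), mask=foreground)
    # On bright plateaus (cells brighter than their dim nuclear seeds) the
    # flood order lets one seed annex its neighbours' cytoplasm, so the
    # watershed decides only reachability; contested pixels and the radius
    # clip resolve to the nearest seed within cyto_max_radius, which keeps
    # adjacent cells disjoint and the assignment deterministic.
    allowed = expand_labels(nuclei, distance=params.cyto_max_radius)
    cells = np.where((reached > 0) & (allowed > 0), allowed, 0).astype(np.int32)
    cells[nuclei > 0] = nuclei[nuclei > 0]

    cyto = np.where(nuclei > 0, 0, cells).astype(np.int32)
    nuc_out = nuclei.astype(np.int32).copy()
    empty_cyto = sorted(set(np.unique(nuc_out)) - set(np.unique(cyto)) - {0})
    if empty_cyto:
        logger.warning("dropping %d cell(s) with empty cytoplasm: %s", len(empty_cyto), empty_cyto)
        nuc_out[np.isin(nuc_out, empty_cyto)] = 0
    orphan = sorted(set(np.unique(cyto)) - set(np.unique(nuc_out)) - {0})
    if orphan:  # cannot happen (regions are seeded), but keep the contract
        cyto[np.isin(cyto, orphan)] = 0

    nuc_out, fwd, _ = relabel_sequential(nuc_out)
    cyto = np.asarray(fwd)[cyto]
    return LabelMaskPair(nuclei=nuc_out.astype(np.int32), cytoplasm=cyto.astype(np.int32))


def correct_illumination(raster: np.ndarray, model: str = "poly2") -> np.ndarray:
    """Flat-field a raster by dividing out a fitted smooth surface.

    ``model="poly2"`` fits a full second-order 2-D polynomial to the image by
    least squares and divides by the surface normalized to unit mean, which
    removes the quadratic radial vignetting the simulator applies;
    ``model="none"`` is the identity. A fitted surface that is not strictly
    positive raises (the image is then too structured for this simple model).
    """
    img = _check_raster(raster)
    if model == "none":
        return img
    if model != "poly2":
        raise ValueError(f"unknown illumination model {model!r}")
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    y = (yy / max(h - 1, 1)).ravel()
    x = (xx / max(w - 1, 1)).ravel()
    design = np.column_stack([np.ones_like(x), x, y, x * y, x**2, y**2])
    coef, *_ = np.linalg.lstsq(design, img.ravel(), rcond=None)
    surface = (design @ coef).reshape(img.shape)
    if surface.min() <= 0:
        raise ValueError("fitted illumination surface is not strictly positive")
    surface = surface / surface.mean()
    return img / surface
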