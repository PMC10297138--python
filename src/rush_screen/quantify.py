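"""Per-cell intensity extraction, well-level aggregation, and the pixel
colocalization statistics (PCC, SOC) used for clone characterization."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from rush_screen.segmentation import LabelMaskPair

logger = logging.getLogger(__name__)

__all__ = [
    "CellRecord",
    "WellSummary",
    "per_cell_intensity",
    "summarize_well",
    "pearson_colocalization",
    "surface_overlap",
]


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell: identity, region areas (px^2), mean cytoplasmic
    GFP (AFU, nucleus excluded) and whether it touches the field border."""

    plate_id: str
    well_id: str
    field_index: int
    cell_label: int
    nucleus_area: int
    cytoplasm_area: int
    mean_cyto_gfp: float
    touches_border: bool


@dataclass
class WellSummary:
    """Per-well aggregate over all fields: cell count, the median of the
    per-cell mean cytoplasmic GFP (undefined when no cell was found), and QC
    flags (``low_cell_count``, ``segmentation_failure``)."""

    plate_id: str
    well_id: str
    n_cells: int
    well_gfp: float | None
    qc_flags: set[str] = field(default_factory=set)


def per_cell_intensity(
    gfp: np.ndarray,
    masks: LabelMaskPair,
    plate_id: str = "",
    well_id: str = "",
    field_index: int = 0,
) -> list[CellRecord]:
    """Measure each cell's mean cytoplasmic GFP.

    ``mean_cyto_gfp`` is the arithmetic mean of the GFP pixels over the
    cell's cytoplasm mask (nucleus excluded). One record per label, ordered
    by label. A label with no cytoplasm pixel is skipped with a warning (the
    segmentation contract excludes this case).
    """
    gfp = np.asarray(gfp, dtype=np.float64)
    if gfp.shape != masks.cytoplasm.shape:
        raise ValueError(
            f"shape mismatch: gfp {gfp.shape} vs masks {masks.cytoplasm.shape}"
        )
    labels = masks.labels()
    if labels.size == 0:
        return []

    nuc_areas = np.bincount(masks.nuclei.ravel(), minlength=labels.max() + 1)
    cyt_areas = np.bincount(masks.cytoplasm.ravel(), minlength=labels.max() + 1)
    means = ndi.mean(gfp, labels=masks.cytoplasm, index=labels)

    border = np.zeros(labels.max() + 1, dtype=bool)
    footprint = np.where(masks.nuclei > 0, masks.nuclei, masks.cytoplasm)
    for edge in (footprint[0], footprint[-1], footprint[:, 0], footprint[:, -1]):
        border[np.unique(edge[edge > 0])] = True

    records: list[CellRecord] = []
    for lbl, mean in zip(labels, np.atleast_1d(means)):
        if cyt_areas[lbl] == 0:
            logger.warning("cell %d has an empty cytoplasm mask; skipped", lbl)
            continue
        records.append(
            CellRecord(
                plate_id=plate_id,
                well_id=well_id,
                field_index=field_index,
                cell_label=int(lbl),
                nucleus_area=int(nuc_areas[lbl]),
                cytoplasm_area=int(cyt_areas[lbl]),
                mean_cyto_gfp=float(mean),
                touches_border=bool(border[lbl]),
            )
        )
    return records


def summarize_well(records: list[CellRecord], min_cells: int = 10) -> WellSummary:
    """Aggregate a well's cell records over all its fields.

    The well statistic is the median of per-cell means — robust to debris
    and segmentation outliers. An empty record list yields a summary flagged
    ``segmentation_failure`` with undefined ``well_gfp``.
    """
    if not records:
        return WellSummary(
            plate_id="", well_id="", n_cells=0, well_gfp=None,
            qc_flags={"segmentation_failure"},
        )
    wells = {(r.plate_id, r.well_id) for r in records}
    if len(wells) > 1:
        raise ValueError(f"records span multiple wells: {sorted(wells)}")
    plate_id, well_id = records[0].plate_id, records[0].well_id
    n = len(records)
    flags: set[str] = set()
    if n < min_cells:
        flags.add("low_cell_count")
    well_gfp = float(np.median([r.mean_cyto_gfp for r in records]))
    return WellSummary(plate_id=plate_id, well_id=well_id, n_cells=n, well_gfp=well_gfp, qc_flags=flags)


def pearson_colocalization(
    ch1: np.ndarray, ch2: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Pearson's correlation coefficient (PCC) over co-registered pixels.

    Computed over ``mask`` when given, else the whole frame. Requires at
    least two pixels and both channels non-constant over the mask (a
    constant channel leaves the correlation undefined).
    """
    a = np.asarray(ch1, dtype=np.float64)
    b = np.asarray(ch2, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape differs from channels")
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 pixels to correlate")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: a channel is constant over the mask")
    return float(np.corrcoef(a, b)[0, 1])


def surface_overlap(
    ch1: np.ndarray,
    ch2: np.ndarray,
    threshold_method: str = "otsu",
    mode: str = "jaccard",
) -> float:
    """Surface overlap coefficient (SOC) of two channels.

    Each channel is binarized (per-channel Otsu by default; ``"positive"``
    takes any pixel > 0, for already-binary masks) and the overlap of the
    foregrounds is returned: Jaccard |A∩B|/|A∪B| by default, or Manders-style
    M1 |A∩B|/|A| with ``mode="manders_m1"``. An empty union raises.
    """
    a = np.asarray(ch1, dtype=np.float64)
    b = np.asarray(ch2, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")

    def fg(img: np.ndarray) -> np.ndarray:
        if threshold_method == "positive":
            return img > 0
        if threshold_method == "otsu":
            if img.max() == img.min():
                return img > 0
            return img > threshold_otsu(img)
        raise ValueError(f"unknown threshold method {threshold_method!r}")

    A, B = fg(a), fg(b)
    union = np.count_nonzero(A | B)
    if union == 0:
        raise ValueError("empty foreground union: nothing to overlap")
    inter = np.count_nonzero(A & B)
    if mode == "jaccard":
        return inter / union
    if mode == "manders_m1":
        nA = np.count_nonzero(A)
        if nA == 0:
            raise ValueError("channel 1 has empty foreground")
        return inter / nA
    raise ValueError(f"unknown SOC mode {mode!r}")
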