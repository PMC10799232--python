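"""Nuclei segmentation on the stitched nuclear mosaic, ROI extraction and
per-cell measurements across all channel mosaics."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation

__all__ = [
    "LabelImage",
    "CellRecord",
    "PolygonROI",
    "segment_nuclei",
    "labels_to_rois",
    "measure_cells",
]


@dataclass(frozen=True)
class LabelImage:
    """Integer nucleus labels: 0 = background, 1..n_labels = nuclei, no gaps."""

    labels: np.ndarray
    n_labels: int

    @staticmethod
    def from_array(labels: np.ndarray) -> "LabelImage":
        labels = np.asarray(labels)
        if labels.ndim != 2 or not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be a 2D integer array")
        present = np.unique(labels)
        present = present[present > 0]
        n = int(present.max()) if present.size else 0
        if present.size != n:  # gaps — relabel sequentially
            relabeled, _, _ = segmentation.relabel_sequential(labels)
            return LabelImage(
                labels=relabeled.astype(np.int32), n_labels=int(relabeled.max())
            )
        return LabelImage(labels=labels.astype(np.int32), n_labels=n)


@dataclass(frozen=True)
class PolygonROI:
    """Boundary polygon of one nucleus, vertices as (x, y) in mosaic pixels."""

    name: str
    vertices: np.ndarray  # (n, 2) float, columns x, y

    def __post_init__(self) -> None:
        if self.vertices.shape[0] < 3:
            raise ValueError(f"ROI {self.name!r} needs >= 3 vertices")


@dataclass(frozen=True)
class CellRecord:
    label: int
    centroid_x: float
    centroid_y: float
    area: float
    perimeter: float
    circularity: float
    orientation: float  # degrees
    mean_intensity: dict = field(default_factory=dict)  # (cycle, channel, reporter) -> mean
    intensity_stats: dict = field(default_factory=dict)  # (cycle, channel) -> (min, max, std)


def segment_nuclei(
    image: np.ndarray,
    method: str = "classical",
    plugin: Callable[[np.ndarray], np.ndarray] | None = None,
    smooth_sigma: float = 2.0,
    min_area: int = 15,
    h_maxima: float = 0.1,
) -> LabelImage:
    """Segment nuclei from the nuclear-stain mosaic.

    The classical method normalises to the 1st–99th percentile, smooths,
    Otsu-thresholds and splits touching nuclei by a distance-transform
    watershed seeded at h-maxima. ``method="plugin"`` delegates to any
    callable returning an integer label array (e.g. a StarDist adapter).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    if method == "plugin":
        if plugin is None:
            raise ValueError("method='plugin' requires a plugin callable")
        return LabelImage.from_array(np.asarray(plugin(image)))
    if method != "classical":
        raise ValueError(f"unknown segmentation method: {method!r}")

    lo, hi = np.percentile(image, (1.0, 99.0))
    if hi <= lo:
        return LabelImage(labels=np.zeros(image.shape, dtype=np.int32), n_labels=0)
    norm = np.clip((image - lo) / (hi - lo), 0.0, 1.0)
    smooth = ndimage.gaussian_filter(norm, smooth_sigma, mode="reflect")
    if smooth.max() <= smooth.min():
        return LabelImage(labels=np.zeros(image.shape, dtype=np.int32), n_labels=0)
    mask = smooth > filters.threshold_otsu(smooth)
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        return LabelImage(labels=np.zeros(image.shape, dtype=np.int32), n_labels=0)

    distance = ndimage.distance_transform_edt(mask)
    seeds_mask = morphology.h_maxima(distance, h_maxima * max(distance.max(), 1e-9))
    seeds, _ = ndimage.label(seeds_mask)
    if seeds.max() == 0:
        seeds, _ = ndimage.label(mask)
    labels = segmentation.watershed(-distance, seeds, mask=mask)
    sizes = np.bincount(labels.ravel())
    too_small = np.flatnonzero(sizes < min_area)
    labels[np.isin(labels, too_small)] = 0
    relabeled, _, _ = segmentation.relabel_sequential(labels)
    return LabelImage(
        labels=relabeled.astype(np.int32), n_labels=int(relabeled.max())
    )


def labels_to_rois(label_image: LabelImage) -> list[PolygonROI]:
    """Trace one boundary polygon per label, in mosaic pixel coordinates."""
    rois: list[PolygonROI] = []
    labels = label_image.labels
    for region in measure.regionprops(labels):
        mask = np.pad(region.image, 1)  # pad so boundary contours close
        contours = measure.find_contours(mask.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        y0, x0 = region.bbox[0], region.bbox[1]
        verts = np.column_stack(
            [contour[:, 1] - 1 + x0, contour[:, 0] - 1 + y0]
        )
        if np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        rois.append(PolygonROI(name=str(region.label), vertices=verts))
    return rois


def measure_cells(
    label_image: LabelImage,
    mosaics: dict,
    reporters: dict | None = None,
    with_stats: bool = True,
) -> list[CellRecord]:
    """One record per label: centroid, shape descriptors and per-(cycle, channel)
    mean intensity over the label's pixels.

    ``mosaics`` maps (cycle, channel) to a 2D image of the label image's
    shape; ``reporters`` optionally maps the same keys to reporter names.
    """
    labels = label_image.labels
    for key, mosaic in mosaics.items():
        if mosaic.shape != labels.shape:
            raise ValueError(
                f"mosaic {key} shape {mosaic.shape} != labels shape {labels.shape}"
            )
    records: list[CellRecord] = []
    for region in measure.regionprops(labels):
        cy, cx = region.centroid
        perimeter = region.perimeter
        circularity = (
            min(4.0 * np.pi * region.area / perimeter**2, 1.0 + 1e-6)
            if perimeter > 0
            else 1.0
        )
        coords = region.coords
        means: dict = {}
        stats: dict = {}
        for (cycle, channel), mosaic in mosaics.items():
            values = np.asarray(mosaic, dtype=np.float64)[coords[:, 0], coords[:, 1]]
            name = reporters.get((cycle, channel), "") if reporters else ""
            means[(cycle, channel, name)] = float(values.mean())
            if with_stats:
                stats[(cycle, channel)] = (
                    float(values.min()),
                    float(values.max()),
                    float(values.std()),
                )
        records.append(
            CellRecord(
                label=int(region.label),
                centroid_x=float(cx),
                centroid_y=float(cy),
                area=float(region.area),
                perimeter=float(perimeter),
                circularity=float(circularity),
                orientation=float(np.degrees(region.orientation)),
                mean_intensity=means,
                intensity_stats=stats,
            )
        )
    return records
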