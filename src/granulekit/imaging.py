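"""Quantification of protein partitioning into granules and condensates.

The central statistic is the per-plane granule/cytoplasm intensity
ratio: granules are segmented from a marker channel (Laplacian-of-
Gaussian band-pass, then thresholding), and for every confocal plane
the mean query-channel intensity over granule pixels is divided by the
mean over cytoplasm pixels; the summary is the mean +/- SD over planes.
Also provided: a perinuclear ring SD metric (the SD of intensity along
a band hugging the nuclear envelope, high when signal is punctate),
ROI-based dense/dilute condensate partition ratios, per-nucleus granule
count/volume statistics and Pearson colocalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .images import ImageStack

__all__ = [
    "SegmentationParams",
    "GranuleSegmentation",
    "PartitionResult",
    "RingProfile",
    "CondensatePartition",
    "GranuleStats",
    "log_filter",
    "segment_granules",
    "make_cytoplasm_mask",
    "granule_cytoplasm_ratio",
    "perinuclear_ring_metric",
    "condensate_partition_ratio",
    "granule_count_volume",
    "pearson_colocalization",
    "default_aggregate_exclusion",
]


class EmptyResultError(ValueError):
    """No usable planes/ROIs remain after filtering."""


@dataclass
class SegmentationParams:
    """Granule segmentation knobs.

    ``threshold_method`` is "otsu" (one Otsu threshold computed on the
    whole-stack LoG response, applied per plane — robust on planes that
    contain no granules) or "otsu-plane" (Otsu recomputed per plane).
    Components smaller than ``min_area_px`` (per plane, 4-connected)
    are discarded.
    """

    log_sigma_um: float = 0.2
    threshold_method: str = "otsu"
    min_area_px: int = 4

    def validate(self) -> None:
        if self.log_sigma_um <= 0:
            raise ValueError("log_sigma_um must be > 0")
        if self.threshold_method not in ("otsu", "otsu-plane"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.min_area_px < 0:
            raise ValueError("min_area_px must be >= 0")


@dataclass
class GranuleSegmentation:
    """Per-plane granule mask and connected-component labels."""

    mask: np.ndarray  # bool, (plane, y, x)
    labels: np.ndarray  # int, per-plane 4-connected components
    params: SegmentationParams

    @property
    def n_components(self) -> int:
        return int(self.labels.max())


@dataclass
class PartitionResult:
    """Per-plane granule/cytoplasm ratios with mean +/- SD summary."""

    per_plane_ratio: np.ndarray
    n_planes_skipped: int = 0

    def __post_init__(self) -> None:
        self.per_plane_ratio = np.asarray(self.per_plane_ratio, dtype=float)

    @property
    def n_planes_used(self) -> int:
        return int(self.per_plane_ratio.size)

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.per_plane_ratio))

    @property
    def sd_ratio(self) -> float:
        if self.per_plane_ratio.size < 2:
            return 0.0
        return float(np.std(self.per_plane_ratio, ddof=1))


@dataclass
class RingProfile:
    """Perinuclear ring selection and the SD of intensity along it."""

    nucleus_label: int
    plane: int
    ring_mask: np.ndarray  # 2D bool
    intensities: np.ndarray
    clipped: bool = False

    @property
    def sd(self) -> float:
        return float(np.std(self.intensities, ddof=0))


@dataclass
class CondensatePartition:
    """Dense/dilute partition ratios from paired square ROIs."""

    per_roi_ratio: list[float]
    excluded_rois: list[tuple[int, str]] = field(default_factory=list)
    outside_mean: float = float("nan")

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.per_roi_ratio))

    @property
    def sd_ratio(self) -> float:
        if len(self.per_roi_ratio) < 2:
            return 0.0
        return float(np.std(self.per_roi_ratio, ddof=1))


@dataclass
class GranuleStats:
    """Per-nucleus granule count and total volume."""

    per_nucleus: list[dict]


def log_filter(stack: ImageStack, channel: str, sigma_um: float) -> np.ndarray:
    """Per-plane Laplacian-of-Gaussian response, positive on bright blobs.

    The response is ``-sigma_px^2 * LoG(I)`` with reflective boundaries
    (scale-normalized, so blobs of matching size respond comparably
    across sigma). Linear in the input; constant images map to 0.
    """
    if sigma_um <= 0:
        raise ValueError("sigma_um must be > 0")
    vol = stack.channel(channel).astype(float)
    sigma_px = sigma_um / stack.pixel_size_um
    out = np.empty_like(vol)
    for z in range(vol.shape[0]):
        # generous truncation keeps the kernel's DC response negligible
        out[z] = -(sigma_px**2) * ndimage.gaussian_laplace(
            vol[z], sigma=sigma_px, mode="reflect", truncate=8.0
        )
    return out


def segment_granules(
    stack: ImageStack, marker_channel: str, params: SegmentationParams | None = None
) -> GranuleSegmentation:
    """Segment granules from a marker channel: LoG, threshold, label.

    Per plane, the mask is ``response > threshold`` with small
    components removed; labels are 4-connected within each plane and
    unique across planes. A blank channel gives an empty segmentation.
    """
    params = params or SegmentationParams()
    params.validate()
    resp = log_filter(stack, marker_channel, params.log_sigma_um)
    nz = resp.shape[0]
    mask = np.zeros_like(resp, dtype=bool)

    def _otsu(values: np.ndarray) -> float | None:
        if np.ptp(values) == 0:
            return None
        return float(threshold_otsu(values))

    if params.threshold_method == "otsu":
        thr = _otsu(resp)
        if thr is not None:
            mask = resp > thr
    else:  # otsu-plane
        for z in range(nz):
            thr = _otsu(resp[z])
            if thr is not None:
                mask[z] = resp[z] > thr

    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labels = np.zeros_like(resp, dtype=np.int32)
    next_label = 0
    for z in range(nz):
        lab, n = ndimage.label(mask[z], structure=structure)
        if n == 0:
            continue
        if params.min_area_px > 0:
            areas = np.bincount(lab.ravel())
            small = np.flatnonzero(areas < params.min_area_px)
            kill = np.isin(lab, small[small > 0])
            lab[kill] = 0
            mask[z] &= lab > 0
            lab, n = ndimage.label(mask[z], structure=structure)
        lab_out = np.where(lab > 0, lab + next_label, 0)
        labels[z] = lab_out
        next_label += n
    return GranuleSegmentation(mask=mask, labels=labels, params=params)


def make_cytoplasm_mask(
    region_mask: np.ndarray,
    nucleus_masks: np.ndarray,
    granule_mask: np.ndarray,
    guard_px: int = 1,
) -> np.ndarray:
    """Cytoplasm = analysis region minus nuclei minus dilated granules.

    The granule mask is dilated ``guard_px`` pixels in-plane before
    subtraction so partial-volume pixels at granule edges do not leak
    into the cytoplasm estimate.
    """
    guard = granule_mask.astype(bool)
    if guard_px > 0:
        selem = disk(guard_px)
        guard = np.stack(
            [ndimage.binary_dilation(guard[z], structure=selem) for z in range(guard.shape[0])]
        )
    return region_mask.astype(bool) & (np.asarray(nucleus_masks) == 0) & ~guard


def granule_cytoplasm_ratio(
    stack: ImageStack,
    query_channel: str,
    granule_mask: np.ndarray,
    cytoplasm_mask: np.ndarray,
) -> PartitionResult:
    """Per-plane mean(query | granule) / mean(query | cytoplasm).

    Planes lacking granule or cytoplasm pixels (or with zero cytoplasm
    mean) are skipped and counted; raises if no plane is usable.
    """
    granule_mask = np.asarray(granule_mask, dtype=bool)
    cytoplasm_mask = np.asarray(cytoplasm_mask, dtype=bool)
    if (granule_mask & cytoplasm_mask).any():
        raise ValueError("granule and cytoplasm masks must be disjoint")
    query = stack.channel(query_channel).astype(float)
    if granule_mask.shape != query.shape or cytoplasm_mask.shape != query.shape:
        raise ValueError("masks must match the stack geometry")

    ratios = []
    skipped = 0
    for z in range(query.shape[0]):
        g = granule_mask[z]
        c = cytoplasm_mask[z]
        if not g.any() or not c.any():
            skipped += 1
            continue
        cyt_mean = query[z][c].mean()
        if cyt_mean == 0:
            warnings.warn(f"plane {z}: zero cytoplasm mean, skipped", stacklevel=2)
            skipped += 1
            continue
        ratios.append(query[z][g].mean() / cyt_mean)
    if not ratios:
        raise EmptyResultError("no plane contained both granule and cytoplasm pixels")
    return PartitionResult(per_plane_ratio=np.array(ratios), n_planes_skipped=skipped)


def perinuclear_ring_metric(
    stack: ImageStack,
    query_channel: str,
    nucleus_masks: np.ndarray,
    band_um: float = 0.5,
) -> list[RingProfile]:
    """SD of query intensity along a perinuclear ring, per nucleus.

    For each labeled nucleus the plane of largest cross-section is
    selected; the ring is the in-plane dilation of the nucleus by
    ``band_um`` minus the nucleus itself. A ring clipped by the image
    border is flagged but still measured on the available pixels.
    """
    if band_um <= 0:
        raise ValueError("band_um must be > 0")
    nucleus_masks = np.asarray(nucleus_masks)
    query = stack.channel(query_channel).astype(float)
    band_px = max(1, int(round(band_um / stack.pixel_size_um)))
    selem = disk(band_px)

    profiles = []
    for label in np.unique(nucleus_masks):
        if label == 0:
            continue
        areas = (nucleus_masks == label).sum(axis=(1, 2))
        z = int(np.argmax(areas))
        nuc2d = nucleus_masks[z] == label
        dil = ndimage.binary_dilation(nuc2d, structure=selem)
        ring = dil & ~nuc2d
        # clipped if the dilation saturates the border
        border = np.zeros_like(dil)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        clipped = bool((dil & border).any())
        profiles.append(
            RingProfile(
                nucleus_label=int(label),
                plane=z,
                ring_mask=ring,
                intensities=query[z][ring],
                clipped=clipped,
            )
        )
    return profiles


def default_aggregate_exclusion(roi_pixels: np.ndarray, all_inside_pixels: np.ndarray,
                                k: float = 5.0) -> bool:
    """Exclude an inside ROI whose maximum query intensity exceeds
    ``k`` times the median over all inside-ROI pixels (a bright
    aggregate rather than homogeneous dense phase)."""
    return bool(roi_pixels.max() > k * np.median(all_inside_pixels))


def _roi_slice(stack: ImageStack, roi: tuple[float, float, float]) -> tuple[slice, slice]:
    top_um, left_um, side_um = roi
    px = stack.pixel_size_um
    r0, c0 = int(round(top_um / px)), int(round(left_um / px))
    side = int(round(side_um / px))
    ny, nx = stack.data.shape[2:]
    if r0 < 0 or c0 < 0 or r0 + side > ny or c0 + side > nx:
        raise ValueError(f"ROI {roi} exceeds image bounds")
    return slice(r0, r0 + side), slice(c0, c0 + side)


def condensate_partition_ratio(
    stack: ImageStack,
    query_channel: str,
    inside_rois: list[tuple[float, float, float]],
    outside_rois: list[tuple[float, float, float]],
    aggregate_exclusion=default_aggregate_exclusion,
    plane: int = 0,
) -> CondensatePartition:
    """Dense/dilute partition ratio from square ROIs.

    Each retained inside-ROI mean is divided by the average query
    intensity over all outside ROIs (the dilute phase). ROIs are
    ``(top_um, left_um, side_um)`` squares of equal size. The exclusion
    predicate (default: bright-aggregate rule) is applied to inside
    ROIs before ratios are computed; exclusions are recorded.
    """
    if not inside_rois or not outside_rois:
        raise ValueError("need at least one inside and one outside ROI")
    sides = {round(r[2], 9) for r in inside_rois + outside_rois}
    if len(sides) != 1:
        raise ValueError("all ROIs must have equal size")
    query = stack.channel(query_channel)[plane].astype(float)

    inside_pix = [query[_roi_slice(stack, r)] for r in inside_rois]
    outside_pix = [query[_roi_slice(stack, r)] for r in outside_rois]
    outside_mean = float(np.mean([p.mean() for p in outside_pix]))
    if outside_mean == 0:
        raise ValueError("mean outside (dilute-phase) intensity is zero")

    pooled_inside = np.concatenate([p.ravel() for p in inside_pix])
    ratios, excluded = [], []
    for i, pix in enumerate(inside_pix):
        if aggregate_exclusion is not None and aggregate_exclusion(pix, pooled_inside):
            excluded.append((i, "aggregate"))
            continue
        ratios.append(float(pix.mean() / outside_mean))
    if not ratios:
        raise EmptyResultError("all inside ROIs were excluded")
    return CondensatePartition(
        per_roi_ratio=ratios, excluded_rois=excluded, outside_mean=outside_mean
    )


def granule_count_volume(
    granule_mask: np.ndarray,
    voxel_size_um3: float,
    nucleus_masks: np.ndarray,
) -> GranuleStats:
    """Per-nucleus granule count and total volume (3D, 6-connected).

    Each 6-connected component of the granule mask is assigned to the
    nucleus whose centroid is nearest to the component centroid
    (physical distances are not needed for an argmin over isotropically
    indexed centroids when voxels are shared across both label images).
    """
    if voxel_size_um3 <= 0:
        raise ValueError("voxel size must be positive")
    granule_mask = np.asarray(granule_mask, dtype=bool)
    nucleus_masks = np.asarray(nucleus_masks)
    nucleus_ids = [int(l) for l in np.unique(nucleus_masks) if l != 0]
    stats = {nid: {"nucleus": nid, "granule_count": 0, "total_volume_um3": 0.0}
             for nid in nucleus_ids}
    lab, n = ndimage.label(granule_mask)  # default structure = 6-connectivity in 3D
    if n and nucleus_ids:
        nuc_centroids = np.array(ndimage.center_of_mass(
            nucleus_masks > 0, nucleus_masks, nucleus_ids))
        comp_centroids = np.array(ndimage.center_of_mass(
            granule_mask, lab, range(1, n + 1)))
        sizes = ndimage.sum_labels(granule_mask, lab, range(1, n + 1))
        for ci in range(n):
            d = np.linalg.norm(nuc_centroids - comp_centroids[ci], axis=1)
            nid = nucleus_ids[int(np.argmin(d))]
            stats[nid]["granule_count"] += 1
            stats[nid]["total_volume_um3"] += float(sizes[ci]) * voxel_size_um3
    return GranuleStats(per_nucleus=[stats[nid] for nid in nucleus_ids])


def pearson_colocalization(
    stack: ImageStack, channel_a: str, channel_b: str, mask: np.ndarray
) -> float:
    """Pearson correlation of two channels over a voxel mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    a = stack.channel(channel_a)[mask].astype(float)
    b = stack.channel(channel_b)[mask].astype(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: zero variance in a channel")
    return float(np.corrcoef(a, b)[0, 1])
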