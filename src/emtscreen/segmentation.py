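"""Image quantification: nuclei, focal-adhesion puncta, fibrous networks
and the signal-to-background line-scan metric.

The screen scores each imaging site from four channels: DAPI (nuclei),
FITC (paxillin, focal adhesions), TxRed (phalloidin, stress fibers) and
Cy5 (fibronectin).  All channels are thresholded at a fixed offset above
a local-background estimate (grayscale morphological opening), which
makes every count invariant under uniform additive intensity shifts.
Objects are then filtered by equivalent circular diameter: 9-16 um for
nuclei, 1-10 um for focal-adhesion puncta.  Fibrous channels are reduced
to a morphological skeleton whose pixels are classified by 8-neighbor
count into segments (S), branch points (B) and endpoint nodes (N); the
per-cell fiber score is (S + B + N) / nuclei.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation as sk_seg
from skimage.feature import peak_local_max

__all__ = [
    "MicrographSet",
    "SegmentationParams",
    "NucleiResult",
    "PunctaResult",
    "FiberNetworkResult",
    "estimate_local_background",
    "segment_nuclei",
    "detect_puncta",
    "quantify_fiber_network",
    "skeleton_graph_counts",
    "line_scan_sb_ratio",
    "calibrate_thresholds",
    "quantify_well",
]


class InputError(ValueError):
    pass


@dataclass
class MicrographSet:
    """One imaging site's co-registered channel images.

    channels maps channel name -> 2-D intensity array (16-bit range);
    ``pixel_size`` is in um/px.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    site_id: str = "s1"
    well_id: str = ""

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise InputError("pixel_size must be positive")
        shapes = {img.shape for img in self.channels.values()}
        if len(shapes) > 1:
            raise InputError(f"channel shapes differ: {shapes}")

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise InputError(f"channel {name!r} missing "
                             f"(have {sorted(self.channels)})")
        return np.asarray(self.channels[name], dtype=float)


@dataclass
class SegmentationParams:
    """Size windows (um, closed intervals on equivalent diameter) and
    local-background thresholding parameters."""

    nuclei_diameter_range: tuple[float, float] = (9.0, 16.0)
    puncta_diameter_range: tuple[float, float] = (1.0, 10.0)
    fiber_size_range: tuple[float, float] = (1.0, 5.0)
    local_background_radius: float | None = None   # um; default 3x max object diameter
    threshold_offset: dict[str, float] = field(
        default_factory=lambda: {"DAPI": 500.0, "FITC": 500.0,
                                 "TxRed": 500.0, "Cy5": 500.0})

    def __post_init__(self):
        for rng in (self.nuclei_diameter_range, self.puncta_diameter_range,
                    self.fiber_size_range):
            lo, hi = rng
            if not (0 < lo <= hi):
                raise InputError(f"size range must be positive and ordered: {rng}")
        if any(v < 0 for v in self.threshold_offset.values()):
            raise InputError("threshold offsets must be non-negative")

    def background_radius_for(self, max_object_diameter: float) -> float:
        if self.local_background_radius is not None:
            return self.local_background_radius
        return 3.0 * max_object_diameter


@dataclass
class NucleiResult:
    count: int
    centroids: np.ndarray          # (n, 2) pixel coordinates
    equivalent_diameters: np.ndarray   # um


@dataclass
class PunctaResult:
    count: int
    centroids: np.ndarray
    equivalent_diameters: np.ndarray
    per_cell: float                # nan when nuclei count is 0


@dataclass
class FiberNetworkResult:
    segments: int
    branch_points: int
    nodes: int

    @property
    def total_score(self) -> int:
        return self.segments + self.branch_points + self.nodes

    def per_cell(self, nuclei_count: int) -> float:
        return math.nan if nuclei_count == 0 else self.total_score / nuclei_count


# -- local background ------------------------------------------------------


def estimate_local_background(image: np.ndarray, radius_um: float,
                              pixel_size: float) -> np.ndarray:
    """Local background by grayscale morphological opening.

    The opening (erosion then dilation with a square window of half-width
    ``radius_um``) removes every bright structure narrower than the
    window, so with a radius comfortably above the largest target object
    it returns the smooth background under the objects; subtracting it
    from a flat image leaves ~0 everywhere.  The square window makes the
    filter separable, which keeps large radii cheap; it is monotone and
    commutes with additive offsets exactly like the disk variant.
    """
    radius_px = radius_um / pixel_size
    if radius_px < 1:
        raise InputError("background radius is smaller than one pixel")
    size = 2 * int(round(radius_px)) + 1
    img = np.asarray(image, dtype=float)
    eroded = ndimage.minimum_filter(img, size=size, mode="nearest")
    return ndimage.maximum_filter(eroded, size=size, mode="nearest")


def _foreground_mask(image, pixel_size, radius_um, offset):
    background = estimate_local_background(image, radius_um, pixel_size)
    return (image - background) > offset


# -- nuclei ----------------------------------------------------------------


def segment_nuclei(micrographs: MicrographSet,
                   params: SegmentationParams = SegmentationParams(),
                   channel: str = "DAPI") -> NucleiResult:
    """Detect nuclei: local-background threshold, distance-transform
    watershed to split touching pairs, size filter on equivalent diameter
    (closed interval, 9-16 um by default)."""
    img = micrographs.channel(channel)
    px = micrographs.pixel_size
    lo, hi = params.nuclei_diameter_range
    mask = _foreground_mask(img, px, params.background_radius_for(hi),
                            params.threshold_offset.get(channel, 0.0))
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        return NucleiResult(0, np.empty((0, 2)), np.empty(0))

    distance = ndimage.distance_transform_edt(mask)
    min_sep = max(1, int(0.7 * lo / px))
    peaks = peak_local_max(distance, min_distance=min_sep, labels=mask,
                           exclude_border=False)
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = sk_seg.watershed(-distance, markers, mask=mask)

    centroids, diams = [], []
    for region in measure.regionprops(labels):
        d_um = region.equivalent_diameter_area * px
        if lo <= d_um <= hi:
            centroids.append(region.centroid)
            diams.append(d_um)
    return NucleiResult(len(centroids),
                        np.asarray(centroids).reshape(-1, 2),
                        np.asarray(diams))


# -- puncta ----------------------------------------------------------------


def detect_puncta(micrographs: MicrographSet, nuclei: NucleiResult | int,
                  params: SegmentationParams = SegmentationParams(),
                  channel: str = "FITC") -> PunctaResult:
    """Detect focal-adhesion puncta ('vesicles', 1-10 um) and normalise
    the count by the nuclei count.  With zero nuclei the per-cell value
    is flagged undefined (NaN) while the raw count is still reported."""
    img = micrographs.channel(channel)
    px = micrographs.pixel_size
    lo, hi = params.puncta_diameter_range
    mask = _foreground_mask(img, px, params.background_radius_for(hi),
                            params.threshold_offset.get(channel, 0.0))
    labels = measure.label(mask, connectivity=2)
    centroids, diams = [], []
    for region in measure.regionprops(labels):
        d_um = region.equivalent_diameter_area * px
        if lo <= d_um <= hi:
            centroids.append(region.centroid)
            diams.append(d_um)
    n_nuclei = nuclei.count if isinstance(nuclei, NucleiResult) else int(nuclei)
    count = len(centroids)
    per_cell = count / n_nuclei if n_nuclei > 0 else math.nan
    return PunctaResult(count, np.asarray(centroids).reshape(-1, 2),
                        np.asarray(diams), per_cell)


# -- fibrous networks ------------------------------------------------------


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def skeleton_graph_counts(skeleton: np.ndarray,
                          pixel_size: float = 1.0,
                          fiber_size_range: tuple[float, float] | None = None,
                          ) -> FiberNetworkResult:
    """Classify a binary skeleton into segments, branch points and nodes.

    Skeleton pixels with >= 3 eight-neighbors are junction pixels; their
    8-connected clusters are the branch points (B).  Pixels with exactly
    one neighbor are endpoints; their clusters are the nodes (N).
    Removing junction clusters leaves maximal paths, each counted as one
    segment (S) if its path length -- (n_pixels - 1) * pixel_size, with
    isolated pixels counting one pixel -- falls inside the (closed)
    fiber size window.
    """
    skel = np.asarray(skeleton, dtype=bool)
    if not skel.any():
        return FiberNetworkResult(0, 0, 0)
    neighbors = ndimage.convolve(skel.astype(int), _NEIGHBOR_KERNEL,
                                 mode="constant", cval=0)
    junctions = skel & (neighbors >= 3)
    endpoints = skel & (neighbors == 1)

    _, n_branch = ndimage.label(junctions, structure=np.ones((3, 3)))
    _, n_nodes = ndimage.label(endpoints, structure=np.ones((3, 3)))

    paths = skel & ~junctions
    labels, n_paths = ndimage.label(paths, structure=np.ones((3, 3)))
    n_segments = 0
    for i in range(1, n_paths + 1):
        npix = int(np.sum(labels == i))
        length_um = max(npix - 1, 1) * pixel_size
        if fiber_size_range is None:
            n_segments += 1
        else:
            lo, hi = fiber_size_range
            if lo <= length_um <= hi:
                n_segments += 1
    return FiberNetworkResult(n_segments, n_branch, n_nodes)


def quantify_fiber_network(micrographs: MicrographSet, channel: str,
                           nuclei: NucleiResult | int,
                           params: SegmentationParams = SegmentationParams(),
                           ) -> tuple[FiberNetworkResult, float]:
    """Score a fibrous channel (TxRed stress fibers, Cy5 fibronectin, or
    a vimentin FITC staining): threshold above local background,
    skeletonize, decompose the skeleton graph, and normalise
    (S + B + N) by the nuclei count.  An empty skeleton yields an
    all-zero result, not an error."""
    img = micrographs.channel(channel)
    px = micrographs.pixel_size
    lo, hi = params.fiber_size_range
    mask = _foreground_mask(img, px, params.background_radius_for(hi),
                            params.threshold_offset.get(channel, 0.0))
    skel = morphology.skeletonize(mask)
    result = skeleton_graph_counts(skel, px, params.fiber_size_range)
    n_nuclei = nuclei.count if isinstance(nuclei, NucleiResult) else int(nuclei)
    return result, result.per_cell(n_nuclei)


# -- line scans ------------------------------------------------------------


def line_scan_sb_ratio(images, n_scans: int = 1, *,
                       pseudo_floor: float = 1.0) -> float:
    """Signal-to-background from horizontal line scans.

    Scans the midline of each image plus (n_scans - 1) evenly spaced
    parallels, takes max/min gray level per scan, and returns the mean
    ratio over all scans and images.  A zero minimum is lifted to the
    configurable pseudo-floor (1 count) with a warning.
    """
    if n_scans < 1:
        raise InputError("n_scans must be >= 1")
    ratios = []
    for image in images:
        img = np.asarray(image, dtype=float)
        h = img.shape[0]
        if n_scans == 1:
            rows = [h // 2]
        else:
            rows = np.unique(np.linspace(0, h - 1, n_scans + 2,
                                         dtype=int)[1:-1])
        for r in rows:
            scan = img[r, :]
            lo = scan.min()
            if lo <= 0:
                warnings.warn("line scan minimum <= 0; applying pseudo-floor",
                              stacklevel=2)
                lo = pseudo_floor
            ratios.append(scan.max() / lo)
    return float(np.mean(ratios))


# -- well-level aggregation ------------------------------------------------


def quantify_well(sites: list[MicrographSet],
                  params: SegmentationParams = SegmentationParams()) -> dict:
    """Quantify one well: per-site results averaged over sites (mean, for
    linearity with counts) before per-cell normalization of well values."""
    nuclei_counts, fa_counts, sf_scores, fn_scores = [], [], [], []
    for mset in sites:
        nuclei = segment_nuclei(mset, params)
        nuclei_counts.append(nuclei.count)
        fa_counts.append(detect_puncta(mset, nuclei, params).count)
        sf_scores.append(quantify_fiber_network(mset, "TxRed", nuclei,
                                                params)[0].total_score)
        fn_scores.append(quantify_fiber_network(mset, "Cy5", nuclei,
                                                params)[0].total_score)
    mean_nuclei = float(np.mean(nuclei_counts))
    def _per_cell(values):
        return float(np.mean(values)) / mean_nuclei if mean_nuclei > 0 else math.nan
    return {
        "nuclei": mean_nuclei,
        "fa_per_cell": _per_cell(fa_counts),
        "sf_per_cell": _per_cell(sf_scores),
        "fn_per_cell": _per_cell(fn_scores),
        "n_sites_used": len(sites),
    }


# -- threshold calibration -------------------------------------------------


class CalibrationError(RuntimeError):
    pass


_CHANNEL_READOUT = {
    "DAPI": "nuclei",
    "FITC": "fa",
    "TxRed": "sf",
    "Cy5": "fn",
}


def _well_value(sites, params, channel):
    values = []
    for mset in sites:
        if channel == "DAPI":
            values.append(segment_nuclei(mset, params).count)
        elif channel == "FITC":
            nuclei = segment_nuclei(mset, params)
            values.append(detect_puncta(mset, nuclei, params).count)
        else:
            values.append(quantify_fiber_network(
                mset, channel, 1, params)[0].total_score)
    return float(np.mean(values))


def calibrate_thresholds(
    positive_wells: list[list[MicrographSet]],
    negative_wells: list[list[MicrographSet]],
    params: SegmentationParams = SegmentationParams(),
    *,
    offset_grid: tuple[float, ...] = (100., 200., 400., 800., 1600.),
    channels: tuple[str, ...] = ("DAPI", "FITC", "TxRed", "Cy5"),
) -> tuple[SegmentationParams, dict[str, float]]:
    """Per-channel grid search of the threshold offset maximizing the Z'
    of that channel's readout over the provided positive / negative
    control wells, compensating for inter-experimental staining
    variations.  Returns the updated params and the achieved Z' per
    channel.  Identical control classes raise CalibrationError."""
    from .plate import zprime

    if len(positive_wells) < 2 or len(negative_wells) < 2:
        raise CalibrationError("need >= 2 wells per control class")
    best_offsets = dict(params.threshold_offset)
    achieved: dict[str, float] = {}
    for channel in channels:
        best = None
        for offset in offset_grid:
            trial = replace(params,
                            threshold_offset={**params.threshold_offset,
                                              channel: offset})
            pos = [_well_value(w, trial, channel) for w in positive_wells]
            neg = [_well_value(w, trial, channel) for w in negative_wells]
            try:
                z = zprime(pos, neg)
            except ValueError:
                continue
            if best is None or z > best[0]:
                best = (z, offset)
        if best is None:
            raise CalibrationError(
                f"calibration failed for {channel}: controls are degenerate")
        achieved[channel] = best[0]
        best_offsets[channel] = best[1]
    return replace(params, threshold_offset=best_offsets), achieved
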