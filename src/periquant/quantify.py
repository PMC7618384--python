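"""Vessel-proximity classification of labelled cells in multi-channel volumes.

The analysis mirrors the manual FIJI workflow used on cleared, FITC-perfused
nerves: threshold the FITC channel to get a vessel mask, artificially broaden
it in-plane so that cells hugging the wall fall onto it, segment nuclei in the
DAPI channel plane by plane, drop ROIs below a 10 um^2 area floor, and then
count

* ``n_nuclei``   — all surviving nuclear ROIs,
* ``n_tdtomato`` — ROIs overlapping the tdTomato (reporter) mask,
* ``n_mural``    — ROIs overlapping tdTomato AND the broadened vessel mask,

on five z-planes 8 um apart, averaging across planes and — when a region was
imaged twice — across images.

Nucleus segmentation here is a classical stand-in for the star-convex CNN used
originally: Gaussian smoothing, IsoData threshold, distance-transform
watershed. The counting contract is segmentation-agnostic, so the segmenter
can be swapped for any ROI source with the same interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

from .simulate import AcquisitionSpec, GroundTruth, MultiChannelVolume

__all__ = [
    "ChannelThreshold",
    "VesselMask",
    "NucleusROI",
    "PlaneCounts",
    "PlanesSpec",
    "RegionQuant",
    "ClassScores",
    "isodata_threshold",
    "compute_threshold",
    "make_vessel_mask",
    "broaden_mask",
    "segment_nuclei",
    "classify_and_count",
    "quantify_region",
    "aggregate_region_images",
    "evaluate_against_truth",
]


class DegenerateHistogramError(ValueError):
    """Automatic thresholding is undefined on a constant image."""


# ---------------------------------------------------------------------------
# thresholds


def isodata_threshold(values: np.ndarray, tol: float = 1e-6, max_iter: int = 500) -> float:
    """IsoData (iterative intermeans) threshold of an intensity sample.

    Starts at the global mean and iterates t <- (mean below t + mean above t)/2
    until the fixed point; the common default of histogram-based imaging
    software.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0 or np.ptp(x) == 0:
        raise DegenerateHistogramError("constant or empty image has no IsoData threshold")
    t = float(x.mean())
    for _ in range(max_iter):
        below = x[x <= t]
        above = x[x > t]
        if below.size == 0 or above.size == 0:
            break
        t_new = 0.5 * (below.mean() + above.mean())
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new
    return float(t)


@dataclass(frozen=True)
class ChannelThreshold:
    channel: str
    method: str  # "auto" | "manual" | "cross-channel"
    value: float
    source_channel: str | None = None


def compute_threshold(
    volume: MultiChannelVolume,
    channel: str,
    method: str = "auto",
    manual_value: float | None = None,
    source_threshold: ChannelThreshold | None = None,
) -> ChannelThreshold:
    """Set a channel threshold the way the original analysis did.

    ``auto`` runs IsoData on the channel; ``manual`` takes an explicit value;
    ``cross-channel`` copies a previously computed threshold from another
    channel verbatim — the convention used when software-recommended reporter
    thresholds drifted between experimental conditions and the vessel-channel
    thresholds were applied to the reporter channel instead.
    """
    if channel not in volume.channels:
        raise KeyError(f"no channel named {channel!r}")
    if method == "auto":
        value = isodata_threshold(volume.channels[channel])
        return ChannelThreshold(channel=channel, method="auto", value=value)
    if method == "manual":
        if manual_value is None:
            raise ValueError("manual thresholding requires manual_value")
        return ChannelThreshold(channel=channel, method="manual", value=float(manual_value))
    if method == "cross-channel":
        if source_threshold is None:
            raise ValueError(
                "cross-channel thresholding requires a previously computed "
                "threshold on the source channel"
            )
        return ChannelThreshold(
            channel=channel,
            method="cross-channel",
            value=source_threshold.value,
            source_channel=source_threshold.channel,
        )
    raise ValueError(f"unknown thresholding method {method!r}")


# ---------------------------------------------------------------------------
# vessel mask


@dataclass(frozen=True)
class VesselMask:
    mask: np.ndarray  # bool, (Z, Y, X)
    pixel_area_um2: float
    broadened: bool = False
    broaden_radius_um: float = 0.0

    @property
    def plane_areas_um2(self) -> np.ndarray:
        """Vessel area per z-plane, um^2 (voxel count x in-plane voxel area)."""
        return self.mask.sum(axis=(1, 2)) * self.pixel_area_um2


def make_vessel_mask(
    volume: MultiChannelVolume, fitc_threshold: ChannelThreshold
) -> VesselMask:
    """Vessel mask = FITC strictly above threshold; empty masks are valid."""
    if fitc_threshold.channel != "FITC":
        raise ValueError("vessel masking expects a threshold computed on FITC")
    mask = volume.channels["FITC"] > fitc_threshold.value
    return VesselMask(mask=mask, pixel_area_um2=volume.acquisition.pixel_area_um2)


def broaden_mask(
    vessel_mask: VesselMask, radius_um: float, in_plane_voxel_um: float
) -> VesselMask:
    """Artificially broaden the vessel mask in-plane by a disk.

    The disk radius is ``ceil(radius_um / in_plane_voxel_um)`` pixels; dilation
    acts within each z-plane only, matching the plane-wise analysis.
    """
    if radius_um < 0:
        raise ValueError("broaden radius must be non-negative")
    radius_px = math.ceil(radius_um / in_plane_voxel_um)
    if radius_px == 0:
        out = vessel_mask.mask.copy()
    else:
        structure = disk(radius_px)[None, :, :]
        out = ndi.binary_dilation(vessel_mask.mask, structure=structure)
    return VesselMask(
        mask=out,
        pixel_area_um2=vessel_mask.pixel_area_um2,
        broadened=True,
        broaden_radius_um=radius_um,
    )


# ---------------------------------------------------------------------------
# nucleus segmentation (classical stand-in, swappable)


@dataclass(frozen=True)
class NucleusROI:
    id: int
    plane: int
    coords: np.ndarray  # (N, 2) int pixel coordinates (y, x)
    area_um2: float
    centroid_um: tuple[float, float]  # (y, x)


def segment_nuclei(
    volume: MultiChannelVolume,
    plane: int,
    channel: str = "DAPI",
    threshold: float | None = None,
    smooth_sigma_um: float = 0.5,
    min_distance_um: float = 2.5,
) -> list[NucleusROI]:
    """Segment nuclei in one z-plane of the DAPI channel.

    Pipeline: Gaussian smoothing -> IsoData threshold (or a supplied one) ->
    Euclidean distance transform -> watershed from its local maxima. Touching
    nuclei are split at the watershed line; a blank plane yields no ROIs.
    """
    acq = volume.acquisition
    nz = acq.shape_zyx[0]
    if not 0 <= plane < nz:
        raise IndexError(f"plane {plane} outside stack of {nz} planes")
    img = np.asarray(volume.channels[channel][plane], dtype=float)
    if np.ptp(img) == 0:
        return []
    vy, vx = acq.voxel_size_zyx[1], acq.voxel_size_zyx[2]
    sm = ndi.gaussian_filter(img, (smooth_sigma_um / vy, smooth_sigma_um / vx))
    if threshold is None:
        try:
            threshold = isodata_threshold(sm)
        except DegenerateHistogramError:
            return []
    mask = sm > threshold
    if not mask.any():
        return []

    distance = ndi.distance_transform_edt(mask, sampling=(vy, vx))
    components, n_comp = ndi.label(mask)
    min_dist_px = max(1, int(round(min_distance_um / min(vy, vx))))
    peaks = peak_local_max(
        distance,
        min_distance=min_dist_px,
        labels=components,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=int)
    for i, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = i
    # guarantee every connected component seeds at least one basin
    next_marker = len(peaks) + 1
    seeded = set(np.unique(components[markers > 0]))
    for comp_id in range(1, n_comp + 1):
        if comp_id in seeded:
            continue
        comp = components == comp_id
        flat = np.argmax(np.where(comp, distance, -1.0))
        markers[np.unravel_index(flat, mask.shape)] = next_marker
        next_marker += 1
    labels = watershed(-distance, markers, mask=mask)

    rois: list[NucleusROI] = []
    for rp in regionprops(labels):
        cy, cx = rp.centroid
        rois.append(
            NucleusROI(
                id=rp.label,
                plane=plane,
                coords=rp.coords,
                area_um2=float(rp.area) * acq.pixel_area_um2,
                centroid_um=((cy + 0.5) * vy, (cx + 0.5) * vx),
            )
        )
    return rois


# ---------------------------------------------------------------------------
# classification and counting


@dataclass(frozen=True)
class ClassifiedROI:
    roi: NucleusROI
    is_tdtomato: bool
    is_mural: bool


@dataclass(frozen=True)
class PlaneCounts:
    plane: int
    n_nuclei: int
    n_mural: int
    n_tdtomato: int
    vessel_area_um2: float = 0.0
    rois: tuple[ClassifiedROI, ...] = ()


def _overlaps(
    roi: NucleusROI, mask_plane: np.ndarray, overlap_frac: float
) -> bool:
    inter = int(mask_plane[roi.coords[:, 0], roi.coords[:, 1]].sum())
    if inter < 1:
        return False
    return inter / len(roi.coords) >= overlap_frac


def classify_and_count(
    rois: Sequence[NucleusROI],
    tdtomato_mask_plane: np.ndarray,
    broadened_vessel_mask_plane: np.ndarray,
    min_area_um2: float = 10.0,
    overlap_frac: float = 0.0,
    plane: int | None = None,
    vessel_area_um2: float = 0.0,
) -> PlaneCounts:
    """Apply the area floor, then count nuclei / tdTomato+ / mural per plane.

    ROIs below ``min_area_um2`` are discarded before any counting. A surviving
    ROI is tdTomato+ if it overlaps the tdTomato mask, and mural if it
    overlaps the tdTomato AND broadened-vessel co-expression mask; overlap
    means >= 1 shared pixel and an intersection fraction >= ``overlap_frac``.
    """
    if tdtomato_mask_plane.shape != broadened_vessel_mask_plane.shape:
        raise ValueError("tdTomato and vessel mask planes have different shapes")
    co_mask = tdtomato_mask_plane & broadened_vessel_mask_plane
    kept = [r for r in rois if r.area_um2 >= min_area_um2]
    classified = []
    for r in kept:
        if np.any(r.coords[:, 0] >= tdtomato_mask_plane.shape[0]) or np.any(
            r.coords[:, 1] >= tdtomato_mask_plane.shape[1]
        ):
            raise ValueError("ROI pixels fall outside the mask plane")
        is_td = _overlaps(r, tdtomato_mask_plane, overlap_frac)
        is_mural = _overlaps(r, co_mask, overlap_frac)
        classified.append(ClassifiedROI(roi=r, is_tdtomato=is_td, is_mural=is_mural))
    return PlaneCounts(
        plane=plane if plane is not None else (kept[0].plane if kept else -1),
        n_nuclei=len(kept),
        n_mural=sum(c.is_mural for c in classified),
        n_tdtomato=sum(c.is_tdtomato for c in classified),
        vessel_area_um2=vessel_area_um2,
        rois=tuple(classified),
    )


# ---------------------------------------------------------------------------
# per-region aggregation


@dataclass(frozen=True)
class PlanesSpec:
    """Which z-planes to analyse: k planes spaced s um apart, centred by default."""

    n_planes: int = 5
    spacing_um: float = 8.0
    start_index: int | None = None

    def select(self, acq: AcquisitionSpec) -> list[int]:
        step_f = self.spacing_um / acq.z_step
        step = int(round(step_f))
        if abs(step_f - step) > 1e-9 or step < 1:
            raise ValueError(
                f"plane spacing {self.spacing_um} um is not a multiple of the "
                f"stack z_step {acq.z_step} um"
            )
        nz = acq.shape_zyx[0]
        span = (self.n_planes - 1) * step
        start = self.start_index
        if start is None:
            start = (nz - 1 - span) // 2
        planes = [start + i * step for i in range(self.n_planes)]
        if planes[0] < 0 or planes[-1] >= nz:
            raise ValueError(
                f"requested planes {planes} do not fit in a stack of {nz} planes"
            )
        return planes


@dataclass(frozen=True)
class RegionQuant:
    region: str
    condition: str
    planes: tuple[int, ...]
    per_plane: tuple[PlaneCounts, ...]
    params: dict = field(default_factory=dict)

    def mean(self, which: str) -> float:
        """Arithmetic mean of a per-plane count across the analysed planes."""
        return float(np.mean([getattr(p, which) for p in self.per_plane]))

    @property
    def means(self) -> dict[str, float]:
        return {
            k: self.mean(k)
            for k in ("n_nuclei", "n_mural", "n_tdtomato", "vessel_area_um2")
        }

    @property
    def n_fibroblast_derived(self) -> float:
        """Derived fibroblast estimate: tdTomato+ minus mural (not a direct count)."""
        return self.mean("n_tdtomato") - self.mean("n_mural")


def quantify_region(
    volume: MultiChannelVolume,
    fitc_threshold: ChannelThreshold | None = None,
    tdtomato_threshold: ChannelThreshold | None = None,
    dapi_threshold: float | None = None,
    broaden_radius_um: float = 5.0,
    planes_spec: PlanesSpec | None = None,
    min_area_um2: float = 10.0,
    overlap_frac: float = 0.0,
    region: str = "away",
    condition: str = "sham-ipsi",
) -> RegionQuant:
    """Run the full per-region quantification on one volume.

    Default thresholds follow the published convention: IsoData on FITC, the
    FITC threshold applied cross-channel to tdTomato, IsoData on the whole
    DAPI stack for segmentation. Counts are averaged across the selected
    planes; every parameter used is echoed into ``params``.
    """
    acq = volume.acquisition
    planes_spec = planes_spec or PlanesSpec()
    planes = planes_spec.select(acq)

    if fitc_threshold is None:
        fitc_threshold = compute_threshold(volume, "FITC", "auto")
    if tdtomato_threshold is None:
        tdtomato_threshold = compute_threshold(
            volume, "tdTomato", "cross-channel", source_threshold=fitc_threshold
        )
    if dapi_threshold is None:
        try:
            dapi_threshold = isodata_threshold(volume.channels["DAPI"])
        except DegenerateHistogramError:
            dapi_threshold = None  # blank stack: planes will yield no ROIs

    vmask = make_vessel_mask(volume, fitc_threshold)
    broadened = broaden_mask(vmask, broaden_radius_um, acq.voxel_size_zyx[2])
    td_mask = volume.channels["tdTomato"] > tdtomato_threshold.value

    per_plane = []
    vessel_areas = vmask.plane_areas_um2
    for p in planes:
        rois = segment_nuclei(volume, p, threshold=dapi_threshold)
        per_plane.append(
            classify_and_count(
                rois,
                td_mask[p],
                broadened.mask[p],
                min_area_um2=min_area_um2,
                overlap_frac=overlap_frac,
                plane=p,
                vessel_area_um2=float(vessel_areas[p]),
            )
        )

    params = {
        "fitc_threshold": fitc_threshold.value,
        "fitc_method": fitc_threshold.method,
        "tdtomato_threshold": tdtomato_threshold.value,
        "tdtomato_method": tdtomato_threshold.method,
        "dapi_threshold": dapi_threshold,
        "broaden_radius_um": broaden_radius_um,
        "min_area_um2": min_area_um2,
        "overlap_frac": overlap_frac,
        "n_planes": planes_spec.n_planes,
        "plane_spacing_um": planes_spec.spacing_um,
    }
    return RegionQuant(
        region=region,
        condition=condition,
        planes=tuple(planes),
        per_plane=tuple(per_plane),
        params=params,
    )


def aggregate_region_images(quants: Sequence[RegionQuant]) -> dict[str, float]:
    """Average the per-image averages when a region was imaged more than once."""
    if not quants:
        raise ValueError("need at least one image per region")
    keys = ("n_nuclei", "n_mural", "n_tdtomato", "vessel_area_um2")
    return {k: float(np.mean([q.mean(k) for q in quants])) for k in keys}


# ---------------------------------------------------------------------------
# evaluation against simulated truth


@dataclass(frozen=True)
class ClassScores:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def _truth_in_plane(
    truth: GroundTruth,
    plane_z: float,
    classes: Sequence[str],
    min_area_um2: float,
) -> list[tuple[float, float]]:
    """(y, x) centroids of true cells whose nuclear cross-section at plane_z
    clears the area floor."""
    out = []
    for c in truth.cells:
        if c.cls not in classes:
            continue
        cz, cy, cx = c.centroid_um
        az, ay, ax = c.axes_um
        dz = plane_z - cz
        if abs(dz) >= az:
            continue
        area = math.pi * ay * ax * (1.0 - (dz / az) ** 2)
        if area >= min_area_um2:
            out.append((cy, cx))
    return out


def _greedy_match(
    pred: list[tuple[float, float]],
    true: list[tuple[float, float]],
    radius_um: float,
) -> int:
    """One-to-one greedy matching by in-plane distance; returns #matches."""
    pairs = []
    for i, p in enumerate(pred):
        for j, t in enumerate(true):
            d = math.hypot(p[0] - t[0], p[1] - t[1])
            if d <= radius_um:
                pairs.append((d, i, j))
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    matches = 0
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matches += 1
    return matches


def evaluate_against_truth(
    quant: RegionQuant,
    truth: GroundTruth,
    acq: AcquisitionSpec,
    match_radius_um: float = 5.0,
    min_area_um2: float = 10.0,
) -> dict[str, ClassScores]:
    """Score predicted mural and tdTomato+ nuclei against simulated truth.

    Per analysed plane, predicted centroids are matched one-to-one (greedy,
    by distance, within ``match_radius_um``) to true cells whose nuclear
    cross-section in that plane clears the area floor. The *mural* class is
    scored against true mural cells, the *tdtomato* class against all
    labelled cells.
    """
    class_truth = {"mural": ("mural",), "tdtomato": ("mural", "fibroblast")}
    tallies = {k: [0, 0, 0] for k in class_truth}  # tp, fp, fn
    for pc in quant.per_plane:
        plane_z = acq.plane_z_um(pc.plane)
        preds = {
            "mural": [c.roi.centroid_um for c in pc.rois if c.is_mural],
            "tdtomato": [c.roi.centroid_um for c in pc.rois if c.is_tdtomato],
        }
        for cls, truth_classes in class_truth.items():
            true_pts = _truth_in_plane(truth, plane_z, truth_classes, min_area_um2)
            m = _greedy_match(preds[cls], true_pts, match_radius_um)
            tallies[cls][0] += m
            tallies[cls][1] += len(preds[cls]) - m
            tallies[cls][2] += len(true_pts) - m
    return {k: ClassScores(tp=v[0], fp=v[1], fn=v[2]) for k, v in tallies.items()}
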