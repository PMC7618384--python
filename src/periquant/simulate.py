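"""Synthetic cleared-nerve scenes and their rendering into noisy 3-channel volumes.

The generator emulates a whole-mount, vessel-perfused peripheral nerve as seen
on a confocal microscope after aqueous clearing:

* the **FITC** channel carries vessel lumens, filled by intravascular
  FITC-albumin gelatin perfusion, modelled as tubes around polyline
  centerlines;
* the **tdTomato** channel carries the somata of Pdgfrb-lineage reporter
  cells, which come in two ground-truth classes — *mural* cells (pericytes /
  vascular smooth muscle cells) wrapped onto vessel walls, and *fibroblasts*
  scattered through the endoneurium away from vessels;
* the **DAPI** channel carries one nuclear ellipsoid per cell.

Cell counts are Poisson with means ``density x extent x effect multiplier``,
where the per-(condition, region) multipliers encode the injury design: after
partial sciatic nerve ligation the lesion site and the degenerating distal
stump gain stromal cells, while sham and contralateral nerves are unchanged.

Every scene and every rendered volume is a pure function of its spec and a
seed, so the downstream quantification can be scored against exact ground
truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "AcquisitionSpec",
    "Vessel",
    "SceneSpec",
    "Cell",
    "GroundTruth",
    "MultiChannelVolume",
    "CHANNEL_NAMES",
    "CONDITIONS",
    "REGIONS",
    "DEFAULT_EFFECT_MULTIPLIERS",
    "build_scene",
    "render_volume",
    "simulate_group",
]

CHANNEL_NAMES = ("FITC", "tdTomato", "DAPI")

CONDITIONS = ("sham-ipsi", "psnl-ipsi", "psnl-contra")
REGIONS = ("lesion", "proximal", "distal", "away")

#: Injury design: (mural multiplier, fibroblast multiplier) per (condition, region).
#: Nerve ligation roughly doubles mural cell numbers in the distal (Wallerian
#: degeneration) stump and increases total Pdgfrb+ cells at the lesion and
#: distally; sham and contralateral nerves stay at baseline (1.0).
DEFAULT_EFFECT_MULTIPLIERS: dict[tuple[str, str], tuple[float, float]] = {
    ("psnl-ipsi", "lesion"): (1.0, 2.0),
    ("psnl-ipsi", "distal"): (2.0, 1.5),
    ("psnl-ipsi", "proximal"): (1.2, 1.2),
}


class ConfigurationError(ValueError):
    """Raised when a spec describes impossible or inconsistent geometry."""


@dataclass(frozen=True)
class AcquisitionSpec:
    """Confocal acquisition geometry and noise model.

    Defaults describe a 20x/0.8 NA objective field: 0.62 um in-plane pixels and
    a z-stack at 2 um steps. ``z_step`` is the spacing between acquired planes
    and equals the z voxel size of the stored stack.
    """

    shape_zyx: tuple[int, int, int] = (24, 160, 160)
    voxel_size_zyx: tuple[float, float, float] = (2.0, 0.62, 0.62)
    z_step: float = 2.0
    psf_sigma_xy: float = 0.3  # um
    psf_sigma_z: float = 1.0  # um
    photon_gain: float = 10.0  # expected photons per intensity unit
    read_noise_sd: float = 2.0  # intensity units
    background: tuple[float, float, float] = (2.0, 2.0, 2.0)
    z_step_range: tuple[float, float] = (2.0, 8.0)

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.shape_zyx):
            raise ConfigurationError("shape_zyx entries must be positive")
        if any(v <= 0 for v in self.voxel_size_zyx):
            raise ConfigurationError("voxel sizes must be positive")
        if self.z_step <= 0:
            raise ConfigurationError("z_step must be positive")
        lo, hi = self.z_step_range
        if not (lo <= self.z_step <= hi):
            raise ConfigurationError(
                f"z_step {self.z_step} um outside the allowed range [{lo}, {hi}] um"
            )
        if abs(self.z_step - self.voxel_size_zyx[0]) > 1e-9:
            raise ConfigurationError("z voxel size must equal z_step")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the volume along (z, y, x) in um."""
        return tuple(n * v for n, v in zip(self.shape_zyx, self.voxel_size_zyx))

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_zyx))

    @property
    def pixel_area_um2(self) -> float:
        return self.voxel_size_zyx[1] * self.voxel_size_zyx[2]

    def plane_z_um(self, plane: int) -> float:
        """z coordinate (um) of the centre of plane ``plane``."""
        return (plane + 0.5) * self.voxel_size_zyx[0]


@dataclass(frozen=True)
class Vessel:
    """A blood vessel: a tube of constant radius around a polyline centerline."""

    points_um: tuple[tuple[float, float, float], ...]  # (z, y, x) control points
    radius_um: float = 8.0
    wall_offset_um: float = 2.0  # how far outside the lumen mural somata sit
    kind: str = "arteriole"  # pass-through morphology label

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ConfigurationError("vessel radius must be positive")
        if self.wall_offset_um < 0:
            raise ConfigurationError("wall offset must be non-negative")
        if len(self.points_um) < 2:
            raise ConfigurationError("a vessel centerline needs >= 2 points")

    @property
    def length_um(self) -> float:
        pts = np.asarray(self.points_um, dtype=float)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        pts = np.asarray(self.points_um, dtype=float)
        return pts[:-1], pts[1:]


def _default_vessels(bounds_zyx: tuple[float, float, float]) -> tuple[Vessel, ...]:
    """Two arteriole-calibre vessels crossing the field, tilted through the
    stack so that successive analysis planes sample different wall segments
    (vessels in a mounted nerve are never perfectly parallel to the imaging
    plane)."""
    bz, by, bx = bounds_zyx
    z_lo, z_hi = 0.375 * bz, 0.625 * bz
    return (
        Vessel(points_um=((z_lo, 0.0, bx / 3.0), (z_hi, by, bx / 3.0))),
        Vessel(points_um=((z_hi, 0.0, 2.0 * bx / 3.0), (z_lo, by, 2.0 * bx / 3.0))),
    )


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to draw one simulated nerve region.

    Densities are calibrated to an arteriole-scale field: ``mural_density`` is
    cells per 100 um of vessel length (smooth-muscle/pericyte coverage is
    near-continuous on arterioles), ``fibroblast_density`` is cells per
    1e5 um^3 of non-vessel tissue.
    """

    bounds_zyx: tuple[float, float, float] = (48.0, 99.2, 99.2)  # um
    vessels: tuple[Vessel, ...] | None = None
    mural_density: float = 15.0  # per 100 um vessel length
    fibroblast_density: float = 5.0  # per 1e5 um^3 non-vessel tissue
    nucleus_axes_range: tuple[tuple[float, float], ...] = (
        (1.8, 2.5),  # z semi-axis, um
        (2.3, 3.2),  # y semi-axis, um
        (2.3, 3.2),  # x semi-axis, um
    )
    mural_elongation: float = 1.3  # stretch along the vessel axis
    mural_axial_band: float = 0.5  # |axial offset| <= band * radius
    exclusion_margin_um: float = 10.0  # min fibroblast distance to vessel surface
    min_separation_um: float = 8.0  # min centroid-centroid distance
    condition: str = "sham-ipsi"
    region: str = "away"
    effect_multipliers: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_MULTIPLIERS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mural_density < 0 or self.fibroblast_density < 0:
            raise ConfigurationError("densities must be non-negative")
        if any(b <= 0 for b in self.bounds_zyx):
            raise ConfigurationError("bounds must be positive")
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if self.region not in REGIONS:
            raise ConfigurationError(f"unknown region {self.region!r}")
        for lo, hi in self.nucleus_axes_range:
            if not (0 < lo <= hi):
                raise ConfigurationError("nucleus axis ranges must be 0 < lo <= hi")
        # In-plane cross-sections must be able to clear the 10 um^2 ROI floor.
        min_area = math.pi * self.nucleus_axes_range[1][0] * self.nucleus_axes_range[2][0]
        if min_area < 10.0:
            raise ConfigurationError(
                f"nucleus axes admit in-plane cross-sections of {min_area:.1f} um^2 "
                "< 10 um^2; enlarge nucleus_axes_range"
            )
        if not 0.0 <= self.mural_axial_band <= 1.0:
            raise ConfigurationError("mural_axial_band must lie in [0, 1]")
        for v in self.resolved_vessels():
            if 2.0 * v.radius_um >= min(self.bounds_zyx):
                raise ConfigurationError(
                    f"vessel radius {v.radius_um} um does not fit inside bounds "
                    f"{self.bounds_zyx}"
                )

    def resolved_vessels(self) -> tuple[Vessel, ...]:
        return self.vessels if self.vessels is not None else _default_vessels(self.bounds_zyx)

    def multipliers(self) -> tuple[float, float]:
        """(mural, fibroblast) density multipliers for this condition/region."""
        return self.effect_multipliers.get((self.condition, self.region), (1.0, 1.0))


@dataclass(frozen=True)
class Cell:
    id: int
    cls: str  # "mural" | "fibroblast"
    centroid_um: tuple[float, float, float]  # (z, y, x)
    axes_um: tuple[float, float, float]  # nucleus semi-axes (z, y, x)
    distance_um: float  # distance to nearest vessel surface


@dataclass(frozen=True)
class GroundTruth:
    """Simulated cell roster plus the vessel geometry it was drawn around."""

    cells: tuple[Cell, ...]
    vessels: tuple[Vessel, ...]
    bounds_zyx: tuple[float, float, float]
    condition: str = "sham-ipsi"
    region: str = "away"

    @property
    def totals(self) -> dict[str, int]:
        out = {"mural": 0, "fibroblast": 0}
        for c in self.cells:
            out[c.cls] += 1
        return out

    def cells_of(self, cls: str) -> tuple[Cell, ...]:
        return tuple(c for c in self.cells if c.cls == cls)


@dataclass(frozen=True)
class MultiChannelVolume:
    """Named intensity grids sharing one shape, plus acquisition metadata."""

    channels: dict[str, np.ndarray]
    acquisition: AcquisitionSpec

    def __post_init__(self) -> None:
        shapes = {ch: arr.shape for ch, arr in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ConfigurationError(f"channel shapes differ: {shapes}")
        if next(iter(shapes.values())) != tuple(self.acquisition.shape_zyx):
            raise ConfigurationError("channel shape does not match acquisition spec")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.acquisition.shape_zyx)

    def stack(self, order: Sequence[str] = CHANNEL_NAMES) -> np.ndarray:
        """(C, Z, Y, X) array in the requested channel order."""
        return np.stack([self.channels[c] for c in order], axis=0)


# ---------------------------------------------------------------------------
# geometry helpers


def _point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance from each row of ``points`` to segment a-b (all um)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=-1)
    t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.linalg.norm(points - proj, axis=-1)


def distance_to_vessel_surface(
    points: np.ndarray, vessels: Sequence[Vessel]
) -> np.ndarray:
    """Signed distance (um) from points (N, 3 zyx) to the nearest vessel surface.

    Negative inside a lumen.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    best = np.full(points.shape[0], np.inf)
    for v in vessels:
        starts, ends = v.segments()
        for a, b in zip(starts, ends):
            d = _point_segment_distance(points, a, b) - v.radius_um
            best = np.minimum(best, d)
    return best


def _perp_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = tangent / np.linalg.norm(tangent)
    ref = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(t, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t, e1)
    return e1, e2


# ---------------------------------------------------------------------------
# scene construction


def _sample_axes(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    return np.array([rng.uniform(lo, hi) for lo, hi in spec.nucleus_axes_range])


def _fits_inside(c: np.ndarray, axes: np.ndarray, bounds: np.ndarray) -> bool:
    return bool(np.all(c - axes >= 0.0) and np.all(c + axes <= bounds))


def _separated(c: np.ndarray, placed: list[np.ndarray], min_sep: float) -> bool:
    if not placed:
        return True
    arr = np.asarray(placed)
    return bool(np.min(np.linalg.norm(arr - c, axis=1)) >= min_sep)


_MAX_TRIES = 200


def build_scene(spec: SceneSpec) -> GroundTruth:
    """Draw a cell roster around the scene's vessels.

    Counts are Poisson (mean = density x extent x multiplier); mural cells sit
    on vessel surfaces within ``wall_offset_um``, restricted to the lateral
    band ``mural_axial_band`` of the lumen; fibroblasts are uniform in tissue
    at least ``exclusion_margin_um`` away from any vessel surface. Placement
    uses rejection resampling of *positions* only, so counts keep their
    Poisson law; reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    vessels = spec.resolved_vessels()
    bounds = np.asarray(spec.bounds_zyx, dtype=float)
    mural_mult, fibro_mult = spec.multipliers()

    total_length = sum(v.length_um for v in vessels)
    lam_mural = spec.mural_density / 100.0 * total_length * mural_mult

    volume = float(np.prod(bounds))
    vessel_volume = sum(math.pi * v.radius_um**2 * v.length_um for v in vessels)
    tissue_volume = max(volume - vessel_volume, 0.0)
    lam_fibro = spec.fibroblast_density / 1e5 * tissue_volume * fibro_mult

    n_mural = int(rng.poisson(lam_mural)) if lam_mural > 0 else 0
    n_fibro = int(rng.poisson(lam_fibro)) if lam_fibro > 0 else 0

    cells: list[Cell] = []
    placed: list[np.ndarray] = []
    next_id = 0

    # mural cells: on vessel walls, lateral band of the lumen
    seg_info = []
    for v in vessels:
        starts, ends = v.segments()
        for a, b in zip(starts, ends):
            seg_info.append((v, a, b, float(np.linalg.norm(b - a))))
    seg_weights = np.array([s[3] for s in seg_info], dtype=float)
    if seg_weights.sum() > 0:
        seg_weights = seg_weights / seg_weights.sum()

    for _ in range(n_mural):
        axes = _sample_axes(rng, spec)
        fallback: tuple[np.ndarray, np.ndarray, float] | None = None
        for _attempt in range(_MAX_TRIES):
            k = int(rng.choice(len(seg_info), p=seg_weights))
            v, a, b, _ = seg_info[k]
            t = rng.uniform()
            base = a + t * (b - a)
            tangent = b - a
            e1, e2 = _perp_basis(tangent)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            offset_dir = math.cos(phi) * e1 + math.sin(phi) * e2
            if abs(offset_dir[0]) > spec.mural_axial_band:
                continue  # polar cap: nucleus would sit above/below the lumen
            u = rng.uniform(0.0, v.wall_offset_um)
            c = base + (v.radius_um + u) * offset_dir
            # elongate the nucleus along the vessel axis
            tdir = np.abs(tangent) / np.linalg.norm(tangent)
            ax = axes * (1.0 + (spec.mural_elongation - 1.0) * tdir)
            if not _fits_inside(c, ax, bounds):
                continue
            fallback = (c, ax, float(u))
            if _separated(c, placed, spec.min_separation_um):
                break
        if fallback is None:
            continue  # no admissible position at all (degenerate geometry)
        c, ax, u = fallback
        cells.append(
            Cell(
                id=next_id,
                cls="mural",
                centroid_um=tuple(c),
                axes_um=tuple(ax),
                distance_um=u,
            )
        )
        placed.append(c)
        next_id += 1

    # fibroblasts: uniform in tissue, outside the exclusion margin
    for _ in range(n_fibro):
        axes = _sample_axes(rng, spec)
        fb: tuple[np.ndarray, float] | None = None
        for _attempt in range(_MAX_TRIES):
            c = rng.uniform(axes, bounds - axes)
            d = float(distance_to_vessel_surface(c[None, :], vessels)[0])
            if d <= spec.exclusion_margin_um:
                continue
            fb = (c, d)
            if _separated(c, placed, spec.min_separation_um):
                break
        if fb is None:
            continue  # exclusion margin leaves no admissible tissue
        c, d = fb
        cells.append(
            Cell(
                id=next_id,
                cls="fibroblast",
                centroid_um=tuple(c),
                axes_um=tuple(axes),
                distance_um=d,
            )
        )
        placed.append(c)
        next_id += 1

    return GroundTruth(
        cells=tuple(cells),
        vessels=vessels,
        bounds_zyx=spec.bounds_zyx,
        condition=spec.condition,
        region=spec.region,
    )


# ---------------------------------------------------------------------------
# rendering


DEFAULT_AMPLITUDES = {"FITC": 100.0, "tdTomato": 100.0, "DAPI": 100.0}
SOMA_SCALE = 1.5  # soma ellipsoid = nucleus semi-axes x this factor


def _voxel_centers(acq: AcquisitionSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return tuple(
        (np.arange(n) + 0.5) * v
        for n, v in zip(acq.shape_zyx, acq.voxel_size_zyx)
    )


def rasterize_vessels(vessels: Sequence[Vessel], acq: AcquisitionSpec) -> np.ndarray:
    """Boolean lumen mask: voxel centres within radius of a centerline."""
    zc, yc, xc = _voxel_centers(acq)
    zz, yy, xx = np.meshgrid(zc, yc, xc, indexing="ij")
    pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    d = distance_to_vessel_surface(pts, vessels)
    return (d <= 0.0).reshape(acq.shape_zyx)


def rasterize_ellipsoid(
    grid: np.ndarray,
    centroid_um: Sequence[float],
    axes_um: Sequence[float],
    acq: AcquisitionSpec,
    amplitude: float,
) -> None:
    """Add ``amplitude`` to every voxel whose centre lies inside the ellipsoid."""
    c = np.asarray(centroid_um, dtype=float)
    ax = np.asarray(axes_um, dtype=float)
    vox = np.asarray(acq.voxel_size_zyx, dtype=float)
    lo = np.maximum(np.floor((c - ax) / vox - 0.5).astype(int), 0)
    hi = np.minimum(np.ceil((c + ax) / vox + 0.5).astype(int) + 1, acq.shape_zyx)
    if np.any(lo >= hi):
        return
    coords = [
        (np.arange(l, h) + 0.5) * v for l, h, v in zip(lo, hi, vox)
    ]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    inside = (
        ((zz - c[0]) / ax[0]) ** 2
        + ((yy - c[1]) / ax[1]) ** 2
        + ((xx - c[2]) / ax[2]) ** 2
    ) <= 1.0
    grid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]][inside] += amplitude


def render_volume(
    truth: GroundTruth,
    acq: AcquisitionSpec,
    seed: int = 0,
    blur: bool = True,
    noise: bool = True,
    amplitudes: dict[str, float] | None = None,
) -> MultiChannelVolume:
    """Rasterize a ground-truth scene and apply PSF blur and shot/read noise.

    FITC = vessel lumens, tdTomato = somata of all labelled cells, DAPI =
    nuclear ellipsoids; then per-channel background, Gaussian PSF blur
    (sigma set by the acquisition spec), Poisson shot noise at
    ``photon_gain`` and additive Gaussian read noise. ``blur`` and ``noise``
    are independently disableable; everything is deterministic given
    (truth, acq, seed).
    """
    if noise and acq.photon_gain <= 0:
        raise ConfigurationError("photon_gain must be positive when noise is enabled")
    extent = acq.extent_um
    if any(b > e + 1e-6 for b, e in zip(truth.bounds_zyx, extent)):
        raise ConfigurationError(
            f"scene bounds {truth.bounds_zyx} um exceed the acquisition extent {extent} um"
        )
    amps = dict(DEFAULT_AMPLITUDES)
    if amplitudes:
        amps.update(amplitudes)

    shape = tuple(acq.shape_zyx)
    fitc = np.zeros(shape, dtype=float)
    td = np.zeros(shape, dtype=float)
    dapi = np.zeros(shape, dtype=float)

    if truth.vessels:
        fitc[rasterize_vessels(truth.vessels, acq)] += amps["FITC"]
    for cell in truth.cells:
        soma_axes = tuple(a * SOMA_SCALE for a in cell.axes_um)
        rasterize_ellipsoid(td, cell.centroid_um, soma_axes, acq, amps["tdTomato"])
        rasterize_ellipsoid(dapi, cell.centroid_um, cell.axes_um, acq, amps["DAPI"])

    channels = {"FITC": fitc, "tdTomato": td, "DAPI": dapi}
    for name, bg in zip(CHANNEL_NAMES, acq.background):
        channels[name] = channels[name] + bg

    if blur:
        sigma_vox = (
            acq.psf_sigma_z / acq.voxel_size_zyx[0],
            acq.psf_sigma_xy / acq.voxel_size_zyx[1],
            acq.psf_sigma_xy / acq.voxel_size_zyx[2],
        )
        for name in channels:
            channels[name] = gaussian_filter(channels[name], sigma_vox, mode="constant")

    if noise:
        rng = np.random.default_rng(seed)
        for name in channels:
            img = np.clip(channels[name], 0.0, None)
            shot = rng.poisson(img * acq.photon_gain) / acq.photon_gain
            out = shot + rng.normal(0.0, acq.read_noise_sd, size=img.shape)
            channels[name] = np.clip(out, 0.0, None)

    return MultiChannelVolume(channels=channels, acquisition=acq)


# ---------------------------------------------------------------------------
# grouped simulation


@dataclass(frozen=True)
class SimulatedSample:
    condition: str
    region: str
    index: int
    truth: GroundTruth
    volume: MultiChannelVolume


def simulate_group(
    design: Sequence[tuple[str, str, int]],
    base_spec: SceneSpec,
    acq: AcquisitionSpec,
    seed: int = 0,
    blur: bool = True,
    noise: bool = True,
) -> list[SimulatedSample]:
    """Simulate ``n`` independent volume/truth pairs per (condition, region) group.

    Per-sample seeds are derived from the master seed with a counter-based
    seed-sequence split, so any sample is reproducible in isolation.
    """
    for condition, region, n in design:
        if condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {condition!r}")
        if region not in REGIONS:
            raise ConfigurationError(f"unknown region {region!r}")
        if n < 1:
            raise ConfigurationError("each group needs n >= 1")

    samples: list[SimulatedSample] = []
    counter = 0
    for condition, region, n in design:
        for i in range(n):
            child = np.random.SeedSequence(seed, spawn_key=(counter,))
            scene_seed, render_seed = [
                int(s) % (2**31) for s in child.generate_state(2)
            ]
            spec = replace(
                base_spec, condition=condition, region=region, seed=scene_seed
            )
            truth = build_scene(spec)
            volume = render_volume(
                truth, acq, seed=render_seed, blur=blur, noise=noise
            )
            samples.append(
                SimulatedSample(
                    condition=condition,
                    region=region,
                    index=i,
                    truth=truth,
                    volume=volume,
                )
            )
            counter += 1
    return samples
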