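"""File formats: multi-page TIFF volumes with YAML sidecars, CSV tables.

A volume is written either as one interleaved TIFF (axes ZCYX) or one file
per channel, always with a YAML sidecar carrying the acquisition metadata and
channel order; ground truth and per-region counts travel as plain CSV so runs
diff cleanly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .quantify import RegionQuant
from .simulate import (
    CHANNEL_NAMES,
    AcquisitionSpec,
    Cell,
    GroundTruth,
    MultiChannelVolume,
    Vessel,
)

__all__ = [
    "FormatError",
    "sidecar_path",
    "write_volume",
    "load_stack",
    "truth_to_frame",
    "write_truth_csv",
    "read_truth_csv",
    "region_counts_frame",
    "write_region_csv",
    "write_params_csv",
]


class FormatError(ValueError):
    """A file does not match its declared layout or lacks required metadata."""


def sidecar_path(tiff_path: Path | str) -> Path:
    return Path(tiff_path).with_suffix(".yaml")


def _acq_to_dict(acq: AcquisitionSpec) -> dict:
    d = dataclasses.asdict(acq)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def _acq_from_dict(d: dict) -> AcquisitionSpec:
    kwargs = dict(d)
    for key in ("shape_zyx", "voxel_size_zyx", "background", "z_step_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return AcquisitionSpec(**kwargs)


def write_volume(
    volume: MultiChannelVolume,
    path: Path | str,
    layout: str = "interleaved",
    channel_order: Sequence[str] = CHANNEL_NAMES,
) -> list[Path]:
    """Write a volume as TIFF plus a YAML sidecar; returns the files written.

    ``layout='interleaved'`` stores one file with axes (Z, C, Y, X);
    ``'per-channel'`` stores ``<stem>_<channel>.tif`` per channel.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = volume.stack(channel_order).astype(np.float32)  # (C, Z, Y, X)
    written: list[Path] = []
    if layout == "interleaved":
        tifffile.imwrite(
            path, np.moveaxis(stack, 0, 1), photometric="minisblack"
        )  # (Z, C, Y, X)
        written.append(path)
    elif layout == "per-channel":
        for i, ch in enumerate(channel_order):
            p = path.with_name(f"{path.stem}_{ch}{path.suffix}")
            tifffile.imwrite(p, stack[i], photometric="minisblack")
            written.append(p)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    sidecar = {
        "layout": layout,
        "channel_order": list(channel_order),
        "acquisition": _acq_to_dict(volume.acquisition),
    }
    sc = sidecar_path(path)
    sc.write_text(yaml.safe_dump(sidecar, sort_keys=True))
    written.append(sc)
    return written


def load_stack(path: Path | str, config: dict | None = None) -> MultiChannelVolume:
    """Load a TIFF volume and its metadata back into a MultiChannelVolume.

    Metadata comes from the YAML sidecar, optionally overridden by ``config``
    (same keys). Channel-count mismatches and missing voxel sizes raise
    FormatError.
    """
    path = Path(path)
    sc = sidecar_path(path)
    meta: dict = {}
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
    if config:
        meta.update(config)
    if "acquisition" not in meta or "voxel_size_zyx" not in meta["acquisition"]:
        raise FormatError(
            f"no voxel-size metadata for {path.name}: provide a YAML sidecar or a "
            "config block with an 'acquisition' entry carrying voxel_size_zyx"
        )
    acq = _acq_from_dict(meta["acquisition"])
    channel_order = list(meta.get("channel_order", CHANNEL_NAMES))
    layout = meta.get("layout", "interleaved")

    if layout == "interleaved":
        data = tifffile.imread(path)  # (Z, C, Y, X)
        if data.ndim != 4 or data.shape[1] != len(channel_order):
            raise FormatError(
                f"{path.name}: expected {len(channel_order)} channels "
                f"(axes ZCYX), found array of shape {data.shape}"
            )
        channels = {
            ch: np.asarray(data[:, i], dtype=float)
            for i, ch in enumerate(channel_order)
        }
    elif layout == "per-channel":
        channels = {}
        for ch in channel_order:
            p = path.with_name(f"{path.stem}_{ch}{path.suffix}")
            if not p.exists():
                raise FormatError(f"missing per-channel file {p.name}")
            channels[ch] = np.asarray(tifffile.imread(p), dtype=float)
    else:
        raise FormatError(f"unknown layout {layout!r} in sidecar")
    return MultiChannelVolume(channels=channels, acquisition=acq)


# ---------------------------------------------------------------------------
# ground truth


def truth_to_frame(truth: GroundTruth) -> pd.DataFrame:
    rows = []
    for c in truth.cells:
        rows.append(
            {
                "id": c.id,
                "class": c.cls,
                "z": c.centroid_um[0],
                "y": c.centroid_um[1],
                "x": c.centroid_um[2],
                "axis_z": c.axes_um[0],
                "axis_y": c.axes_um[1],
                "axis_x": c.axes_um[2],
                "distance": c.distance_um,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "class", "z", "y", "x", "axis_z", "axis_y", "axis_x", "distance"],
    )


def write_truth_csv(truth: GroundTruth, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth_to_frame(truth).to_csv(path, index=False)
    return path


def read_truth_csv(
    path: Path | str,
    vessels: Sequence[Vessel] = (),
    bounds_zyx: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> GroundTruth:
    df = pd.read_csv(path)
    cells = tuple(
        Cell(
            id=int(r.id),
            cls=str(r["class"]),
            centroid_um=(float(r.z), float(r.y), float(r.x)),
            axes_um=(float(r.axis_z), float(r.axis_y), float(r.axis_x)),
            distance_um=float(r.distance),
        )
        for _, r in df.iterrows()
    )
    return GroundTruth(cells=cells, vessels=tuple(vessels), bounds_zyx=bounds_zyx)


# ---------------------------------------------------------------------------
# quantification outputs


def region_counts_frame(quants: Sequence[RegionQuant], sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Long-format per-plane counts: one row per (sample, plane)."""
    rows = []
    for i, q in enumerate(quants):
        sid = sample_ids[i] if sample_ids is not None else str(i)
        for pc in q.per_plane:
            rows.append(
                {
                    "sample": sid,
                    "region": q.region,
                    "condition": q.condition,
                    "plane": pc.plane,
                    "n_nuclei": pc.n_nuclei,
                    "n_mural": pc.n_mural,
                    "n_tdtomato": pc.n_tdtomato,
                    "vessel_area_um2": pc.vessel_area_um2,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "region", "condition", "plane",
            "n_nuclei", "n_mural", "n_tdtomato", "vessel_area_um2",
        ],
    )


def write_region_csv(
    quants: Sequence[RegionQuant],
    path: Path | str,
    sample_ids: Sequence[str] | None = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    region_counts_frame(quants, sample_ids).to_csv(path, index=False)
    return path


def write_params_csv(params: dict, path: Path | str) -> Path:
    """One-row CSV logging every parameter a run used (re-execution record)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([params]).to_csv(path, index=False)
    return path
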