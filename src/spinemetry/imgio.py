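"""Image-volume and result-table I/O.

Conventions
-----------
* Arrays are indexed ``(z, y, x)``; ``voxel_size`` is the matching
  ``(z, y, x)`` triple in micrometres.
* Physical coordinates are micrometres with the origin at the volume corner;
  the centre of voxel ``i`` sits at ``(i + 0.5) * voxel_size``.
* Volumes are written as multi-page TIFF (one page per z slice) with
  ImageJ-style pixel-size metadata, so they open correctly in Fiji.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("spinemetry")

__all__ = ["VolumeImage", "read_volume", "write_volume", "write_tables", "read_tables"]

TABLE_COLUMNS = [
    "id", "time", "attach_x_um", "attach_y_um", "attach_z_um",
    "arclength_um", "azimuth_rad", "length_um", "head_width_um",
    "neck_width_um", "head_volume_um3", "class", "fate", "quality",
]


@dataclass
class VolumeImage:
    """One 3D intensity grid plus voxel dimensions and a time index."""

    data: np.ndarray                     # (z, y, x), nonnegative intensities
    voxel_size: tuple                    # (z, y, x) um
    time_index: int = 0
    roi: Optional[tuple] = None          # optional ((z0,y0,x0),(z1,y1,x1))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("volume must be a non-empty 3D array")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be a positive (z, y, x) triple")
        self.voxel_size = vs

    @property
    def shape(self):
        return self.data.shape

    @property
    def extent_um(self):
        return tuple(n * v for n, v in zip(self.data.shape, self.voxel_size))


def write_volume(volume: VolumeImage, path) -> None:
    """Write a volume as a multi-page TIFF with pixel-size metadata."""
    vz, vy, vx = volume.voxel_size
    data = np.asarray(volume.data, dtype=np.float32)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZYX"},
    )


def _resolution_to_um(tag_value) -> Optional[float]:
    try:
        num, den = tag_value
        if num == 0:
            return None
        return float(Fraction(den, num) if isinstance(num, int) else den / num)
    except Exception:
        return None


def read_volume(path, voxel_size_override: Optional[Sequence[float]] = None,
                time_index: int = 0) -> VolumeImage:
    """Read a multi-page TIFF as a :class:`VolumeImage`.

    Voxel size is taken from ImageJ/TIFF metadata; an explicit
    ``voxel_size_override`` always wins (with a logged notice).
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_voxel = None
        ij = tf.imagej_metadata or {}
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        vx = _resolution_to_um(xres.value) if xres is not None else None
        vy = _resolution_to_um(yres.value) if yres is not None else None
        vz = ij.get("spacing")
        if vx and vy and vz:
            meta_voxel = (float(vz), float(vy), float(vx))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D z-stack, got shape {data.shape}")
    if voxel_size_override is not None:
        if meta_voxel is not None:
            logger.info(
                "voxel size override %s replaces file metadata %s",
                tuple(voxel_size_override), meta_voxel,
            )
        voxel = tuple(float(v) for v in voxel_size_override)
    elif meta_voxel is not None:
        voxel = meta_voxel
    else:
        raise ValueError(
            f"{path}: no voxel-size metadata found and no override given"
        )
    return VolumeImage(data=data, voxel_size=voxel, time_index=time_index)


def _record_row(rec, time=None, fate=""):
    az, ay, ax = rec.attachment_point
    return {
        "id": rec.id,
        "time": rec.time_index if time is None else time,
        "attach_x_um": ax, "attach_y_um": ay, "attach_z_um": az,
        "arclength_um": rec.attachment_arclength,
        "azimuth_rad": rec.azimuth,
        "length_um": rec.length,
        "head_width_um": rec.head_width,
        "neck_width_um": rec.neck_width,
        "head_volume_um3": rec.head_volume,
        "class": rec.spine_class,
        "fate": fate,
        "quality": rec.quality,
    }


def records_to_table(records) -> pd.DataFrame:
    """Spine records (or tracks) -> one row per spine (or spine x time)."""
    rows = []
    voxel_sizes = set()
    for item in records:
        if hasattr(item, "records"):        # SpineTrack
            for t in sorted(item.records):
                rec = item.records[t]
                row = _record_row(rec, time=t, fate=item.fate or "")
                row["id"] = item.track_id
                rows.append(row)
                if rec.voxel_size is not None:
                    voxel_sizes.add(round(rec.voxel_size, 9))
        else:                               # SpineRecord
            rows.append(_record_row(item))
            if item.voxel_size is not None:
                voxel_sizes.add(round(item.voxel_size, 9))
    if len(voxel_sizes) > 1:
        raise ValueError(
            f"records from mixed voxel sizes in one table: {sorted(voxel_sizes)}"
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_tables(records, path) -> pd.DataFrame:
    """Write the per-spine (or per spine x time) CSV; returns the frame."""
    df = records_to_table(records)
    df.to_csv(path, index=False, float_format="%.6g")
    return df


def read_tables(path) -> pd.DataFrame:
    return pd.read_csv(path)
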