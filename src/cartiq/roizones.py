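"""ROI handling: boundary erosion, equal two-zone partition, caliper geometry.

The depth axis is the image row axis (row 0 at the top).  The articular
surface faces the bottom of the image by default, matching the coronal scene
orientation in which the sample sits on the tibial side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cartiq.relaxometry import ParameterMap

__all__ = [
    "MaskError",
    "SampleROI",
    "ZonalSummary",
    "ZoneStats",
    "erode_boundary",
    "split_zones",
    "caliper",
    "zonal_stats",
    "ZONES",
]

ZONES = ("ECS", "sf", "dp")


class MaskError(ValueError):
    """Raised for empty or unusable masks."""


@dataclass
class SampleROI:
    """Entire-sample mask and its superficial / deep half-zone masks."""

    ecs_mask: np.ndarray
    sf_mask: np.ndarray
    dp_mask: np.ndarray
    surface_side: str = "bottom"
    pixel_spacing: float = 0.375

    def __post_init__(self) -> None:
        if not np.array_equal(self.sf_mask | self.dp_mask, self.ecs_mask):
            raise MaskError("sf and dp masks must partition the ECS mask")
        if np.any(self.sf_mask & self.dp_mask):
            raise MaskError("sf and dp masks overlap")


@dataclass
class ZoneStats:
    mean: float
    count: int
    invalid_fraction: float


@dataclass
class ZonalSummary:
    """Per-zone mean / valid-pixel count for one map.

    ``zones`` maps each of ``("ECS", "sf", "dp")`` to a :class:`ZoneStats`;
    a zone without valid pixels carries a NaN mean and count 0.
    """

    zones: dict[str, ZoneStats]

    def __getitem__(self, zone: str) -> ZoneStats:
        return self.zones[zone]


def erode_boundary(mask: np.ndarray) -> np.ndarray:
    """Remove the top-most and bottom-most masked pixel of every column.

    Depth-direction erosion only, guarding against partial-volume
    contamination at the surface and bone interfaces.

    Raises
    ------
    MaskError
        If the input is empty or nothing survives the erosion.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MaskError("mask is empty")
    out = mask.copy()
    for c in np.flatnonzero(mask.any(axis=0)):
        rows = np.flatnonzero(mask[:, c])
        out[rows[0], c] = False
        out[rows[-1], c] = False
    if not out.any():
        raise MaskError("mask too thin: boundary erosion removed every pixel")
    return out


def split_zones(
    mask: np.ndarray,
    surface_side: str = "bottom",
    pixel_spacing: float = 0.375,
) -> SampleROI:
    """Partition a mask column-wise into equal superficial and deep halves.

    Per column, the half of the masked pixels nearer ``surface_side`` forms
    the superficial zone; the remainder is the deep zone.  Columns with an
    odd pixel count assign the extra pixel to the deep zone.
    """
    if surface_side not in ("top", "bottom"):
        raise ValueError("surface_side must be 'top' or 'bottom'")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MaskError("mask is empty")
    sf = np.zeros_like(mask)
    dp = np.zeros_like(mask)
    for c in np.flatnonzero(mask.any(axis=0)):
        rows = np.flatnonzero(mask[:, c])
        n_sf = rows.size // 2
        if surface_side == "bottom":
            sf_rows, dp_rows = rows[rows.size - n_sf :], rows[: rows.size - n_sf]
        else:
            sf_rows, dp_rows = rows[:n_sf], rows[n_sf:]
        sf[sf_rows, c] = True
        dp[dp_rows, c] = True
    return SampleROI(
        ecs_mask=mask,
        sf_mask=sf,
        dp_mask=dp,
        surface_side=surface_side,
        pixel_spacing=pixel_spacing,
    )


def caliper(mask: np.ndarray, pixel_spacing: float) -> tuple[float, float]:
    """Measure sample height and width (mm) at the mask's center.

    Height is the masked extent of the central column, width that of the
    central row; the center is the bounding-box midpoint.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MaskError("mask is empty")
    rows, cols = np.nonzero(mask)
    rc = (rows.min() + rows.max()) // 2
    cc = (cols.min() + cols.max()) // 2
    height = int(mask[:, cc].sum()) * pixel_spacing
    width = int(mask[rc, :].sum()) * pixel_spacing
    return float(height), float(width)


def zonal_stats(pmap: ParameterMap, roi: SampleROI) -> ZonalSummary:
    """Mean fitted value and valid-pixel count per zone.

    The ECS statistics are computed over the union of the two zones.  Zones
    whose pixels are all invalid are flagged with a NaN mean, not an error.
    """
    if pmap.shape != roi.ecs_mask.shape:
        raise ValueError("map and ROI grids differ")
    out: dict[str, ZoneStats] = {}
    for zone, zmask in (
        ("ECS", roi.ecs_mask),
        ("sf", roi.sf_mask),
        ("dp", roi.dp_mask),
    ):
        ok = zmask & pmap.valid
        count = int(ok.sum())
        total = int(zmask.sum())
        mean = float(np.mean(pmap.values[ok])) if count else float("nan")
        invalid = 1.0 - count / total if total else float("nan")
        out[zone] = ZoneStats(mean=mean, count=count, invalid_fraction=invalid)
    return ZonalSummary(zones=out)
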