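"""Series / map / mask readers and writers plus overlay rendering.

Image series travel as NIfTI (``.nii``/``.nii.gz``) with a JSON sidecar
carrying the time points and acquisition metadata, or as a single NPZ
bundle.  Both backends round-trip losslessly and produce identical
downstream maps.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from cartiq.protocols import AcquisitionProtocol
from cartiq.relaxometry import ImageSeries, ParameterMap

__all__ = [
    "SidecarError",
    "read_series",
    "write_series",
    "write_map",
    "render_overlay",
    "OVERLAY_SCALES_MS",
]

#: Fixed color-scale upper bounds (ms) for overlay rendering, per kind.
OVERLAY_SCALES_MS = {"T1": 2000.0, "T1rho": 250.0, "T2": 120.0, "T2star": 80.0}

_SIDE_FIELDS = ("kind", "time_points", "repetition_time", "fov_mm", "grid")


class SidecarError(ValueError):
    """Raised for missing or malformed sidecar metadata."""


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _protocol_from_meta(meta: dict) -> AcquisitionProtocol:
    for fieldname in _SIDE_FIELDS:
        if fieldname not in meta:
            raise SidecarError(f"sidecar is missing required field {fieldname!r}")
    return AcquisitionProtocol(
        kind=str(meta["kind"]),
        time_points=tuple(float(t) for t in meta["time_points"]),
        repetition_time=float(meta["repetition_time"]),
        fov_mm=float(meta["fov_mm"]),
        grid=tuple(int(g) for g in meta["grid"]),
    )


def _meta_from_series(series: ImageSeries) -> dict:
    p = series.protocol
    return {
        "kind": p.kind,
        "time_points": list(p.time_points),
        "repetition_time": p.repetition_time,
        "fov_mm": p.fov_mm,
        "grid": list(p.grid),
        "sample_id": series.sample_id,
        "displacement": series.displacement,
    }


def write_series(path, series: ImageSeries) -> Path:
    """Write an image series; backend chosen by suffix (.npz or .nii[.gz])."""
    path = Path(path)
    meta = _meta_from_series(series)
    if path.suffix == ".npz":
        np.savez(path, data=series.data, meta=json.dumps(meta, sort_keys=True))
        return path
    import nibabel as nib

    spacing = series.protocol.pixel_spacing
    # (rows, cols, time) on disk; affine encodes in-plane spacing
    affine = np.diag([spacing, spacing, 1.0, 1.0])
    img = nib.Nifti1Image(np.moveaxis(series.data, 0, -1), affine)
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True, indent=1))
    return path


def read_series(path) -> ImageSeries:
    """Read an image series written by :func:`write_series`.

    Raises
    ------
    SidecarError
        If metadata is missing/malformed or inconsistent with the array.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as f:
            data = f["data"]
            meta = json.loads(str(f["meta"]))
    else:
        import nibabel as nib

        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise SidecarError(f"sidecar {sidecar} not found")
        meta = json.loads(sidecar.read_text())
        data = np.moveaxis(np.asarray(nib.load(str(path)).dataobj), -1, 0)
    protocol = _protocol_from_meta(meta)
    if data.shape[0] != protocol.n_points:
        raise SidecarError(
            f"stack length {data.shape[0]} does not match sidecar time_points "
            f"({protocol.n_points})"
        )
    return ImageSeries(
        data=np.asarray(data, dtype=float),
        protocol=protocol,
        sample_id=str(meta.get("sample_id", "")),
        displacement=str(meta.get("displacement", "d0")),
    )


def write_map(path, pmap: ParameterMap) -> Path:
    """Write a fitted map (values/valid/r2) as an NPZ with JSON metadata."""
    path = Path(path)
    meta = {
        "kind": pmap.kind,
        "sample_id": pmap.sample_id,
        "displacement": pmap.displacement,
        "r2_threshold": pmap.r2_threshold,
    }
    np.savez(
        path,
        values=pmap.values,
        valid=pmap.valid,
        r2=pmap.r2,
        mask=pmap.mask,
        meta=json.dumps(meta, sort_keys=True),
    )
    return path


def read_map(path) -> ParameterMap:
    with np.load(Path(path), allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        return ParameterMap(
            kind=meta["kind"],
            values=f["values"],
            valid=f["valid"],
            r2=f["r2"],
            mask=f["mask"],
            sample_id=meta["sample_id"],
            displacement=meta["displacement"],
            r2_threshold=float(meta["r2_threshold"]),
        )


def render_overlay(pmap: ParameterMap, background: np.ndarray, out) -> Path:
    """Color-coded map overlaid on a grayscale morphological image.

    The color scale is fixed per parameter kind (0-2000 ms for T1) so that
    serial maps are visually comparable.  All-invalid maps render the
    background alone.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    background = np.asarray(background, dtype=float)
    if background.shape != pmap.shape:
        raise ValueError("background shape does not match map grid")
    vmax = OVERLAY_SCALES_MS.get(pmap.kind, float(np.nanmax(pmap.values) or 1.0))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(background, cmap="gray", interpolation="nearest")
    overlay = np.ma.masked_where(~pmap.valid, pmap.values)
    im = ax.imshow(overlay, cmap="jet", vmin=0.0, vmax=vmax, interpolation="nearest")
    fig.colorbar(im, ax=ax, label=f"{pmap.kind} [ms], scale 0-{vmax:g}")
    ax.set_axis_off()
    out = Path(out)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out
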