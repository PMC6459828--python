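"""Per-sample loading-response assembly.

Relative changes of zonal qMRI means under loading, Young's modulus from
stress-strain curves, and the tidy cohort table feeding the statistics and
diagnostics stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "relative_change",
    "young_modulus",
    "build_cohort_table",
    "summarize_groups",
    "PARAMETERS",
    "ZONES",
    "DISPLACEMENTS",
    "LOADED_DISPLACEMENTS",
]

PARAMETERS = ("T1", "T1rho", "T2", "T2star")
ZONES = ("ECS", "sf", "dp")
DISPLACEMENTS = ("d0", "d2.5", "d5.0")
LOADED_DISPLACEMENTS = ("d2.5", "d5.0")

#: Strain window (fractional) for the tangent modulus fit.
TANGENT_WINDOW = (0.10, 0.20)


def relative_change(v_loaded: float, v_unloaded: float) -> float:
    """Percent change of a loaded value relative to its unloaded reference.

    ``((v_loaded / v_unloaded) - 1) * 100``.  Returns NaN (flagged
    undefined) when the unloaded reference is missing, zero or negative.
    """
    if not np.isfinite(v_unloaded) or v_unloaded <= 0 or not np.isfinite(v_loaded):
        return float("nan")
    return (v_loaded / v_unloaded - 1.0) * 100.0


def young_modulus(curve) -> float:
    """Tangent Young's modulus (MPa) over the 10-20% strain window.

    ``curve`` is any object with ``strain`` (fractional) and ``stress``
    (MPa) array attributes.  The modulus is the ordinary-least-squares slope
    of stress versus strain restricted to strain in [0.10, 0.20].

    Raises
    ------
    ValueError
        If fewer than three samples fall inside the window.
    """
    strain = np.asarray(curve.strain, dtype=float)
    stress = np.asarray(curve.stress, dtype=float)
    lo, hi = TANGENT_WINDOW
    sel = (strain >= lo) & (strain <= hi)
    if sel.sum() < 3:
        raise ValueError("stress-strain curve has fewer than 3 points in the 10-20% strain window")
    slope, _ = np.polyfit(strain[sel], stress[sel], 1)
    return float(slope)


@dataclass
class SampleRecord:
    """One sample's zonal qMRI means across displacements plus references.

    ``zonal_means`` / ``zonal_counts`` are keyed by
    ``(parameter, zone, displacement)``.  Relative changes are computed per
    sample from its own unloaded reference (never from group means).
    """

    sample_id: str
    group: str
    mss: int
    zonal_means: dict[tuple[str, str, str], float]
    zonal_counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    heights: dict[str, float] = field(default_factory=dict)
    widths: dict[str, float] = field(default_factory=dict)
    young_modulus: float = float("nan")

    def delta(self, parameter: str, zone: str, displacement: str) -> float:
        """Percent change at a loaded displacement relative to d0."""
        if displacement not in LOADED_DISPLACEMENTS:
            raise ValueError(f"delta undefined for displacement {displacement!r}")
        loaded = self.zonal_means.get((parameter, zone, displacement), float("nan"))
        ref = self.zonal_means.get((parameter, zone, "d0"), float("nan"))
        return relative_change(loaded, ref)


def build_cohort_table(records: list[SampleRecord]) -> pd.DataFrame:
    """Tidy cohort table: one row per (sample, parameter, zone, displacement).

    Sample-level columns (group, MSS, Young's modulus, heights) repeat on
    every row; per-sample relative changes are attached on loaded-
    displacement rows.  Round-trips losslessly through CSV.

    Raises
    ------
    ValueError
        On duplicate sample ids.
    """
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in records")
    rows = []
    for rec in records:
        for param in PARAMETERS:
            for zone in ZONES:
                for disp in DISPLACEMENTS:
                    key = (param, zone, disp)
                    rows.append(
                        {
                            "sample_id": rec.sample_id,
                            "group": rec.group,
                            "mss": rec.mss,
                            "young_modulus": rec.young_modulus,
                            "parameter": param,
                            "zone": zone,
                            "displacement": disp,
                            "mean": rec.zonal_means.get(key, float("nan")),
                            "count": rec.zonal_counts.get(key, 0),
                            "height_mm": rec.heights.get(disp, float("nan")),
                            "width_mm": rec.widths.get(disp, float("nan")),
                            "delta_pct": (
                                rec.delta(param, zone, disp)
                                if disp in LOADED_DISPLACEMENTS
                                else float("nan")
                            ),
                        }
                    )
    columns = [
        "sample_id",
        "group",
        "mss",
        "young_modulus",
        "parameter",
        "zone",
        "displacement",
        "mean",
        "count",
        "height_mm",
        "width_mm",
        "delta_pct",
    ]
    return pd.DataFrame(rows, columns=columns)


def summarize_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Group-level mean +/- SD summary of a tidy cohort table.

    One row per (parameter, zone, displacement, group | all) with mean, SD,
    range, n, and the group-mean relative changes.  A ``display`` column
    mirrors the one-decimal reporting convention; the numeric columns keep
    full precision.
    """
    rows = []
    for (param, zone, disp), sub in table.groupby(
        ["parameter", "zone", "displacement"], sort=True
    ):
        for group in ("all", "int", "deg"):
            g = sub if group == "all" else sub[sub["group"] == group]
            vals = g["mean"].dropna()
            deltas = g["delta_pct"].dropna()
            if vals.empty:
                continue
            m, s = float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows.append(
                {
                    "parameter": param,
                    "zone": zone,
                    "displacement": disp,
                    "group": group,
                    "n": int(len(vals)),
                    "mean": m,
                    "sd": s,
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "delta_mean_pct": float(deltas.mean()) if len(deltas) else float("nan"),
                    "delta_sd_pct": (
                        float(deltas.std(ddof=1)) if len(deltas) > 1 else float("nan")
                    ),
                    "display": f"{m:.1f} ± {s:.1f}",
                }
            )
    return pd.DataFrame(rows)
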