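"""Synthetic phantom cohorts for the serial cartilage qMRI pipeline.

Generates ground-truth phantoms (zonal relaxation fields, histology scores,
geometry, stiffness), renders serial magnitude image series under loading
with Rician noise, and synthesizes unconfined-compression stress-strain
curves — so the whole downstream pipeline is testable without any external
data.

The phantom is a 2-D mid-coronal disc cross-section (a rectangle with
rounded ends, ~8 mm wide x 3 mm high) embedded in a silicone-covered
condyle scene: disc hyperintense, silicone hypointense, background dark.
True relaxation values are piecewise-constant per zone (superficial /
deep); loading scales the disc height and switches the true fields to the
loaded-displacement values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cartiq import roizones
from cartiq.diagnostics import SUBSCORE_RANGES, HistologyScore
from cartiq.protocols import AcquisitionProtocol, make_protocols
from cartiq.relaxometry import ImageSeries, signal_ir, signal_monoexp
from cartiq.response import SampleRecord, young_modulus

__all__ = [
    "ZonalDistribution",
    "CohortConfig",
    "GroundTruthPhantom",
    "StressStrainCurve",
    "Cohort",
    "make_protocols",
    "sample_truth",
    "deform",
    "render_series",
    "generate_cohort",
    "synth_stress_strain",
    "simulate_measured_records",
    "PARAMETERS",
    "ZONES",
    "DISPLACEMENTS",
    "GROUPS",
    "ECS_REFERENCE",
]

PARAMETERS = ("T1", "T1rho", "T2", "T2star")
ZONES = ("sf", "dp")
DISPLACEMENTS = ("d0", "d2.5", "d5.0")
GROUPS = ("int", "deg")

# Reference zonal statistics for the simulated cohort: unloaded mean and SD
# plus the mean values at the two loaded positions (ms), per parameter, zone
# and degeneration group.  Loading shifts are applied as multiplicative
# factors mean_loaded / mean_unloaded.
_ZONAL_REFERENCE = {
    # (parameter, zone, group): (mean_d0, sd_d0, mean_d2.5, mean_d5.0)
    ("T1", "sf", "int"): (784.1, 133.8, 685.4, 640.0),
    ("T1", "dp", "int"): (684.4, 121.2, 663.9, 642.2),
    ("T1rho", "sf", "int"): (108.5, 18.7, 107.0, 104.0),
    ("T1rho", "dp", "int"): (94.9, 18.1, 105.5, 108.1),
    ("T2", "sf", "int"): (46.4, 7.0, 45.7, 41.2),
    ("T2", "dp", "int"): (35.1, 5.8, 38.8, 37.9),
    ("T2star", "sf", "int"): (23.9, 5.2, 24.6, 23.8),
    ("T2star", "dp", "int"): (19.9, 4.3, 20.2, 20.1),
    ("T1", "sf", "deg"): (788.3, 100.3, 716.0, 684.6),
    ("T1", "dp", "deg"): (763.3, 123.4, 740.5, 726.2),
    ("T1rho", "sf", "deg"): (103.7, 18.2, 105.7, 112.1),
    ("T1rho", "dp", "deg"): (93.0, 17.7, 112.0, 114.2),
    ("T2", "sf", "deg"): (46.3, 9.9, 46.0, 43.8),
    ("T2", "dp", "deg"): (39.9, 7.3, 42.0, 45.4),
    ("T2star", "sf", "deg"): (22.7, 5.1, 25.1, 25.1),
    ("T2star", "dp", "deg"): (21.7, 6.0, 20.0, 22.1),
}

# Whole-sample (ECS) unloaded reference statistics per parameter and group
# (ms).  The ECS mean is pixel-weighted over both zones in the reference
# cohort and is therefore tabulated separately from the zonal values above.
ECS_REFERENCE = {
    ("T1", "int"): (734.5, 121.3),
    ("T1", "deg"): (777.0, 104.0),
    ("T1rho", "int"): (101.5, 16.8),
    ("T1rho", "deg"): (98.4, 16.2),
    ("T2", "int"): (40.8, 5.4),
    ("T2", "deg"): (43.1, 7.8),
    ("T2star", "int"): (22.0, 4.3),
    ("T2star", "deg"): (22.0, 4.3),
}

# Group-wise Young's modulus mean/SD (MPa) and histology sum-score ranges.
_YM_REFERENCE = {"int": (0.55, 0.31), "deg": (0.35, 0.34)}
_MSS_RANGES = {"int": (0, 4), "deg": (5, 8)}

# Mean fractional height change under loading.
_HEIGHT_FACTORS = {"d0": 1.0, "d2.5": 1.0 - 0.061, "d5.0": 1.0 - 0.156}

_SUBSCORE_ORDER = ("structure", "cellularity", "proteoglycan", "tidemark")


@dataclass(frozen=True)
class ZonalDistribution:
    """Unloaded mean +/- SD and multiplicative loading shift factors."""

    mean: float
    sd: float
    shift_d25: float
    shift_d50: float

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd < 0:
            raise ValueError("mean must be positive and SD non-negative")
        if self.shift_d25 <= 0 or self.shift_d50 <= 0:
            raise ValueError("shift factors must be positive")

    def shifted_mean(self, displacement: str) -> float:
        return self.mean * {"d0": 1.0, "d2.5": self.shift_d25, "d5.0": self.shift_d50}[
            displacement
        ]


def _default_distributions() -> dict:
    return {
        key: ZonalDistribution(m0, sd, m25 / m0, m50 / m0)
        for key, (m0, sd, m25, m50) in _ZONAL_REFERENCE.items()
    }


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    With the default settings the cohort reproduces the reference group
    statistics (27 intact / 22 degenerative samples, zonal means and SDs,
    loading shifts, height loss).  A fixed seed makes the cohort
    byte-identical across runs.
    """

    n_int: int = 27
    n_deg: int = 22
    distributions: dict = field(default_factory=_default_distributions)
    width_mm: float = 8.0
    height_mm_mean: float = 3.0
    height_mm_sd: float = 0.0
    height_factors: dict = field(default_factory=lambda: dict(_HEIGHT_FACTORS))
    s0: float = 1000.0
    noise_sigma: float = 20.0  # disc SNR ~ 50 at S0
    measurement_cv: float = 0.05  # zonal-mean noise of the table-level simulator
    ym_stats: dict = field(default_factory=lambda: dict(_YM_REFERENCE))
    mss_ranges: dict = field(default_factory=lambda: dict(_MSS_RANGES))
    stress_noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_int < 0 or self.n_deg < 0:
            raise ValueError("group sizes must be non-negative")
        if self.noise_sigma < 0 or self.measurement_cv < 0:
            raise ValueError("noise levels must be non-negative")

    @classmethod
    def zero_noise(cls, n_int: int = 27, n_deg: int = 22, **kw) -> "CohortConfig":
        """Degenerate configuration: zero SDs and zero noise everywhere.

        Every downstream estimate must then recover the configured means
        exactly.
        """
        dists = {
            key: replace(d, sd=0.0) for key, d in _default_distributions().items()
        }
        ym = {g: (m, 0.0) for g, (m, _) in _YM_REFERENCE.items()}
        return cls(
            n_int=n_int,
            n_deg=n_deg,
            distributions=dists,
            height_mm_sd=0.0,
            noise_sigma=0.0,
            measurement_cv=0.0,
            ym_stats=ym,
            stress_noise_sd=0.0,
            **kw,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["distributions"] = {
            "|".join(k): list(dataclasses.astuple(v))
            for k, v in self.distributions.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "distributions" in d:
            d["distributions"] = {
                tuple(k.split("|")): ZonalDistribution(*v)
                for k, v in d["distributions"].items()
            }
        if "ym_stats" in d:
            d["ym_stats"] = {g: tuple(v) for g, v in d["ym_stats"].items()}
        if "mss_ranges" in d:
            d["mss_ranges"] = {g: tuple(v) for g, v in d["mss_ranges"].items()}
        return cls(**d)


@dataclass
class StressStrainCurve:
    """Unconfined-compression curve on a monotone strain grid (max 21%)."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape:
            raise ValueError("strain and stress must have equal length")
        if np.any(np.diff(self.strain) <= 0):
            raise ValueError("strain must be strictly increasing")
        if self.strain.max() > 0.21 + 1e-12:
            raise ValueError("maximum strain exceeds 21%")
        if np.any(self.stress < 0):
            raise ValueError("stress must be non-negative")


@dataclass
class GroundTruthPhantom:
    """Ground truth for one synthetic sample.

    ``true_fields`` maps ``(parameter, zone, displacement)`` to the true
    relaxation time in ms.  ``height_mm`` is the unloaded disc height;
    loaded heights follow from ``height_factors``.
    """

    sample_id: str
    group: str
    mss_subscores: HistologyScore
    width_mm: float
    height_mm: float
    true_fields: dict
    height_factors: dict = field(default_factory=lambda: dict(_HEIGHT_FACTORS))
    proton_density: float = 1000.0
    noise_sigma: float = 20.0
    young_modulus_true: float = 0.46
    displacement: str = "d0"

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("geometry must be positive")
        if any(v <= 0 for v in self.true_fields.values()):
            raise ValueError("all true time constants must be positive")
        f = self.height_factors
        if not f["d0"] >= f["d2.5"] >= f["d5.0"] > 0:
            raise ValueError("height must be non-increasing across displacements")
        expected = "int" if self.mss_subscores.mss <= 4 else "deg"
        if self.mss_subscores.mss > 8 or self.group != expected:
            raise ValueError(
                f"group {self.group!r} inconsistent with sum score "
                f"{self.mss_subscores.mss}"
            )

    @property
    def mss(self) -> int:
        return self.mss_subscores.mss

    def height_at(self, displacement: str) -> float:
        return self.height_mm * self.height_factors[displacement]

    def true_value(self, parameter: str, zone: str, displacement: str | None = None) -> float:
        return self.true_fields[(parameter, zone, displacement or self.displacement)]


def _draw_truncated_normal(rng, mean: float, sd: float, lower: float) -> float:
    if sd == 0:
        return max(mean, lower)
    for _ in range(200):
        v = rng.normal(mean, sd)
        if v > lower:
            return float(v)
    return lower  # pathological configuration; clamp


def _draw_subscores(rng, lo: int, hi: int) -> HistologyScore:
    """Draw a target sum uniformly in [lo, hi] and spread it over subscores."""
    target = int(rng.integers(lo, hi + 1))
    counts = {name: 0 for name in _SUBSCORE_ORDER}
    caps = {name: SUBSCORE_RANGES[name][1] for name in _SUBSCORE_ORDER}
    for _ in range(target):
        open_names = [n for n in _SUBSCORE_ORDER if counts[n] < caps[n]]
        counts[str(rng.choice(open_names))] += 1
    return HistologyScore(**counts)


def sample_truth(
    config: CohortConfig, group: str, rng: np.random.Generator, sample_id: str = "s0"
) -> GroundTruthPhantom:
    """Draw one phantom's ground truth from the configured group distributions.

    Zonal base values are drawn from the unloaded normal distributions
    (truncated at positivity); loaded truths apply the configured
    multiplicative shift factors to the same base draw, so every sample has
    a coherent within-sample loading response.

    Raises
    ------
    KeyError
        For an unknown group label.
    """
    if group not in GROUPS:
        raise KeyError(f"unknown group label {group!r}")
    fields = {}
    for param in PARAMETERS:
        for zone in ZONES:
            dist = config.distributions[(param, zone, group)]
            base = _draw_truncated_normal(rng, dist.mean, dist.sd, lower=1.0)
            fields[(param, zone, "d0")] = base
            fields[(param, zone, "d2.5")] = base * dist.shift_d25
            fields[(param, zone, "d5.0")] = base * dist.shift_d50
    lo, hi = config.mss_ranges[group]
    subscores = _draw_subscores(rng, lo, hi)
    ym_mean, ym_sd = config.ym_stats[group]
    ym = _draw_truncated_normal(rng, ym_mean, ym_sd, lower=0.02)
    height = _draw_truncated_normal(
        rng, config.height_mm_mean, config.height_mm_sd, lower=0.5
    )
    return GroundTruthPhantom(
        sample_id=sample_id,
        group=group,
        mss_subscores=subscores,
        width_mm=config.width_mm,
        height_mm=height,
        true_fields=fields,
        height_factors=dict(config.height_factors),
        proton_density=config.s0,
        noise_sigma=config.noise_sigma,
        young_modulus_true=ym,
    )


def deform(truth: GroundTruthPhantom, displacement: str) -> GroundTruthPhantom:
    """Return the phantom at a loading position.

    The disc height scales by the configured mean fractional change (width
    unchanged) and true-value lookups switch to the displacement's values.
    ``"d0"`` is the identity.
    """
    if displacement not in DISPLACEMENTS:
        raise KeyError(f"unknown displacement label {displacement!r}")
    out = replace(truth)
    out.height_mm = truth.height_at(displacement)
    factor = truth.height_factors[displacement]
    out.height_factors = {d: truth.height_factors[d] / factor for d in DISPLACEMENTS}
    out.displacement = displacement
    return out


def _disc_mask(
    grid: tuple[int, int], spacing: float, width_mm: float, height_mm: float
) -> np.ndarray:
    """Stadium-shaped disc mask (rectangle with rounded ends), centered."""
    rows, cols = grid
    y = (np.arange(rows) - (rows - 1) / 2.0)[:, None] * spacing  # depth
    x = (np.arange(cols) - (cols - 1) / 2.0)[None, :] * spacing  # width
    h2 = height_mm / 2.0
    half_flat = max(width_mm / 2.0 - h2, 0.0)
    core = (np.abs(x) <= half_flat) & (np.abs(y) <= h2)
    cap = (np.abs(x) - half_flat) ** 2 + y**2 <= h2**2
    return core | (cap & (np.abs(x) > half_flat))


# Silicone rendering: constant hypointense level relative to S0, plus a
# band of this thickness (mm) around the disc.
_SILICONE_LEVEL = 0.06
_SILICONE_BAND_MM = 1.5


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return signal
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def render_series(
    truth: GroundTruthPhantom,
    protocol: AcquisitionProtocol,
    displacement: str,
    rng: np.random.Generator,
) -> tuple[ImageSeries, np.ndarray, np.ndarray]:
    """Render one serial magnitude image stack at a loading position.

    Returns ``(series, disc_mask, zone_labels)`` where ``zone_labels`` is 0
    for background/silicone, 1 for the superficial and 2 for the deep zone
    of the *uneroded* ground-truth disc mask.  Disc pixels follow the
    sequence's signal model with the zone's true time constant; silicone is
    rendered as a hypointense rim; Rician noise is applied per image.
    """
    deformed = deform(truth, displacement)
    spacing = protocol.pixel_spacing
    mask = _disc_mask(protocol.grid, spacing, deformed.width_mm, deformed.height_mm)
    if not mask.any():
        raise ValueError("deformed disc does not cover any pixel")
    roi = roizones.split_zones(mask, surface_side="bottom", pixel_spacing=spacing)
    zone_labels = np.zeros(protocol.grid, dtype=np.uint8)
    zone_labels[roi.sf_mask] = 1
    zone_labels[roi.dp_mask] = 2

    silicone = _disc_mask(
        protocol.grid,
        spacing,
        deformed.width_mm + 2 * _SILICONE_BAND_MM,
        deformed.height_mm + 2 * _SILICONE_BAND_MM,
    ) & ~mask

    s0 = deformed.proton_density
    times = np.asarray(protocol.time_points)
    stack = np.zeros((times.size,) + protocol.grid)
    for zone, zmask in (("sf", roi.sf_mask), ("dp", roi.dp_mask)):
        tc = deformed.true_value(protocol.kind, zone, displacement)
        if protocol.kind == "T1":
            sig = signal_ir(times, s0, tc, protocol.repetition_time)
        else:
            sig = signal_monoexp(times, s0, tc)
        stack[:, zmask] = sig[:, None]
    stack[:, silicone] = _SILICONE_LEVEL * s0
    stack = _rician(stack, deformed.noise_sigma, rng)
    series = ImageSeries(
        data=stack,
        protocol=protocol,
        sample_id=deformed.sample_id,
        displacement=displacement,
    )
    return series, mask, zone_labels


@dataclass
class Cohort:
    """A generated cohort bundle."""

    config: CohortConfig
    phantoms: list
    protocols: dict
    series: dict  # (sample_id, kind, displacement) -> (ImageSeries, mask, zones)
    curves: dict  # sample_id -> StressStrainCurve
    metadata: pd.DataFrame


def synth_stress_strain(
    e_true: float,
    noise_sd: float,
    rng: np.random.Generator,
    n_points: int = 43,
) -> StressStrainCurve:
    """Linear stress-strain curve on a 0-21% strain grid with additive noise.

    Raises
    ------
    ValueError
        For non-positive true modulus.
    """
    if e_true <= 0:
        raise ValueError("true modulus must be positive")
    strain = np.linspace(0.0, 0.21, n_points)
    stress = e_true * strain
    if noise_sd > 0:
        stress = np.clip(stress + rng.normal(0.0, noise_sd, strain.shape), 0.0, None)
    return StressStrainCurve(strain=strain, stress=stress)


def _metadata_frame(phantoms, curves) -> pd.DataFrame:
    rows = []
    for ph in phantoms:
        rows.append(
            {
                "sample_id": ph.sample_id,
                "group": ph.group,
                "mss": ph.mss,
                "mss_structure": ph.mss_subscores.structure,
                "mss_cellularity": ph.mss_subscores.cellularity,
                "mss_proteoglycan": ph.mss_subscores.proteoglycan,
                "mss_tidemark": ph.mss_subscores.tidemark,
                "width_mm": ph.width_mm,
                "height_mm": ph.height_mm,
                "ym_true": ph.young_modulus_true,
            }
        )
    cols = [
        "sample_id", "group", "mss", "mss_structure", "mss_cellularity",
        "mss_proteoglycan", "mss_tidemark", "width_mm", "height_mm", "ym_true",
    ]
    return pd.DataFrame(rows, columns=cols)


def generate_cohort(config: CohortConfig, render_images: bool = True) -> Cohort:
    """Generate a full cohort: phantoms, serial image series, curves, metadata.

    Deterministic under the config seed.  With ``render_images=False`` only
    the ground truths, curves and metadata are produced (cheap for large
    statistical simulations).
    """
    rng = np.random.default_rng(config.seed)
    protocols = make_protocols()
    phantoms = []
    for group, n in (("int", config.n_int), ("deg", config.n_deg)):
        for i in range(n):
            sid = f"{group}{i:03d}"
            phantoms.append(sample_truth(config, group, rng, sample_id=sid))
    series = {}
    if render_images:
        for ph in phantoms:
            for kind, protocol in protocols.items():
                for disp in DISPLACEMENTS:
                    series[(ph.sample_id, kind, disp)] = render_series(
                        ph, protocol, disp, rng
                    )
    curves = {
        ph.sample_id: synth_stress_strain(
            ph.young_modulus_true, config.stress_noise_sd, rng
        )
        for ph in phantoms
    }
    return Cohort(
        config=config,
        phantoms=phantoms,
        protocols=protocols,
        series=series,
        curves=curves,
        metadata=_metadata_frame(phantoms, curves),
    )


def simulate_measured_records(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> list[SampleRecord]:
    """Table-level cohort simulation bypassing the imaging chain.

    Draws per-sample ground truths and perturbs each zonal mean with
    multiplicative log-normal measurement noise (``config.measurement_cv``),
    standing in for the Rician-noise fit + zonal averaging chain at a tiny
    fraction of its cost.  Used for large repeated statistical simulations;
    the full imaging chain is exercised by :func:`generate_cohort`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records = []
    for group, n in (("int", config.n_int), ("deg", config.n_deg)):
        for i in range(n):
            sid = f"{group}{i:03d}"
            ph = sample_truth(config, group, rng, sample_id=sid)
            means, counts = {}, {}
            for param in PARAMETERS:
                for disp in DISPLACEMENTS:
                    zvals = {}
                    for zone in ZONES:
                        v = ph.true_value(param, zone, disp)
                        if config.measurement_cv > 0:
                            v *= np.exp(rng.normal(0.0, config.measurement_cv))
                        zvals[zone] = v
                        means[(param, zone, disp)] = v
                        counts[(param, zone, disp)] = 54
                    means[(param, "ECS", disp)] = 0.5 * (zvals["sf"] + zvals["dp"])
                    counts[(param, "ECS", disp)] = 108
            curve = synth_stress_strain(
                ph.young_modulus_true, config.stress_noise_sd, rng
            )
            records.append(
                SampleRecord(
                    sample_id=sid,
                    group=group,
                    mss=ph.mss,
                    zonal_means=means,
                    zonal_counts=counts,
                    heights={d: ph.height_at(d) for d in DISPLACEMENTS},
                    widths={d: ph.width_mm for d in DISPLACEMENTS},
                    young_modulus=young_modulus(curve),
                )
            )
    return records
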