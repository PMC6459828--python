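"""Signal models and pixel-wise mono-exponential relaxometry fitting.

Produces spatially resolved T1, T1rho, T2 and T2* maps from serial magnitude
image stacks.  Fitting follows the mapping conventions used throughout:

* T1rho, T2, T2*: two-parameter mono-exponential decay ``S0 * exp(-t/Tc)``
  fitted by trust-region nonlinear least squares with a log-linear seed.
* T1: three-parameter magnitude inversion recovery
  ``|A + B * exp(-TI/T1)|`` fitted with a polarity-restoring grid seed.

Per-pixel quality control uses the coefficient of determination adjusted for
the degrees of freedom; pixels below the threshold (default 0.7) are flagged
invalid rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from cartiq.protocols import AcquisitionProtocol, ProtocolError, select_times

__all__ = [
    "ImageSeries",
    "PixelFit",
    "ParameterMap",
    "signal_monoexp",
    "signal_ir",
    "adjusted_r2",
    "fit_pixel",
    "fit_map",
    "DEFAULT_R2_THRESHOLD",
    "TC_BOUNDS_MS",
]

#: Validity threshold on the adjusted coefficient of determination.
DEFAULT_R2_THRESHOLD = 0.7

#: Search bounds for all fitted time constants, ms.
TC_BOUNDS_MS = (1.0, 5000.0)

_MAX_ITER = 200


@dataclass
class ImageSeries:
    """A stack of 2-D magnitude images over one protocol's time points.

    ``data`` has shape ``(n_time_points, rows, cols)`` and is aligned with
    ``protocol.time_points``.
    """

    data: np.ndarray
    protocol: AcquisitionProtocol
    sample_id: str = ""
    displacement: str = "d0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("series data must be 3-D (time, rows, cols)")
        if self.data.shape[0] != self.protocol.n_points:
            raise ValueError(
                f"stack length {self.data.shape[0]} does not match the "
                f"protocol's {self.protocol.n_points} time points"
            )
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")

    @property
    def pixel_spacing(self) -> float:
        return self.protocol.pixel_spacing

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class PixelFit:
    """Result of fitting one pixel's signal curve."""

    time_constant: float
    amplitude: float
    offset: float
    adjusted_r2: float
    valid: bool
    n_points_used: int


@dataclass
class ParameterMap:
    """A fitted relaxation-time map with validity and quality layers.

    ``values`` holds the fitted time constant in ms where ``valid`` is True
    and NaN elsewhere (including outside the fitted mask).
    """

    kind: str
    values: np.ndarray
    valid: np.ndarray
    r2: np.ndarray
    mask: np.ndarray
    sample_id: str = ""
    displacement: str = "d0"
    r2_threshold: float = DEFAULT_R2_THRESHOLD

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def signal_monoexp(t, s0, tc):
    """Mono-exponential decay ``S0 * exp(-t / Tc)``.

    Raises
    ------
    ValueError
        If ``tc`` is not positive.
    """
    if np.any(np.asarray(tc) <= 0):
        raise ValueError("time constant must be positive")
    return s0 * np.exp(-np.asarray(t, dtype=float) / tc)


def signal_ir(ti, s0, t1, tr):
    """Magnitude inversion-recovery signal with finite-TR recovery.

    ``|S0 * (1 - 2 exp(-TI/T1) + exp(-TR/T1))|``

    Raises
    ------
    ValueError
        If ``t1`` is not positive.
    """
    if np.any(np.asarray(t1) <= 0):
        raise ValueError("T1 must be positive")
    ti = np.asarray(ti, dtype=float)
    return np.abs(s0 * (1.0 - 2.0 * np.exp(-ti / t1) + np.exp(-tr / t1)))


def adjusted_r2(observed, predicted, n_params: int) -> float:
    """Coefficient of determination adjusted for the degrees of freedom.

    ``1 - (1 - R^2) * (n - 1) / (n - n_params - 1)``

    Returns NaN for degenerate input (constant observed vector).
    """
    y = np.asarray(observed, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if y.shape != f.shape:
        raise ValueError("observed and predicted must have equal length")
    n = y.size
    if n <= n_params + 1:
        raise ValueError("need more observations than parameters plus one")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((y - f) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def _invalid_fit(n_used: int) -> PixelFit:
    return PixelFit(
        time_constant=float("nan"),
        amplitude=float("nan"),
        offset=float("nan"),
        adjusted_r2=float("nan"),
        valid=False,
        n_points_used=n_used,
    )


def _fit_monoexp(t: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Two-parameter decay fit; returns (Tc, S0, predicted)."""
    lo, hi = TC_BOUNDS_MS
    # log-linear seed on the positive part of the signal
    ypos = np.clip(y, max(1e-12, 1e-9 * max(y.max(), 1.0)), None)
    slope, intercept = np.polyfit(t, np.log(ypos), 1)
    tc0 = -1.0 / slope if slope < 0 else hi / 2
    tc0 = float(np.clip(tc0, lo * 1.01, hi * 0.99))
    s0_0 = float(max(np.exp(intercept), y.max(), 1e-9))

    def resid(p):
        return p[0] * np.exp(-t / p[1]) - y

    sol = least_squares(
        resid,
        x0=[s0_0, tc0],
        bounds=([0.0, lo], [np.inf, hi]),
        method="trf",
        max_nfev=_MAX_ITER,
    )
    s0, tc = sol.x
    return float(tc), float(s0), s0 * np.exp(-t / tc)


def _fit_ir(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    """Three-parameter magnitude IR fit ``|A + B exp(-TI/T1)|``.

    Polarity restoration: for every candidate null index j the first j
    samples are sign-flipped and (A, B) solved linearly; the best (T1, j)
    pair over a log-spaced T1 grid seeds the nonlinear refinement.

    Returns (T1, A, B, predicted).
    """
    lo, hi = TC_BOUNDS_MS
    n = t.size
    grid = np.geomspace(lo * 2, hi / 2, 40)
    best = None
    for t1 in grid:
        e = np.exp(-t / t1)
        design = np.column_stack([np.ones(n), e])
        for j in range(n + 1):
            ys = y.copy()
            ys[:j] *= -1.0
            coef, *_ = np.linalg.lstsq(design, ys, rcond=None)
            pred = np.abs(design @ coef)
            sse = float(np.sum((pred - y) ** 2))
            if best is None or sse < best[0]:
                best = (sse, t1, coef[0], coef[1])
    _, t1_0, a0, b0 = best

    def resid(p):
        return np.abs(p[0] + p[1] * np.exp(-t / p[2])) - y

    sol = least_squares(
        resid,
        x0=[a0, b0, float(np.clip(t1_0, lo * 1.01, hi * 0.99))],
        bounds=([-np.inf, -np.inf, lo], [np.inf, np.inf, hi]),
        method="trf",
        max_nfev=_MAX_ITER,
    )
    a, b, t1 = sol.x
    pred = np.abs(a + b * np.exp(-t / t1))
    return float(t1), float(a), float(b), pred


def fit_pixel(
    signal,
    protocol: AcquisitionProtocol,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> PixelFit:
    """Fit one pixel's signal curve with the kind-appropriate model.

    The protocol's exclusion rules are applied internally, so ``signal``
    must be aligned with the *full* ``protocol.time_points``.  Degenerate
    signals (all zero, constant), non-convergence and time constants pinned
    at the search bounds yield an invalid :class:`PixelFit` — never an
    exception.
    """
    y_full = np.asarray(signal, dtype=float)
    if y_full.size != protocol.n_points:
        raise ValueError(
            f"signal length {y_full.size} does not match protocol "
            f"({protocol.n_points} points)"
        )
    times, idx = select_times(protocol)
    t = np.asarray(times, dtype=float)
    y = y_full[list(idx)]
    n_used = t.size

    if not np.all(np.isfinite(y)) or np.allclose(y, y[0]):
        return _invalid_fit(n_used)

    try:
        if protocol.kind == "T1":
            tc, a, b, pred = _fit_ir(t, y)
            amplitude, offset, n_params = -b / 2.0, a, 3
        else:
            tc, s0, pred = _fit_monoexp(t, y)
            amplitude, offset, n_params = s0, 0.0, 2
    except Exception:
        return _invalid_fit(n_used)

    ar2 = adjusted_r2(y, pred, n_params)
    lo, hi = TC_BOUNDS_MS
    at_bound = tc <= lo * 1.0001 or tc >= hi * 0.9999
    valid = bool(np.isfinite(ar2) and ar2 >= r2_threshold and not at_bound and tc > 0)
    return PixelFit(
        time_constant=tc,
        amplitude=amplitude,
        offset=offset,
        adjusted_r2=ar2,
        valid=valid,
        n_points_used=n_used,
    )


def fit_map(
    series: ImageSeries,
    mask: np.ndarray,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> ParameterMap:
    """Fit every masked pixel of a series, producing a parameter map.

    Identical signal vectors are fitted once and cached, which makes
    noiseless piecewise-constant phantoms essentially free.

    Raises
    ------
    ValueError
        If the mask is empty or its shape does not match the series grid.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.shape:
        raise ValueError("mask shape does not match series grid")
    if not mask.any():
        raise ValueError("mask is empty")

    values = np.full(mask.shape, np.nan)
    valid = np.zeros(mask.shape, dtype=bool)
    r2 = np.full(mask.shape, np.nan)
    cache: dict[bytes, PixelFit] = {}
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        y = np.ascontiguousarray(series.data[:, r, c])
        key = y.tobytes()
        fit = cache.get(key)
        if fit is None:
            fit = fit_pixel(y, series.protocol, r2_threshold)
            cache[key] = fit
        r2[r, c] = fit.adjusted_r2
        if fit.valid:
            values[r, c] = fit.time_constant
            valid[r, c] = True
    return ParameterMap(
        kind=series.protocol.kind,
        values=values,
        valid=valid,
        r2=r2,
        mask=mask,
        sample_id=series.sample_id,
        displacement=series.displacement,
        r2_threshold=r2_threshold,
    )
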