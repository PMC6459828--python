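"""Acquisition protocols for the four quantitative MRI sequences.

Each protocol carries the ordered measurement time points (inversion times,
spin-lock durations, or echo times, all in ms), the repetition time, and the
reconstruction geometry shared by all sequences (30 mm field of view on an
80 x 80 grid, i.e. 0.375 mm pixels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "ProtocolError",
    "make_protocols",
    "select_times",
    "KINDS",
]

#: Recognised sequence kinds, keyed by the parameter they measure.
KINDS = ("T1", "T1rho", "T2", "T2star")

#: Minimum number of time points a fit needs after exclusion rules.
MIN_POINTS = 3

#: Echo times above this value (ms) are excluded for T2/T2* fitting.
TE_CUTOFF_MS = 60.0


class ProtocolError(ValueError):
    """Raised for invalid protocol definitions or unusable time-point sets."""


@dataclass(frozen=True)
class AcquisitionProtocol:
    """A qMRI sequence protocol.

    Parameters
    ----------
    kind
        One of ``"T1"`` (inversion recovery), ``"T1rho"`` (spin-lock),
        ``"T2"`` (multi-spin echo), ``"T2star"`` (multi-gradient echo).
    time_points
        Ordered measurement times in ms (TI, TSL or TE depending on kind).
    repetition_time
        Sequence TR in ms; enters the signal model only for inversion
        recovery.
    fov_mm
        In-plane field of view (square), mm.
    grid
        Reconstruction matrix (rows, cols).
    """

    kind: str
    time_points: tuple[float, ...]
    repetition_time: float
    fov_mm: float = 30.0
    grid: tuple[int, int] = (80, 80)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ProtocolError(f"unknown sequence kind {self.kind!r}")
        tp = np.asarray(self.time_points, dtype=float)
        if tp.ndim != 1 or tp.size == 0:
            raise ProtocolError("time_points must be a non-empty 1-D sequence")
        if np.any(tp < 0):
            raise ProtocolError("time_points must be non-negative")
        if np.any(np.diff(tp) <= 0):
            raise ProtocolError("time_points must be strictly increasing")

    @property
    def pixel_spacing(self) -> float:
        """In-plane pixel spacing in mm (FOV / grid columns)."""
        return self.fov_mm / self.grid[1]

    @property
    def n_points(self) -> int:
        return len(self.time_points)


def make_protocols() -> dict[str, AcquisitionProtocol]:
    """Build the four default acquisition protocols.

    Returns
    -------
    dict
        Mapping kind -> :class:`AcquisitionProtocol`:

        * ``T1``: inversion recovery, 7 TIs (150-1500 ms), TR 3000 ms.
        * ``T1rho``: spin-lock, 5 TSLs (0-40 ms).
        * ``T2``: multi-spin echo, 8 TEs at n x 9.01 ms, n = 1..8.
        * ``T2star``: multi-gradient echo, 10 TEs at 2.84 + n x 4.54 ms,
          n = 0..9.
    """
    t1 = AcquisitionProtocol(
        kind="T1",
        time_points=(150.0, 300.0, 500.0, 800.0, 1000.0, 1300.0, 1500.0),
        repetition_time=3000.0,
    )
    t1rho = AcquisitionProtocol(
        kind="T1rho",
        time_points=(0.0, 10.0, 20.0, 30.0, 40.0),
        repetition_time=30.0,
    )
    t2 = AcquisitionProtocol(
        kind="T2",
        time_points=tuple(round(9.01 * n, 2) for n in range(1, 9)),
        repetition_time=1000.0,
    )
    t2star = AcquisitionProtocol(
        kind="T2star",
        time_points=tuple(round(2.84 + 4.54 * n, 2) for n in range(0, 10)),
        repetition_time=700.0,
    )
    return {"T1": t1, "T1rho": t1rho, "T2": t2, "T2star": t2star}


def select_times(
    protocol: AcquisitionProtocol,
) -> tuple[tuple[float, ...], tuple[int, ...]]:
    """Apply the per-kind time-point exclusion rules.

    All points are retained for T1 and T1rho.  For T2 and T2* the first echo
    is dropped (stimulated-echo / fitting inaccuracy) and so is every echo
    time above 60 ms (too low SNR).

    Returns
    -------
    (times, indices)
        The retained time points and their indices into
        ``protocol.time_points``, order preserved.

    Raises
    ------
    ProtocolError
        If fewer than three points survive.
    """
    tp = np.asarray(protocol.time_points, dtype=float)
    if protocol.kind in ("T1", "T1rho"):
        idx = np.arange(tp.size)
    else:
        keep = tp <= TE_CUTOFF_MS
        keep[0] = False
        idx = np.flatnonzero(keep)
    if idx.size < MIN_POINTS:
        raise ProtocolError(
            f"only {idx.size} usable time points remain for kind "
            f"{protocol.kind!r}; at least {MIN_POINTS} required"
        )
    return tuple(tp[idx]), tuple(int(i) for i in idx)
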