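"""Variable-flip-angle T1 estimation and signal-to-concentration conversion.

The spoiled gradient-echo signal at flip angle ``a`` is

    S(M0, a) = M0 sin(a) (1 - E1) / (1 - cos(a) E1),   E1 = exp(-TR / T1)

With exactly two flip angles the fit is determined and solved in closed
form (DESPOT1).  Post-contrast concentration uses the linearized
relationship

    c = (S_Gd - S0) / S0 / (r1 * T1_0)

which returns the superficial concentration (tracer amount per total
tissue volume) in mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionParams",
    "SignalSeries",
    "T1Map",
    "ConcentrationSeries",
    "spgr_signal",
    "fit_t1_vfa",
    "signal_to_concentration",
    "total_amount",
]


@dataclass
class AcquisitionParams:
    """Acquisition metadata for the FLASH / SPGR protocol.

    Parameters
    ----------
    tr : repetition time in ms.
    flip_angles : the two baseline flip angles in degrees (low, high);
        the high angle is also the imaging flip angle of the dynamic
        series.
    r1 : contrast-agent relaxivity in L/(mmol*ms).
    frame_times : acquisition times of the dynamic frames in minutes.
    """

    tr: float = 16.0
    flip_angles: tuple[float, float] = (3.0, 15.0)
    r1: float = 3.2e-3
    frame_times: np.ndarray = field(default_factory=lambda: np.arange(0.0, 90.0, 10.0))

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        lo, hi = self.flip_angles
        if lo == hi:
            raise ValueError("flip angles must be distinct")
        for a in (lo, hi):
            if not 0.0 < a < 90.0:
                raise ValueError(f"flip angle {a} outside (0, 90) degrees")
        if self.r1 <= 0:
            raise ValueError("relaxivity r1 must be positive")


@dataclass
class SignalSeries:
    """4D T1-weighted signal: dynamic frames plus two pre-contrast baselines.

    ``frames`` has shape ``(nx, ny, nz, nt)``; ``baselines`` maps flip
    angle (degrees) to a 3D volume on the same grid.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    baselines: dict[float, np.ndarray]
    voxel_size: float = 0.1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must be 4D (x, y, z, t)")
        if self.frames.shape[-1] != self.frame_times.size:
            raise ValueError("frame count does not match frame_times")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.frames.shape[:3]

    def baseline(self, angle: float) -> np.ndarray:
        for a, vol in self.baselines.items():
            if np.isclose(a, angle):
                return vol
        raise KeyError(f"no baseline at flip angle {angle}")


@dataclass
class T1Map:
    """Per-voxel pre-contrast T1 (ms) with a validity mask."""

    values: np.ndarray
    valid: np.ndarray
    m0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values/valid shape mismatch")


@dataclass
class ConcentrationSeries:
    """Per-voxel, per-frame superficial concentration (mM).

    Superficial concentration is pore concentration times porosity; no
    extra porosity factor is needed when integrating over tissue volume.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    voxel_size: float = 0.1
    porosity: float = 0.20
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must be 4D (x, y, z, t)")
        if self.frames.shape[-1] != self.frame_times.size:
            raise ValueError("frame count does not match frame_times")
        if np.any(np.diff(self.frame_times) < 0):
            raise ValueError("frame_times must be non-decreasing")
        if not 0.0 < self.porosity <= 1.0:
            raise ValueError("porosity must be in (0, 1]")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.frames.shape[:3]

    def frame_at(self, t: float) -> tuple[np.ndarray, float]:
        """Return the frame nearest to time ``t`` and its actual time."""
        i = int(np.argmin(np.abs(self.frame_times - t)))
        return self.frames[..., i], float(self.frame_times[i])


def spgr_signal(m0, t1_ms, alpha_deg: float, tr_ms: float):
    """Forward SPGR/FLASH signal for proton density ``m0`` and T1 (ms)."""
    m0 = np.asarray(m0, dtype=float)
    t1 = np.asarray(t1_ms, dtype=float)
    a = np.deg2rad(alpha_deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = np.exp(-tr_ms / t1)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)


def fit_t1_vfa(
    baseline_low: np.ndarray,
    baseline_high: np.ndarray,
    acq: AcquisitionParams,
) -> T1Map:
    """Closed-form two-point VFA (DESPOT1) T1 estimate.

    Rearranging the SPGR equation, the points (S/tan(a), S/sin(a)) lie on
    a line of slope E1 = exp(-TR/T1); with two angles the slope is exact.
    Voxels yielding non-physical E1 (<= 0 or >= 1), or with zero signal at
    both angles, are masked invalid rather than raising.
    """
    s_lo = np.asarray(baseline_low, dtype=float)
    s_hi = np.asarray(baseline_high, dtype=float)
    if s_lo.shape != s_hi.shape:
        raise ValueError("baseline shape mismatch")
    a_lo, a_hi = (np.deg2rad(a) for a in acq.flip_angles)

    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.stack([s_lo / np.tan(a_lo), s_hi / np.tan(a_hi)])
        y = np.stack([s_lo / np.sin(a_lo), s_hi / np.sin(a_hi)])
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]

    valid = np.isfinite(slope) & (slope > 0.0) & (slope < 1.0)
    t1 = np.full(s_lo.shape, np.nan)
    m0 = np.full(s_lo.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1[valid] = -acq.tr / np.log(slope[valid])
        m0[valid] = intercept[valid] / (1.0 - slope[valid])
    valid &= np.isfinite(t1) & (t1 > 0.0) & (t1 < 10000.0)
    t1[~valid] = np.nan
    return T1Map(values=t1, valid=valid, m0=m0)


def signal_to_concentration(
    series: SignalSeries,
    s0: np.ndarray,
    t1: T1Map,
    acq: AcquisitionParams,
    porosity: float = 0.20,
    clamp_negative: bool = False,
) -> ConcentrationSeries:
    """Convert dynamic signal to superficial gadoteridol concentration (mM).

    ``s0`` is the pre-contrast baseline at the imaging flip angle.  Voxels
    with invalid T1 or zero baseline are masked; negative concentrations
    from noise are retained unless ``clamp_negative``.
    """
    s0 = np.asarray(s0, dtype=float)
    if s0.shape != series.grid_shape:
        raise ValueError("s0 shape does not match series grid")
    if t1.values.shape != series.grid_shape:
        raise ValueError("T1 map shape does not match series grid")

    valid = t1.valid & (s0 > 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (series.frames - s0[..., None]) / s0[..., None]
        conc = rel / (acq.r1 * t1.values[..., None])
    conc[~valid] = 0.0
    conc[~np.isfinite(conc)] = 0.0
    if clamp_negative:
        conc = np.clip(conc, 0.0, None)
    return ConcentrationSeries(
        frames=conc,
        frame_times=series.frame_times,
        voxel_size=series.voxel_size,
        porosity=porosity,
        valid=valid,
    )


def total_amount(conc: ConcentrationSeries, brain_mask: np.ndarray) -> np.ndarray:
    """Total tracer amount per frame in µmol over the masked voxels.

    Superficial concentration in mM (µmol/L) times voxel volume in mm³
    gives nmol; divided by 1000 to report µmol.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != conc.grid_shape:
        raise ValueError("mask shape does not match concentration grid")
    if not mask.any():
        raise ValueError("empty brain mask")
    voxel_vol = conc.voxel_size ** 3  # mm^3
    sums = conc.frames[mask].sum(axis=0)  # mM * n_voxels
    return sums * voxel_vol / 1000.0  # nmol -> µmol
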