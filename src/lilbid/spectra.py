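"""Per-droplet mass-spectrum processing and % ssDNA.

One time-of-flight trace is recorded per droplet.  Processing follows the
fixed order calibrate -> smooth -> linearize -> integrate:

* two-point ToF calibration using the quadratic flight-time law
  m/z = a (t - t0)^2,
* moving-average smoothing over a fixed m/z range (default full width
  20 m/z),
* linear resampling onto a uniform m/z grid,
* peak integration between the flanking intensity minima with the area
  under the straight background chord subtracted.

The dissociation statistic is

    % ssDNA = 100 * A(35mer-) / (A(35mer-) + A(dsDNA-)),

computed from the singly charged anion peaks by default; the multi-charge
generalisation sums areas over the included charge states of each species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

PROTON_MASS = 1.008  # Da, for [M - zH]^z- m/z positions


def mz_of(mass_da: float, charge: int = 1) -> float:
    """m/z of the deprotonated anion [M - zH]^z-."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return (mass_da - charge * PROTON_MASS) / charge


@dataclass(frozen=True)
class RawTrace:
    """Two-column trace: strictly increasing abscissa vs intensity.

    ``abscissa`` is ``"tof"`` (uncalibrated flight time, arbitrary units)
    or ``"mz"`` (already calibrated).
    """

    x: np.ndarray
    intensity: np.ndarray
    abscissa: str = "tof"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if x.ndim != 1 or x.shape != y.shape or len(x) < 3:
            raise ValueError("trace needs >= 3 points with matching shapes")
        if not np.all(np.diff(x) > 0):
            raise ValueError("abscissa must be strictly increasing")
        if self.abscissa not in ("tof", "mz"):
            raise ValueError("abscissa must be 'tof' or 'mz'")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "intensity", y)


@dataclass(frozen=True)
class CalibratedSpectrum:
    """Intensity on a uniform m/z grid."""

    mz: np.ndarray
    intensity: np.ndarray
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if self.mz[0] <= 0:
            raise ValueError("m/z grid must be positive")


@dataclass(frozen=True)
class PeakAreaResult:
    species: str
    left_mz: float
    right_mz: float
    raw_integral: float
    background_integral: float
    net_area: float
    clipped: bool = False


def calibrate_two_point(
    trace: RawTrace,
    cal1: tuple[float, float],
    cal2: tuple[float, float],
) -> RawTrace:
    """Map flight times to m/z using two calibrant (time, m/z) points.

    sqrt(m/z) is linear in flight time, so the two points fix the law
    m/z = a (t - t0)^2.  Points with t <= t0 (where the law is not
    monotone) are dropped.
    """
    if trace.abscissa == "mz":
        return trace
    (t1, m1), (t2, m2) = cal1, cal2
    if t1 == t2:
        raise ValueError("calibration times must be distinct")
    if m1 <= 0 or m2 <= 0 or m1 == m2:
        raise ValueError("calibration m/z values must be distinct and positive")
    c = (np.sqrt(m2) - np.sqrt(m1)) / (t2 - t1)
    if c <= 0:
        raise ValueError("calibration points imply a non-positive ToF constant (a <= 0)")
    t0 = t1 - np.sqrt(m1) / c
    keep = trace.x > t0
    if keep.sum() < 3:
        raise ValueError("fewer than 3 points beyond the calibration origin t0")
    mz = (c * (trace.x[keep] - t0)) ** 2
    return RawTrace(x=mz, intensity=trace.intensity[keep], abscissa="mz")


def smooth_moving_average(trace: RawTrace, window: float = 20.0) -> RawTrace:
    """Boxcar smoothing over a fixed m/z range (full window width).

    Each point becomes the mean of all points within +/- window/2 on the
    m/z axis; near the edges the window shrinks symmetrically so the mean
    stays centred.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if trace.abscissa != "mz":
        raise ValueError("smoothing operates on a calibrated (m/z) abscissa")
    x, y = trace.x, trace.intensity
    half = np.minimum(window / 2.0, np.minimum(x - x[0], x[-1] - x))
    lo = np.searchsorted(x, x - half, side="left")
    hi = np.searchsorted(x, x + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(y)])
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return RawTrace(x=x, intensity=out, abscissa="mz")


def linearize(trace: RawTrace, step: float = 1.0) -> CalibratedSpectrum:
    """Resample onto a uniform m/z grid by linear interpolation (no extrapolation)."""
    if step <= 0:
        raise ValueError("step must be positive")
    if trace.abscissa != "mz":
        raise ValueError("linearization requires a calibrated (m/z) abscissa")
    x = trace.x
    n = int(np.floor((x[-1] - x[0]) / step)) + 1
    grid = x[0] + step * np.arange(n)
    return CalibratedSpectrum(mz=grid, intensity=np.interp(grid, x, trace.intensity), step=step)


def find_peak_bounds(
    spectrum: CalibratedSpectrum,
    center: float,
    search_halfwidth: float,
) -> tuple[float, float]:
    """Locate the background anchor points flanking a peak.

    Left bound = m/z of the intensity minimum in [center - hw, center];
    right bound = minimum in [center, center + hw].  For two overlapping
    peaks the shared valley minimum becomes the inner bound of each.  A
    window truncated by the spectrum edge raises a warning and anchors at
    the edge.
    """
    mz, y = spectrum.mz, spectrum.intensity
    if not mz[0] <= center <= mz[-1]:
        raise ValueError("peak center outside spectrum range")
    if search_halfwidth <= 0:
        raise ValueError("search_halfwidth must be positive")
    if center - search_halfwidth < mz[0] or center + search_halfwidth > mz[-1]:
        warnings.warn(
            "peak search window truncated by spectrum edge; bound set at edge",
            stacklevel=2,
        )
    li = np.searchsorted(mz, center - search_halfwidth, side="left")
    ci = int(np.searchsorted(mz, center))
    ri = np.searchsorted(mz, center + search_halfwidth, side="right") - 1
    left = int(li + np.argmin(y[li : ci + 1]))
    right = int(ci + np.argmin(y[ci : ri + 1]))
    return float(mz[left]), float(mz[right])


def integrate_peak(
    spectrum: CalibratedSpectrum,
    bounds: tuple[float, float],
    species: str = "",
) -> PeakAreaResult:
    """Trapezoidal peak area minus the area under the background chord.

    The background is the straight line joining the spectrum intensities
    at the two bounds; subtracting its trapezoid makes the net area
    invariant to constant offsets.  Negative net areas are clipped to 0
    and flagged.
    """
    left, right = bounds
    mz = spectrum.mz
    if left > right:
        raise ValueError("left bound must not exceed right bound")
    if left < mz[0] or right > mz[-1]:
        raise ValueError("bounds outside spectrum grid")
    i0 = int(np.searchsorted(mz, left, side="left"))
    i1 = int(np.searchsorted(mz, right, side="right") - 1)
    seg_mz, seg_y = mz[i0 : i1 + 1], spectrum.intensity[i0 : i1 + 1]
    if len(seg_mz) < 2:
        raw = bg = 0.0
    else:
        raw = float(np.trapezoid(seg_y, seg_mz))
        bg = float(0.5 * (seg_y[0] + seg_y[-1]) * (seg_mz[-1] - seg_mz[0]))
    net = raw - bg
    clipped = net < 0
    return PeakAreaResult(
        species=species,
        left_mz=float(seg_mz[0]) if len(seg_mz) else left,
        right_mz=float(seg_mz[-1]) if len(seg_mz) else right,
        raw_integral=raw,
        background_integral=bg,
        net_area=0.0 if clipped else net,
        clipped=clipped,
    )


def percent_ssdna(ss_areas: Sequence[float], ds_areas: Sequence[float]) -> float:
    """% ssDNA = 100 * sum(ss areas) / (sum(ss) + sum(ds)).

    One entry per included charge state of each species; the single-charge
    default uses one area per list.
    """
    ss = np.asarray(ss_areas, dtype=float)
    ds = np.asarray(ds_areas, dtype=float)
    if ss.size == 0 or ds.size == 0:
        raise ValueError("need at least one area per species")
    if (ss < 0).any() or (ds < 0).any():
        raise ValueError("areas must be non-negative")
    total = ss.sum() + ds.sum()
    if total == 0:
        raise ValueError("no signal: all peak areas are zero")
    return float(100.0 * ss.sum() / total)


@dataclass
class SpectrumParams:
    """Processing settings for one sample's spectra.

    Peak centers default to the theoretical [M - zH]^z- m/z of the 35mer
    scaffold and the duplex; the search halfwidth is a convention (the
    flanking-minimum rule, not the halfwidth, sets the bounds).
    """

    ss_mass_da: float
    ds_mass_da: float
    charge_states: tuple[int, ...] = (1,)
    smooth_window_mz: float = 20.0
    grid_step_mz: float = 1.0
    search_halfwidth_mz: float = 700.0
    cal1: tuple[float, float] | None = None  # (time, m/z)
    cal2: tuple[float, float] | None = None


def process_trace(trace: RawTrace, params: SpectrumParams) -> CalibratedSpectrum:
    """calibrate -> smooth -> linearize, in that fixed order."""
    if trace.abscissa == "tof":
        if params.cal1 is None or params.cal2 is None:
            raise ValueError("ToF trace requires two calibration points")
        trace = calibrate_two_point(trace, params.cal1, params.cal2)
    trace = smooth_moving_average(trace, params.smooth_window_mz)
    return linearize(trace, params.grid_step_mz)


def measure_percent_ssdna(
    spectrum: CalibratedSpectrum, params: SpectrumParams
) -> tuple[float, list[PeakAreaResult]]:
    """Integrate the ss and ds peaks at every configured charge state and
    return (% ssDNA, per-peak areas)."""
    results: list[PeakAreaResult] = []
    ss_areas, ds_areas = [], []
    for label, mass, sink in (
        ("ss", params.ss_mass_da, ss_areas),
        ("ds", params.ds_mass_da, ds_areas),
    ):
        for z in params.charge_states:
            center = mz_of(mass, z)
            bounds = find_peak_bounds(spectrum, center, params.search_halfwidth_mz)
            res = integrate_peak(spectrum, bounds, species=f"{label}{z}-")
            results.append(res)
            sink.append(res.net_area)
    return percent_ssdna(ss_areas, ds_areas), results
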