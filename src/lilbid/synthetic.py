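"""Synthetic droplet events with known ground truth.

The instrument records, per droplet, a snapshot of the explosive expansion
and one ToF mass spectrum, index-matched.  This module emulates both so
the whole analysis chain (width measurement, spectrum processing, curve
assembly, affinity models) can be exercised against a known truth:

* the plume is a filled ellipse "crown" over a vertical stem whose crown
  caliper width equals the requested width after the measurement pipeline
  (2x2 binning, threshold, top region, corner Feret) to within one binned
  pixel;
* the spectrum holds Gaussian [M - zH]^z- peaks for the 35mer single
  strand and the duplex over a constant baseline with additive Gaussian
  noise, with noiseless areas obeying 100*A_ss/(A_ss+A_ds) = pct_ss;
* the per-droplet % ssDNA follows a linear truth law in explosion width,
  clamped to [0, 100], with optional droplet-to-droplet scatter;
* total peak intensity decays beyond an optional falloff width, emulating
  the ion-optics signal loss seen above ~1200 µm.

Everything is reproducible bit-exactly from (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage.draw import ellipse as draw_ellipse

from .spectra import RawTrace, mz_of

# Raster intensity conventions (16-bit scale).  The margin between the
# half-covered binned block level (~23 500) and the threshold is wide
# relative to the binned noise, so the measured width is set by geometry,
# not by noise.
_BG_LEVEL = 2000.0
_FG_LEVEL = 45000.0
_IMAGE_NOISE_SD = 300.0
DEFAULT_IMAGE_THRESHOLD = 16000.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth study conditions for one simulated dissociation run.

    Defaults emulate one run on a mid-affinity duplex (the 10_Amer/35_Amer
    pair: single strand 10 823 Da, duplex 13 827 Da): ~300 droplets per
    curve, explosion widths spanning 400-1600 µm, % ssDNA rising linearly
    with width (60% at the 1.1 mm reference point), camera pitch 15 µm.
    """

    n_droplets: int = 300
    width_range: tuple[float, float] = (400.0, 1600.0)
    truth_slope: float = 0.07  # %ssDNA per µm
    truth_intercept: float = -17.0  # %ssDNA at width 0 (=> 60% at 1100 µm)
    ss_mass: float = 10823.0  # Da
    ds_mass: float = 13827.0  # Da
    charge_states: tuple[int, ...] = (1,)
    peak_width: float = 50.0  # m/z Gaussian sd
    baseline_level: float = 5.0  # intensity
    noise_sd: float = 2.0  # intensity, per spectrum sample
    pct_scatter_sd: float = 4.0  # droplet-to-droplet %ssDNA scatter
    intensity_falloff_width: float | None = 1200.0  # µm; None disables
    falloff_scale: float = 250.0  # µm e-folding of the falloff
    pixel_pitch: float = 15.0  # µm per raw camera pixel
    total_area: float = 5.0e4  # summed noiseless peak area (intensity * m/z)
    tof_a: float = 0.01  # m/z = tof_a * (t - tof_t0)^2
    tof_t0: float = 2.0
    abscissa: str = "tof"  # "tof" or "mz"
    mz_margin: float = 800.0  # baseline flanks beyond the outermost peaks
    seed: int = 0

    def truth_pct_ss(self, width_um):
        """Truth law: clamp(slope*w + intercept, 0, 100)."""
        return np.clip(self.truth_slope * np.asarray(width_um) + self.truth_intercept, 0.0, 100.0)

    def falloff_factor(self, width_um: float) -> float:
        if self.intensity_falloff_width is None or width_um <= self.intensity_falloff_width:
            return 1.0
        return float(np.exp(-(width_um - self.intensity_falloff_width) / self.falloff_scale))


@dataclass(frozen=True)
class DropletEvent:
    """One droplet's paired image and spectrum, keyed by droplet index."""

    index: int
    image: np.ndarray  # uint16 grayscale
    pixel_pitch: float  # µm per raw pixel
    trace: RawTrace
    true_width: float  # µm (synthetic ground truth)
    true_pct_ss: float  # % (value of the truth line at true_width)


def render_explosion_image(width: float, pixel_pitch: float, seed: int) -> np.ndarray:
    """Render a plume snapshot whose measured crown width equals ``width``.

    The crown is a filled ellipse whose horizontal caliper, measured by
    the imaging pipeline, lands within one binned pixel of ``width``; a
    narrower stem hangs below it.  Returns a 16-bit grayscale raster.
    """
    if width <= 0 or pixel_pitch <= 0:
        raise ValueError("width and pixel_pitch must be positive")
    if width < 4 * pixel_pitch:
        raise ValueError("unresolvable width: below 2 binned pixels")
    rng = np.random.default_rng(seed)
    # Semi-axis in raw pixels; the -0.4 offsets the half-pixel growth from
    # pixel-center rasterisation, corner-based Feret and 2x2 binning.
    a_px = width / (2.0 * pixel_pitch) - 0.4
    b_px = max(3.0, 0.30 * a_px)
    stem_half = max(2.0, 0.20 * a_px)
    stem_len = 1.5 * b_px
    r0 = int(np.ceil(b_px)) + 4
    cols = 2 * (int(np.ceil(a_px)) + 8)
    c0 = cols // 2  # even center column keeps binning alignment fixed
    rows = 2 * ((r0 + int(np.ceil(b_px + stem_len)) + 6) // 2 + 1)

    img = rng.normal(_BG_LEVEL, _IMAGE_NOISE_SD, size=(rows, cols))
    rr, cc = draw_ellipse(r0, c0, b_px, a_px, shape=(rows, cols))
    img[rr, cc] = _FG_LEVEL
    sr0, sr1 = r0, min(rows, int(r0 + b_px + stem_len))
    sc0, sc1 = int(c0 - stem_half), int(c0 + stem_half) + 1
    img[sr0:sr1, sc0:sc1] = _FG_LEVEL
    img += rng.normal(0.0, _IMAGE_NOISE_SD, size=img.shape) * (img >= _FG_LEVEL)
    return np.clip(img, 0, 65535).astype(np.uint16)


def synth_spectrum(
    pct_ss: float, config: SyntheticConfig, width: float, seed: int
) -> RawTrace:
    """Generate one raw droplet trace at a given dissociation fraction.

    Noiseless integrated areas satisfy 100*A_ss/(A_ss+A_ds) = pct_ss, with
    each species' area split equally across the configured charge states
    (equal relative response of ss and ds species is assumed throughout).
    """
    if not 0.0 <= pct_ss <= 100.0:
        raise ValueError("pct_ss must lie in [0, 100]")
    if config.peak_width <= 0:
        raise ValueError("peak_width must be positive")
    rng = np.random.default_rng(seed)
    scale = config.falloff_factor(width) * config.total_area
    nz = len(config.charge_states)
    peaks = []  # (center m/z, area)
    for z in config.charge_states:
        peaks.append((mz_of(config.ss_mass, z), scale * pct_ss / 100.0 / nz))
        peaks.append((mz_of(config.ds_mass, z), scale * (1.0 - pct_ss / 100.0) / nz))
    centers = [c for c, _ in peaks]
    mz_lo = min(centers) - config.mz_margin
    mz_hi = max(centers) + config.mz_margin
    n = int((mz_hi - mz_lo) / 0.7)

    if config.abscissa == "tof":
        t = np.linspace(
            config.tof_t0 + np.sqrt(mz_lo / config.tof_a),
            config.tof_t0 + np.sqrt(mz_hi / config.tof_a),
            n,
        )
        mz = config.tof_a * (t - config.tof_t0) ** 2
        x = t
    else:
        x = mz = np.linspace(mz_lo, mz_hi, n)

    sigma = config.peak_width
    intensity = np.full(n, config.baseline_level)
    for center, area in peaks:
        intensity += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((mz - center) / sigma) ** 2
        )
    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, size=n)
    return RawTrace(x=x, intensity=intensity, abscissa=config.abscissa)


def calibration_points(
    config: SyntheticConfig,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """(time, m/z) pairs at the singly charged ss and ds peak apexes,
    from the generator's ToF law — the two-point calibration input."""
    out = []
    for mass in (config.ss_mass, config.ds_mass):
        mz = mz_of(mass, 1)
        out.append((float(config.tof_t0 + np.sqrt(mz / config.tof_a)), float(mz)))
    return out[0], out[1]


def simulate_events(config: SyntheticConfig) -> list[DropletEvent]:
    """Simulate one dissociation run: paired image/spectrum per droplet.

    Widths are uniform over ``width_range``; each droplet's realised
    % ssDNA is the truth line plus Gaussian scatter (sd
    ``pct_scatter_sd``), clamped to [0, 100].
    """
    if config.n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    lo, hi = config.width_range
    if not hi > lo or lo <= 0:
        raise ValueError("width_range must be a positive, non-empty interval")
    rng = np.random.default_rng(config.seed)
    widths = rng.uniform(lo, hi, size=config.n_droplets)
    scatter = rng.normal(0.0, config.pct_scatter_sd, size=config.n_droplets)
    child_seeds = rng.integers(0, 2**31, size=(config.n_droplets, 2))
    events = []
    for i in range(config.n_droplets):
        w = float(widths[i])
        true_pct = float(config.truth_pct_ss(w))
        realised = float(np.clip(true_pct + scatter[i], 0.0, 100.0))
        events.append(
            DropletEvent(
                index=i,
                image=render_explosion_image(w, config.pixel_pitch, int(child_seeds[i, 0])),
                pixel_pitch=config.pixel_pitch,
                trace=synth_spectrum(realised, config, w, int(child_seeds[i, 1])),
                true_width=w,
                true_pct_ss=true_pct,
            )
        )
    return events


def write_events(events: list[DropletEvent], outdir: str | Path, config: SyntheticConfig) -> Path:
    """Write events to disk as the instrument would: 16-bit grayscale PNGs
    ``droplet_<n>.png``, two-column tab-separated spectra ``droplet_<n>.txt``
    with an ``# abscissa=`` header, and a manifest CSV.  Returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ev in events:
        img_name = f"droplet_{ev.index}.png"
        spec_name = f"droplet_{ev.index}.txt"
        iio.imwrite(outdir / img_name, ev.image)
        with open(outdir / spec_name, "w") as fh:
            fh.write(f"# abscissa={ev.trace.abscissa}\n")
            np.savetxt(fh, np.column_stack([ev.trace.x, ev.trace.intensity]), delimiter="\t")
        rows.append(
            {
                "index": ev.index,
                "image": img_name,
                "spectrum": spec_name,
                "true_width_um": ev.true_width,
                "true_pct_ss": ev.true_pct_ss,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)
    return manifest


def synth_melting_curve(
    tm: float,
    slope_param: float,
    t_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    a_lo: float = 0.5,
    a_hi: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-state UV melting curve: logistic absorbance step centred at the
    melting temperature, plus additive noise.

    A(T) = a_lo + (a_hi - a_lo) / (1 + exp(-(T - tm)/slope_param))
    """
    if slope_param <= 0:
        raise ValueError("slope_param must be positive")
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")
    a = a_lo + (a_hi - a_lo) / (1.0 + np.exp(-(t - tm) / slope_param))
    if noise_sd > 0:
        a = a + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(t))
    return t, a
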