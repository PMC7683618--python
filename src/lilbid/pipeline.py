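"""End-to-end orchestration: manifest -> widths -> % ssDNA -> ROI fit.

``run_pipeline`` is the file-based entry point (droplet PNGs + spectrum
text files listed in a manifest CSV, outputs written as CSV/JSON with the
full configuration embedded so every result is re-derivable).
``analyze_events`` is the in-memory equivalent used on simulated events.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import curves, imaging, spectra
from .synthetic import DEFAULT_IMAGE_THRESHOLD, DropletEvent

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to re-derive one dissociation-curve analysis."""

    manifest: str = ""
    output_dir: str = ""
    # imaging
    threshold: float = DEFAULT_IMAGE_THRESHOLD
    top_fraction: float = 0.5
    pixel_pitch_um: float = 15.0
    # spectra
    ss_mass_da: float = 10823.0
    ds_mass_da: float = 13827.0
    charge_states: tuple[int, ...] = (1,)
    smooth_window_mz: float = 20.0
    grid_step_mz: float = 1.0
    search_halfwidth_mz: float = 700.0
    cal1: tuple[float, float] | None = None  # (time, m/z)
    cal2: tuple[float, float] | None = None
    # curve
    roi_um: tuple[float, float] = curves.ROI_UM
    ref_width_um: float = curves.REF_WIDTH_UM
    seed: int = 0

    def spectrum_params(self) -> spectra.SpectrumParams:
        return spectra.SpectrumParams(
            ss_mass_da=self.ss_mass_da,
            ds_mass_da=self.ds_mass_da,
            charge_states=tuple(self.charge_states),
            smooth_window_mz=self.smooth_window_mz,
            grid_step_mz=self.grid_step_mz,
            search_halfwidth_mz=self.search_halfwidth_mz,
            cal1=self.cal1,
            cal2=self.cal2,
        )

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, (tuple, list)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return {k: plain(v) for k, v in dataclasses.asdict(self).items()}

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("charge_states", "roi_um", "cal1", "cal2"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def read_trace(path: str | Path) -> spectra.RawTrace:
    """Read a two-column spectrum text file with an ``# abscissa=`` header."""
    path = Path(path)
    abscissa = "tof"
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#") and "abscissa=" in first:
        abscissa = first.split("abscissa=")[1].strip()
    data = np.loadtxt(path)
    return spectra.RawTrace(x=data[:, 0], intensity=data[:, 1], abscissa=abscissa)


def _pct_for_trace(trace: spectra.RawTrace, params: spectra.SpectrumParams) -> float:
    spec = spectra.process_trace(trace, params)
    pct, _ = spectra.measure_percent_ssdna(spec, params)
    return pct


def analyze_events(events: list[DropletEvent], config: RunConfig) -> dict:
    """Run the full analysis on in-memory droplet events.

    Returns {"widths": DataFrame, "points": DataFrame, "fit": RoiFit}.
    Droplets failing a stage are logged with their index and skipped.
    """
    params = config.spectrum_params()
    widths, pcts = [], []
    for ev in events:
        try:
            widths.append(
                imaging.measure_explosion_width(
                    ev.image,
                    config.threshold,
                    ev.pixel_pitch,
                    config.top_fraction,
                    droplet_index=ev.index,
                )
            )
        except ValueError as exc:
            log.warning("droplet %d: width measurement failed (%s)", ev.index, exc)
        try:
            pcts.append((ev.index, _pct_for_trace(ev.trace, params)))
        except ValueError as exc:
            log.warning("droplet %d: spectrum processing failed (%s)", ev.index, exc)
    points = curves.assemble_curve(widths, pcts)
    roi_points = curves.filter_roi(points, config.roi_um)
    fit = curves.fit_and_interpolate(roi_points, config.ref_width_um, config.roi_um)
    wdf = pd.DataFrame(
        [
            (m.droplet_index, m.width_um, m.width_err_um, m.threshold, m.top_fraction)
            for m in widths
        ],
        columns=["droplet_index", "width_um", "width_err_um", "threshold", "top_fraction"],
    )
    return {"widths": wdf, "points": points, "fit": fit}


def run_pipeline(config: RunConfig) -> dict:
    """File-based pipeline: read the manifest, analyse every droplet, and
    write widths/points CSVs plus a JSON fit report into ``output_dir``."""
    manifest_path = Path(config.manifest)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    base = manifest_path.parent
    if "spectrum" not in manifest.columns or manifest["spectrum"].isna().all():
        raise ValueError("no spectra listed in manifest")
    if "image" not in manifest.columns or manifest["image"].isna().all():
        raise ValueError("no images listed in manifest")

    params = config.spectrum_params()
    widths, pcts = [], []
    for _, row in manifest.iterrows():
        idx = int(row["index"])
        try:
            img = iio.imread(base / row["image"])
            widths.append(
                imaging.measure_explosion_width(
                    img, config.threshold, config.pixel_pitch_um,
                    config.top_fraction, droplet_index=idx,
                )
            )
        except (ValueError, FileNotFoundError) as exc:
            log.warning("droplet %d: image stage failed (%s)", idx, exc)
        try:
            pcts.append((idx, _pct_for_trace(read_trace(base / row["spectrum"]), params)))
        except (ValueError, FileNotFoundError) as exc:
            log.warning("droplet %d: spectrum stage failed (%s)", idx, exc)

    points = curves.assemble_curve(widths, pcts)
    roi_points = curves.filter_roi(points, config.roi_um)
    fit = curves.fit_and_interpolate(roi_points, config.ref_width_um, config.roi_um)

    outdir = Path(config.output_dir) if config.output_dir else manifest_path.parent / "out"
    outdir.mkdir(parents=True, exist_ok=True)
    wdf = pd.DataFrame(
        [
            (m.droplet_index, m.width_um, m.width_err_um, m.threshold, m.top_fraction)
            for m in widths
        ],
        columns=["droplet_index", "width_um", "width_err_um", "threshold", "top_fraction"],
    )
    float_fmt = "%.6f"
    wdf.to_csv(outdir / "widths.csv", index=False, float_format=float_fmt)
    points.to_csv(outdir / "curve.csv", index=False, float_format=float_fmt)
    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_droplets": int(len(manifest)),
        "n_points": int(len(points)),
        "fit": dataclasses.asdict(fit),
    }
    with open(outdir / "fit_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    return report
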