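"""Dissociation-curve assembly, ROI fitting and replicate statistics.

A dissociation curve is the per-droplet scatter of % ssDNA against
explosion width for one run.  Within the region of interest (620-1200 µm)
dissociation grows approximately linearly with width, so the curve is
fitted by ordinary least squares and the fit is evaluated at the 1.1 mm
reference width; that interpolated value, with the standard error of the
fitted mean, is the run's binding-affinity readout.  Replicate runs are
summarised as mean +/- s.e.m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .imaging import WidthMeasurement

log = logging.getLogger(__name__)

ROI_UM = (620.0, 1200.0)
REF_WIDTH_UM = 1100.0


@dataclass(frozen=True)
class RoiFit:
    """Linear fit of % ssDNA vs width inside the ROI, evaluated at the
    reference width."""

    roi: tuple[float, float]
    n_points: int
    slope: float  # % per µm
    intercept: float  # %
    residual_sd: float
    ref_width: float
    pct_ss_at_ref: float
    pct_ss_se: float  # se of the fitted mean at ref_width
    clipped: bool = False  # True if pct_ss_at_ref was clipped into [0, 100]


@dataclass(frozen=True)
class SampleSummary:
    sample: str
    values: tuple[float, ...]
    mean: float
    sd: float
    sem: float
    n_replicates: int


def assemble_curve(
    widths: Iterable[WidthMeasurement],
    pct_ss: Iterable[tuple[int, float]],
) -> pd.DataFrame:
    """Inner-join width and % ssDNA measurements on droplet index.

    Returns a DataFrame (droplet_index, width_um, pct_ss).  Orphans on
    either side are logged, never silently dropped; duplicate indices are
    an error.
    """
    wdf = pd.DataFrame(
        [(w.droplet_index, w.width_um) for w in widths],
        columns=["droplet_index", "width_um"],
    )
    pdf = pd.DataFrame(list(pct_ss), columns=["droplet_index", "pct_ss"])
    for name, df in (("width", wdf), ("pct_ss", pdf)):
        if df["droplet_index"].duplicated().any():
            raise ValueError(f"duplicate droplet index in {name} list")
    merged = wdf.merge(pdf, on="droplet_index", how="inner")
    for name, df in (("spectrum", wdf), ("image", pdf)):
        orphans = set(df["droplet_index"]) - set(merged["droplet_index"])
        for idx in sorted(orphans):
            log.warning("droplet %d has no matching %s; dropped", idx, name)
    if merged.empty:
        raise ValueError("no droplet indices in common between widths and spectra")
    return merged.sort_values("droplet_index", ignore_index=True)


def filter_roi(points: pd.DataFrame, roi: tuple[float, float] = ROI_UM) -> pd.DataFrame:
    """Keep droplets whose width lies in the ROI (inclusive ends).

    Above ~1200 µm overall signal decays for instrumental reasons, so the
    analysis is defined only on the ROI.
    """
    lo, hi = roi
    kept = points[(points["width_um"] >= lo) & (points["width_um"] <= hi)]
    if len(kept) < 3:
        raise ValueError("insufficient ROI coverage: fewer than 3 droplets in ROI")
    return kept.reset_index(drop=True)


def fit_and_interpolate(
    points: pd.DataFrame,
    ref_width: float = REF_WIDTH_UM,
    roi: tuple[float, float] = ROI_UM,
) -> RoiFit:
    """Unweighted OLS of % ssDNA on width; evaluate at the reference width.

    The reported uncertainty is the standard error of the fitted mean,
    s * sqrt(1/n + (ref - wbar)^2 / Sxx), with s the residual sd — the
    error propagated from the linear fit, not a prediction interval.
    """
    w = points["width_um"].to_numpy(dtype=float)
    y = points["pct_ss"].to_numpy(dtype=float)
    n = len(w)
    if n < 3:
        raise ValueError("need at least 3 points for a fit")
    if np.unique(w).size < 2:
        raise ValueError("degenerate design: all widths identical")
    wbar = w.mean()
    sxx = float(((w - wbar) ** 2).sum())
    slope = float(((w - wbar) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * wbar)
    resid = y - (slope * w + intercept)
    s = float(np.sqrt((resid**2).sum() / (n - 2)))
    at_ref = slope * ref_width + intercept
    se = s * float(np.sqrt(1.0 / n + (ref_width - wbar) ** 2 / sxx))
    clipped = not 0.0 <= at_ref <= 100.0
    if clipped:
        log.warning("pct_ss_at_ref %.2f outside [0, 100]; clipped", at_ref)
    return RoiFit(
        roi=roi,
        n_points=n,
        slope=slope,
        intercept=intercept,
        residual_sd=s,
        ref_width=ref_width,
        pct_ss_at_ref=float(np.clip(at_ref, 0.0, 100.0)),
        pct_ss_se=se,
        clipped=clipped,
    )


def aggregate_replicates(
    fits: Sequence[RoiFit | float], sample: str = ""
) -> SampleSummary:
    """Mean, sample s.d. (n-1 denominator) and s.e.m. over replicate runs.

    Accepts RoiFit objects or bare % ssDNA values.  With a single
    replicate the spread statistics are NaN.
    """
    values = tuple(
        float(f.pct_ss_at_ref) if isinstance(f, RoiFit) else float(f) for f in fits
    )
    if len(values) == 0:
        raise ValueError("need at least one replicate")
    arr = np.asarray(values)
    n = len(arr)
    sd = float(arr.std(ddof=1)) if n > 1 else float("nan")
    return SampleSummary(
        sample=sample,
        values=values,
        mean=float(arr.mean()),
        sd=sd,
        sem=sd / np.sqrt(n) if n > 1 else float("nan"),
        n_replicates=n,
    )
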