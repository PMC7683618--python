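"""Explosion-width measurement from droplet snapshot images.

A droplet irradiated by the IR desorption pulse undergoes an explosive
expansion; a camera snapshot taken 5 µs later shows a bright plume whose
width tracks the laser energy transferred to the droplet.  This module
turns one grayscale snapshot into one width value in µm:

    bin2x2 -> binarize -> extract_top_region -> feret_diameter

The Feret (maximum caliper) diameter is evaluated on the *corners* of the
foreground pixels, so even a single pixel has a nonzero extent and width
values are reproducible bit-exactly.  The dominant error is the binned
pixel size, which is reported alongside every measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError


@dataclass(frozen=True)
class BinaryMask:
    """Boolean foreground grid with its physical pixel pitch (µm)."""

    mask: np.ndarray
    pixel_pitch: float

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")


@dataclass(frozen=True)
class WidthMeasurement:
    """One droplet's explosion width.

    ``width_error`` is the binned pixel pitch: the measurement is
    pixel-limited, not statistics-limited.
    """

    droplet_index: int
    width_um: float
    width_err_um: float
    threshold: float
    top_fraction: float


def bin2x2(image: np.ndarray) -> np.ndarray:
    """2x2-bin an image by block averaging.

    Output pixel = mean of each 2x2 block; a trailing odd row/column is
    dropped.  The physical pixel pitch of the result is twice that of the
    input.  Averaging (not summing) keeps threshold semantics unchanged.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a nonempty 2-D grayscale image")
    r, c = (image.shape[0] // 2) * 2, (image.shape[1] // 2) * 2
    if r == 0 or c == 0:
        raise ValueError("image too small to 2x2 bin")
    blocks = image[:r, :c].reshape(r // 2, 2, c // 2, 2)
    return blocks.mean(axis=(1, 3))


def binarize(image: np.ndarray, threshold: float, pixel_pitch: float) -> BinaryMask:
    """Threshold an image into a foreground mask (foreground = value >= threshold)."""
    image = np.asarray(image, dtype=float)
    mask = image >= threshold
    if not mask.any():
        raise ValueError("empty mask: threshold above all pixel values")
    return BinaryMask(mask=mask, pixel_pitch=pixel_pitch)


def extract_top_region(mask: BinaryMask, top_fraction: float = 0.5) -> BinaryMask:
    """Keep the top part of the largest connected foreground component.

    The largest 8-connected component is selected (detached debris and
    satellite droplets are discarded); of its pixels, those whose row lies
    in the upper ``top_fraction`` of the component's bounding box are kept.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    labels, n = ndimage.label(mask.mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("empty mask")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    component = labels == (int(np.argmax(sizes)) + 1)
    rows = np.nonzero(component.any(axis=1))[0]
    r_min, r_max = rows[0], rows[-1]
    height = r_max - r_min + 1
    keep_rows = np.arange(component.shape[0])
    row_ok = (keep_rows - r_min) < top_fraction * height
    out = component & row_ok[:, None]
    if not out.any():
        raise ValueError("empty mask after top-region selection")
    return BinaryMask(mask=out, pixel_pitch=mask.pixel_pitch)


def _corner_points(mask: np.ndarray) -> np.ndarray:
    rr, cc = np.nonzero(mask)
    corners = np.concatenate(
        [
            np.stack([rr, cc], axis=1),
            np.stack([rr, cc + 1], axis=1),
            np.stack([rr + 1, cc], axis=1),
            np.stack([rr + 1, cc + 1], axis=1),
        ]
    )
    return np.unique(corners, axis=0).astype(float)


def feret_diameter(mask: BinaryMask) -> float:
    """Maximum caliper diameter of the foreground, in µm.

    Computed as the maximum pairwise distance over the convex hull of the
    pixel-corner coordinates, scaled by the pixel pitch.
    """
    if not mask.mask.any():
        raise ValueError("empty mask")
    pts = _corner_points(mask.mask)
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) point sets: brute force below
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).max()) * mask.pixel_pitch


def measure_explosion_width(
    image: np.ndarray,
    threshold: float,
    pixel_pitch: float,
    top_fraction: float = 0.5,
    droplet_index: int = -1,
) -> WidthMeasurement:
    """Full width pipeline: bin, threshold, select the plume top, caliper it.

    ``pixel_pitch`` is the *raw* (pre-binning) pitch in µm; the reported
    error is one binned pixel (2x the raw pitch).
    """
    binned = bin2x2(image)
    binned_pitch = 2.0 * pixel_pitch
    mask = binarize(binned, threshold, binned_pitch)
    top = extract_top_region(mask, top_fraction)
    width = feret_diameter(top)
    return WidthMeasurement(
        droplet_index=droplet_index,
        width_um=width,
        width_err_um=binned_pitch,
        threshold=threshold,
        top_fraction=top_fraction,
    )
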