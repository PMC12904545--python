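"""Device-style B-scan image I/O, ROI selection and synthetic fixtures.

Reads 8-bit grayscale OCT exports (PNG/TIFF/BMP), locates the corneal
surface and the central analysis ROI around the apex, and -- because no
public porcine dataset accompanies the method -- generates synthetic
"device-like" fixture images from the simulator: a simulated envelope ROI is
log10-compressed, affinely mapped to the 8-bit range (the conventional OCT
display transform), embedded below a synthetic curved surface in a
full-size frame, and written alongside a JSON ground-truth sidecar.  These
fixtures are synthetic stand-ins for real acquisitions; their role is to
make the full experimental pipeline testable end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from PIL import Image
from scipy.ndimage import uniform_filter1d

from .mc_transport import DetectorSpec, LayerStack
from .oct_synthesis import (
    DepthGrid,
    SourceSpec,
    build_bscan,
    extract_sim_roi,
)

__all__ = [
    "ImagingGrid",
    "RoiSpec",
    "read_bscan",
    "write_bscan",
    "locate_surface_and_roi",
    "make_fixture",
    "save_fixture",
]


@dataclass(frozen=True)
class ImagingGrid:
    """Pixel geometry of the device images (um per pixel, image size)."""

    pixel_x_um: float = 3.25
    pixel_z_um: float = 2.70
    width_px: int = 1538
    depth_px: int = 733

    def __post_init__(self) -> None:
        if self.pixel_x_um <= 0 or self.pixel_z_um <= 0:
            raise ValueError("pixel sizes must be positive")


@dataclass(frozen=True)
class RoiSpec:
    """Central analysis ROI: width around the apex, depth below the surface."""

    width_px: int = 308  # ~1000 um at 3.25 um/px
    depth_px: int = 193  # ~520 um at 2.70 um/px
    threshold: float = 100.0  # surface-detection intensity threshold
    smooth_px: int = 3  # axial smoothing before thresholding


def read_bscan(path) -> np.ndarray:
    """Read an 8-bit grayscale B-scan image as an integer array in [0, 255]."""
    with Image.open(path) as img:
        if img.mode == "L":
            return np.asarray(img, dtype=np.uint8)
        if img.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
            raise ValueError(
                f"{path}: {img.mode}-mode image is not 8-bit; convert to "
                "8-bit grayscale (e.g. Image.open(p).convert('L')) first"
            )
        raise ValueError(
            f"{path}: color image (mode {img.mode}); convert to 8-bit "
            "grayscale (mode 'L') first"
        )


def write_bscan(image: np.ndarray, path) -> None:
    """Write an 8-bit grayscale image; round-trips pixels exactly."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("image values must fit in [0, 255]")
        arr = arr.astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def _surface_rows(image: np.ndarray, spec: RoiSpec) -> np.ndarray:
    """Per-column first row whose (axially smoothed) intensity exceeds the
    threshold; -1 where no surface is found."""
    smoothed = uniform_filter1d(image.astype(float), size=spec.smooth_px, axis=0)
    above = smoothed >= spec.threshold
    has = above.any(axis=0)
    first = above.argmax(axis=0)
    return np.where(has, first, -1)


def locate_surface_and_roi(
    image: np.ndarray,
    spec: RoiSpec | None = None,
    center_column: int | None = None,
) -> tuple:
    """Detect the corneal surface, centre the ROI on the apex, and extract it.

    The apex is the column of minimal surface row within the central third
    of the image (override with ``center_column``).  The ROI is flattened
    per column: row 0 of the block is each column's own surface row, so a
    vertical shift of the whole image leaves the block unchanged.

    Returns (roi_block, apex_column, surface_rows_in_roi).
    """
    spec = spec or RoiSpec()
    image = np.asarray(image)
    depth, width = image.shape
    surface = _surface_rows(image, spec)

    if center_column is None:
        lo, hi = width // 3, 2 * width // 3
        central = surface[lo:hi]
        if (central < 0).all():
            raise ValueError("no tissue surface found in the central columns")
        central_valid = np.where(central >= 0, central, np.iinfo(int).max)
        # the apex plateau can span several columns (quantized curvature);
        # take its central column
        minima = np.flatnonzero(central_valid == central_valid.min())
        center_column = lo + int(minima[len(minima) // 2])

    half = spec.width_px // 2
    c0 = center_column - half
    c1 = c0 + spec.width_px
    if c0 < 0 or c1 > width:
        raise ValueError(
            f"ROI columns [{c0}, {c1}) exceed image width {width}"
        )
    cols = np.arange(c0, c1)
    block = np.empty((spec.depth_px, spec.width_px), dtype=image.dtype)
    for j, c in enumerate(cols):
        r = surface[c]
        if r < 0:
            raise ValueError(f"no surface found in ROI column {c}")
        if r + spec.depth_px > depth:
            raise ValueError(
                f"ROI depth {spec.depth_px} below surface row {r} exceeds "
                f"image depth {depth} in column {c}"
            )
        block[:, j] = image[r:r + spec.depth_px, c]
    return block, int(center_column), surface[c0:c1].copy()


# ----------------------------------------------------------------------------
# synthetic device-like fixtures
# ----------------------------------------------------------------------------

LOG_FLOOR_DECADES = 2.5  # envelope dynamic range kept by the 8-bit display map


def _log_compress(envelope: np.ndarray, noise_floor: int) -> np.ndarray:
    """log10 display transform: [-LOG_FLOOR_DECADES, 0] decades of the
    normalized envelope mapped affinely onto [noise_floor, 255]."""
    peak = envelope.max()
    if peak <= 0:
        return np.full(envelope.shape, noise_floor, dtype=np.uint8)
    rel = envelope / peak
    v = np.log10(np.maximum(rel, 10.0 ** (-LOG_FLOOR_DECADES)))
    scaled = (v + LOG_FLOOR_DECADES) / LOG_FLOOR_DECADES
    return np.clip(
        np.round(noise_floor + scaled * (255 - noise_floor)), 0, 255
    ).astype(np.uint8)


def make_fixture(
    mu_s: float,
    g: float,
    seed: int = 0,
    n_packets: int = 1_000_000,
    noise_floor: int = 8,
    imaging: ImagingGrid | None = None,
    roi: RoiSpec | None = None,
    detector: DetectorSpec | None = None,
    source: SourceSpec | None = None,
    depth_grid: DepthGrid | None = None,
    n_ascans: int = 40,
    surface_row: int = 120,
    curvature_px: float = 4.0e-4,
) -> tuple:
    """Simulate a device-like 8-bit B-scan frame with known ground truth.

    The simulated 40-column ROI is embedded at its native width around the
    apex of a synthetic curved surface (deterministic for a fixed seed); the
    remaining columns carry only the surface line and background noise.
    Returns (image, truth) where ``truth`` records (mu_s, g, seed) and the
    embedded ROI bounds for downstream extraction.
    """
    imaging = imaging or ImagingGrid()
    roi = roi or RoiSpec()
    stack = LayerStack.single_layer(mu_s=mu_s, g=g)
    bscan = build_bscan(
        stack, detector, source, depth_grid,
        n_ascans=n_ascans, n_packets=n_packets, seed=seed,
    )
    envelope_roi = extract_sim_roi(bscan, roi.depth_px)
    compressed = _log_compress(envelope_roi, noise_floor)

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xF1D0)))
    frame = rng.poisson(noise_floor, size=(imaging.depth_px, imaging.width_px))
    frame = np.clip(frame, 0, 255).astype(np.uint8)

    apex_col = imaging.width_px // 2
    cols = np.arange(imaging.width_px)
    surf = np.round(
        surface_row + curvature_px * (cols - apex_col) ** 2
    ).astype(int)
    surf = np.clip(surf, 0, imaging.depth_px - roi.depth_px - 1)
    # bright specular surface line, 2 px thick
    for c in cols:
        frame[surf[c]:surf[c] + 2, c] = 230

    c0 = apex_col - n_ascans // 2
    for j in range(n_ascans):
        c = c0 + j
        r = surf[c] + 2
        col = compressed[:, j]
        n_rows = min(roi.depth_px, imaging.depth_px - r)
        frame[r:r + n_rows, c] = np.maximum(frame[r:r + n_rows, c], col[:n_rows])

    truth = {
        "mu_s": float(mu_s),
        "g": float(g),
        "seed": int(seed),
        "n_packets": int(n_packets),
        "n_ascans": int(n_ascans),
        "noise_floor": int(noise_floor),
        "apex_column": int(apex_col),
        "roi": {
            "col0": int(c0),
            "width_px": int(n_ascans),
            "row0": int(surf[apex_col] + 2),
            "depth_px": int(roi.depth_px),
        },
        "synthetic": True,
    }
    return frame, truth


def save_fixture(image: np.ndarray, truth: dict, image_path, truth_path=None):
    """Write the fixture image plus its JSON ground-truth sidecar."""
    write_bscan(image, image_path)
    if truth_path is None:
        truth_path = str(image_path) + ".json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth_path
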