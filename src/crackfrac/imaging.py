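"""Crack segmentation from product surface images.

Implements the classic particle-analysis workflow used for surface
morphometry of baked goods: grayscale conversion, circular region of
interest, Otsu thresholding, small-object noise removal, and connected
component labeling with physical calibration of areas (pixel pitch in
micrometers -> mm^2).

Cracks are assumed darker than the surrounding crust; a polarity flag
inverts this. Areas are exact in pixel units; the mm^2 conversion is
``area_px * (pixel_pitch_um / 1000)**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology

__all__ = [
    "ImageGray",
    "CircularROI",
    "BinaryMask",
    "Particle",
    "ParticleSet",
    "rgb_to_gray",
    "apply_roi",
    "otsu_threshold",
    "binarize",
    "denoise",
    "label_particles",
    "total_cracked_area",
]

#: ITU-R BT.601 luma weights (ImageJ default for RGB -> 8-bit conversion).
GRAY_WEIGHTS_601 = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class ImageGray:
    """8-bit grayscale image with a physical pixel scale.

    Parameters
    ----------
    pixels
        2-D array of intensities in [0, 255].
    pixel_pitch_um
        Physical edge length of one pixel in micrometers (63.5 at 400 dpi).
    """

    pixels: np.ndarray
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected 2-D pixel array, got shape {px.shape}")
        if px.size and (px.min() < 0 or px.max() > 255):
            raise ValueError("intensities must lie in [0, 255]")
        if not self.pixel_pitch_um > 0:
            raise ValueError("pixel_pitch_um must be positive")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CircularROI:
    """Circular region of interest: pixel-coordinate center, physical diameter.

    ``diameter_mm`` is converted to pixels with the image's pixel pitch at
    application time, so one ROI definition serves images of any resolution.
    """

    center: tuple[float, float]  # (row, col) in pixels
    diameter_mm: float

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise ValueError("ROI diameter must be positive")

    def radius_px(self, pixel_pitch_um: float) -> float:
        return self.diameter_mm * 1000.0 / (2.0 * pixel_pitch_um)


@dataclass(frozen=True)
class BinaryMask:
    """Boolean crack mask; True marks crack (foreground) pixels.

    ``threshold`` records the intensity level the mask was derived from
    (provenance; None for synthetic ground-truth masks).
    """

    pixels: np.ndarray
    threshold: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Particle:
    """One connected crack region."""

    label: int
    area_px: int
    area_mm2: float
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)


@dataclass(frozen=True)
class ParticleSet:
    """All crack regions extracted from one image."""

    particles: tuple[Particle, ...]
    image_id: str = ""
    pixel_pitch_um: float = float("nan")

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def areas_mm2(self) -> np.ndarray:
        return np.array([p.area_mm2 for p in self.particles], dtype=float)

    @property
    def total_area_mm2(self) -> float:
        # sum in exact pixel units first, convert once
        total_px = sum(p.area_px for p in self.particles)
        return total_px * (self.pixel_pitch_um / 1000.0) ** 2 if self.particles else 0.0


def rgb_to_gray(rgb: np.ndarray, weights: tuple[float, float, float] = GRAY_WEIGHTS_601,
                pixel_pitch_um: float = 63.5) -> ImageGray:
    """Convert an 8-bit RGB image to grayscale with ITU-R 601 luma weights.

    ``gray = round(0.299 R + 0.587 G + 0.114 B)``, clipped to [0, 255].
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {arr.shape}")
    w = np.asarray(weights, dtype=float)
    gray = np.clip(np.rint(arr @ w), 0, 255).astype(np.uint8)
    return ImageGray(gray, pixel_pitch_um)


def apply_roi(gray: ImageGray, roi: CircularROI, background_value: int = 255) -> ImageGray:
    """Blank everything outside a circular ROI to ``background_value``."""
    r = roi.radius_px(gray.pixel_pitch_um)
    nrow, ncol = gray.shape
    cr, cc = roi.center
    if cr + r < 0 or cr - r > nrow - 1 or cc + r < 0 or cc - r > ncol - 1:
        raise ValueError("ROI circle lies entirely outside the image")
    rows, cols = np.ogrid[:nrow, :ncol]
    inside = (rows - cr) ** 2 + (cols - cc) ** 2 <= r**2
    out = np.where(inside, gray.pixels, np.uint8(background_value))
    return ImageGray(out, gray.pixel_pitch_um)


def roi_mask(gray: ImageGray, roi: CircularROI) -> np.ndarray:
    """Boolean mask of pixels inside the circular ROI."""
    r = roi.radius_px(gray.pixel_pitch_um)
    nrow, ncol = gray.shape
    cr, cc = roi.center
    rows, cols = np.ogrid[:nrow, :ncol]
    return (rows - cr) ** 2 + (cols - cc) ** 2 <= r**2


def otsu_threshold(gray: ImageGray | np.ndarray) -> int:
    """Otsu threshold level over the fixed 256-bin intensity histogram.

    Exhaustively evaluates every integer level ``t`` in 0..254, splitting
    pixels into classes ``<= t`` and ``> t``, and returns the level that
    maximizes the between-class variance (smallest such level on ties).
    This matches the integer-level convention of particle-analysis tools
    rather than data-range binning.

    Raises
    ------
    ValueError
        If the image is constant (no split exists).
    """
    px = gray.pixels if isinstance(gray, ImageGray) else np.asarray(gray)
    hist = np.bincount(px.ravel().astype(np.uint8), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("constant image: Otsu threshold is undefined")
    n = hist.sum()
    omega = np.cumsum(hist) / n                      # P(class0) for t = 0..255
    mu = np.cumsum(hist * np.arange(256)) / n        # cumulative first moment
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        # between-class variance for each candidate level t
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b[:255]))


def binarize(gray: ImageGray, level: float, polarity: str = "dark_foreground") -> BinaryMask:
    """Threshold to a binary crack mask.

    ``dark_foreground`` (default): foreground = pixels <= level (cracks are
    dark). ``light_foreground`` inverts: foreground = pixels > level.
    """
    if not 0 <= level <= 255:
        raise ValueError("level must lie in [0, 255]")
    if polarity == "dark_foreground":
        fg = gray.pixels <= level
    elif polarity == "light_foreground":
        fg = gray.pixels > level
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return BinaryMask(fg, threshold=float(level))


def denoise(mask: BinaryMask, min_size_px: int = 2, connectivity: int = 8) -> BinaryMask:
    """Remove connected components smaller than ``min_size_px`` pixels."""
    if min_size_px < 0:
        raise ValueError("min_size_px must be >= 0")
    if min_size_px <= 1:
        return mask
    # max_size semantics: removes components with area <= max_size,
    # i.e. keeps everything with area >= min_size_px
    cleaned = morphology.remove_small_objects(
        mask.pixels, max_size=min_size_px - 1,
        connectivity=_skimage_connectivity(connectivity)
    )
    return BinaryMask(cleaned, threshold=mask.threshold)


def median_denoise(mask: BinaryMask) -> BinaryMask:
    """3x3 median filter (ImageJ 'despeckle') alternative to size filtering."""
    from scipy.ndimage import median_filter

    return BinaryMask(median_filter(mask.pixels, size=3), threshold=mask.threshold)


def _skimage_connectivity(connectivity: int) -> int:
    if connectivity == 4:
        return 1
    if connectivity == 8:
        return 2
    raise ValueError("connectivity must be 4 or 8")


def label_particles(mask: BinaryMask, connectivity: int = 8,
                    pixel_pitch_um: float = 63.5, image_id: str = "") -> ParticleSet:
    """Label connected crack regions and calibrate their areas to mm^2."""
    if not pixel_pitch_um > 0:
        raise ValueError("pixel_pitch_um must be positive")
    labeled = measure.label(mask.pixels, connectivity=_skimage_connectivity(connectivity))
    scale = (pixel_pitch_um / 1000.0) ** 2
    particles = tuple(
        Particle(
            label=int(rp.label),
            area_px=int(rp.area),
            area_mm2=float(rp.area) * scale,
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            bbox=tuple(int(v) for v in rp.bbox),
        )
        for rp in measure.regionprops(labeled)
    )
    return ParticleSet(particles, image_id=image_id, pixel_pitch_um=pixel_pitch_um)


def total_cracked_area(ps: ParticleSet) -> float:
    """Total crack area in mm^2 (0 for an empty set)."""
    return ps.total_area_mm2


def segment_image(gray: ImageGray, roi: CircularROI | None = None,
                  min_size_px: int = 2, connectivity: int = 8,
                  polarity: str = "dark_foreground", image_id: str = "") -> ParticleSet:
    """Full pipeline: optional ROI, Otsu, binarize, denoise, label.

    When an ROI is given, pixels outside it are forced to background before
    thresholding (light for dark cracks, dark for light cracks) and the
    threshold is computed on the ROI interior only, so the blanked exterior
    cannot bias the histogram.
    """
    work = gray
    if roi is not None:
        background = 255 if polarity == "dark_foreground" else 0
        work = apply_roi(gray, roi, background_value=background)
        inside = roi_mask(gray, roi)
        level = otsu_threshold(work.pixels[inside])
    else:
        level = otsu_threshold(work)
    mask = binarize(work, level, polarity=polarity)
    mask = denoise(mask, min_size_px=min_size_px, connectivity=connectivity)
    return label_particles(mask, connectivity=connectivity,
                           pixel_pitch_um=gray.pixel_pitch_um, image_id=image_id)
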