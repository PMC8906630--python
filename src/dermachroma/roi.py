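"""Circular region-of-interest extraction.

A skin capture is reduced to one twelve-component color vector by
converting every pixel inside a centered circular ROI (design radius
300 px, matching the 1 cm^2 field of the acquisition device) and then
averaging each parameter — convert-then-average, never the reverse,
since HSV and L*a*b* are nonlinear in RGB.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import color

__all__ = [
    "BREASTS",
    "SITES",
    "TIME_POINTS",
    "DESIGN_RADIUS",
    "SkinImage",
    "CircularROI",
    "default_roi",
    "roi_mask",
    "extract_parameters",
    "read_skin_image",
]

BREASTS = ("irradiated", "unirradiated")
SITES = ("upper", "lower", "inner", "outer")
TIME_POINTS = ("RT_before", "RT_7days", "RT_14days", "RT_after")

#: ROI radius (pixels) used at the device's native 1624x1212 resolution.
DESIGN_RADIUS = 300.0


@dataclass
class SkinImage:
    """8-bit RGB raster plus the acquisition cell it belongs to.

    ``pixels`` has shape (H, W, 3) with channels in [0, 255].  The
    metadata fields locate the image in the study design: patient,
    breast (irradiated vs unirradiated control), measurement site
    around the nipple, and longitudinal time point.
    """

    pixels: np.ndarray
    patient_id: str = ""
    breast: str = "irradiated"
    site: str = "upper"
    time_point: str = "RT_before"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise ValueError("pixels must have shape (H, W, 3)")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        pf = self.pixels.astype(float)
        if pf.min() < 0 or pf.max() > 255:
            raise ValueError("channels must lie in [0, 255]")
        if self.breast not in BREASTS:
            raise ValueError(f"breast must be one of {BREASTS}")
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}")
        if self.time_point not in TIME_POINTS:
            raise ValueError(f"time_point must be one of {TIME_POINTS}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class CircularROI:
    """Disc in pixel coordinates; a pixel belongs if its integer
    coordinate lies within ``radius`` of the (possibly fractional)
    center."""

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def default_roi(image: SkinImage, radius: float = DESIGN_RADIUS, strict: bool = False) -> CircularROI:
    """Centered ROI with the design radius, shrunk to fit small images.

    The center is ((W-1)/2, (H-1)/2) so the disc is symmetric for odd
    dimensions and sits between pixels for even ones.  If the image
    cannot contain the requested disc, the radius shrinks to the
    largest inscribed value — unless ``strict``, which raises instead
    (for workflows where silent shrinking would hide a cropping bug).
    """
    h, w = image.height, image.width
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    fit = min(cx, cy)
    if radius > fit:
        if strict:
            raise ValueError(
                f"ROI radius {radius} does not fit a {w}x{h} image (max {fit})"
            )
        radius = fit
    if radius <= 0:  # 1-pixel-wide images: keep the single center pixel
        radius = 0.5
    return CircularROI(cx, cy, radius)


def roi_mask(image: SkinImage, roi: CircularROI) -> np.ndarray:
    """Boolean (H, W) membership mask; errors if no pixel falls inside."""
    yy, xx = np.mgrid[0 : image.height, 0 : image.width]
    mask = (xx - roi.center_x) ** 2 + (yy - roi.center_y) ** 2 <= roi.radius**2
    if not mask.any():
        raise ValueError("degenerate ROI: no pixel inside the disc")
    return mask


def extract_parameters(image: SkinImage, roi: CircularROI | None = None) -> np.ndarray:
    """ROI mean of each of the 12 per-pixel color parameters.

    Returns a length-12 vector ordered as :data:`color.PARAMETER_NAMES`.
    Hue is averaged arithmetically (not circularly), matching how a
    matrix mean of the converted image behaves; see the methods note
    for the wraparound caveat.
    """
    if roi is None:
        roi = default_roi(image)
    mask = roi_mask(image, roi)
    pixels = image.pixels.astype(float)[mask]
    return color.pixel_to_vector12(pixels).mean(axis=0)


_PATH_RE = re.compile(
    r"(?P<patient>[^/\\]+)[/\\](?P<breast>[^/\\]+)[/\\](?P<site>[^/\\]+)[/\\](?P<tp>[^/\\.]+)\.(png|tif|tiff)$",
    re.IGNORECASE,
)


def read_skin_image(path: str | Path, strip_alpha: bool = False) -> SkinImage:
    """Load a PNG/TIFF skin capture, inferring metadata from the
    ``patient/breast/site/timepoint.png`` directory convention when
    the path follows it.

    Images with an alpha channel are rejected unless ``strip_alpha``.
    """
    import imageio.v3 as iio

    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] == 4:
        if not strip_alpha:
            raise ValueError(f"{path} has an alpha channel; pass strip_alpha=True")
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"{path} is not an RGB image")
    if arr.dtype != np.uint8:
        raise ValueError(f"{path} is not 8-bit ({arr.dtype})")

    meta: dict[str, str] = {}
    m = _PATH_RE.search(str(path))
    if m and m.group("breast") in BREASTS and m.group("site") in SITES and m.group("tp") in TIME_POINTS:
        meta = dict(
            patient_id=m.group("patient"),
            breast=m.group("breast"),
            site=m.group("site"),
            time_point=m.group("tp"),
        )
    return SkinImage(pixels=arr, **meta)
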