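"""Color-space models for skin colorimetry.

Four models are computed per pixel from 8-bit sRGB input: RGB itself
(0-255 scale), the HSV hexcone model (all components in [0, 1]), CIE
L*a*b* under the D65 illuminant, and studio-swing YCbCr (ITU-R BT.601,
luma nominally 16-235 and chroma 16-240).  Together they yield the
twelve parameters used to track erythema: R, G, B, H, S, V, L*, a*,
b*, Y, Cb, Cr.

The transforms are implemented directly from their defining equations
rather than delegated to an image library, because the parameter
definitions are the quantity under study: the exact dialect (sRGB
gamma, D65 white point, studio-swing chroma scaling, hue convention
for achromatic pixels) must be pinned down and testable.  All
arithmetic is double precision; YCbCr is never re-quantized to 8 bits
before averaging.

Every function accepts arrays of shape ``(..., 3)`` and broadcasts
over leading dimensions, so whole images convert in one call.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize_rgb",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "rgb_to_lab",
    "lab_to_rgb",
    "rgb_to_ycbcr",
    "pixel_to_vector12",
    "PARAMETER_NAMES",
    "SRGB_TO_XYZ",
    "D65_WHITE",
]

#: The twelve color parameters, in reporting order.
PARAMETER_NAMES = ("R", "G", "B", "H", "S", "V", "L", "a", "b", "Y", "Cb", "Cr")

#: Linear sRGB -> CIE XYZ matrix (D65 reference white).
SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

#: D65 white point as the image of sRGB white, so (1,1,1) maps to L*=100 exactly.
D65_WHITE = SRGB_TO_XYZ.sum(axis=1)

_XYZ_TO_SRGB = np.linalg.inv(SRGB_TO_XYZ)

# CIE f(t) linear-segment threshold: (6/29)^3.
_CIE_EPS = (6.0 / 29.0) ** 3
_CIE_KAPPA = (29.0 / 6.0) ** 2 / 3.0  # slope of the linear segment


def _as_triplet(arr, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.shape[-1] != 3:
        raise ValueError(f"{name} must have shape (..., 3), got {a.shape}")
    return a


def normalize_rgb(rgb) -> np.ndarray:
    """Map 8-bit channels in [0, 255] to unit floats (channel / 255).

    Raises ``ValueError`` for channels outside [0, 255].
    """
    a = _as_triplet(rgb, "rgb")
    if a.min(initial=0.0) < 0 or a.max(initial=0.0) > 255:
        raise ValueError("RGB channels must lie in [0, 255]")
    return a / 255.0


def _check_unit(a: np.ndarray) -> None:
    if a.min(initial=0.0) < 0 or a.max(initial=0.0) > 1:
        raise ValueError("unit RGB components must lie in [0, 1]")


def rgb_to_hsv(rgb) -> np.ndarray:
    """Hexcone HSV from unit RGB; all outputs in [0, 1], hue in [0, 1).

    Achromatic pixels (max == min) get hue 0 and saturation 0 so that
    averaging over a region stays deterministic.
    """
    a = _as_triplet(rgb, "rgb")
    _check_unit(a)
    r, g, b = a[..., 0], a[..., 1], a[..., 2]
    v = a.max(axis=-1)
    mn = a.min(axis=-1)
    delta = v - mn
    chromatic = delta > 0
    safe_delta = np.where(chromatic, delta, 1.0)

    h = np.zeros_like(v)
    r_is_max = chromatic & (v == r)
    g_is_max = chromatic & (v == g) & ~r_is_max
    b_is_max = chromatic & ~r_is_max & ~g_is_max
    h = np.where(r_is_max, ((g - b) / safe_delta) % 6.0, h)
    h = np.where(g_is_max, (b - r) / safe_delta + 2.0, h)
    h = np.where(b_is_max, (r - g) / safe_delta + 4.0, h)
    h = (h / 6.0) % 1.0

    s = np.where(v > 0, delta / np.where(v > 0, v, 1.0), 0.0)
    return np.stack([h, s, v], axis=-1)


def hsv_to_rgb(hsv) -> np.ndarray:
    """Inverse hexcone transform; exact round-trip partner of rgb_to_hsv."""
    a = _as_triplet(hsv, "hsv")
    h, s, v = a[..., 0], a[..., 1], a[..., 2]
    h6 = (h % 1.0) * 6.0
    i = np.floor(h6).astype(int) % 6
    f = h6 - np.floor(h6)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    lut = np.stack(
        [
            np.stack([v, t, p], axis=-1),
            np.stack([q, v, p], axis=-1),
            np.stack([p, v, t], axis=-1),
            np.stack([p, q, v], axis=-1),
            np.stack([t, p, v], axis=-1),
            np.stack([v, p, q], axis=-1),
        ],
        axis=0,
    )
    return np.take_along_axis(lut, i[None, ..., None], axis=0)[0]


def _srgb_inverse_gamma(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _srgb_forward_gamma(c: np.ndarray) -> np.ndarray:
    c = np.clip(c, 0.0, None)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1.0 / 2.4) - 0.055)


def _cie_f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _CIE_EPS, np.cbrt(t), _CIE_KAPPA * t + 4.0 / 29.0)


def _cie_f_inv(ft: np.ndarray) -> np.ndarray:
    return np.where(ft > 6.0 / 29.0, ft**3, (ft - 4.0 / 29.0) / _CIE_KAPPA)


def rgb_to_lab(rgb) -> np.ndarray:
    """CIE L*a*b* from unit sRGB, D65 white point.

    Applies the sRGB inverse gamma, the sRGB->XYZ matrix, white-point
    normalization, and the CIE cube-root function with its linear
    segment below (6/29)^3.  L* lies in [0, 100].
    """
    a = _as_triplet(rgb, "rgb")
    _check_unit(a)
    linear = _srgb_inverse_gamma(a)
    xyz = linear @ SRGB_TO_XYZ.T
    f = _cie_f(xyz / D65_WHITE)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    L = 116.0 * fy - 16.0
    astar = 500.0 * (fx - fy)
    bstar = 200.0 * (fy - fz)
    return np.stack([L, astar, bstar], axis=-1)


def lab_to_rgb(lab, clip: bool = True) -> np.ndarray:
    """Unit sRGB from CIE L*a*b* (D65); inverse of :func:`rgb_to_lab`.

    Out-of-gamut colors are clipped to [0, 1] unless ``clip=False``,
    in which case raw (possibly out-of-range) values are returned.
    """
    a = _as_triplet(lab, "lab")
    L, astar, bstar = a[..., 0], a[..., 1], a[..., 2]
    fy = (L + 16.0) / 116.0
    fx = fy + astar / 500.0
    fz = fy - bstar / 200.0
    xyz = np.stack([_cie_f_inv(fx), _cie_f_inv(fy), _cie_f_inv(fz)], axis=-1)
    xyz = xyz * D65_WHITE
    linear = xyz @ _XYZ_TO_SRGB.T
    srgb = _srgb_forward_gamma(linear)
    return np.clip(srgb, 0.0, 1.0) if clip else srgb


# BT.601 studio-swing analog coefficients (Kr=0.299, Kb=0.114), scaled so
# that luma spans 16-235 and chroma 16-240 over the unit RGB cube.
_YCBCR_MATRIX = np.array(
    [
        [65.481, 128.553, 24.966],
        [-37.797, -74.203, 112.0],
        [112.0, -93.786, -18.214],
    ]
)
_YCBCR_OFFSET = np.array([16.0, 128.0, 128.0])


def rgb_to_ycbcr(rgb) -> np.ndarray:
    """Studio-swing BT.601 YCbCr from unit RGB.

    Black maps to (16, 128, 128) and white to (235, 128, 128).  Values
    are kept as doubles; no 8-bit rounding is applied.
    """
    a = _as_triplet(rgb, "rgb")
    _check_unit(a)
    return a @ _YCBCR_MATRIX.T + _YCBCR_OFFSET


def pixel_to_vector12(rgb_8bit) -> np.ndarray:
    """All twelve color parameters for 8-bit RGB input, shape (..., 12).

    Order follows :data:`PARAMETER_NAMES`: R, G, B on the 0-255 scale,
    H, S, V in [0, 1], L* in [0, 100] with a*/b* on the CIE scale, and
    Y, Cb, Cr on the 16-240 digital scale.
    """
    a = _as_triplet(rgb_8bit, "rgb")
    unit = normalize_rgb(a)
    return np.concatenate(
        [a, rgb_to_hsv(unit), rgb_to_lab(unit), rgb_to_ycbcr(unit)], axis=-1
    )
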