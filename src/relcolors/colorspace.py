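"""Color-space conversions and whole-image color-difference metrics.

Implements the deterministic chain sRGB -> CIE 1931 XYZ -> CIELAB /
CIECAM02-UCS used to assess how faithfully a quantized image renders the
colors of the original, plus the spatially filtered S-CIELAB difference,
which low-pass filters opponent-color channels by the eye's contrast
sensitivity before differencing.

All conversions operate in floating point; XYZ is scaled so the reference
white has Y = 100 (2-degree observer).  Euclidean distances in CIELAB and
CIECAM02-UCS approximate perceived color differences (Delta E).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d

__all__ = [
    "D65_WHITE",
    "ViewingConditions",
    "TristimulusImage",
    "LabImage",
    "UCSImage",
    "ColorDifferenceSummary",
    "srgb_to_xyz",
    "xyz_to_srgb",
    "xyz_to_lab",
    "srgb_to_lab",
    "xyz_to_ciecam02ucs",
    "mean_delta_e_ucs",
    "mean_delta_e_scielab",
]

# D65 reference white, 2-degree observer, Y normalized to 100.
D65_WHITE = np.array([95.047, 100.0, 108.883])

# IEC 61966-2-1 sRGB primaries -> XYZ (D65), for Y in [0, 1].
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_XYZ_TO_SRGB = np.linalg.inv(_SRGB_TO_XYZ)


@dataclass(frozen=True)
class ViewingConditions:
    """CIECAM02 viewing conditions.

    Parameters mirror the standard appearance-model inputs: the adopted
    white (XYZ, Y = 100), the adapting field luminance ``L_A`` in cd/m^2,
    the relative background luminance factor ``Y_b`` (percent of white),
    and the surround category.
    """

    whitepoint: np.ndarray = field(default_factory=lambda: D65_WHITE.copy())
    adapting_luminance: float = 64.0
    background_luminance_factor: float = 20.0
    surround: str = "average"

    def __post_init__(self) -> None:
        if self.adapting_luminance <= 0 or not np.isfinite(self.adapting_luminance):
            raise ValueError(
                f"adapting luminance must be a positive finite cd/m^2 value, "
                f"got {self.adapting_luminance}"
            )
        if self.surround not in _SURROUNDS:
            raise ValueError(f"unknown surround {self.surround!r}")


# surround: (F, c, N_c)
_SURROUNDS = {
    "average": (1.0, 0.69, 1.0),
    "dim": (0.9, 0.59, 0.9),
    "dark": (0.8, 0.525, 0.8),
}


@dataclass
class TristimulusImage:
    """Per-pixel CIE 1931 XYZ triplets with the adopted whitepoint."""

    values: np.ndarray  # (..., 3), Y of white = 100
    whitepoint: np.ndarray = field(default_factory=lambda: D65_WHITE.copy())


@dataclass
class LabImage:
    """Per-pixel CIELAB (L*, a*, b*) coordinates."""

    values: np.ndarray
    whitepoint: np.ndarray = field(default_factory=lambda: D65_WHITE.copy())


@dataclass
class UCSImage:
    """Per-pixel CIECAM02-UCS (J', a', b') coordinates."""

    values: np.ndarray
    viewing_conditions: ViewingConditions = field(default_factory=ViewingConditions)


@dataclass
class ColorDifferenceSummary:
    """Mean per-pixel Euclidean color difference in a named space."""

    mean_delta_e: float
    space_tag: str


def _as_rgb_array(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim < 1 or arr.shape[-1] != 3:
        raise ValueError(f"expected trailing axis of 3 RGB channels, got shape {arr.shape}")
    return arr


def srgb_to_xyz(image: np.ndarray) -> TristimulusImage:
    """Decode 8-bit sRGB to CIE 1931 XYZ (D65 white at Y = 100).

    Standard IEC 61966-2-1 decoding: per-channel gamma expansion followed
    by the 3x3 primary matrix.
    """
    arr = _as_rgb_array(image).astype(np.float64) / 255.0
    linear = np.where(arr <= 0.04045, arr / 12.92, ((arr + 0.055) / 1.055) ** 2.4)
    xyz = linear @ _SRGB_TO_XYZ.T * 100.0
    return TristimulusImage(values=xyz, whitepoint=D65_WHITE.copy())


def xyz_to_srgb(image: TristimulusImage) -> np.ndarray:
    """Encode XYZ (Y of white = 100) back to 8-bit sRGB, clipping to gamut."""
    linear = np.asarray(image.values, dtype=np.float64) / 100.0 @ _XYZ_TO_SRGB.T
    linear = np.clip(linear, 0.0, 1.0)
    srgb = np.where(
        linear <= 0.0031308, 12.92 * linear, 1.055 * linear ** (1 / 2.4) - 0.055
    )
    return np.round(srgb * 255.0).astype(np.uint8)


def _lab_f(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)


def xyz_to_lab(image: TristimulusImage) -> LabImage:
    """CIE 1976 L*a*b* relative to the image's whitepoint."""
    white = np.asarray(image.whitepoint, dtype=np.float64)
    if white is None or white.shape != (3,) or not np.all(white > 0):
        raise ValueError("a positive 3-vector whitepoint is required for CIELAB")
    f = _lab_f(np.asarray(image.values, dtype=np.float64) / white)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return LabImage(values=np.stack([L, a, b], axis=-1), whitepoint=white)


def srgb_to_lab(image: np.ndarray) -> LabImage:
    """Convenience chain: 8-bit sRGB -> XYZ -> CIELAB under D65."""
    return xyz_to_lab(srgb_to_xyz(image))


# ---------------------------------------------------------------------------
# CIECAM02 -> CAM02-UCS
# ---------------------------------------------------------------------------

_M_CAT02 = np.array(
    [
        [0.7328, 0.4296, -0.1624],
        [-0.7036, 1.6975, 0.0061],
        [0.0030, 0.0136, 0.9834],
    ]
)
_M_HPE = np.array(
    [
        [0.38971, 0.68898, -0.07868],
        [-0.22981, 1.18340, 0.04641],
        [0.0, 0.0, 1.0],
    ]
)
_M_CAT02_INV = np.linalg.inv(_M_CAT02)


def _nonlinear_adaptation(rgb: np.ndarray, f_l: float) -> np.ndarray:
    # Post-adaptation cone response compression, sign-symmetric.
    x = (f_l * np.abs(rgb) / 100.0) ** 0.42
    return np.sign(rgb) * 400.0 * x / (x + 27.13) + 0.1


def xyz_to_ciecam02ucs(
    image: TristimulusImage, conditions: ViewingConditions | None = None
) -> UCSImage:
    """Map XYZ to CIECAM02 appearance correlates and then to CAM02-UCS.

    Returns per-pixel (J', a', b') where J' is the UCS lightness and
    (a', b') the UCS chromatic plane; Euclidean distance in these
    coordinates is the CIECAM02-UCS Delta E.
    """
    vc = conditions if conditions is not None else ViewingConditions()
    xyz = np.asarray(image.values, dtype=np.float64)
    xyz_w = np.asarray(vc.whitepoint, dtype=np.float64)
    F, c, N_c = _SURROUNDS[vc.surround]
    L_A = float(vc.adapting_luminance)
    Y_b = float(vc.background_luminance_factor)
    Y_w = xyz_w[1]

    rgb = xyz @ _M_CAT02.T
    rgb_w = _M_CAT02 @ xyz_w

    D = np.clip(F * (1.0 - (1.0 / 3.6) * np.exp((-L_A - 42.0) / 92.0)), 0.0, 1.0)
    D_rgb = D * Y_w / rgb_w + 1.0 - D
    rgb_c = rgb * D_rgb
    rgb_wc = rgb_w * D_rgb

    k = 1.0 / (5.0 * L_A + 1.0)
    f_l = 0.2 * k**4 * (5.0 * L_A) + 0.1 * (1.0 - k**4) ** 2 * (5.0 * L_A) ** (1.0 / 3.0)
    n = Y_b / Y_w
    N_bb = N_cb = 0.725 * (1.0 / n) ** 0.2
    z = 1.48 + np.sqrt(n)

    hpe = _M_HPE @ _M_CAT02_INV
    rgb_p = rgb_c @ hpe.T
    rgb_pw = hpe @ rgb_wc
    rgb_pa = _nonlinear_adaptation(rgb_p, f_l)
    rgb_paw = _nonlinear_adaptation(rgb_pw, f_l)

    a = rgb_pa[..., 0] - 12.0 * rgb_pa[..., 1] / 11.0 + rgb_pa[..., 2] / 11.0
    b = (rgb_pa[..., 0] + rgb_pa[..., 1] - 2.0 * rgb_pa[..., 2]) / 9.0
    h = np.degrees(np.arctan2(b, a)) % 360.0

    A = (2.0 * rgb_pa[..., 0] + rgb_pa[..., 1] + rgb_pa[..., 2] / 20.0 - 0.305) * N_bb
    A_w = (2.0 * rgb_paw[0] + rgb_paw[1] + rgb_paw[2] / 20.0 - 0.305) * N_bb
    J = 100.0 * np.clip(A / A_w, 0.0, None) ** (c * z)

    e_t = 0.25 * (np.cos(np.radians(h) + 2.0) + 3.8)
    t_num = (50000.0 / 13.0) * N_c * N_cb * e_t * np.hypot(a, b)
    t_den = rgb_pa[..., 0] + rgb_pa[..., 1] + 21.0 / 20.0 * rgb_pa[..., 2]
    t = t_num / t_den
    C = t**0.9 * np.sqrt(J / 100.0) * (1.64 - 0.29**n) ** 0.73
    M = C * f_l**0.25

    # CAM02-UCS (Luo, Cui & Li 2006): K_L = 1, c1 = 0.007, c2 = 0.0228
    J_p = 1.7 * J / (1.0 + 0.007 * J)
    M_p = np.log1p(0.0228 * M) / 0.0228
    a_p = M_p * np.cos(np.radians(h))
    b_p = M_p * np.sin(np.radians(h))
    return UCSImage(values=np.stack([J_p, a_p, b_p], axis=-1), viewing_conditions=vc)


def mean_delta_e_ucs(
    original: np.ndarray,
    quantized: np.ndarray,
    conditions: ViewingConditions | None = None,
) -> ColorDifferenceSummary:
    """Mean CIECAM02-UCS Euclidean difference over all pixels."""
    orig = _as_rgb_array(original)
    quant = _as_rgb_array(quantized)
    if orig.shape != quant.shape:
        raise ValueError(f"image shapes differ: {orig.shape} vs {quant.shape}")
    ucs_a = xyz_to_ciecam02ucs(srgb_to_xyz(orig), conditions).values
    ucs_b = xyz_to_ciecam02ucs(srgb_to_xyz(quant), conditions).values
    de = np.linalg.norm(ucs_a - ucs_b, axis=-1)
    return ColorDifferenceSummary(mean_delta_e=float(de.mean()), space_tag="CIECAM02-UCS")


# ---------------------------------------------------------------------------
# S-CIELAB
# ---------------------------------------------------------------------------

# XYZ -> opponent channels (luminance, red-green, blue-yellow),
# Poirson-Wandell pattern-color separable transform.
_XYZ_TO_OPP = np.array(
    [
        [0.279, 0.72, -0.107],
        [-0.449, 0.29, -0.077],
        [0.086, -0.59, 0.501],
    ]
)
_OPP_TO_XYZ = np.linalg.inv(_XYZ_TO_OPP)

# Zhang-Wandell Gaussian-mixture spatial filters: per-channel
# (weight, halfwidth-in-degrees) pairs.
_SCIELAB_FILTERS = {
    "lum": ((0.921, 0.0283), (0.105, 0.133), (-0.108, 4.336)),
    "rg": ((0.531, 0.0392), (0.330, 0.494)),
    "by": ((0.488, 0.0536), (0.386, 0.386)),
}


def _scielab_kernels(
    weight_spread: tuple, samples_per_degree: float
) -> list[tuple[float, np.ndarray]]:
    """(weight, 1-D Gaussian) components for one opponent channel.

    The channel's spatial filter is a sum of separable Gaussians
    w_i exp(-x^2 / s_i^2) with s_i the tabulated spread (degrees) scaled
    by samples_per_degree.  Each Gaussian is normalized to unit sum and
    the weights are renormalized to sum to 1, so spatially uniform fields
    pass through unchanged.
    """
    spreads = [h * samples_per_degree for _, h in weight_spread]
    half = max(int(np.ceil(3.0 * max(spreads))), 1)
    x = np.arange(-half, half + 1, dtype=np.float64)
    w_total = sum(w for w, _ in weight_spread)
    out = []
    for (w, _), s in zip(weight_spread, spreads):
        g = np.exp(-(x**2) / s**2)
        out.append((w / w_total, g / g.sum()))
    return out


def mean_delta_e_scielab(
    original: np.ndarray,
    quantized: np.ndarray,
    samples_per_degree: float = 72.0,
    whitepoint: np.ndarray | None = None,
) -> ColorDifferenceSummary:
    """Mean S-CIELAB difference between an image and its quantization.

    Both images are transformed to opponent channels, spatially low-pass
    filtered by the Zhang-Wandell contrast-sensitivity kernels (separable
    Gaussian mixtures, reflective edge padding), converted back to XYZ and
    then CIELAB, and differenced per pixel with the plain Euclidean
    Delta E*ab, averaged over the image.
    """
    if samples_per_degree <= 0:
        raise ValueError(f"samples_per_degree must be positive, got {samples_per_degree}")
    orig = _as_rgb_array(original)
    quant = _as_rgb_array(quantized)
    if orig.shape != quant.shape:
        raise ValueError(f"image shapes differ: {orig.shape} vs {quant.shape}")
    white = D65_WHITE if whitepoint is None else np.asarray(whitepoint, dtype=np.float64)

    def filtered_lab(img: np.ndarray) -> np.ndarray:
        xyz = srgb_to_xyz(img).values
        opp = xyz @ _XYZ_TO_OPP.T
        out = np.empty_like(opp)
        for ch, name in enumerate(("lum", "rg", "by")):
            acc = np.zeros_like(opp[..., ch])
            for w, g in _scielab_kernels(_SCIELAB_FILTERS[name], samples_per_degree):
                plane = convolve1d(opp[..., ch], g, axis=0, mode="reflect")
                acc += w * convolve1d(plane, g, axis=1, mode="reflect")
            out[..., ch] = acc
        xyz_f = out @ _OPP_TO_XYZ.T
        return xyz_to_lab(TristimulusImage(values=xyz_f, whitepoint=white)).values

    de = np.linalg.norm(filtered_lab(orig) - filtered_lab(quant), axis=-1)
    return ColorDifferenceSummary(mean_delta_e=float(de.mean()), space_tag="S-CIELAB")
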