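"""Beam-fluorescence image processing.

Converts paired RGB images (irradiated + dark) of a photosensitiser
cuvette into a depth-intensity profile: grayscale conversion, integer-
pixel registration and subtraction, lateral averaging over the beam band,
and sub-pixel localisation of the fluorescence maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.registration import phase_cross_correlation

from ._peaks import parabolic_peak
from .errors import AnalysisError, InputError
from .photoexcitation import FluorescenceProfile

#: ITU-R 601 luminance weights (same combination as MATLAB's rgb2gray),
#: normalised to sum exactly to 1 so grey inputs map to themselves
_LUMA = np.array([0.2989, 0.5870, 0.1140])
_LUMA = _LUMA / _LUMA.sum()

MAX_REGISTRATION_SHIFT = 10       # px
# lit frames are signal-dominated, so lit-vs-dark correlation is weak even
# when alignment is perfect; the threshold only has to reject unrelated
# frames (correlation ~ 1/sqrt(n_pixels))
REGISTRATION_MIN_CORRELATION = 0.02


@dataclass
class BeamImage:
    """An RGB beam-fluorescence frame plus its geometry.

    ``beam_axis="row"`` means the beam travels along image rows, so depth
    increases with the column index (axis 1) and rows are lateral
    positions; ``"column"`` is the transpose convention.
    ``entrance_line`` is the pixel index (along the depth axis) of the
    cuvette inner face.
    """

    pixels: np.ndarray               # (h, w, 3)
    pixel_scale: float               # mm per pixel
    beam_axis: str = "row"
    entrance_line: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InputError("expected an RGB raster of shape (h, w, 3)")
        if self.pixel_scale <= 0:
            raise InputError("pixel scale must be positive")
        if self.beam_axis not in ("row", "column"):
            raise InputError("beam_axis must be 'row' or 'column'")
        n_depth = self.pixels.shape[1] if self.beam_axis == "row" else self.pixels.shape[0]
        if not (0 <= self.entrance_line < n_depth):
            raise InputError("entrance line outside the raster")

    @property
    def depth_axis(self) -> int:
        return 1 if self.beam_axis == "row" else 0


def to_grayscale(image: BeamImage | np.ndarray) -> np.ndarray:
    """Luminance grayscale of an RGB raster (hue/saturation discarded)."""
    px = image.pixels if isinstance(image, BeamImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise InputError("expected an RGB raster of shape (h, w, 3)")
    return px.astype(float) @ _LUMA


def register_and_subtract(lit: BeamImage, dark: BeamImage) -> np.ndarray:
    """Align the dark frame to the lit frame (integer-pixel translation)
    and return the clipped difference lit - dark.

    Registration is by cross-correlation; a shift beyond +/-10 px or a
    post-alignment correlation below threshold raises AnalysisError.
    """
    if lit.pixels.shape != dark.pixels.shape:
        raise InputError("image dimensions differ")
    g_lit = to_grayscale(lit)
    g_dark = to_grayscale(dark)
    if np.array_equal(g_lit, g_dark):
        return np.zeros_like(g_lit)
    if np.ptp(g_dark) == 0:
        # structureless dark frame: nothing to register against
        shift = np.zeros(2, dtype=int)
    else:
        shift, _, _ = phase_cross_correlation(g_lit, g_dark, upsample_factor=1)
        shift = np.round(shift).astype(int)
    if np.any(np.abs(shift) > MAX_REGISTRATION_SHIFT):
        raise AnalysisError(
            f"registration shift {tuple(shift)} exceeds +/-{MAX_REGISTRATION_SHIFT} px"
        )
    aligned = np.roll(g_dark, shift, axis=(0, 1))
    flat_l = g_lit.ravel() - g_lit.mean()
    flat_d = aligned.ravel() - aligned.mean()
    denom = np.linalg.norm(flat_l) * np.linalg.norm(flat_d)
    corr = float(flat_l @ flat_d / denom) if denom > 0 else 1.0
    if corr < REGISTRATION_MIN_CORRELATION:
        raise AnalysisError(f"registration correlation {corr:.3f} below threshold")
    return np.clip(g_lit - aligned, 0.0, None)


def _lateral_band(raster: np.ndarray, depth_axis: int, entrance: int) -> np.ndarray:
    """Indices of lateral positions inside the beam's lateral FWHM."""
    lateral_axis = 1 - depth_axis
    sl = [slice(None), slice(None)]
    sl[depth_axis] = slice(entrance, None)
    lateral = raster[tuple(sl)].sum(axis=depth_axis)
    if lateral.size == 0:
        raise InputError("empty lateral band")
    half = 0.5 * lateral.max()
    idx = np.flatnonzero(lateral >= half)
    if idx.size == 0:
        raise InputError("empty lateral band")
    # keep the contiguous run around the maximum
    peak = int(np.argmax(lateral))
    lo = peak
    while lo - 1 >= 0 and lateral[lo - 1] >= half:
        lo -= 1
    hi = peak
    while hi + 1 < lateral.size and lateral[hi + 1] >= half:
        hi += 1
    return np.arange(lo, hi + 1)


def depth_profile(raster: np.ndarray, geometry: BeamImage) -> FluorescenceProfile:
    """Average the raster across the beam's lateral FWHM band and return
    intensity versus depth (mm beyond the entrance line)."""
    raster = np.asarray(raster, dtype=float)
    if raster.ndim != 2:
        raise InputError("expected a 2-D intensity raster")
    dax = geometry.depth_axis
    n_depth = raster.shape[dax]
    if not (0 <= geometry.entrance_line < n_depth):
        raise InputError("entrance line outside the raster")
    band = _lateral_band(raster, dax, geometry.entrance_line)
    if dax == 1:
        sub = raster[band, geometry.entrance_line:]
        profile = sub.mean(axis=0)
    else:
        sub = raster[geometry.entrance_line:, band]
        profile = sub.mean(axis=1)
    depths = np.arange(profile.size) * geometry.pixel_scale
    return FluorescenceProfile(depths, profile)


def locate_fluorescence_max(profile: FluorescenceProfile) -> float:
    """Depth (mm) of the fluorescence maximum, parabolic interpolation."""
    return parabolic_peak(profile.depth_grid, profile.intensity)


def image_pair_peak_depth(lit: BeamImage, dark: BeamImage) -> float:
    """Full pipeline: register/subtract, profile, locate the maximum."""
    raster = register_and_subtract(lit, dark)
    return locate_fluorescence_max(depth_profile(raster, lit))
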