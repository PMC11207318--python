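"""Radiometric preprocessing and acquisition-geometry utilities.

Covers the empirical line method (ELM) radiance-to-reflectance calibration
through in-scene reference panels, BayesShrink soft-threshold wavelet
denoising along the spectral axis, the first spectral derivative, and the
ground-sample-distance / swath-path geometry checks that justify treating
every pixel as equidistant from a line-scanning sensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pywt

from .datacube import SensorGeometry, SpectralCube

__all__ = [
    "ELMCoefficients",
    "compute_gsd",
    "swath_path_difference",
    "panel_mean_spectrum",
    "fit_elm",
    "apply_elm",
    "invert_elm",
    "denoise_wavelet",
    "spectral_derivative",
]

#: Nominal flat reflectances of the dark and light calibration panels.
DEFAULT_PANEL_REFLECTANCES = (0.06, 0.55)


@dataclass
class ELMCoefficients:
    """Per-band affine map ``reflectance = gain * radiance + bias``."""

    gain: np.ndarray
    bias: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if not (len(self.gain) == len(self.bias) == len(self.wavelengths)):
            raise ValueError("gain, bias and wavelengths must have equal length")
        if not np.all(np.isfinite(self.gain)) or not np.all(np.isfinite(self.bias)):
            raise ValueError("ELM coefficients must be finite")
        if np.any(self.gain == 0):
            raise ValueError("ELM gains must be nonzero")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "gain": self.gain, "bias": self.bias}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ELMCoefficients":
        df = pd.read_csv(path)
        return cls(df["gain"].to_numpy(), df["bias"].to_numpy(), df["wavelength_nm"].to_numpy())


def compute_gsd(geometry: SensorGeometry) -> float:
    """Ground sample distance: ``altitude * pixel_pitch / focal_length`` (m)."""
    return geometry.altitude * geometry.pixel_pitch / geometry.focal_length


def swath_path_difference(altitude: float, swath_width: float) -> tuple[float, float]:
    """Slant-path excess of the swath-edge pixel over the nadir pixel.

    Returns ``(excess_m, excess_percent_of_altitude)``; the percentage is the
    quantity that justifies the equidistance assumption of the ELM.
    """
    if altitude <= 0:
        raise ValueError("altitude must be > 0")
    if swath_width < 0:
        raise ValueError("swath_width must be >= 0")
    excess = math.hypot(altitude, swath_width / 2.0) - altitude
    return excess, 100.0 * excess / altitude


def panel_mean_spectrum(cube: SpectralCube, mask: np.ndarray, stat: str = "mean") -> np.ndarray:
    """Per-band mean (or median) radiance over a boolean panel mask."""
    if mask.shape != cube.shape[1:]:
        raise ValueError("panel mask shape does not match cube extent")
    if not mask.any():
        raise ValueError("panel mask selects no pixels")
    pix = cube.values[:, mask].astype(np.float64)
    if stat == "mean":
        return pix.mean(axis=1)
    if stat == "median":
        return np.median(pix, axis=1)
    raise ValueError(f"unknown stat {stat!r}")


def fit_elm(
    dark_panel_spectrum: np.ndarray,
    light_panel_spectrum: np.ndarray,
    wavelengths: np.ndarray,
    dark_reflectance: float = DEFAULT_PANEL_REFLECTANCES[0],
    light_reflectance: float = DEFAULT_PANEL_REFLECTANCES[1],
) -> ELMCoefficients:
    """Two-point empirical line fit through the dark and light panels.

    Per band: ``gain = (rho_l - rho_d) / (L_l - L_d)``;
    ``bias = rho_d - gain * L_d``.
    """
    if not dark_reflectance < light_reflectance:
        raise ValueError("dark panel reflectance must be below the light panel's")
    dark = np.asarray(dark_panel_spectrum, dtype=float)
    light = np.asarray(light_panel_spectrum, dtype=float)
    if dark.shape != light.shape:
        raise ValueError("panel spectra must have equal length")
    delta = light - dark
    degenerate = np.nonzero(delta == 0)[0]
    if degenerate.size:
        raise ValueError(
            f"degenerate calibration: identical panel radiances in band(s) {degenerate.tolist()}"
        )
    gain = (light_reflectance - dark_reflectance) / delta
    bias = dark_reflectance - gain * dark
    return ELMCoefficients(gain, bias, wavelengths)


def _check_grids(a: np.ndarray, b: np.ndarray) -> None:
    if len(a) != len(b) or not np.allclose(a, b, atol=1e-6):
        raise ValueError("wavelength grids do not match")


def apply_elm(cube: SpectralCube, coeffs: ELMCoefficients) -> SpectralCube:
    """Convert a radiance cube to reflectance, band by band."""
    if cube.domain != "radiance":
        raise ValueError(f"apply_elm expects a radiance cube, got domain={cube.domain!r}")
    _check_grids(cube.wavelengths, coeffs.wavelengths)
    dt = cube.values.dtype
    out = cube.values * coeffs.gain.astype(dt)[:, None, None] + coeffs.bias.astype(dt)[:, None, None]
    return SpectralCube(out, cube.wavelengths, "reflectance", cube.gsd, dict(cube.meta))


def invert_elm(cube: SpectralCube, coeffs: ELMCoefficients) -> SpectralCube:
    """Invert the per-band affine calibration (reflectance back to radiance)."""
    if cube.domain != "reflectance":
        raise ValueError(f"invert_elm expects a reflectance cube, got domain={cube.domain!r}")
    _check_grids(cube.wavelengths, coeffs.wavelengths)
    dt = cube.values.dtype
    out = (cube.values - coeffs.bias.astype(dt)[:, None, None]) / coeffs.gain.astype(dt)[:, None, None]
    return SpectralCube(out, cube.wavelengths, "radiance", cube.gsd, dict(cube.meta))


def denoise_wavelet(
    cube: SpectralCube,
    wavelet: str = "sym4",
    level: int | None = None,
) -> SpectralCube:
    """BayesShrink soft-threshold wavelet denoising along the spectral axis.

    Each pixel spectrum is decomposed with a multi-level DWT; the noise sigma
    is estimated per pixel from the median absolute deviation of the finest
    detail coefficients (MAD / 0.6745); each level gets the BayesShrink
    threshold ``sigma_n**2 / sigma_x`` (with ``sigma_x**2 = max(var - sigma_n**2, 0)``)
    and its coefficients are soft-thresholded before reconstruction.  The
    smoothing is 1-D per pixel; no spatial mixing occurs.
    """
    n = cube.n_bands
    w = pywt.Wavelet(wavelet)
    if n < w.dec_len:
        raise ValueError(f"spectrum of {n} bands is shorter than the {wavelet} filter support")
    if level is None:
        level = max(1, int(math.floor(math.log2(n))) - 2)
    level = min(level, pywt.dwt_max_level(n, w.dec_len))
    vals = cube.values.astype(np.float64, copy=False)
    coeffs = pywt.wavedec(vals, w, level=level, axis=0)
    finest = coeffs[-1]
    med = np.median(finest, axis=0)
    sigma_n = np.median(np.abs(finest - med[None]), axis=0) / 0.6745
    var_n = sigma_n**2
    for i in range(1, len(coeffs)):
        d = coeffs[i]
        var_d = np.mean(d**2, axis=0)
        sigma_x = np.sqrt(np.maximum(var_d - var_n, 0.0))
        # sigma_x == 0 means the level is pure noise: kill every coefficient
        thr = np.where(sigma_x > 0, var_n / np.maximum(sigma_x, 1e-300), np.inf)
        coeffs[i] = np.sign(d) * np.maximum(np.abs(d) - thr[None], 0.0)
    rec = pywt.waverec(coeffs, w, axis=0)[:n]
    return SpectralCube(
        rec.astype(cube.values.dtype), cube.wavelengths, cube.domain, cube.gsd, dict(cube.meta)
    )


def spectral_derivative(cube: SpectralCube) -> SpectralCube:
    """First derivative of each pixel spectrum with respect to wavelength.

    Central finite differences on the wavelength grid, one-sided at the ends
    (exact for spectra linear in wavelength).
    """
    if cube.n_bands < 2:
        raise ValueError("spectral derivative needs at least 2 bands")
    deriv = np.gradient(cube.values.astype(np.float64, copy=False), cube.wavelengths, axis=0)
    return SpectralCube(
        deriv.astype(cube.values.dtype), cube.wavelengths, "derivative", cube.gsd, dict(cube.meta)
    )
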