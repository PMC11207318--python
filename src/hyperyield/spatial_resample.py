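"""Spatial GSD degradation: tile, PSF-blur, block-average.

Emulates acquiring the same subplot with a coarser-resolution system:

1. **tile** — repeat the subplot image in a near-square grid (default eight
   copies, 2 x 4), enlarging its area so even a 30 m pixel sees more than one
   sample; optionally zero-pad the border.
2. **blur** — convolve each band with a Gaussian point spread function whose
   FWHM (in metres) equals the target GSD, emulating the coarser system's
   optics.
3. **average** — non-overlapping block means at the target GSD.

Boundary handling: the default is periodic (``wrap``), which is the exact
continuum of tiling-by-replication — the blurred mosaic stays periodic, so
interior means are conserved exactly.  Zero padding plus constant-boundary
convolution (``boundary="zero"``) reproduces the alternative edge treatment;
the padded ring is recorded in cube metadata and excluded from means.
Large-sigma wrap blurs go through the FFT (circular convolution is exact
there).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import fourier_gaussian, gaussian_filter

from .datacube import SpectralCube

__all__ = ["tile_subplot", "psf_blur", "block_downsample", "spatial_pipeline"]

FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Default number of tiled copies (area ratio 0.72 ha / 0.09 ha).
DEFAULT_TILING_FACTOR = 8


def _tile_grid(factor: int) -> tuple[int, int]:
    """Near-square (rows, cols) arrangement: largest divisor <= sqrt."""
    r = max(d for d in range(1, int(math.isqrt(factor)) + 1) if factor % d == 0)
    return r, factor // r


def tile_subplot(cube: SpectralCube, factor: int, pad_px: int = 0) -> SpectralCube:
    """Repeat the subplot image ``factor`` times in a near-square grid.

    The per-band pixel multiset of the (unpadded) mosaic is exactly
    ``factor`` copies of the original.  ``pad_px`` adds a zero border on all
    sides (used with the zero boundary mode); the pad width and tile geometry
    are recorded in ``meta``.
    """
    if factor < 1:
        raise ValueError(f"tiling factor must be >= 1, got {factor}")
    gr, gc = _tile_grid(int(factor))
    vals = np.tile(cube.values, (1, gr, gc))
    if pad_px > 0:
        vals = np.pad(vals, ((0, 0), (pad_px, pad_px), (pad_px, pad_px)))
    meta = dict(cube.meta)
    meta.update(
        tile_grid=(gr, gc),
        tile_shape=cube.values.shape[1:],
        pad_px=pad_px,
    )
    return SpectralCube(vals, cube.wavelengths, cube.domain, cube.gsd, meta)


def psf_sigma_px(cube_gsd: float, target_gsd: float, fwhm_multiplier: float = 1.0) -> float:
    """PSF sigma in input pixels for a kernel of FWHM = target GSD (metres)."""
    return fwhm_multiplier * target_gsd / FWHM_TO_SIGMA / cube_gsd


def psf_blur(
    cube: SpectralCube,
    target_gsd: float,
    fwhm_multiplier: float = 1.0,
    boundary: str = "wrap",
) -> SpectralCube:
    """Per-band 2-D Gaussian blur with kernel FWHM (metres) = target GSD.

    The kernel is normalized to unit sum (unit DC gain), so interior band
    means are preserved.  ``boundary`` is ``"wrap"`` (periodic; exact for
    tiled mosaics) or ``"zero"`` (zero-filled outside, matching explicit zero
    padding).  Wrap blurs with large sigma use the FFT.
    """
    if target_gsd < cube.gsd:
        raise ValueError(f"target GSD {target_gsd} is finer than the cube's {cube.gsd}")
    if boundary not in ("wrap", "zero"):
        raise ValueError("boundary must be 'wrap' or 'zero'")
    sigma = psf_sigma_px(cube.gsd, target_gsd, fwhm_multiplier)
    out = np.empty_like(cube.values)
    if boundary == "wrap" and sigma > 8.0:
        for b in range(cube.n_bands):
            f = np.fft.rfft2(cube.values[b].astype(np.float64))
            f = fourier_gaussian(f, sigma=sigma, n=cube.values.shape[2])
            out[b] = np.fft.irfft2(f, s=cube.values.shape[1:])
    else:
        mode = "wrap" if boundary == "wrap" else "constant"
        for b in range(cube.n_bands):
            gaussian_filter(
                cube.values[b], sigma=sigma, mode=mode, cval=0.0, truncate=3.0, output=out[b]
            )
    meta = dict(cube.meta)
    meta.update(psf_sigma_px=sigma, psf_boundary=boundary)
    return SpectralCube(out, cube.wavelengths, cube.domain, cube.gsd, meta)


def block_downsample(cube: SpectralCube, target_gsd: float) -> SpectralCube:
    """Non-overlapping block means at the target GSD.

    The block edge is ``round(target / current)`` input pixels; trailing rows
    and columns that do not fill a block are dropped, and the realized GSD
    (``block * current``) is recorded — the nominal value is not forced.
    """
    ratio = target_gsd / cube.gsd
    block = int(round(ratio))
    if block < 1:
        raise ValueError(f"target GSD {target_gsd} below the cube GSD {cube.gsd}")
    if block == 1:
        return cube.copy()
    nb, rows, cols = cube.shape
    out_r, out_c = rows // block, cols // block
    if out_r < 1 or out_c < 1:
        raise ValueError(
            f"block edge {block} px exceeds the cube extent {rows}x{cols}; tile first"
        )
    v = cube.values[:, : out_r * block, : out_c * block]
    v = v.reshape(nb, out_r, block, out_c, block).mean(axis=(2, 4))
    meta = dict(cube.meta)
    meta.update(block_px=block, realized_gsd=block * cube.gsd)
    for key in ("pad_px", "interior_margin_px"):
        if key in meta:
            meta[key] = int(math.ceil(meta[key] / block))
    return SpectralCube(v, cube.wavelengths, cube.domain, block * cube.gsd, meta)


def spatial_pipeline(
    cube: SpectralCube,
    target_gsd: float,
    tiling_factor: int = DEFAULT_TILING_FACTOR,
    fwhm_multiplier: float = 1.0,
    boundary: str = "wrap",
) -> SpectralCube:
    """Full cascade tile -> blur -> block-average for one subplot cube.

    When ``target_gsd`` equals the native GSD the result is the tiled-only
    product (no blur, no averaging).  With ``boundary="zero"`` the tile step
    zero-pads by the PSF half-width (3 sigma, rounded up).
    """
    if target_gsd < cube.gsd:
        raise ValueError(f"target GSD {target_gsd} is finer than the cube's {cube.gsd}")
    native = math.isclose(target_gsd, cube.gsd, rel_tol=1e-9)
    pad = 0
    if boundary == "zero" and not native:
        pad = int(math.ceil(3.0 * psf_sigma_px(cube.gsd, target_gsd, fwhm_multiplier)))
    tiled = tile_subplot(cube, tiling_factor, pad_px=pad)
    if native:
        return tiled
    if pad > 0:
        # ring influenced by the zero boundary: pad itself plus blur reach
        tiled.meta["interior_margin_px"] = 2 * pad
    blurred = psf_blur(tiled, target_gsd, fwhm_multiplier, boundary=boundary)
    return block_downsample(blurred, target_gsd)
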