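"""Synthetic field-scene generator.

Emulates the statistical structure of a UAS hyperspectral acquisition over a
corn silage trial: a VNIR radiance cube (default 272 bands over 400-1000 nm)
covering 36 rectangular subplots, ~20% bare-soil pixels, two flat Lambertian
calibration panels (6% and 55% reflectance), band-dependent sensor noise
inflated in the blue and NIR, and right-skewed per-subplot yields linked to
canopy spectral parameters.  Every draw is controlled by a single seed; the
same :class:`SceneParams` produce bitwise-identical scenes.

The vegetation model is parametric (Gaussian bumps + logistic red edge +
Gaussian water dips), not a radiative-transfer code: parametric spectra have
analytically checkable features (the red-edge inflection, the green peak, the
water dips), which is what the downstream tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datacube import FieldLayout, SpectralCube, Subplot, YieldTable

__all__ = [
    "CanopyParams",
    "SceneParams",
    "SceneData",
    "make_vegetation_spectrum",
    "make_soil_spectrum",
    "illumination_spectrum",
    "noise_sigma_profile",
    "make_field_scene",
    "make_yields",
]


@dataclass(frozen=True)
class CanopyParams:
    """Per-subplot canopy state driving the vegetation spectrum.

    chlorophyll and water are dimensionless levels in [0, 1.5]; nir_plateau
    is the asymptotic NIR reflectance; red_edge_nm is the logistic inflection
    wavelength of the red-edge rise.
    """

    chlorophyll: float = 0.7
    water: float = 0.7
    nir_plateau: float = 0.5
    red_edge_nm: float = 715.0

    def validate(self) -> None:
        if not (0.0 <= self.chlorophyll <= 1.5):
            raise ValueError(f"chlorophyll level {self.chlorophyll} outside [0, 1.5]")
        if not (0.0 <= self.water <= 1.5):
            raise ValueError(f"water level {self.water} outside [0, 1.5]")
        if not (0.1 <= self.nir_plateau <= 0.9):
            raise ValueError(f"nir_plateau {self.nir_plateau} outside [0.1, 0.9]")
        if not (690.0 <= self.red_edge_nm <= 745.0):
            raise ValueError(f"red_edge_nm {self.red_edge_nm} outside [690, 745]")


@dataclass
class SceneParams:
    """Knobs of the synthetic acquisition.

    Defaults mirror the emulated campaign: 36 subplots in a 6x6 grid, 272
    bands over 400-1000 nm, ~20% soil pixels, panels at 6%/55%.  Subplot
    pixel extents are a scaled stand-in for the 15 x 61 m plots (full native
    resolution is far beyond desk scale); the aspect ratio is preserved and
    the extents divide evenly into the block sizes used by the spatial
    degradation ladder.
    """

    n_subplots: int = 36
    subplot_grid: tuple[int, int] = (6, 6)
    subplot_shape_px: tuple[int, int] = (64, 240)
    n_bands: int = 272
    wavelength_range_nm: tuple[float, float] = (400.0, 1000.0)
    gsd: float = 0.063
    soil_fraction: float = 0.2
    soil_brightness: float = 1.0
    # per-subplot canopy parameter sampling ranges
    chlorophyll_range: tuple[float, float] = (0.45, 1.0)
    water_range: tuple[float, float] = (0.35, 1.0)
    nir_plateau_range: tuple[float, float] = (0.38, 0.62)
    red_edge_range_nm: tuple[float, float] = (706.0, 724.0)
    canopy_params: list[CanopyParams] | None = None  # explicit override
    # within-subplot canopy variability: relative per-pixel jitter of the
    # chlorophyll and water levels (leaf-to-leaf biochemical variation)
    canopy_jitter: float = 0.15
    # radiometric noise: relative sigma, inflated below 450 nm / above 900 nm
    noise_sigma: float = 0.01
    speckle_sigma: float = 0.0  # per-pixel multiplicative (brightness) speckle
    illumination_scale: float = 100.0
    panel_reflectances: tuple[float, float] = (0.06, 0.55)
    panel_size_px: tuple[int, int] = (16, 16)
    # yield link: yield = yield_scale * exp(yield_skew * z(score)) + noise
    yield_weights: tuple[float, float] = (1.0, 4.0)  # (chlorophyll, nir_plateau)
    yield_scale: float = 16.0
    yield_skew: float = 0.8
    yield_noise_sigma: float = 0.25
    dtype: type = np.float32
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.soil_fraction <= 1.0):
            raise ValueError("soil_fraction must lie in [0, 1]")
        if self.noise_sigma < 0 or self.speckle_sigma < 0 or self.yield_noise_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        lo, hi = self.panel_reflectances
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("panel reflectances must satisfy 0 < dark < light < 1")
        gr, gc = self.subplot_grid
        if gr * gc != self.n_subplots:
            raise ValueError(f"subplot grid {self.subplot_grid} does not hold {self.n_subplots} subplots")

    @property
    def wavelengths(self) -> np.ndarray:
        lo, hi = self.wavelength_range_nm
        return np.linspace(lo, hi, self.n_bands)


@dataclass
class SceneData:
    """Everything :func:`make_field_scene` produces."""

    cube: SpectralCube  # radiance
    layout: FieldLayout
    yields: YieldTable
    panel_masks: dict[str, np.ndarray]  # "dark"/"light" boolean (row, col) masks
    canopy: list[CanopyParams]
    params: SceneParams


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_vegetation_spectrum(wavelengths: np.ndarray, params: CanopyParams) -> np.ndarray:
    """Parametric green-vegetation reflectance on the given wavelength grid.

    Structure: a low visible baseline rising through a logistic red edge to
    the NIR plateau; a chlorophyll-scaled green peak near 550 nm and red
    absorption well near 670 nm; water-scaled absorption dips near 820 and
    940 nm.  All features are smooth, and the result stays inside [0, 1].
    """
    params.validate()
    wl = np.asarray(wavelengths, dtype=float)
    if wl.min() > 420 or wl.max() < 950:
        raise ValueError("wavelength grid must span the VNIR range (~400-1000 nm)")
    base = 0.05
    r = base + (params.nir_plateau - base) * _sigmoid((wl - params.red_edge_nm) / 14.0)
    r = r + 0.07 * params.chlorophyll * np.exp(-0.5 * ((wl - 550.0) / 22.0) ** 2)
    r = r - 0.033 * params.chlorophyll * np.exp(-0.5 * ((wl - 670.0) / 28.0) ** 2)
    r = r - params.water * (
        0.05 * np.exp(-0.5 * ((wl - 820.0) / 14.0) ** 2)
        + 0.09 * np.exp(-0.5 * ((wl - 940.0) / 22.0) ** 2)
    )
    return np.clip(r, 1e-4, 1.0)


def make_soil_spectrum(wavelengths: np.ndarray, brightness: float = 1.0) -> np.ndarray:
    """Slowly increasing bare-soil reflectance, linear in ``brightness``.

    At default brightness the red (670 nm) soil reflectance exceeds the
    default vegetation green peak, matching the contrast that depresses
    green-region scores when soil pixels are present.
    """
    if brightness < 0:
        raise ValueError("brightness must be >= 0")
    wl = np.asarray(wavelengths, dtype=float)
    return brightness * (0.14 + 0.18 * (wl - 400.0) / 600.0)


def illumination_spectrum(wavelengths: np.ndarray, scale: float = 100.0) -> np.ndarray:
    """Smooth positive downwelling spectrum (arbitrary radiance units)."""
    wl = np.asarray(wavelengths, dtype=float)
    return scale * (0.5 + np.exp(-(((wl - 550.0) / 350.0) ** 2)))


def noise_sigma_profile(wavelengths: np.ndarray, sigma_rel: float, scale: float) -> np.ndarray:
    """Per-band additive radiance noise sigma, inflated in blue and NIR."""
    wl = np.asarray(wavelengths, dtype=float)
    inflation = 1.0 + 2.0 * _sigmoid((450.0 - wl) / 15.0) + 2.0 * _sigmoid((wl - 900.0) / 25.0)
    return sigma_rel * scale * inflation


def _canopy_score(c: CanopyParams, weights: tuple[float, float]) -> float:
    return weights[0] * c.chlorophyll + weights[1] * c.nir_plateau


def make_yields(
    canopy_params: list[CanopyParams],
    params: SceneParams | None = None,
    seed: int | None = None,
) -> YieldTable:
    """Generate per-subplot yields from canopy parameters.

    The canopy score (weighted chlorophyll + NIR plateau) is standardized
    against the mid-point and span of the sampling ranges and passed through
    an exponential (right-skewing) link, then seeded Gaussian noise is added.
    Non-positive draws are resampled (iteration cap 100).  Yields carry the
    35% dry-matter convention flag.
    """
    p = params if params is not None else SceneParams()
    rng = np.random.default_rng(p.seed if seed is None else seed)
    w = p.yield_weights
    lo = w[0] * p.chlorophyll_range[0] + w[1] * p.nir_plateau_range[0]
    hi = w[0] * p.chlorophyll_range[1] + w[1] * p.nir_plateau_range[1]
    mid, span = 0.5 * (lo + hi), max(0.5 * (hi - lo), 1e-9)
    yields: dict[str, float] = {}
    for i, c in enumerate(canopy_params):
        z = (_canopy_score(c, w) - mid) / span
        clean = p.yield_scale * float(np.exp(p.yield_skew * z))
        y = clean + float(rng.normal(0.0, p.yield_noise_sigma))
        for _ in range(100):
            if y > 0:
                break
            y = clean + float(rng.normal(0.0, p.yield_noise_sigma))
        else:
            raise RuntimeError("could not draw a positive yield within 100 attempts")
        yields[f"sp{i:02d}"] = y
    return YieldTable(yields, dry_matter_fraction=0.35)


def _sample_canopy(params: SceneParams, rng: np.random.Generator) -> list[CanopyParams]:
    def u(rg: tuple[float, float], n: int) -> np.ndarray:
        return rng.uniform(rg[0], rg[1], n)

    n = params.n_subplots
    chl = u(params.chlorophyll_range, n)
    wat = u(params.water_range, n)
    nir = u(params.nir_plateau_range, n)
    red = u(params.red_edge_range_nm, n)
    return [CanopyParams(chl[i], wat[i], nir[i], red[i]) for i in range(n)]


# nitrogen sidedress rates of the emulated trial (kg/ha), cycled over subplots
NITROGEN_RATES = (0.0, 43.0, 85.0, 130.0, 172.0, 215.0)


def make_field_scene(params: SceneParams) -> SceneData:
    """Render the full synthetic acquisition.

    The radiance cube is ``illumination x per-pixel reflectance`` plus
    band-dependent Gaussian sensor noise.  Vegetation pixels within a subplot
    share that subplot's canopy parameters; soil pixels are placed by seeded
    binomial sampling at ``soil_fraction``; optional per-pixel multiplicative
    speckle models pixel-scale brightness variability (leaf angle, glint).
    Two panel squares with flat 6%/55% reflectance sit in a strip below the
    subplot grid.  Yields derive from the canopy parameters via
    :func:`make_yields` (same seed stream).
    """
    rng = np.random.default_rng(params.seed)
    wl = params.wavelengths
    gr, gc = params.subplot_grid
    sr, sc = params.subplot_shape_px
    pr, pc = params.panel_size_px
    panel_strip = pr + 8
    rows = gr * sr + panel_strip
    cols = gc * sc
    if cols < 2 * pc + 24:
        raise ValueError("scene too narrow to hold the two calibration panels")

    canopy = params.canopy_params
    if canopy is None:
        canopy = _sample_canopy(params, rng)
    elif len(canopy) != params.n_subplots:
        raise ValueError("need one CanopyParams per subplot")
    for c in canopy:
        c.validate()

    soil = make_soil_spectrum(wl, params.soil_brightness)
    reflectance = np.empty((params.n_bands, rows, cols), dtype=params.dtype)
    reflectance[:, :, :] = soil[:, None, None]  # background / panel strip default

    subplots = []
    for i in range(params.n_subplots):
        g_r, g_c = divmod(i, gc)
        r0, c0 = g_r * sr, g_c * sc
        veg = make_vegetation_spectrum(wl, canopy[i]).astype(params.dtype)
        block = np.broadcast_to(veg[:, None, None], (params.n_bands, sr, sc)).copy()
        if params.canopy_jitter > 0:
            # linearized per-pixel biochemical variation: one spectral
            # direction per parameter, amplitude ~ N(0, jitter) per pixel
            c = canopy[i]
            d_chl = (
                make_vegetation_spectrum(wl, replace(c, chlorophyll=min(c.chlorophyll * 1.1, 1.5)))
                - veg.astype(float)
            ) / max(0.1 * c.chlorophyll, 1e-6)
            d_wat = (
                make_vegetation_spectrum(wl, replace(c, water=min(c.water * 1.1, 1.5)))
                - veg.astype(float)
            ) / max(0.1 * c.water, 1e-6)
            a = rng.normal(0.0, params.canopy_jitter * c.chlorophyll, (sr, sc))
            b2 = rng.normal(0.0, params.canopy_jitter * c.water, (sr, sc))
            block += (
                d_chl.astype(params.dtype)[:, None, None] * a[None].astype(params.dtype)
                + d_wat.astype(params.dtype)[:, None, None] * b2[None].astype(params.dtype)
            )
        if params.soil_fraction > 0:
            soil_mask = rng.random((sr, sc)) < params.soil_fraction
            block[:, soil_mask] = soil.astype(params.dtype)[:, None]
        reflectance[:, r0 : r0 + sr, c0 : c0 + sc] = block
        subplots.append(
            Subplot(
                f"sp{i:02d}",
                r0,
                r0 + sr,
                c0,
                c0 + sc,
                nitrogen_rate=NITROGEN_RATES[i % len(NITROGEN_RATES)],
                manure=i % 2 == 0,
            )
        )
    layout = FieldLayout(subplots)

    # calibration panels in the strip below the subplots
    strip_r0 = gr * sr + 4
    dark_rect = (strip_r0, strip_r0 + pr, 8, 8 + pc)
    light_rect = (strip_r0, strip_r0 + pr, 8 + pc + 16, 8 + 2 * pc + 16)
    masks = {}
    for name, rect, rho in (
        ("dark", dark_rect, params.panel_reflectances[0]),
        ("light", light_rect, params.panel_reflectances[1]),
    ):
        m = np.zeros((rows, cols), dtype=bool)
        m[rect[0] : rect[1], rect[2] : rect[3]] = True
        reflectance[:, m] = rho
        masks[name] = m

    if params.speckle_sigma > 0:
        speckle = rng.normal(1.0, params.speckle_sigma, (rows, cols)).astype(params.dtype)
        np.clip(speckle, 0.05, None, out=speckle)
        speckle[masks["dark"] | masks["light"]] = 1.0  # panels stay flat
        reflectance *= speckle[None, :, :]

    illum = illumination_spectrum(wl, params.illumination_scale).astype(params.dtype)
    radiance = reflectance
    radiance *= illum[:, None, None]
    if params.noise_sigma > 0:
        sigma = noise_sigma_profile(wl, params.noise_sigma, params.illumination_scale)
        noise = rng.standard_normal(radiance.shape, dtype=np.float32).astype(params.dtype)
        noise *= sigma.astype(params.dtype)[:, None, None]
        radiance += noise

    cube = SpectralCube(radiance, wl, "radiance", params.gsd)
    yields = make_yields(canopy, params, seed=rng.integers(0, 2**31 - 1))
    return SceneData(cube, layout, yields, masks, list(canopy), params)
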