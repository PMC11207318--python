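"""Core spectral-cube and tabular data types, with ENVI-dialect readers/writers.

A :class:`SpectralCube` holds a (band, row, col) array of samples together
with its wavelength grid (nm), the value domain (radiance, reflectance, or
first spectral derivative), and the ground sample distance (GSD, metres per
pixel).  Cubes are stored on disk as band-sequential (BSQ) rasters with a
plain-text ENVI-style header; pixel coordinates are 0-based, row-major,
origin at top-left, and rectangles are half-open ``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectralCube",
    "SensorGeometry",
    "Subplot",
    "FieldLayout",
    "YieldTable",
    "read_cube",
    "write_cube",
    "subset_wavelengths",
]

VALID_DOMAINS = ("radiance", "reflectance", "derivative")

#: Slack allowed for reflectance values outside [0, 1] (sensor noise).
DEFAULT_REFLECTANCE_TOL = 0.25


class CubeFormatError(ValueError):
    """Raised when an on-disk cube (header or raster) cannot be parsed."""


@dataclass
class SpectralCube:
    """A hyperspectral or multispectral image cube.

    Parameters
    ----------
    values
        Array of shape ``(bands, rows, cols)`` in the units implied by
        ``domain``.
    wavelengths
        Band-centre wavelengths in nm, strictly increasing, one per band.
    domain
        One of ``"radiance"``, ``"reflectance"``, ``"derivative"``.
    gsd
        Ground sample distance in metres per pixel (> 0).
    meta
        Free-form provenance (tiling pad, realized GSD, ...); not validated.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    domain: str
    gsd: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self, reflectance_tol: float = DEFAULT_REFLECTANCE_TOL) -> None:
        if self.values.ndim != 3:
            raise ValueError(f"cube values must be 3-D (band,row,col), got {self.values.ndim}-D")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[0]:
            raise ValueError(
                f"wavelength count {len(self.wavelengths)} != band axis {self.values.shape[0]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.domain not in VALID_DOMAINS:
            raise ValueError(f"domain must be one of {VALID_DOMAINS}, got {self.domain!r}")
        if not (self.gsd > 0):
            raise ValueError(f"gsd must be > 0, got {self.gsd}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube contains non-finite values")
        if self.domain == "reflectance":
            lo, hi = float(self.values.min()), float(self.values.max())
            if lo < -reflectance_tol or hi > 1.0 + reflectance_tol:
                raise ValueError(
                    f"reflectance values [{lo:.3g}, {hi:.3g}] outside [0,1] beyond "
                    f"tolerance {reflectance_tol}"
                )

    # -- convenience ----------------------------------------------------
    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "SpectralCube":
        return SpectralCube(
            self.values.copy(), self.wavelengths.copy(), self.domain, self.gsd, dict(self.meta)
        )

    def crop(self, r0: int, r1: int, c0: int, c1: int) -> "SpectralCube":
        """Spatial crop with half-open bounds; metadata carried over."""
        return SpectralCube(
            self.values[:, r0:r1, c0:c1], self.wavelengths, self.domain, self.gsd, dict(self.meta)
        )


@dataclass(frozen=True)
class SensorGeometry:
    """Line-scanner acquisition geometry (all lengths in metres)."""

    altitude: float
    pixel_pitch: float
    focal_length: float
    swath_width: float

    def __post_init__(self) -> None:
        for name in ("altitude", "pixel_pitch", "focal_length", "swath_width"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class Subplot:
    """One field subplot: id, half-open pixel rectangle, treatment labels."""

    id: str
    r0: int
    r1: int
    c0: int
    c1: int
    nitrogen_rate: float = 0.0  # kg/ha
    manure: bool = False

    def __post_init__(self) -> None:
        if not (self.r0 < self.r1 and self.c0 < self.c1):
            raise ValueError(f"subplot {self.id}: empty rectangle")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.r1 - self.r0, self.c1 - self.c0)


@dataclass
class FieldLayout:
    """The field's division into non-overlapping subplots."""

    subplots: list[Subplot]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subplots]
        if len(set(ids)) != len(ids):
            raise ValueError("subplot ids must be unique")
        self._check_overlap()

    def _check_overlap(self) -> None:
        for i, a in enumerate(self.subplots):
            for b in self.subplots[i + 1 :]:
                if a.r0 < b.r1 and b.r0 < a.r1 and a.c0 < b.c1 and b.c0 < a.c1:
                    raise ValueError(f"subplots {a.id} and {b.id} overlap")

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.subplots]

    def __iter__(self):
        return iter(self.subplots)

    def __len__(self) -> int:
        return len(self.subplots)

    def validate_against(self, shape: tuple[int, int, int]) -> None:
        """Check every rectangle lies within a cube of the given shape."""
        _, rows, cols = shape
        for s in self.subplots:
            if s.r0 < 0 or s.c0 < 0 or s.r1 > rows or s.c1 > cols:
                raise ValueError(f"subplot {s.id} rectangle outside cube extent {rows}x{cols}")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "subplot_id": s.id,
                    "r0": s.r0,
                    "r1": s.r1,
                    "c0": s.c0,
                    "c1": s.c1,
                    "nitrogen_rate_kg_ha": s.nitrogen_rate,
                    "manure": int(s.manure),
                }
                for s in self.subplots
            ]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FieldLayout":
        df = pd.read_csv(path)
        return cls(
            [
                Subplot(
                    str(r.subplot_id),
                    int(r.r0),
                    int(r.r1),
                    int(r.c0),
                    int(r.c1),
                    float(r.nitrogen_rate_kg_ha),
                    bool(r.manure),
                )
                for r in df.itertuples()
            ]
        )


@dataclass
class YieldTable:
    """Per-subplot silage yield in Mg/ha at a fixed dry-matter convention."""

    yields: dict[str, float]
    dry_matter_fraction: float = 0.35

    def __post_init__(self) -> None:
        for k, v in self.yields.items():
            if not (v > 0):
                raise ValueError(f"yield for subplot {k} must be > 0, got {v}")

    def __getitem__(self, key: str) -> float:
        return self.yields[key]

    def __len__(self) -> int:
        return len(self.yields)

    def check_layout(self, layout: FieldLayout) -> None:
        missing = set(layout.ids) - set(self.yields)
        extra = set(self.yields) - set(layout.ids)
        if missing or extra:
            raise ValueError(f"yield table mismatch: missing={sorted(missing)} extra={sorted(extra)}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.yields, name="yield_mg_ha")

    def to_csv(self, path: str | Path) -> None:
        df = self.as_series().rename_axis("subplot_id").reset_index()
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, dry_matter_fraction: float = 0.35) -> "YieldTable":
        df = pd.read_csv(path)
        return cls(
            {str(r.subplot_id): float(r.yield_mg_ha) for r in df.itertuples()},
            dry_matter_fraction,
        )


# ---------------------------------------------------------------------------
# ENVI-dialect BSQ I/O
# ---------------------------------------------------------------------------

_DTYPE_CODES = {4: np.float32, 5: np.float64}
_DTYPE_TO_CODE = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _header_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hdr") if path.suffix != ".hdr" else path


def write_cube(
    cube: SpectralCube,
    path: str | Path,
    overwrite: bool = True,
    dtype: np.dtype | None = None,
) -> None:
    """Write a cube as a raw BSQ raster plus an ENVI-style text header.

    ``path`` names the raster; the header is written next to it as
    ``<path>.hdr``.  With ``overwrite=False`` an existing raster raises
    :class:`FileExistsError`.  Samples default to 32-bit floats.
    """
    path = Path(path)
    if not overwrite and path.exists():
        raise FileExistsError(f"{path} exists and overwrite protection is set")
    dt = np.dtype(dtype) if dtype is not None else np.dtype(np.float32)
    if dt not in _DTYPE_TO_CODE:
        raise ValueError(f"unsupported sample type {dt}; use float32 or float64")
    b, rows, cols = cube.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {hyperyield spectral cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_CODE[dt]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"domain = {cube.domain}\n"
        f"gsd = {cube.gsd!r}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    _header_path(path).write_text(header)
    np.ascontiguousarray(cube.values, dtype=dt).tofile(path)


def _parse_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise CubeFormatError("missing ENVI magic line in header")
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_cube(path: str | Path) -> SpectralCube:
    """Read a BSQ raster + ENVI header pair written by :func:`write_cube`."""
    path = Path(path)
    hdr = _header_path(path)
    if not hdr.exists():
        raise CubeFormatError(f"header {hdr} not found")
    fields = _parse_header(hdr.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields.get("interleave", "bsq").lower()
    except (KeyError, ValueError) as exc:
        raise CubeFormatError(f"garbled header {hdr}: {exc}") from exc
    if interleave != "bsq":
        raise CubeFormatError(f"unsupported interleave {interleave!r}; only bsq")
    if code not in _DTYPE_CODES:
        raise CubeFormatError(f"unsupported data type code {code}")
    m = re.search(r"wavelength\s*=\s*\{([^}]*)\}", hdr.read_text(), flags=re.I | re.S)
    if not m:
        raise CubeFormatError("header lacks a wavelength block")
    wavelengths = np.array([float(x) for x in m.group(1).replace("\n", " ").split(",") if x.strip()])
    if len(wavelengths) != bands:
        raise ValueError(
            f"header declares {bands} bands but lists {len(wavelengths)} wavelengths"
        )
    values = np.fromfile(path, dtype=_DTYPE_CODES[code])
    if values.size != bands * rows * cols:
        raise CubeFormatError(
            f"raster holds {values.size} samples, header implies {bands * rows * cols}"
        )
    return SpectralCube(
        values.reshape(bands, rows, cols),
        wavelengths,
        fields.get("domain", "radiance"),
        float(fields.get("gsd", 1.0)),
    )


def subset_wavelengths(cube: SpectralCube, lo_nm: float, hi_nm: float) -> SpectralCube:
    """Retain exactly the bands with ``lo_nm <= lambda <= hi_nm`` (closed).

    Used to trim the sensor-noise-dominated edges of the sensed range
    (bands below 420 nm and above 950 nm in the source acquisition).
    """
    if not lo_nm < hi_nm:
        raise ValueError(f"need lo_nm < hi_nm, got [{lo_nm}, {hi_nm}]")
    keep = (cube.wavelengths >= lo_nm) & (cube.wavelengths <= hi_nm)
    if not keep.any():
        raise ValueError(f"no bands inside the requested interval [{lo_nm}, {hi_nm}] nm")
    return SpectralCube(
        cube.values[keep], cube.wavelengths[keep], cube.domain, cube.gsd, dict(cube.meta)
    )
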