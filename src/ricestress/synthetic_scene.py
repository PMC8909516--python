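"""Synthetic multispectral scene generation.

Produces labeled reflectance time stacks with the statistical structure the
stress-detection pipeline assumes: a double-logistic rice phenology, a
persistent multiplicative vigor depression plus a mid-season Gaussian trough
for stressed pixels, random cloud contamination with QA flags, and a smooth
DEM with a tail of steep slopes. The mechanism is generative and invented;
only the ordering structure it guarantees (stressed red-edge indices below
unstressed ones, deepest mid-season) matters downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: Band identifiers carried by every reflectance stack, in storage order.
#: This is also the operand set of all spectral-index formulas.
BANDS = ("B1", "B3", "B4", "B5", "B6", "B7", "B8")

#: Per-band affine mixing reflectance = intercept + slope * vigor.
#: Chosen so NIR (B7, B8) rises strongly with canopy vigor, red (B4) falls,
#: and the red-edge bands (B5, B6) respond intermediately — the sign
#: structure that makes every red-edge index increase with vigor.
_VIGOR_MIXING = {
    "B1": (0.040, 0.000),
    "B3": (0.080, -0.020),
    "B4": (0.100, -0.070),
    "B5": (0.120, 0.050),
    "B6": (0.150, 0.200),
    "B7": (0.180, 0.320),
    "B8": (0.200, 0.350),
}

#: Constant soil-like spectrum for nonrice pixels (brightens with wavelength).
_SOIL_SPECTRUM = {
    "B1": 0.060,
    "B3": 0.095,
    "B4": 0.130,
    "B5": 0.155,
    "B6": 0.180,
    "B7": 0.205,
    "B8": 0.220,
}

#: Bright flat spectrum assigned to cloud-contaminated observations.
_CLOUD_REFLECTANCE = 0.9

NONRICE, RICE_UNSTRESSED, RICE_STRESSED = 0, 1, 2


class SceneConfigError(ValueError):
    """Raised when a SceneConfig violates its invariants."""


def _default_dates() -> tuple[int, ...]:
    # 33 acquisitions evenly spread over April 1 .. October 15 (DOY 91..288).
    return tuple(int(round(d)) for d in np.linspace(91, 288, 33))


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic scene generator.

    Defaults encode the study conditions: 33 acquisition dates across the
    April–October growing season, a rice population split roughly 66/34
    between stressed and unstressed, a persistent vigor depression with a
    June–August trough for stressed pixels, mild reflectance noise and
    sparse cloud contamination.
    """

    n_rows: int = 64
    n_cols: int = 64
    dates: tuple[int, ...] = field(default_factory=_default_dates)
    class_fractions: tuple[float, float, float] = (0.30, 0.24, 0.46)
    stress_depression: float = 0.85
    trough_center_doy: float = 196.0
    trough_width_days: float = 25.0
    trough_depth: float = 0.25
    noise_sd: float = 0.01
    cloud_prob: float = 0.05
    vigor_heterogeneity: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        dates = np.asarray(self.dates, dtype=float)
        if dates.ndim != 1 or len(dates) < 2 or np.any(np.diff(dates) <= 0):
            raise SceneConfigError("dates must be a strictly increasing sequence")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise SceneConfigError("class_fractions must sum to 1")
        if not 0.0 < self.stress_depression <= 1.0:
            raise SceneConfigError("stress_depression must lie in (0, 1]")
        if not 0.0 <= self.cloud_prob < 1.0:
            raise SceneConfigError("cloud_prob must lie in [0, 1)")
        if not 0.0 <= self.trough_depth < 1.0:
            raise SceneConfigError("trough_depth must lie in [0, 1)")
        if self.noise_sd < 0:
            raise SceneConfigError("noise_sd must be nonnegative")
        if not 0.0 <= self.vigor_heterogeneity < 1.0:
            raise SceneConfigError("vigor_heterogeneity must lie in [0, 1)")
        if self.n_rows < 1 or self.n_cols < 1:
            raise SceneConfigError("grid must be nonempty")


@dataclass
class ReflectanceStack:
    """Reflectance indexed (date, band, row, col) with per-(date,pixel) QA.

    ``qa`` is True where the observation is valid and False under cloud.
    ``geotransform`` is a north-up affine (x0, dx, 0, y0, 0, -dy).
    """

    values: np.ndarray
    qa: np.ndarray
    dates: np.ndarray
    geotransform: tuple[float, float, float, float, float, float] = (
        0.0, 10.0, 0.0, 0.0, 0.0, -10.0,
    )

    @property
    def n_dates(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[2], self.values.shape[3]

    def band(self, name: str) -> np.ndarray:
        return self.values[:, BANDS.index(name)]


@dataclass
class LabelRaster:
    """Per-pixel class: 0 = nonrice, 1 = unstressed rice, 2 = stressed rice."""

    labels: np.ndarray

    CLASS_NAMES = ("nonrice", "rice_unstressed", "rice_stressed")


@dataclass
class DemRaster:
    """Elevation in meters on the scene grid, with square cells."""

    elevation: np.ndarray
    cell_size: float = 10.0


def _double_logistic(doy: np.ndarray, green_up: float, senescence: float,
                     rate_up: float = 12.0, rate_down: float = 18.0) -> np.ndarray:
    """Canonical crop phenology curve: green-up sigmoid times senescence sigmoid."""
    up = 1.0 / (1.0 + np.exp(-(doy - green_up) / rate_up))
    down = 1.0 / (1.0 + np.exp((doy - senescence) / rate_down))
    return up * down


def vigor_curves(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free latent vigor trajectories (unstressed, stressed) on the date grid."""
    doy = np.asarray(config.dates, dtype=float)
    v = _double_logistic(doy, green_up=140.0, senescence=280.0)
    v = v / v.max()
    trough = config.trough_depth * np.exp(
        -((doy - config.trough_center_doy) ** 2) / (2.0 * config.trough_width_days ** 2)
    )
    v_stressed = config.stress_depression * v * (1.0 - trough)
    return v, v_stressed


def bands_from_vigor(vigor: np.ndarray) -> np.ndarray:
    """Map vigor (any shape) to reflectance, output shape (..., n_bands)."""
    out = np.empty(vigor.shape + (len(BANDS),), dtype=np.float64)
    for b, name in enumerate(BANDS):
        intercept, slope = _VIGOR_MIXING[name]
        out[..., b] = intercept + slope * vigor
    return out


def simulate_scene(config: SceneConfig) -> tuple[ReflectanceStack, LabelRaster, DemRaster]:
    """Generate a labeled reflectance time stack, QA flags and a DEM.

    Deterministic given ``config.seed``. Stressed rice pixels carry a
    persistently depressed vigor with an extra mid-season Gaussian trough, so
    every red-edge index of stressed rice lies below the unstressed value at
    every noise-free date, with the largest gap in June–August.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_rows, n_cols = config.n_rows, config.n_cols
    n_pix = n_rows * n_cols
    doy = np.asarray(config.dates, dtype=float)
    n_dates = len(doy)

    # Per-pixel class assignment by the configured fractions.
    labels = rng.choice(3, size=n_pix, p=np.asarray(config.class_fractions))
    labels = labels.reshape(n_rows, n_cols).astype(np.uint8)

    v_unstressed, v_stressed = vigor_curves(config)

    # Per-pixel multiplicative vigor heterogeneity (field-to-field variation).
    pixel_scale = rng.uniform(1.0 - config.vigor_heterogeneity, 1.0,
                              size=(n_rows, n_cols))

    vigor = np.zeros((n_dates, n_rows, n_cols))
    vigor[:, labels == RICE_UNSTRESSED] = v_unstressed[:, None]
    vigor[:, labels == RICE_STRESSED] = v_stressed[:, None]
    vigor *= pixel_scale[None, :, :]

    values = np.transpose(bands_from_vigor(vigor), (0, 3, 1, 2))
    soil = np.array([_SOIL_SPECTRUM[b] for b in BANDS])
    values[:, :, labels == NONRICE] = soil[None, :, None]

    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)

    # Cloud contamination: independent per (pixel, date).
    qa = rng.random(size=(n_dates, n_rows, n_cols)) >= config.cloud_prob
    values[np.broadcast_to(~qa[:, None], values.shape)] = _CLOUD_REFLECTANCE

    values = np.clip(values, 0.0, 1.2)

    dem = _simulate_dem(rng, n_rows, n_cols)
    stack = ReflectanceStack(values=values, qa=qa, dates=doy.copy())
    return stack, LabelRaster(labels=labels), dem


def _simulate_dem(rng: np.random.Generator, n_rows: int, n_cols: int,
                  cell_size: float = 10.0, steep_fraction: float = 0.10) -> DemRaster:
    """Smooth random cosine field scaled so ~steep_fraction of pixels exceed 8° slope."""
    y, x = np.mgrid[0:n_rows, 0:n_cols].astype(float)
    z = np.zeros((n_rows, n_cols))
    for _ in range(6):
        fx, fy = rng.uniform(0.5, 2.5, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        z += rng.uniform(0.5, 1.0) * np.cos(
            2 * np.pi * (fx * x / n_cols + fy * y / n_rows) + phase
        )
    # Central-difference gradient magnitude of the unit field; scale the
    # amplitude so the (1 - steep_fraction) quantile sits exactly at tan(8°).
    gy, gx = np.gradient(z, cell_size)
    grad = np.hypot(gx, gy)
    q = np.quantile(grad, 1.0 - steep_fraction)
    if q > 0:
        z *= np.tan(np.radians(8.0)) / q
    return DemRaster(elevation=z, cell_size=cell_size)


def write_scene(stack: ReflectanceStack, labels: LabelRaster, dem: DemRaster,
                directory: str | Path) -> Path:
    """Write the scene as one multiband TIFF per date plus QA, label and DEM
    TIFFs and a plain-text manifest; returns the manifest path.

    The manifest records acquisition dates, band order, geotransform and cell
    size, so a read round-trips losslessly through :func:`ricestress.cli_io.read_scene`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    date_files = []
    for i, doy in enumerate(stack.dates):
        fname = f"reflectance_doy{int(doy):03d}_{i:02d}.tif"
        tifffile.imwrite(directory / fname, stack.values[i])
        date_files.append(fname)
    tifffile.imwrite(directory / "qa.tif", stack.qa.astype(np.uint8))
    tifffile.imwrite(directory / "labels.tif", labels.labels.astype(np.uint8))
    tifffile.imwrite(directory / "dem.tif", dem.elevation.astype(np.float32))

    manifest = directory / "manifest.txt"
    lines = [
        "format: ricestress-scene-v1",
        "bands: " + ",".join(BANDS),
        "dates: " + ",".join(str(int(d)) for d in stack.dates),
        "date_files: " + ",".join(date_files),
        "qa_file: qa.tif",
        "label_file: labels.tif",
        "dem_file: dem.tif",
        "geotransform: " + ",".join(repr(g) for g in stack.geotransform),
        f"cell_size: {dem.cell_size!r}",
    ]
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
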