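"""Per-plant spectrum extraction from hyperspectral image cubes.

A hyperspectral cube is a stack of co-registered grayscale images, one per
spectral band.  Plant pixels are separated from background (pot, stand,
frame) with an NDVI mask built from one red and one near-infrared band,
the cube is cropped to the plant's bounding box, and per-band mean pixel
intensities give the plant's reflectance spectrum for that day.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "SpectralCube",
    "PlantMask",
    "ReflectanceSpectrum",
    "EmptyPlantError",
    "band_index",
    "compute_ndvi",
    "make_mask",
    "crop_to_mask",
    "mean_spectrum",
    "extract_spectrum",
    "write_cube",
    "read_cube",
]

PIXEL_MODES = ("zero_inclusive", "nonzero_only")


class EmptyPlantError(ValueError):
    """Raised when a mask contains no plant pixels (a failed segmentation)."""


@dataclass
class SpectralCube:
    """One plant/day stack of band images with its wavelength grid.

    ``bands`` has shape ``(n_bands, height, width)`` with non-negative
    intensities; ``wavelengths_nm`` is strictly increasing with one entry
    per band.
    """

    bands: np.ndarray
    wavelengths_nm: np.ndarray
    plant_id: str = ""
    day: int = 0

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.bands.ndim != 3:
            raise ValueError("bands must be a (n_bands, height, width) stack")
        if len(self.wavelengths_nm) != self.bands.shape[0]:
            raise ValueError("one wavelength required per band")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]


@dataclass
class PlantMask:
    """Boolean plant/background segmentation of one cube."""

    mask: np.ndarray
    n_plant_pixels: int = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.n_plant_pixels = int(self.mask.sum())


@dataclass
class ReflectanceSpectrum:
    """Per-band mean plant-pixel intensity for one plant on one day."""

    values: np.ndarray
    wavelengths_nm: np.ndarray
    pixel_mode: str = "nonzero_only"
    plant_id: str = ""
    day: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.values.shape != self.wavelengths_nm.shape:
            raise ValueError("values and wavelengths must align")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("spectrum values must be finite and non-negative")
        if self.pixel_mode not in PIXEL_MODES:
            raise ValueError(f"pixel_mode must be one of {PIXEL_MODES}")


def band_index(wavelengths_nm: np.ndarray, target_nm: float) -> int:
    """Position of the grid wavelength nearest to ``target_nm``.

    Ties are broken toward the lower index.  Raises on an empty grid.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    if wl.size == 0:
        raise ValueError("empty wavelength grid")
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    return int(np.argmin(np.abs(wl - target_nm)))


def compute_ndvi(cube: SpectralCube, red_band: int, nir_band: int) -> np.ndarray:
    """Pixel-wise normalized difference vegetation index, (NIR-red)/(NIR+red).

    Pixels where NIR + red == 0 are defined as 0 (background-like), so dark
    pixels never enter the plant mask.
    """
    n = cube.n_bands
    if not (0 <= red_band < n and 0 <= nir_band < n):
        raise IndexError("band position out of range")
    red = cube.bands[red_band]
    nir = cube.bands[nir_band]
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0), 0.0)
    return ndvi


def make_mask(ndvi: np.ndarray, threshold: float = 0.25) -> PlantMask:
    """Threshold an NDVI image into a plant mask (NDVI strictly above)."""
    if not -1.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (-1, 1)")
    return PlantMask(np.asarray(ndvi) > threshold)


def otsu_mask(ndvi: np.ndarray, n_bins: int = 256) -> PlantMask:
    """Alternative mask using Otsu's histogram threshold on the NDVI image."""
    flat = np.asarray(ndvi, dtype=float).ravel()
    hist, edges = np.histogram(flat, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    cw = np.cumsum(w)
    cm = np.cumsum(w * centers)
    mean_total = cm[-1] / total
    with np.errstate(invalid="ignore", divide="ignore"):
        between = (mean_total * cw - cm) ** 2 / (cw * (total - cw))
    between[~np.isfinite(between)] = -np.inf
    thr = centers[int(np.argmax(between))]
    return PlantMask(np.asarray(ndvi) > thr)


def crop_to_mask(
    cube: SpectralCube, mask: PlantMask, padding: int = 0
) -> tuple[SpectralCube, PlantMask]:
    """Crop to the mask's bounding box (plus padding) and zero non-plant pixels.

    The box is the tight bounding box of true pixels expanded by ``padding``
    and clipped to the image; coordinates are 0-based, boxes half-open.
    Raises :class:`EmptyPlantError` on an empty mask.
    """
    m = mask.mask
    if m.shape != cube.shape:
        raise ValueError("mask shape does not match cube")
    if mask.n_plant_pixels == 0:
        raise EmptyPlantError("mask contains no plant pixels")
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    r0 = max(rows[0] - padding, 0)
    r1 = min(rows[-1] + 1 + padding, m.shape[0])
    c0 = max(cols[0] - padding, 0)
    c1 = min(cols[-1] + 1 + padding, m.shape[1])
    sub_mask = m[r0:r1, c0:c1]
    sub = cube.bands[:, r0:r1, c0:c1] * sub_mask
    cropped = SpectralCube(sub, cube.wavelengths_nm, cube.plant_id, cube.day)
    return cropped, PlantMask(sub_mask)


def mean_spectrum(
    cube: SpectralCube, mask: PlantMask, pixel_mode: str = "nonzero_only"
) -> ReflectanceSpectrum:
    """Per-band mean intensity over masked pixels.

    ``zero_inclusive`` averages every masked pixel; ``nonzero_only`` averages
    only masked pixels with intensity > 0, which removes the size bias that
    zero-intensity background pixels introduce in small plants.  A band with
    no qualifying pixels yields 0.
    """
    if pixel_mode not in PIXEL_MODES:
        raise ValueError(f"pixel_mode must be one of {PIXEL_MODES}")
    m = mask.mask
    if m.shape != cube.shape:
        raise ValueError("mask shape does not match cube")
    if mask.n_plant_pixels == 0:
        raise EmptyPlantError("mask contains no plant pixels")
    pixels = cube.bands[:, m]  # (n_bands, n_plant_pixels)
    if pixel_mode == "zero_inclusive":
        values = pixels.mean(axis=1)
    else:
        pos = pixels > 0
        counts = pos.sum(axis=1)
        sums = np.where(pos, pixels, 0.0).sum(axis=1)
        values = np.divide(sums, counts, out=np.zeros(cube.n_bands), where=counts > 0)
    return ReflectanceSpectrum(
        values, cube.wavelengths_nm, pixel_mode, cube.plant_id, cube.day
    )


def extract_spectrum(
    cube: SpectralCube,
    red_nm: float = 615.0,
    nir_nm: float = 1117.0,
    threshold: float = 0.25,
    pixel_mode: str = "nonzero_only",
    padding: int = 0,
) -> ReflectanceSpectrum:
    """Full masking -> cropping -> pixel-statistics chain for one cube."""
    red = band_index(cube.wavelengths_nm, red_nm)
    nir = band_index(cube.wavelengths_nm, nir_nm)
    ndvi = compute_ndvi(cube, red, nir)
    mask = make_mask(ndvi, threshold)
    cropped, cropped_mask = crop_to_mask(cube, mask, padding)
    return mean_spectrum(cropped, cropped_mask, pixel_mode)


def write_cube(cube: SpectralCube, directory: str | Path) -> Path:
    """Write one cube as a multi-page TIFF (page k = band k) plus a
    wavelengths.csv sidecar shared by all cubes in the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{cube.plant_id}_day{cube.day:02d}.tif"
    tifffile.imwrite(path, cube.bands.astype(np.float32), photometric="minisblack")
    sidecar = directory / "wavelengths.csv"
    if not sidecar.exists():
        with open(sidecar, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["band", "wavelength_nm"])
            for k, wl in enumerate(cube.wavelengths_nm):
                writer.writerow([k, f"{wl:.6f}"])
    return path


def read_cube(path: str | Path, wavelengths_csv: str | Path | None = None) -> SpectralCube:
    """Read a multi-page TIFF cube written by :func:`write_cube`."""
    path = Path(path)
    bands = np.asarray(tifffile.imread(path), dtype=float)
    if bands.ndim == 2:
        bands = bands[None]
    if wavelengths_csv is None:
        wavelengths_csv = path.parent / "wavelengths.csv"
    wl = []
    with open(wavelengths_csv, newline="") as fh:
        for row in csv.DictReader(fh):
            wl.append(float(row["wavelength_nm"]))
    stem = path.stem
    plant_id, _, day = stem.rpartition("_day")
    return SpectralCube(bands, np.asarray(wl), plant_id, int(day) if day else 0)
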