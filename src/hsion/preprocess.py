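"""Spectral dataset construction: gap-segment derivatives and Q3 band filtering.

Three modeling datasets are built from the raw per-plant mean spectra:

1. the raw mean-pixel spectra themselves,
2. a gap-segment first-derivative smoothed version (the derivative of two
   segment means separated by a gap, which smooths and differentiates in one
   pass while trimming ``gap + segment - 1`` bands off each edge), and
3. the subset of bands whose control-vs-salinity mean absolute difference
   exceeds the third quartile of the per-band difference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import ReflectanceSpectrum

__all__ = [
    "SpectraMatrix",
    "BandFilterResult",
    "WindowTooWideError",
    "gap_segment_derivative",
    "smooth_matrix",
    "q3_band_filter",
    "subset_bands",
]

ANNOTATION_COLUMNS = ["genotype", "treatment", "day", "replicate"]

#: Default smoother geometry: edge loss per side is gap + segment - 1 = 10,
#: so a 243-band spectrum maps to 223 derivative points.
DEFAULT_SEGMENT = 5
DEFAULT_GAP = 6


class WindowTooWideError(ValueError):
    """Raised when a spectrum is too short for the requested gap/segment."""


@dataclass
class SpectraMatrix:
    """Samples x bands matrix with per-sample annotations.

    ``values`` is ``(n_samples, n_bands)`` with no missing entries;
    ``annotations`` carries genotype, treatment, day and replicate per row.
    """

    values: np.ndarray
    wavelengths_nm: np.ndarray
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.annotations = self.annotations.reset_index(drop=True)
        if self.values.shape[1] != len(self.wavelengths_nm):
            raise ValueError("column count must equal wavelength count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra matrix contains missing/non-finite values")
        if len(self.annotations) != self.values.shape[0]:
            raise ValueError("one annotation row required per sample")
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.annotations.columns]
        if missing:
            raise ValueError(f"annotations missing columns {missing}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def select_rows(self, row_mask: np.ndarray) -> "SpectraMatrix":
        row_mask = np.asarray(row_mask)
        return SpectraMatrix(
            self.values[row_mask],
            self.wavelengths_nm,
            self.annotations.loc[row_mask].reset_index(drop=True),
        )

    @classmethod
    def from_spectra(
        cls, spectra: list[ReflectanceSpectrum], annotations: pd.DataFrame
    ) -> "SpectraMatrix":
        if not spectra:
            raise ValueError("no spectra given")
        wl = spectra[0].wavelengths_nm
        for s in spectra[1:]:
            if not np.array_equal(s.wavelengths_nm, wl):
                raise ValueError("spectra are not on a common wavelength grid")
        return cls(np.vstack([s.values for s in spectra]), wl, annotations)

    def to_dataframe(self) -> pd.DataFrame:
        bands = pd.DataFrame(
            self.values, columns=[f"{wl:.2f}" for wl in self.wavelengths_nm]
        )
        return pd.concat([self.annotations[ANNOTATION_COLUMNS], bands], axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraMatrix":
        df = pd.read_csv(path)
        band_cols = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
        return cls(
            df[band_cols].to_numpy(dtype=float),
            np.asarray([float(c) for c in band_cols]),
            df[ANNOTATION_COLUMNS].copy(),
        )


@dataclass
class BandFilterResult:
    """Outcome of the third-quartile between-treatment difference filter."""

    retained_positions: np.ndarray
    q3_threshold: float
    differences: np.ndarray
    wavelengths_nm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_dataframe(self) -> pd.DataFrame:
        retained = np.zeros(len(self.differences), dtype=bool)
        retained[self.retained_positions] = True
        return pd.DataFrame(
            {
                "position": np.arange(len(self.differences)),
                "wavelength_nm": self.wavelengths_nm,
                "difference": self.differences,
                "retained": retained,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _gap_segment_once(
    values: np.ndarray, wavelengths: np.ndarray, segment: int, gap: int
) -> tuple[np.ndarray, np.ndarray]:
    n = values.shape[-1]
    edge = gap + segment - 1
    if n <= 2 * edge:
        raise WindowTooWideError(
            f"spectrum of {n} bands too short for segment={segment}, gap={gap} "
            f"(needs more than {2 * edge} bands)"
        )
    kernel = np.ones(segment) / segment
    # segment means at every valid start position, for rows and single spectra
    if values.ndim == 1:
        seg = np.convolve(values, kernel, mode="valid")
    else:
        seg = np.apply_along_axis(
            lambda row: np.convolve(row, kernel, mode="valid"), 1, values
        )
    wl_seg = np.convolve(wavelengths, kernel, mode="valid")
    shift = 2 * gap + segment - 1
    fwd = seg[..., shift:]
    bwd = seg[..., : seg.shape[-1] - shift]
    denom = wl_seg[shift:] - wl_seg[: len(wl_seg) - shift]
    deriv = (fwd - bwd) / denom
    out_wl = wavelengths[edge : n - edge]
    return deriv, out_wl


def gap_segment_derivative(
    spectrum: ReflectanceSpectrum | np.ndarray,
    segment: int = DEFAULT_SEGMENT,
    gap: int = DEFAULT_GAP,
    order: int = 1,
    wavelengths_nm: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gap-segment derivative of one spectrum.

    At interior band ``i`` the first derivative is the mean over the forward
    segment ``[i+g, i+g+s-1]`` minus the mean over the backward segment
    ``[i-g-s+1, i-g]``, divided by the wavelength distance between the two
    segment centres, so a spectrum linear in wavelength returns its slope
    exactly.  Each application trims ``g + s - 1`` bands from either edge;
    ``order`` > 1 iterates the operator.

    Returns ``(derivative_values, surviving_wavelengths)``.
    """
    if segment < 1 or gap < 1:
        raise ValueError("segment and gap must both be >= 1")
    if order < 1:
        raise ValueError("order must be >= 1")
    if isinstance(spectrum, ReflectanceSpectrum):
        values = spectrum.values
        wl = spectrum.wavelengths_nm
    else:
        values = np.asarray(spectrum, dtype=float)
        if wavelengths_nm is None:
            wl = np.arange(values.shape[-1], dtype=float)
        else:
            wl = np.asarray(wavelengths_nm, dtype=float)
    for _ in range(order):
        values, wl = _gap_segment_once(values, wl, segment, gap)
    return values, wl


def smooth_matrix(
    matrix: SpectraMatrix,
    segment: int = DEFAULT_SEGMENT,
    gap: int = DEFAULT_GAP,
    order: int = 1,
) -> SpectraMatrix:
    """Row-wise gap-segment derivative of a spectra matrix; annotations kept."""
    values, wl = gap_segment_derivative(
        matrix.values, segment, gap, order, matrix.wavelengths_nm
    )
    return SpectraMatrix(values, wl, matrix.annotations)


def q3_band_filter(matrix: SpectraMatrix) -> BandFilterResult:
    """Retain bands whose |salinity mean - control mean| exceeds its Q3.

    The threshold is the linearly interpolated (type-7) third quartile of the
    per-band absolute difference distribution; retention requires a strictly
    greater difference, so with all differences distinct exactly the top
    quarter of bands survives (61 of 243).
    """
    treatment = matrix.annotations["treatment"].to_numpy()
    control = treatment == "control"
    salinity = treatment == "salinity"
    if not control.any() or not salinity.any():
        raise ValueError("matrix must contain both control and salinity rows")
    differences = np.abs(
        matrix.values[salinity].mean(axis=0) - matrix.values[control].mean(axis=0)
    )
    q3 = float(np.quantile(differences, 0.75))  # type-7 linear interpolation
    retained = np.flatnonzero(differences > q3)
    return BandFilterResult(retained, q3, differences, matrix.wavelengths_nm)


def subset_bands(matrix: SpectraMatrix, result: BandFilterResult) -> SpectraMatrix:
    """Column subset of a matrix in the filter's retained order."""
    pos = np.asarray(result.retained_positions, dtype=int)
    if pos.size and (pos.min() < 0 or pos.max() >= matrix.n_bands):
        raise IndexError("retained position out of range")
    return SpectraMatrix(
        matrix.values[:, pos].reshape(matrix.n_samples, len(pos)),
        matrix.wavelengths_nm[pos],
        matrix.annotations,
    )
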