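"""Flame-photometry quantification: standard curves and tissue-content units.

Shoot tissue (default 100 mg) is digested in 10 mL of dilute nitric acid and
the extract diluted 1:50 (0.1 mL sample + 4.9 mL water) before reading on the
flame photometer.  A standard curve over 1-40 ppm converts instrument response
to ppm (mg L^-1) in the diluted solution, and the dilution/volume/mass chain
converts that to tissue ion content in mmol per gram dry weight:

    content = ppm_diluted * dilution * volume_L / (molar_mass * mass_g)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MOLAR_MASS_G_PER_MOL",
    "DEFAULT_STANDARD_PPM",
    "StandardCurve",
    "IonRecord",
    "fit_standard_curve",
    "reading_to_ppm",
    "tissue_content",
    "content_to_ppm",
]

MOLAR_MASS_G_PER_MOL = {"Na": 22.99, "K": 39.10}

#: Concentrations of the calibration standards, ppm.
DEFAULT_STANDARD_PPM = (40.0, 30.0, 20.0, 10.0, 5.0, 1.0)

DEFAULT_DILUTION_FACTOR = 50.0
DEFAULT_EXTRACT_VOLUME_L = 0.010
DEFAULT_TISSUE_MASS_G = 0.1


@dataclass
class StandardCurve:
    """Least-squares line through (ppm, instrument response) standards."""

    slope: float
    intercept: float
    r_squared: float
    standards: list[tuple[float, float]]

    def response(self, ppm: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(ppm, dtype=float) + self.intercept


@dataclass
class IonRecord:
    """Measured or latent ion content of one sample, mmol g^-1 DW."""

    genotype: str
    treatment: str
    day: int
    replicate: int
    ion: str
    content: float


def fit_standard_curve(standards: list[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of instrument response on standard ppm."""
    pts = [(float(p), float(r)) for p, r in standards]
    ppm = np.array([p for p, _ in pts])
    resp = np.array([r for _, r in pts])
    if len(np.unique(ppm)) < 2:
        raise ValueError("need at least two distinct standard concentrations")
    slope, intercept = np.polyfit(ppm, resp, 1)
    fitted = slope * ppm + intercept
    ss_res = float(np.sum((resp - fitted) ** 2))
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return StandardCurve(float(slope), float(intercept), r2, pts)


def reading_to_ppm(response: float | np.ndarray, curve: StandardCurve):
    """Invert the standard curve: ppm in the measured (diluted) solution."""
    if curve.slope == 0:
        raise ValueError("standard curve has zero slope")
    return (np.asarray(response, dtype=float) - curve.intercept) / curve.slope


def tissue_content(
    ppm_diluted: float | np.ndarray,
    molar_mass_g_per_mol: float,
    dilution_factor: float = DEFAULT_DILUTION_FACTOR,
    extract_volume_L: float = DEFAULT_EXTRACT_VOLUME_L,
    tissue_mass_g: float = DEFAULT_TISSUE_MASS_G,
):
    """Convert diluted-solution ppm (mg L^-1) to tissue content, mmol g^-1 DW.

    ppm * dilution recovers mg L^-1 in the undiluted extract; times the
    extract volume gives mg of ion; dividing by molar mass (mg mmol^-1) gives
    mmol, and by tissue dry mass gives mmol g^-1 DW.
    """
    for name, v in (
        ("molar_mass_g_per_mol", molar_mass_g_per_mol),
        ("dilution_factor", dilution_factor),
        ("extract_volume_L", extract_volume_L),
        ("tissue_mass_g", tissue_mass_g),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    ppm = np.asarray(ppm_diluted, dtype=float)
    return ppm * dilution_factor * extract_volume_L / (molar_mass_g_per_mol * tissue_mass_g)


def content_to_ppm(
    content_mmol_per_g: float | np.ndarray,
    molar_mass_g_per_mol: float,
    dilution_factor: float = DEFAULT_DILUTION_FACTOR,
    extract_volume_L: float = DEFAULT_EXTRACT_VOLUME_L,
    tissue_mass_g: float = DEFAULT_TISSUE_MASS_G,
):
    """Exact inverse of :func:`tissue_content` (used to simulate readings)."""
    content = np.asarray(content_mmol_per_g, dtype=float)
    return content * molar_mass_g_per_mol * tissue_mass_g / (
        dilution_factor * extract_volume_L
    )
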