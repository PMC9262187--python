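"""Synthetic salinity-stress hyperspectral experiment generator.

Emulates the structure of a side-view hyperspectral phenotyping study of
rice under salinity stress: 6 genotypes (IR29, Pokkali, FL454, FL478, FL499,
FL510) x 2 treatments (control, salinity) x 5 replicate plants imaged over
18 days, 243 bands spanning 550-1700 nm at 4.77 nm steps.

Each plant is a procedurally generated silhouette (a union of ellipses that
grows daily).  Plant pixels carry a vegetation baseline spectrum plus a
linear response to the plant's latent Na+ and K+ tissue contents plus
Gaussian noise; background pixels carry a flat spectrum whose NIR roughly
equals its red reflectance, so NDVI separates the two classes.  Latent ion
trajectories follow the empirical pattern: Na+ stable under control but
rising under salinity (fastest in salt-sensitive genotypes), K+ declining
from day 12 under salinity.  The exact latent contents are returned as
ground truth, making parameter-recovery tests of the whole pipeline
meaningful.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import chemistry
from .imaging import SpectralCube

__all__ = [
    "GENOTYPES",
    "TREATMENTS",
    "SimulationConfig",
    "GroundTruth",
    "CubeSet",
    "InvalidConfigError",
    "simulate_experiment",
    "simulate_flame_photometry",
    "silhouette_mask",
    "write_cubes",
]

GENOTYPES = ("IR29", "Pokkali", "FL454", "FL478", "FL499", "FL510")
TREATMENTS = ("control", "salinity")

# Na+ rise per day under salinity, mmol g^-1 DW, ordered by sensitivity:
# FL499 (super-sensitive) > IR29 ~ FL454 > FL478 ~ Pokkali > FL510
# (super-tolerant).  With onset at day 4 the day-18 contents span ~0.3-1.0.
_NA_SLOPES = {
    "FL499": 0.065,
    "IR29": 0.048,
    "FL454": 0.046,
    "FL478": 0.028,
    "Pokkali": 0.030,
    "FL510": 0.018,
}


class InvalidConfigError(ValueError):
    """Raised when simulation parameters are inconsistent or non-positive."""


def _default_baseline(wl: np.ndarray) -> np.ndarray:
    """Vegetation-like reflectance: low in the visible, red-edge step to a
    NIR plateau, water-absorption dip near 1450 nm."""
    red_edge = 1.0 / (1.0 + np.exp(-(wl - 715.0) / 18.0))
    water_dip = np.exp(-(((wl - 1450.0) / 60.0) ** 2))
    return 0.08 + 0.45 * red_edge - 0.12 * water_dip


def _default_na_loading(wl: np.ndarray) -> np.ndarray:
    """Reflectance change per unit Na+ content: NIR/SWIR depression as salt
    stress dehydrates tissue, slight brightening around the chlorophyll red
    absorption."""
    return (
        -0.06 * np.exp(-(((wl - 1380.0) / 120.0) ** 2))
        + 0.03 * np.exp(-(((wl - 660.0) / 60.0) ** 2))
        - 0.02 * np.exp(-(((wl - 980.0) / 90.0) ** 2))
    )


def _default_k_loading(wl: np.ndarray) -> np.ndarray:
    """Reflectance change per unit K+ content, on distinct bands from Na+."""
    return 0.05 * np.exp(-(((wl - 1150.0) / 80.0) ** 2)) + 0.025 * np.exp(
        -(((wl - 870.0) / 70.0) ** 2)
    )


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment."""

    genotypes: Sequence[str] = GENOTYPES
    n_reps_per_treatment: int = 5
    n_days: int = 18
    n_bands: int = 243
    wavelength_start_nm: float = 550.0
    wavelength_step_nm: float = 4.77
    image_height: int = 64
    image_width: int = 64
    # silhouette geometry: initial semi-axes (rows, cols) and per-day growth
    plant_shape_params: dict = field(
        default_factory=lambda: {
            "row_axis0": 5.0,
            "col_axis0": 4.0,
            "row_growth": 0.9,
            "col_growth": 0.8,
            "n_tillers": 2,
        }
    )
    # Na+ trajectory: control-level baseline content, onset day of the
    # salinity rise, per-genotype slope (mmol g^-1 DW per day)
    na_trajectory_params: dict = field(
        default_factory=lambda: {
            "baseline": 0.05,
            "onset_day": 4,
            "slopes": dict(_NA_SLOPES),
            "replicate_sd": 0.01,
        }
    )
    # K+ trajectory: shared decline onset at day 12 under salinity
    k_trajectory_params: dict = field(
        default_factory=lambda: {
            "baseline": 1.0,
            "onset_day": 12,
            "decline_per_day": 0.05,
            "replicate_sd": 0.03,
        }
    )
    # band-indexed reflectance change per unit content; None -> defaults
    na_loading: np.ndarray | None = None
    k_loading: np.ndarray | None = None
    baseline_spectrum: np.ndarray | None = None
    background_level: float = 0.18
    plant_perturbation_sd: float = 0.01
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.genotypes) < 1:
            raise InvalidConfigError("need at least one genotype")
        for name in ("n_reps_per_treatment", "n_days", "image_height", "image_width"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be positive")
        if self.n_bands < 2:
            raise InvalidConfigError("n_bands must be >= 2")
        if self.wavelength_step_nm <= 0:
            raise InvalidConfigError("wavelength grid must be strictly increasing")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        wl = self.wavelengths_nm
        if self.baseline_spectrum is None:
            self.baseline_spectrum = _default_baseline(wl)
        if self.na_loading is None:
            self.na_loading = _default_na_loading(wl)
        if self.k_loading is None:
            self.k_loading = _default_k_loading(wl)
        for name in ("baseline_spectrum", "na_loading", "k_loading"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.n_bands,):
                raise InvalidConfigError(f"{name} must have one value per band")
            setattr(self, name, arr)

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.wavelength_start_nm + self.wavelength_step_nm * np.arange(
            self.n_bands
        )

    @property
    def days(self) -> np.ndarray:
        return np.arange(1, self.n_days + 1)


@dataclass
class GroundTruth:
    """Latent per-sample ion contents and silhouette areas used in simulation."""

    records: pd.DataFrame  # genotype, treatment, day, replicate, na_content,
    # k_content, n_plant_pixels

    def content(self, genotype: str, treatment: str, day: int, replicate: int,
                ion: str) -> float:
        df = self.records
        row = df[
            (df.genotype == genotype)
            & (df.treatment == treatment)
            & (df.day == day)
            & (df.replicate == replicate)
        ]
        if len(row) != 1:
            raise KeyError((genotype, treatment, day, replicate))
        return float(row[f"{ion.lower()}_content"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def _plant_index(config: SimulationConfig, genotype: str, treatment: str,
                 replicate: int) -> int:
    g = list(config.genotypes).index(genotype)
    t = TREATMENTS.index(treatment)
    return (g * len(TREATMENTS) + t) * config.n_reps_per_treatment + (replicate - 1)


def _plant_rng(config: SimulationConfig, genotype: str, treatment: str,
               replicate: int, stream: int, day: int = 0) -> np.random.Generator:
    idx = _plant_index(config, genotype, treatment, replicate)
    return np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, stream, idx, day])
    )


def silhouette_mask(config: SimulationConfig, genotype: str, treatment: str,
                    replicate: int, day: int) -> np.ndarray:
    """Deterministic plant silhouette: a union of ellipses growing with day.

    Geometry depends only on the config seed and the plant identity, not on
    the day-to-day pixel noise stream, so the silhouette grows monotonically
    and its area is reproducible truth metadata.
    """
    sp = config.plant_shape_params
    h, w = config.image_height, config.image_width
    rng = _plant_rng(config, genotype, treatment, replicate, stream=1)
    jitter = rng.uniform(0.9, 1.1, size=4)
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = 0.60 * h, 0.50 * w
    ra = min((sp["row_axis0"] + sp["row_growth"] * day) * jitter[0], 0.45 * h)
    ca = min((sp["col_axis0"] + sp["col_growth"] * day) * jitter[1], 0.45 * w)
    mask = ((rows - cy) / ra) ** 2 + ((cols - cx) / ca) ** 2 <= 1.0
    n_tillers = int(sp.get("n_tillers", 0))
    offsets = rng.uniform(-0.18, 0.18, size=(max(n_tillers, 1), 2))
    for k in range(n_tillers):
        dy, dx = offsets[k]
        tra = max(0.55 * ra * jitter[2], 1.5)
        tca = max(0.55 * ca * jitter[3], 1.5)
        tm = ((rows - (cy + dy * h)) / tra) ** 2 + (
            (cols - (cx + dx * w)) / tca
        ) ** 2 <= 1.0
        mask |= tm
    if not mask.any():  # pragma: no cover - geometry keeps axes >= 1.5 px
        raise InvalidConfigError("plant silhouette area must be positive")
    return mask


def _trajectories(config: SimulationConfig, days: np.ndarray) -> pd.DataFrame:
    """Latent Na+/K+ contents per genotype x treatment x replicate x day."""
    na = config.na_trajectory_params
    kp = config.k_trajectory_params
    rows = []
    for genotype in config.genotypes:
        slope = na["slopes"].get(genotype, np.mean(list(na["slopes"].values())))
        for treatment in TREATMENTS:
            for rep in range(1, config.n_reps_per_treatment + 1):
                rng = _plant_rng(config, genotype, treatment, rep, stream=2)
                na_off = rng.normal(0.0, na["replicate_sd"])
                k_off = rng.normal(0.0, kp["replicate_sd"])
                for day in days:
                    if treatment == "salinity":
                        na_c = na["baseline"] + slope * max(0, day - na["onset_day"])
                        k_c = kp["baseline"] - kp["decline_per_day"] * max(
                            0, day - kp["onset_day"]
                        )
                    else:
                        na_c = na["baseline"]
                        k_c = kp["baseline"]
                    rows.append(
                        {
                            "genotype": genotype,
                            "treatment": treatment,
                            "day": int(day),
                            "replicate": rep,
                            "na_content": max(na_c + na_off, 0.0),
                            "k_content": max(k_c + k_off, 0.0),
                        }
                    )
    return pd.DataFrame(rows)


class CubeSet(Mapping):
    """Lazy mapping (genotype, treatment, replicate, day) -> SpectralCube.

    Cubes are generated on access from a per-plant/day random stream, so the
    full default experiment (1080 cubes) never has to reside in memory, and
    any access order yields bit-identical data for a fixed seed.
    """

    def __init__(self, config: SimulationConfig, truth: GroundTruth,
                 days: Sequence[int]):
        self.config = config
        self.truth = truth
        self._days = list(int(d) for d in days)
        self._keys = [
            (g, t, r, d)
            for g in config.genotypes
            for t in TREATMENTS
            for r in range(1, config.n_reps_per_treatment + 1)
            for d in self._days
        ]
        self._index = {k: i for i, k in enumerate(self._keys)}

    def __len__(self) -> int:
        return len(self._keys)

    def __iter__(self) -> Iterator[tuple]:
        return iter(self._keys)

    def __contains__(self, key) -> bool:
        return key in self._index

    def silhouette(self, key: tuple) -> np.ndarray:
        g, t, r, d = key
        return silhouette_mask(self.config, g, t, r, d)

    def __getitem__(self, key: tuple) -> SpectralCube:
        if key not in self._index:
            raise KeyError(key)
        genotype, treatment, rep, day = key
        cfg = self.config
        na_c = self.truth.content(genotype, treatment, day, rep, "na")
        k_c = self.truth.content(genotype, treatment, day, rep, "k")
        mask = silhouette_mask(cfg, genotype, treatment, rep, day)

        plant_rng = _plant_rng(cfg, genotype, treatment, rep, stream=3)
        # smooth per-plant baseline perturbation, uncorrelated with content
        phase = plant_rng.uniform(0, 2 * np.pi, size=2)
        amp = plant_rng.normal(0.0, cfg.plant_perturbation_sd, size=2)
        wl = cfg.wavelengths_nm
        span = wl[-1] - wl[0] if wl[-1] > wl[0] else 1.0
        perturb = amp[0] * np.sin(2 * np.pi * (wl - wl[0]) / span + phase[0]) + amp[
            1
        ] * np.sin(4 * np.pi * (wl - wl[0]) / span + phase[1])

        plant_spectrum = (
            cfg.baseline_spectrum + na_c * cfg.na_loading + k_c * cfg.k_loading + perturb
        )
        cube = np.empty((cfg.n_bands, cfg.image_height, cfg.image_width))
        cube[:] = cfg.background_level
        cube[:, mask] = plant_spectrum[:, None]
        if cfg.noise_sd > 0:
            noise_rng = _plant_rng(cfg, genotype, treatment, rep, stream=4, day=day)
            cube += noise_rng.normal(0.0, cfg.noise_sd, size=cube.shape)
        np.clip(cube, 0.0, None, out=cube)
        plant_id = f"{genotype}_{treatment}_rep{rep}"
        return SpectralCube(cube, wl, plant_id, int(day))


def simulate_experiment(
    config: SimulationConfig | None = None, days: Sequence[int] | None = None
) -> tuple[CubeSet, GroundTruth]:
    """Generate the full synthetic experiment: lazy cubes plus ground truth.

    ``days`` restricts generation to a subset of experiment days (e.g. only
    the final day for model-training studies); default is every day 1..n_days.
    """
    config = config or SimulationConfig()
    if days is None:
        days = list(config.days)
    days = [int(d) for d in days]
    if any(d < 1 or d > config.n_days for d in days):
        raise InvalidConfigError("days must lie in 1..n_days")
    records = _trajectories(config, np.asarray(days))
    records["n_plant_pixels"] = [
        int(
            silhouette_mask(
                config, row.genotype, row.treatment, row.replicate, row.day
            ).sum()
        )
        for row in records.itertuples()
    ]
    truth = GroundTruth(records)
    return CubeSet(config, truth, days), truth


def simulate_flame_photometry(
    truth: GroundTruth,
    curve_slope: float = 1.0,
    curve_intercept: float = 0.0,
    reading_noise_sd: float = 0.0,
    seed: int | None = None,
    ions: Sequence[str] = ("Na", "K"),
) -> pd.DataFrame:
    """Simulated photometer readings for every ground-truth record.

    The latent tissue content is pushed backwards through the quantification
    chain (content -> ppm in the diluted extract -> instrument response on the
    standard curve), with Gaussian noise on the response.  Returned columns:
    genotype, treatment, day, replicate, ion, response, ppm_reading — where
    ``ppm_reading`` is the response mapped back through the curve, so with
    zero noise it round-trips through :func:`hsion.chemistry.tissue_content`
    to the latent content exactly.
    """
    if curve_slope <= 0:
        raise InvalidConfigError("curve_slope must be positive")
    if reading_noise_sd < 0:
        raise InvalidConfigError("reading_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    frames = []
    for ion in ions:
        molar_mass = chemistry.MOLAR_MASS_G_PER_MOL[ion]
        content = truth.records[f"{ion.lower()}_content"].to_numpy()
        ppm_true = chemistry.content_to_ppm(content, molar_mass)
        response = curve_slope * ppm_true + curve_intercept
        if reading_noise_sd > 0:
            response = response + rng.normal(0.0, reading_noise_sd, size=len(response))
        df = truth.records[["genotype", "treatment", "day", "replicate"]].copy()
        df["ion"] = ion
        df["response"] = response
        df["ppm_reading"] = (response - curve_intercept) / curve_slope
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_cubes(cubes: CubeSet, directory: str | Path,
                keys: Sequence[tuple] | None = None) -> list[Path]:
    """Write cubes (all, or the given keys) as multi-page TIFFs + sidecar."""
    from .imaging import write_cube

    paths = []
    for key in keys if keys is not None else cubes:
        paths.append(write_cube(cubes[key], directory))
    return paths
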