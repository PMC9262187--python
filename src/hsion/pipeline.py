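"""End-to-end desk-scale study orchestration.

Runs the whole analysis in one call: simulate the experiment, extract one
mean spectrum per plant per day, build the three modeling datasets (raw,
gap-segment smoothed, Q3 band-filtered), quantify final-day ion contents via
the simulated flame-photometry chain, run the repeated-split PLSR search per
ion and dataset, predict daily ion trajectories for every plant, and write
all artifacts (CSV/JSON) to an output directory with a manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chemistry
from .imaging import extract_spectrum
from .modeling import predict_timeseries, repeated_split_search, save_model
from .preprocess import (
    SpectraMatrix,
    q3_band_filter,
    smooth_matrix,
    subset_bands,
)
from .simulate import (
    SimulationConfig,
    simulate_experiment,
    simulate_flame_photometry,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("hsion.pipeline")


@dataclass
class PipelineConfig:
    """Every stage's parameters plus the output directory."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # imaging
    ndvi_red_nm: float = 615.0
    ndvi_nir_nm: float = 1117.0
    ndvi_threshold: float = 0.25
    pixel_mode: str = "nonzero_only"
    # preprocessing
    segment: int = 5
    gap: int = 6
    derivative_order: int = 1
    # chemistry / simulated photometry
    curve_slope: float = 1.0
    curve_intercept: float = 0.0
    reading_noise_sd: float = 0.0
    # modeling
    ions: Sequence[str] = ("Na", "K")
    n_iterations: int = 2000
    max_components: int = 10
    split_fraction: float = 0.5
    #: replicates per genotype x treatment measured by flame photometry and
    #: used for model training (4 of 5 -> 48 final-day samples, half split 24)
    model_replicates: int = 4
    #: training days; empty means the final imaging day only
    training_days: Sequence[int] = ()
    out_dir: str | Path = "hsion_out"

    def validate(self) -> None:
        if not -1.0 < self.ndvi_threshold < 1.0:
            raise ValueError("ndvi_threshold must lie in (-1, 1)")
        if self.pixel_mode not in ("zero_inclusive", "nonzero_only"):
            raise ValueError("invalid pixel_mode")
        if self.segment < 1 or self.gap < 1 or self.derivative_order < 1:
            raise ValueError("segment, gap and derivative order must be >= 1")
        if self.n_iterations < 1 or self.max_components < 1:
            raise ValueError("n_iterations and max_components must be >= 1")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if not 1 <= self.model_replicates <= self.simulation.n_reps_per_treatment:
            raise ValueError("model_replicates exceeds available replicates")
        for d in self.training_days:
            if not 1 <= int(d) <= self.simulation.n_days:
                raise ValueError("training day outside the experiment")


def _search_seed(base_seed: int, index: int) -> int:
    # independent, reproducible sub-seed per (dataset, ion) search
    return int(
        np.random.SeedSequence([base_seed & 0x7FFFFFFF, 17, index]).generate_state(1)[0]
        % (2**31)
    )


def _extract_all_spectra(cubes, config: PipelineConfig) -> SpectraMatrix:
    spectra = []
    annotations = []
    for key in cubes:
        genotype, treatment, rep, day = key
        spec = extract_spectrum(
            cubes[key],
            red_nm=config.ndvi_red_nm,
            nir_nm=config.ndvi_nir_nm,
            threshold=config.ndvi_threshold,
            pixel_mode=config.pixel_mode,
        )
        spectra.append(spec)
        annotations.append(
            {"genotype": genotype, "treatment": treatment, "day": day, "replicate": rep}
        )
    return SpectraMatrix.from_spectra(spectra, pd.DataFrame(annotations))


def _measured_contents(
    truth, config: PipelineConfig, training_days: Sequence[int]
) -> pd.DataFrame:
    """Simulated flame photometry + standard-curve quantification.

    Only the training-day samples of the first ``model_replicates`` replicates
    are 'sacrificed' for chemistry, mirroring destructive sampling.
    """
    rec = truth.records
    subset = rec[
        rec.day.isin(list(training_days)) & (rec.replicate <= config.model_replicates)
    ]
    sub_truth = type(truth)(subset.reset_index(drop=True))
    readings = simulate_flame_photometry(
        sub_truth,
        curve_slope=config.curve_slope,
        curve_intercept=config.curve_intercept,
        reading_noise_sd=config.reading_noise_sd,
        seed=_search_seed(config.simulation.seed, 999),
        ions=config.ions,
    )
    # calibrate on the six-standard curve and quantify
    standards = [
        (p, config.curve_slope * p + config.curve_intercept)
        for p in chemistry.DEFAULT_STANDARD_PPM
    ]
    curve = chemistry.fit_standard_curve(standards)
    ppm = chemistry.reading_to_ppm(readings["response"].to_numpy(), curve)
    contents = np.empty(len(readings))
    for ion in config.ions:
        sel = (readings["ion"] == ion).to_numpy()
        contents[sel] = chemistry.tissue_content(
            ppm[sel], chemistry.MOLAR_MASS_G_PER_MOL[ion]
        )
    out = readings[["genotype", "treatment", "day", "replicate", "ion"]].copy()
    out["content_mmol_per_gDW"] = contents
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full study; returns a manifest of written artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"artifacts": {}, "summary": None}

    def _register(name: str, path: Path) -> Path:
        manifest["artifacts"][name] = str(path)
        return path

    stage = "simulate"
    try:
        logger.info("[simulate] seed=%d", config.simulation.seed)
        cubes, truth = simulate_experiment(config.simulation)
        truth.to_csv(_register("truth", out / "truth.csv"))

        stage = "imaging"
        logger.info(
            "[imaging] %d cubes, NDVI %s/%s nm, threshold %.2f, %s",
            len(cubes),
            config.ndvi_red_nm,
            config.ndvi_nir_nm,
            config.ndvi_threshold,
            config.pixel_mode,
        )
        raw = _extract_all_spectra(cubes, config)
        raw.to_csv(_register("spectra_raw", out / "spectra_raw.csv"))

        stage = "preprocessing"
        logger.info(
            "[preprocessing] segment=%d gap=%d order=%d",
            config.segment,
            config.gap,
            config.derivative_order,
        )
        smoothed = smooth_matrix(raw, config.segment, config.gap, config.derivative_order)
        smoothed.to_csv(_register("spectra_smoothed", out / "spectra_smoothed.csv"))
        band_filter = q3_band_filter(raw)
        band_filter.to_csv(_register("band_filter", out / "band_filter.csv"))
        filtered = subset_bands(raw, band_filter)
        filtered.to_csv(_register("spectra_filtered", out / "spectra_filtered.csv"))

        stage = "chemistry"
        training_days = [int(d) for d in config.training_days] or [
            int(config.simulation.n_days)
        ]
        logger.info("[chemistry] training days %s", training_days)
        ion_records = _measured_contents(truth, config, training_days)
        ion_records.to_csv(_register("ion_records", out / "ion_records.csv"), index=False)

        stage = "modeling"
        datasets = {"raw": raw, "smoothed": smoothed, "filtered": filtered}
        summary_rows = []
        gap_rows = []
        search_idx = 0
        for ds_name, matrix in datasets.items():
            ann = matrix.annotations
            train_rows = (
                ann.day.isin(training_days) & (ann.replicate <= config.model_replicates)
            ).to_numpy()
            train_matrix = matrix.select_rows(train_rows)
            for ion in config.ions:
                ion_y = ion_records[ion_records.ion == ion]
                merged = train_matrix.annotations.merge(
                    ion_y,
                    on=["genotype", "treatment", "day", "replicate"],
                    how="left",
                )
                y = merged["content_mmol_per_gDW"].to_numpy()
                if np.any(np.isnan(y)):
                    raise RuntimeError("missing measured content for a training row")
                seed = _search_seed(config.simulation.seed, search_idx)
                search_idx += 1
                logger.info(
                    "[modeling] dataset=%s ion=%s n=%d iterations=%d seed=%d",
                    ds_name,
                    ion,
                    train_matrix.n_samples,
                    config.n_iterations,
                    seed,
                )
                result = repeated_split_search(
                    train_matrix,
                    y,
                    n_iterations=config.n_iterations,
                    max_components=config.max_components,
                    split_fraction=config.split_fraction,
                    seed=seed,
                )
                save_model(
                    result,
                    _register(
                        f"model_{ds_name}_{ion}", out / f"model_{ds_name}_{ion}.json"
                    ),
                    metadata={"dataset": ds_name, "ion": ion},
                )
                result.log.to_csv(
                    _register(
                        f"search_log_{ds_name}_{ion}",
                        out / f"search_log_{ds_name}_{ion}.csv",
                    ),
                    index=False,
                )
                preds = predict_timeseries(result, matrix)
                preds.to_csv(
                    _register(
                        f"predictions_{ds_name}_{ion}",
                        out / f"predictions_{ds_name}_{ion}.csv",
                    ),
                    index=False,
                )
                summary_rows.append(
                    {
                        "dataset": ds_name,
                        "ion": ion,
                        "n_train": result.n_train,
                        "n_samples": train_matrix.n_samples,
                        "best_n_components": result.best_n_components,
                        "best_rmsep": result.best_rmsep,
                        "best_r_squared": result.best_r_squared,
                        "n_negative_predictions": int(preds["negative"].sum()),
                    }
                )
                last = preds[preds.day == int(config.simulation.n_days)]
                gaps = (
                    last.groupby(["genotype", "treatment"])["prediction"]
                    .mean()
                    .unstack("treatment")
                )
                for genotype, row in gaps.iterrows():
                    gap_rows.append(
                        {
                            "dataset": ds_name,
                            "ion": ion,
                            "genotype": genotype,
                            "day": int(config.simulation.n_days),
                            "predicted_gap": float(row["salinity"] - row["control"]),
                        }
                    )

        summary = pd.DataFrame(summary_rows)
        summary.to_csv(_register("summary", out / "summary.csv"), index=False)
        pd.DataFrame(gap_rows).to_csv(
            _register("treatment_gaps", out / "treatment_gaps.csv"), index=False
        )
        manifest["summary"] = summary_rows
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        manifest["artifacts"]["manifest"] = str(out / "manifest.json")
        return manifest
    except Exception:
        logger.exception("pipeline failed in stage '%s'", stage)
        raise


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a TOML file with [simulation] and
    [pipeline] tables (both optional; omitted keys keep their defaults)."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    sim = SimulationConfig(**data.get("simulation", {}))
    pipe_kwargs = data.get("pipeline", {})
    return PipelineConfig(simulation=sim, **pipe_kwargs)
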