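"""End-to-end orchestration from a single YAML/dict configuration.

Runs apertures → simulate (or load) → preprocess → [filter] → fit →
ceiling → summarize → compare (when a second dataset is configured) and
writes TSV/JSON artifacts plus a manifest (config hash, seed, versions)
from which every artifact can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ceiling import noise_ceiling_map, normalized_fit
from .design import BarDesign, generate_apertures
from .fit import FitConfig, GridSpec, R2_DISPLAY, R2_SUMMARY, build_grid, fit_map
from .model import HRFSpec
from .preprocess import TimeSeriesSet, preprocess_runs
from .simulate import DEFAULT_NOISE_SD, make_truth_layout, simulate_runs
from .surface import bin_summarize, compare_maps

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline invocation needs, with protocol defaults."""

    design: BarDesign = field(default_factory=BarDesign)
    hrf: HRFSpec = field(default_factory=HRFSpec)
    grid: GridSpec = field(default_factory=GridSpec)
    fit: FitConfig = field(default_factory=FitConfig)
    filter_sd_s: float | None = None
    display_r2: float = R2_DISPLAY
    summary_r2: float = R2_SUMMARY
    bootstrap_n: int = 1000
    bootstrap_level: float = 0.95
    n_vertices: int = 50
    n_runs: int = 6
    noise_sd: float = DEFAULT_NOISE_SD
    sigma_law: tuple[float, float] = (0.5, 0.15)
    ecc_range: tuple[float, float] = (0.5, 8.0)
    second_site_seed: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for thr in (self.fit.gate_r2, self.display_r2, self.summary_r2):
            if not 0 <= thr <= 1:
                raise ValueError("R² thresholds must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "design" in d and isinstance(d["design"], dict):
            if "baseline_after_sweeps" in d["design"]:
                d["design"]["baseline_after_sweeps"] = tuple(
                    d["design"]["baseline_after_sweeps"]
                )
            d["design"] = BarDesign(**d["design"])
        if "hrf" in d and isinstance(d["hrf"], dict):
            d["hrf"] = HRFSpec(**d["hrf"])
        if "grid" in d and isinstance(d["grid"], dict):
            for key in ("ecc_range", "sigma_range"):
                if key in d["grid"]:
                    d["grid"][key] = tuple(d["grid"][key])
            d["grid"] = GridSpec(**d["grid"])
        if "fit" in d and isinstance(d["fit"], dict):
            d["fit"] = FitConfig(**d["fit"])
        for key in ("sigma_law", "ecc_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def _config_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _simulate_site(config: PipelineConfig, movie, noise_seed: int):
    """Simulate one scanning site: the pRF layout is shared across sites
    (drawn from config.seed); only the noise realisation differs."""
    import dataclasses

    truth = make_truth_layout(
        config.n_vertices,
        ecc_range=config.ecc_range,
        sigma_law=config.sigma_law,
        noise_sd=config.noise_sd,
        n_runs=config.n_runs,
        seed=config.seed,
    )
    truth = dataclasses.replace(truth, seed=noise_seed)
    return simulate_runs(truth, movie, config.hrf)


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    runs: TimeSeriesSet | None = None,
) -> dict:
    """Execute all stages and write artifacts under ``out_dir``.

    When ``runs`` is None, data are simulated from the config's generator
    settings (the packaged demonstration mode); otherwise the provided runs
    are analysed.  Returns the manifest dict.  Stage failures abort with a
    stage-tagged error; artifacts written before the failure remain.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    stage = "apertures"
    try:
        movie_full = generate_apertures(config.design, include_dummies=True)
        movie = movie_full.without_dummies()
        movie_full.save(out / "apertures.nii.gz")
        artifacts.append("apertures.nii.gz")

        stage = "simulate-or-load"
        if runs is None:
            dataset = _simulate_site(config, movie, config.seed)
            runs = dataset.runs
            dataset.truth.table.to_csv(out / "truth.tsv", sep="\t", index=False)
            artifacts.append("truth.tsv")
        if runs.n_frames != movie.n_frames:
            raise ValueError(
                f"data has {runs.n_frames} frames but the design implies "
                f"{movie.n_frames} post-dummy frames"
            )

        stage = "preprocess"
        data = preprocess_runs(runs, filter_sd_s=None)
        if config.filter_sd_s is not None:
            stage = "filter"
            from .preprocess import gaussian_lowpass

            data = gaussian_lowpass(data, config.filter_sd_s, runs.tr_s, axis=0)
        np.savetxt(out / "preprocessed.tsv.gz", data, delimiter="\t")
        artifacts.append("preprocessed.tsv.gz")

        stage = "fit"
        grid = build_grid(config.grid, movie, config.hrf)
        fits = fit_map(data, grid, movie, config.hrf, config.fit)
        fits.to_csv(out / "prf_fits.tsv", sep="\t", index=False)
        artifacts.append("prf_fits.tsv")

        stage = "ceiling"
        ceiling = noise_ceiling_map(runs)
        ceiling["normalized_r2"] = normalized_fit(
            fits["r2"].to_numpy(), ceiling["ceiling"].to_numpy()
        )
        ceiling.to_csv(out / "noise_ceiling.tsv", sep="\t", index=False)
        artifacts.append("noise_ceiling.tsv")

        stage = "summarize"
        ecc = np.hypot(fits["x0"], fits["y0"]).to_numpy()
        rng = np.random.default_rng(config.seed)
        summary = bin_summarize(
            ecc,
            fits["sigma"].to_numpy(),
            statistic="mean",
            r_squared=fits["r2"].to_numpy(),
            r2_threshold=config.summary_r2,
            n_boot=config.bootstrap_n,
            ci_level=config.bootstrap_level,
            rng=rng,
        )
        summary.to_csv(out / "size_by_eccentricity.tsv", sep="\t", index=False)
        artifacts.append("size_by_eccentricity.tsv")

        stage = "compare"
        comparison = None
        if config.second_site_seed is not None:
            dataset_b = _simulate_site(config, movie, config.second_site_seed)
            data_b = preprocess_runs(dataset_b.runs, filter_sd_s=config.filter_sd_s)
            fits_b = fit_map(data_b, grid, movie, config.hrf, config.fit)
            fits_b.to_csv(out / "prf_fits_site_b.tsv", sep="\t", index=False)
            artifacts.append("prf_fits_site_b.tsv")
            comparison = compare_maps(fits, fits_b, r2_threshold=config.display_r2)
            (out / "map_comparison.json").write_text(json.dumps(comparison, indent=1))
            artifacts.append("map_comparison.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "prfpipe_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "config": config.to_dict(),
        "artifacts": artifacts,
        "comparison": comparison,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return manifest
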