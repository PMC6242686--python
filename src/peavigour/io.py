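"""Pipeline configuration, file formats and stage runners.

The pipeline chains four re-runnable stages that communicate only through
files in a shared output directory::

    simulate -> extract -> fit -> analyze

``simulate`` writes multi-view scene images, ground truth, replicate
growth series, water logs and field reflectance records, plus a manifest
listing every artifact.  ``extract`` segments the images into a per-plant
trait table; ``fit`` fits the two-phase growth model per genotype;
``analyze`` applies the linear-phase onset rule and builds the genotype
vigour ranking.  All outputs are plain CSV/JSON and byte-reproducible for
a fixed configuration and seed.

Configuration is a YAML file validated against a strict schema (unknown
keys are rejected).  The defaults mirror the scale of the glasshouse
experiment the synthetic cohort emulates: 44 genotypes, 8 replicates,
daily imaging from 11 to 39 days after sowing.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .growth import GrowthSeries, broken_stick_value, fit_broken_stick, linear_phase_onset
from .segmentation import (
    SIDE_VIEWS,
    VIEWS,
    ColourRule,
    MultiViewImageSet,
    extract_traits,
)
from .synthetic import GrowthParams, parametric_scene, make_scene, simulate_field_ndvi, simulate_growth
from .vigour import ReflectanceRecord, WaterLog, rank_genotypes

logger = logging.getLogger("peavigour.io")

__all__ = [
    "ConfigError",
    "InputDataError",
    "PipelineConfig",
    "SimulateConfig",
    "SegmentationConfig",
    "FitConfig",
    "load_config",
    "reference_growth_params",
    "run_simulate",
    "run_extract",
    "run_fit",
    "run_analyze",
]


class ConfigError(ValueError):
    """Invalid or unparseable pipeline configuration."""


class InputDataError(ValueError):
    """A stage input file is missing or violates its schema."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_StrictModel):
    """Cohort and scene parameters for the synthetic generators."""

    n_genotypes: int = Field(44, ge=1, le=44)
    n_reps: int = Field(8, ge=1)
    day_start: int = Field(11, ge=0)
    day_end: int = Field(39, ge=1)
    cv: float = Field(0.03, ge=0)
    image_days: list[int] | None = None
    image_width: int = Field(200, ge=32)
    image_height: int = Field(200, ge=32)
    noise_sd: float = Field(5.0, ge=0)
    pixel_scale: float = Field(0.05, gt=0)
    water_kg_mean: float = Field(2.0, gt=0)
    water_kg_sd: float = Field(0.2, ge=0)
    ndvi_reference_day: int = Field(27, ge=1)
    ndvi_lo: float = Field(0.2, gt=-1, lt=1)
    ndvi_hi: float = Field(0.85, gt=-1, lt=1)
    ndvi_noise_sd: float = Field(0.02, ge=0)
    reflectance_total: float = Field(0.8, gt=0, le=1)
    n_plots: int = Field(3, ge=1)

    @model_validator(mode="after")
    def _check_days(self) -> "SimulateConfig":
        if self.day_start >= self.day_end:
            raise ValueError("day_start must precede day_end")
        if not self.day_start <= self.ndvi_reference_day <= self.day_end:
            raise ValueError("ndvi_reference_day must lie within the day range")
        if self.ndvi_lo >= self.ndvi_hi:
            raise ValueError("ndvi_lo must be below ndvi_hi")
        if self.image_days is not None:
            bad = [d for d in self.image_days if not self.day_start <= d <= self.day_end]
            if bad:
                raise ValueError(f"image_days outside the day range: {bad}")
        return self


class SegmentationConfig(_StrictModel):
    """HSV colour-rule windows and the component-size noise filter."""

    plant_hue: tuple[float, float] = (0.17, 0.50)
    plant_sat_min: float = Field(0.25, ge=0, le=1)
    plant_val_min: float = Field(0.10, ge=0, le=1)
    cage_hue: tuple[float, float] = (0.52, 0.80)
    cage_sat_min: float = Field(0.25, ge=0, le=1)
    min_size: int = Field(50, ge=1)

    def rule(self) -> ColourRule:
        return ColourRule(
            plant_hue=self.plant_hue,
            plant_sat_min=self.plant_sat_min,
            plant_val_min=self.plant_val_min,
            cage_hue=self.cage_hue,
            cage_sat_min=self.cage_sat_min,
        )


class FitConfig(_StrictModel):
    grid_step: float = Field(0.01, gt=0, le=1.0)


class PipelineConfig(_StrictModel):
    """Top-level pipeline configuration (one YAML document)."""

    seed: int = Field(0, ge=0)
    simulate: SimulateConfig = SimulateConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    fit: FitConfig = FitConfig()


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML configuration (defaults when ``path`` is None)."""
    if path is None:
        return PipelineConfig()
    try:
        data = yaml.safe_load(Path(path).read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def reference_growth_params() -> pd.DataFrame:
    """The packaged split-line parameter table for the 44 pea genotypes.

    Columns: genotype, x_day, y_kpix, slope1, slope2 — the published
    breakpoint coordinates and phase slopes for each genotype.
    """
    with resources.files("peavigour").joinpath("data/pea_split_line_params.csv").open() as fh:
        return pd.read_csv(fh)


def _read_csv(path: Path, required: Iterable[str]) -> pd.DataFrame:
    if not path.exists():
        raise InputDataError(f"{path}: input file not found")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # parser errors name the offending line
        raise InputDataError(f"{path}: {exc}") from exc
    for col in required:
        if col not in df.columns:
            raise InputDataError(f"{path}: missing required column '{col}'")
    return df


def _child_seed(base: int, *key: int) -> int:
    """Deterministic sub-stream seed derived from the pipeline seed."""
    return int(np.random.SeedSequence([base, *key]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------- simulate

def run_simulate(
    config: PipelineConfig, outdir: str | Path, seed: int | None = None
) -> dict:
    """Generate the synthetic cohort and write every artifact plus a manifest."""
    cfg = config.simulate
    base_seed = config.seed if seed is None else seed
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    params_table = reference_growth_params().iloc[: cfg.n_genotypes]
    manifest: dict = {"images": [], "seed": base_seed}

    # replicate growth series per genotype
    series_rows = []
    series_by_plant: dict[tuple[str, int], GrowthSeries] = {}
    genotype_code = {}
    for gi, row in enumerate(params_table.itertuples(index=False)):
        code = f"g{gi + 1:02d}"
        genotype_code[row.genotype] = code
        params = GrowthParams(
            genotype=row.genotype,
            x_day=row.x_day, y_kpix=row.y_kpix,
            slope1=row.slope1, slope2=row.slope2,
            day_start=cfg.day_start, day_end=cfg.day_end,
            cv=cfg.cv, n_reps=cfg.n_reps,
            seed=_child_seed(base_seed, 1, gi),
        )
        for s in simulate_growth(params):
            series_by_plant[(row.genotype, int(s.replicate))] = s
            for d, v in zip(s.days, s.values):
                series_rows.append((row.genotype, s.replicate, int(d), round(v, 6)))
    series_df = pd.DataFrame(series_rows, columns=["genotype", "replicate", "das", "eb_kpix"])
    series_path = out / "growth_series.csv"
    series_df.to_csv(series_path, index=False)
    manifest["growth_series"] = series_path.name
    series_dir = out / "series"
    series_dir.mkdir(exist_ok=True)
    manifest["series"] = []
    for genotype, sub in series_df.groupby("genotype", sort=True):
        fname = f"series/{genotype_code[genotype]}.csv"
        sub.to_csv(out / fname, index=False)
        manifest["series"].append(fname)

    # plant registry and water logs (one pot per genotype x replicate)
    rng_water = np.random.default_rng(_child_seed(base_seed, 2))
    plants, water_rows = [], []
    for genotype, code in genotype_code.items():
        for rep in range(1, cfg.n_reps + 1):
            plant_id = f"{code}r{rep}"
            plants.append((plant_id, genotype, rep))
            w = max(float(rng_water.normal(cfg.water_kg_mean, cfg.water_kg_sd)), 0.05)
            water_rows.append((plant_id, round(w, 4)))
    pd.DataFrame(plants, columns=["plant_id", "genotype", "replicate"]).to_csv(
        out / "plants.csv", index=False
    )
    pd.DataFrame(water_rows, columns=["plant_id", "total_water_kg"]).to_csv(
        out / "water.csv", index=False
    )
    manifest["plants"] = "plants.csv"
    manifest["water"] = "water.csv"

    # field reflectance linked to the generating model at the reference day
    means = {
        row.genotype: float(broken_stick_value(
            cfg.ndvi_reference_day, row.x_day, row.y_kpix, row.slope1, row.slope2))
        for row in params_table.itertuples(index=False)
    }
    lo, hi = min(means.values()), max(means.values())
    slope = (cfg.ndvi_hi - cfg.ndvi_lo) / (hi - lo) if hi > lo else 0.0
    link = (cfg.ndvi_lo - slope * lo, slope)
    records = simulate_field_ndvi(
        means, link, noise_sd=cfg.ndvi_noise_sd,
        seed=_child_seed(base_seed, 3),
        total_reflectance=cfg.reflectance_total, n_plots=cfg.n_plots,
    )
    pd.DataFrame(
        [(r.plot_id, r.genotype, round(r.r670, 6), round(r.r760, 6)) for r in records],
        columns=["plot_id", "genotype", "r670", "r760"],
    ).to_csv(out / "reflectance.csv", index=False)
    manifest["reflectance"] = "reflectance.csv"

    # multi-view scene images, sized from each replicate's series value
    if cfg.image_days:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        gt_rows = []
        for (genotype, rep), s in sorted(series_by_plant.items(),
                                         key=lambda kv: (genotype_code[kv[0][0]], kv[0][1])):
            code = genotype_code[genotype]
            gi = int(code[1:])
            plant_id = f"{code}r{rep}"
            for day in cfg.image_days:
                v = float(s.values[np.searchsorted(s.days, day)])
                # floor keeps the rendered seedling well above the size
                # filter so early small plants never vanish from the masks
                per_view = max(int(round(v * 1000 * cfg.pixel_scale / 4)), 150)
                spec = parametric_scene(
                    cfg.image_width, cfg.image_height, per_view,
                    noise_sd=cfg.noise_sd,
                    seed=_child_seed(base_seed, 4, gi, rep, day),
                )
                imageset, gt = make_scene(spec, plant_id=plant_id,
                                          genotype=genotype, das=day)
                for view, img in imageset.views().items():
                    fname = f"{plant_id}_{day}_{view}.png"
                    iio.imwrite(img_dir / fname, img)
                    manifest["images"].append(f"images/{fname}")
                    gt_rows.append((
                        plant_id, genotype, day, view, gt.plant_pixels[view],
                        gt.top_hull_pixels if view == "top" else "",
                        gt.side_heights.get(view, ""),
                    ))
        pd.DataFrame(
            gt_rows,
            columns=["plant_id", "genotype", "das", "view",
                     "plant_pixels", "top_hull_pixels", "side_height"],
        ).to_csv(out / "ground_truth.csv", index=False)
        manifest["ground_truth"] = "ground_truth.csv"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("simulate: %d genotypes, %d series rows, %d images",
                cfg.n_genotypes, len(series_df), len(manifest["images"]))
    return manifest


# ----------------------------------------------------------------- extract

def run_extract(config: PipelineConfig, outdir: str | Path) -> Path:
    """Segment every rendered plant-day and write the trait table."""
    out = Path(outdir)
    img_dir = out / "images"
    if not img_dir.is_dir():
        raise InputDataError(f"{img_dir}: no images directory; run simulate first")
    plants = _read_csv(out / "plants.csv", ["plant_id", "genotype"])
    genotype_of = dict(zip(plants["plant_id"], plants["genotype"]))

    by_key: dict[tuple[str, int], dict[str, Path]] = {}
    for png in sorted(img_dir.glob("*.png")):
        try:
            plant_id, das, view = png.stem.rsplit("_", 2)
        except ValueError:
            logger.warning("extract: unparseable image name %s", png.name)
            continue
        by_key.setdefault((plant_id, int(das)), {})[view] = png

    rule = config.segmentation.rule()
    rows, n_flagged = [], 0
    for (plant_id, das), files in sorted(by_key.items()):
        genotype = genotype_of.get(plant_id, "")
        missing = [v for v in VIEWS if v not in files]
        if missing:
            n_flagged += 1
            logger.warning("extract: %s das=%d missing views %s", plant_id, das, missing)
            rows.append((plant_id, genotype, das, *([np.nan] * 5),
                         ";".join(f"missing_view:{v}" for v in missing)))
            continue
        imageset = MultiViewImageSet(
            plant_id=plant_id, genotype=genotype, das=das,
            top=iio.imread(files["top"]),
            sides={v: iio.imread(files[v]) for v in SIDE_VIEWS},
        )
        rec = extract_traits(imageset, rule, min_size=config.segmentation.min_size)
        if rec.flags:
            n_flagged += 1
        rows.append((plant_id, genotype, das, rec.eb_kpix, rec.tva_kpix,
                     rec.tvch_kpix, rec.tvcom, rec.eh_pix, ";".join(rec.flags)))

    traits = pd.DataFrame(rows, columns=[
        "plant_id", "genotype", "das", "eb_kpix", "tva_kpix",
        "tvch_kpix", "tvcom", "eh_pix", "flags",
    ])
    path = out / "traits.csv"
    traits.to_csv(path, index=False)
    logger.info("extract: %d plant-days in, %d flagged", len(traits), n_flagged)
    return path


# --------------------------------------------------------------------- fit

def run_fit(
    config: PipelineConfig, outdir: str | Path, series_csv: str | Path | None = None
) -> Path:
    """Fit the two-phase model per genotype on replicate-mean series.

    Input is ``series_csv`` when given, else ``traits.csv`` from the
    extract stage, else the simulated ``growth_series.csv``.  Genotypes
    with fewer than six usable days are skipped with a warning, never an
    abort.
    """
    out = Path(outdir)
    if series_csv is not None:
        src = Path(series_csv)
    elif (out / "traits.csv").exists():
        src = out / "traits.csv"
    else:
        src = out / "growth_series.csv"
    df = _read_csv(src, ["genotype", "das", "eb_kpix"])
    usable = df[df["eb_kpix"].notna()]

    fits, skipped = [], []
    for genotype, sub in usable.groupby("genotype", sort=True):
        mean = sub.groupby("das")["eb_kpix"].mean().sort_index()
        if len(mean) < 6:
            skipped.append(genotype)
            continue
        series = GrowthSeries(str(genotype), None,
                              mean.index.to_numpy(dtype=float), mean.to_numpy())
        f = fit_broken_stick(series, grid_step=config.fit.grid_step)
        fits.append((f.genotype, round(f.x_day, 4), round(f.y_kpix, 4),
                     round(f.slope1, 4), round(f.slope2, 4),
                     round(f.adj_r2, 6), round(f.sse, 6), int(f.degenerate), f.n_obs))
    if skipped:
        logger.warning("fit: skipped %d genotypes with < 6 usable days: %s",
                       len(skipped), skipped)
    if not fits:
        raise InputDataError(f"{src}: no genotype had enough usable days to fit")
    path = out / "fits.csv"
    pd.DataFrame(fits, columns=[
        "genotype", "x_day", "y_kpix", "slope1", "slope2",
        "adj_r2", "sse", "degenerate", "n_obs",
    ]).to_csv(path, index=False)
    logger.info("fit: %d genotypes fitted, %d skipped", len(fits), len(skipped))
    return path


# ----------------------------------------------------------------- analyze

def run_analyze(config: PipelineConfig, outdir: str | Path) -> dict:
    """Apply the onset rule and build the genotype vigour ranking."""
    out = Path(outdir)
    fits = _read_csv(out / "fits.csv", ["genotype", "x_day"])
    onset = linear_phase_onset(fits["x_day"].to_list())

    if (out / "traits.csv").exists():
        traits = _read_csv(out / "traits.csv", ["plant_id", "genotype", "das", "eb_kpix"])
    else:
        series = _read_csv(out / "growth_series.csv",
                           ["genotype", "replicate", "das", "eb_kpix"])
        traits = series.assign(
            plant_id=[f"{g}-r{r}" for g, r in zip(series["genotype"], series["replicate"])]
        )[["plant_id", "genotype", "das", "eb_kpix"]]

    days = sorted(set(traits.loc[traits["eb_kpix"].notna(), "das"]))
    candidates = [d for d in days if d >= onset]
    if not candidates:
        raise InputDataError(
            f"fits.csv/traits: no trait day at or after the onset day {onset}"
        )
    comparison_day = int(candidates[0])
    logger.info("analyze: onset day %d, comparison day %d", onset, comparison_day)

    water = None
    if (out / "water.csv").exists():
        wdf = _read_csv(out / "water.csv", ["plant_id", "total_water_kg"])
        if (out / "traits.csv").exists():
            water = [WaterLog(p, w) for p, w in
                     zip(wdf["plant_id"], wdf["total_water_kg"])]
    reflectance = None
    if (out / "reflectance.csv").exists():
        rdf = _read_csv(out / "reflectance.csv", ["plot_id", "genotype", "r670", "r760"])
        reflectance = [ReflectanceRecord(p, g, float(a), float(b)) for p, g, a, b in
                       zip(rdf["plot_id"], rdf["genotype"], rdf["r670"], rdf["r760"])]

    later = [d for d in days if d > comparison_day]
    rgr_interval = (comparison_day, later[-1]) if later else None
    vt = rank_genotypes(
        traits, comparison_day, water=water, reflectance=reflectance,
        rgr_interval=rgr_interval,
    )

    table_path = out / "vigour_table.csv"
    vt.table.round(6).to_csv(table_path)
    anova_path = out / "vigour_anova.csv"
    vt.anova.round(6).to_csv(anova_path)
    paths = {"vigour_table": table_path, "anova": anova_path}
    if vt.ndvi_correlations is not None:
        corr_path = out / "ndvi_correlations.csv"
        vt.ndvi_correlations.round(6).to_csv(corr_path)
        paths["ndvi_correlations"] = corr_path
    summary = {
        "onset_day": onset,
        "comparison_day": comparison_day,
        "n_genotypes": int(len(vt.table)),
    }
    (out / "analyze_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    paths["summary"] = out / "analyze_summary.json"
    logger.info("analyze: ranked %d genotypes", len(vt.table))
    return paths
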