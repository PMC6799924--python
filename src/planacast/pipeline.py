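"""End-to-end orchestration: simulate -> derive RH -> extract -> model.

A single seeded configuration drives the whole chain: synthetic scenes
for every day covering the census calendar (plus the six-week lag
lead-in), RH retrieval per scene, nearest-neighbour resampling,
area-weighted block extraction, lagged-dataset assembly and cleaning,
and the nine predictor configurations — each fitted by linear
regression, polynomial regression and the quickprop MLP — evaluated
with the shared metric set. Every artifact lands in a run directory
with a manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ann import TrainConfig, forward_select_features, search_architecture, train_ann, split_dataset
from .evaluation import evaluate_model
from .regression import fit_regression, stepwise_select
from .rh import Scene, derive_rh, write_scene
from .synthetic import (
    EstateLayout,
    ResponseSpec,
    WeatherSpec,
    census_dates,
    default_layout,
    generate_census,
    generate_scene,
    pw_for_target_rh,
    write_census_csv,
)
from .zonal import (
    LaggedDataset,
    assemble_lagged,
    build_block_series,
    clean_dataset,
    resample_nearest,
)

log = logging.getLogger(__name__)

#: The nine predictor configurations: six single lags, the two
#: three-lag groups, and automatic (stepwise / forward) selection.
CONFIGURATIONS: tuple[tuple[str, tuple[int, ...] | None], ...] = (
    ("T1", (1,)),
    ("T2", (2,)),
    ("T3", (3,)),
    ("T4", (4,)),
    ("T5", (5,)),
    ("T6", (6,)),
    ("T1,T2,T3", (1, 2, 3)),
    ("T4,T5,T6", (4, 5, 6)),
    ("auto", None),
)


def derive_seed(root: int, tag: str) -> int:
    """Stable per-stage seed below 2**31 derived from the root seed."""
    return (root * 2654435761 + zlib.crc32(tag.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    simulate: bool = True
    years: int = 2
    cycles_per_year: int = 24
    start_date: datetime.date = datetime.date(2014, 3, 1)
    pw_variant: str = "as_printed_grouped"
    clamp: bool = True
    target_pixel_m: float = 250.0
    window_days: int = 8
    cleaning_rule: str = "zscore3"
    response: ResponseSpec = field(default_factory=ResponseSpec)
    weather: WeatherSpec = field(default_factory=WeatherSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    auto_hidden: bool = True
    hidden: int = 8
    hidden_range: tuple[int, ...] = tuple(range(1, 11))
    select_hidden: int = 6
    entry_p: float = 0.15
    stay_p: float = 0.15
    write_scenes: bool = False
    seed: int = 0

    _KNOWN = None  # populated below

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["start_date"] = self.start_date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        if "start_date" in d and isinstance(d["start_date"], str):
            d["start_date"] = datetime.date.fromisoformat(d["start_date"])
        for key, sub in (("response", ResponseSpec), ("weather", WeatherSpec),
                         ("train", TrainConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "hidden_range" in d:
            d["hidden_range"] = tuple(d["hidden_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Simulation of daily scenes
# ---------------------------------------------------------------------------

def _daily_fields(layout: EstateLayout, dates, weather: WeatherSpec, seed: int):
    """Per-day pixelwise target RH and Ta fields over the layout grid."""
    rng = np.random.default_rng(seed)
    ny, nx = layout.n_rows, layout.n_cols
    n_days = len(dates)
    innov = rng.normal(0.0, weather.rh_daily_sd, n_days)
    shared = np.empty(n_days)
    shared[0] = innov[0]
    for t in range(1, n_days):
        shared[t] = weather.rh_ar * shared[t - 1] + np.sqrt(
            1 - weather.rh_ar**2
        ) * innov[t]
    pix_offset = rng.normal(0.0, weather.rh_block_sd, (ny, nx))
    doy = np.array([d.timetuple().tm_yday for d in dates])
    seasonal = weather.rh_seasonal_amp * np.sin(2 * np.pi * doy / 365.25)
    ta_seasonal = weather.ta_amp * np.sin(2 * np.pi * doy / 365.25)
    for i, d in enumerate(dates):
        pix_noise = rng.normal(0.0, weather.rh_block_daily_sd, (ny, nx))
        rh = np.clip(
            weather.rh_base + seasonal[i] + shared[i] + pix_offset + pix_noise,
            weather.rh_lo, weather.rh_hi,
        )
        ta = np.full((ny, nx), weather.ta_base + ta_seasonal[i]) + rng.normal(
            0.0, weather.ta_daily_sd
        )
        yield d, rh, ta


def simulate_scenes(
    layout: EstateLayout,
    dates: list[datetime.date],
    weather: WeatherSpec,
    pw_variant: str,
    seed: int,
) -> list[Scene]:
    """Daily scenes whose retrieved RH matches a weather-like field."""
    elev = np.linspace(20.0, 60.0, layout.n_rows * layout.n_cols).reshape(
        layout.n_rows, layout.n_cols
    )
    scenes = []
    for i, (d, rh, ta) in enumerate(_daily_fields(layout, dates, weather, seed)):
        pw = pw_for_target_rh(rh, ta, elev, clip=True)
        scenes.append(
            generate_scene(
                layout, pw, ta, elev,
                pw_variant=pw_variant,
                seed=derive_seed(seed, f"scene:{d.isoformat()}"),
                timestamp=d,
            )
        )
    return scenes


# ---------------------------------------------------------------------------
# Model fitting and reporting
# ---------------------------------------------------------------------------

def fit_all_models(
    ds: LaggedDataset, cfg: PipelineConfig
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Fit the nine regression and nine ANN configurations.

    Returns (models, table3, table4): ``models`` maps config name to the
    fitted objects and their reports; ``table3`` compares adjusted R2 on
    the test split across methods; ``table4`` lists the ANN architecture,
    absolute errors and min-max accuracies per split.
    """
    train, test, validation = split_dataset(ds, seed=derive_seed(cfg.seed, "split"))
    splits = {"training": train, "validation": validation, "testing": test}
    models: dict = {}
    t3_rows, t4_rows = [], []
    for name, lags in CONFIGURATIONS:
        entry: dict = {}
        # -- regressions (fitted on the training split)
        train_ds = LaggedDataset(frame=train, lag_days=ds.lag_days,
                                 window_days=ds.window_days)
        if lags is None:
            lin = stepwise_select(train_ds, degree=1, entry_p=cfg.entry_p,
                                  stay_p=cfg.stay_p)
            poly = stepwise_select(train_ds, degree=2, entry_p=cfg.entry_p,
                                   stay_p=cfg.stay_p)
        else:
            lin = fit_regression(train_ds, lags, degree=1)
            poly = fit_regression(train_ds, lags, degree=2)
        entry["linear"] = lin
        entry["polynomial"] = poly
        entry["linear_report"] = evaluate_model(
            lin, splits, p_terms=max(len(lin.terms), 1),
            metadata={"config": name, "method": "linear"},
        )
        entry["polynomial_report"] = evaluate_model(
            poly, splits, p_terms=max(len(poly.terms), 1),
            metadata={"config": name, "method": "polynomial"},
        )
        # -- ANN
        ann_cfg = dataclasses.replace(
            cfg.train, seed=derive_seed(cfg.seed, f"ann:{name}")
        )
        if lags is None:
            feats, trace = forward_select_features(
                train, validation, [f"rh_T{k}" for k in range(1, 7)],
                n_hidden=cfg.select_hidden, cfg=ann_cfg,
            )
            entry["feature_trace"] = trace
        else:
            feats = tuple(f"rh_T{k}" for k in lags)
        if cfg.auto_hidden:
            n_hidden, fit_table = search_architecture(
                train, validation, feats, cfg.hidden_range, ann_cfg
            )
            entry["fitness_table"] = fit_table
        else:
            n_hidden = cfg.hidden
        fitted = train_ann(train, validation, feats, n_hidden, ann_cfg)
        entry["ann"] = fitted
        entry["ann_report"] = evaluate_model(
            fitted, splits, p_terms=1, metadata={"config": name, "method": "ann"}
        )
        models[name] = entry

        t3_rows.append(
            {
                "configuration": name,
                "linear_adjusted_r2": entry["linear_report"].splits["testing"]["adjusted_r2"],
                "polynomial_adjusted_r2": entry["polynomial_report"].splits["testing"]["adjusted_r2"],
                "ann_adjusted_r2": entry["ann_report"].splits["testing"]["adjusted_r2"],
                "selected_terms_linear": ",".join(f"T{l}" for l, _ in lin.terms),
                "ann_features": ",".join(feats),
            }
        )
        rep = entry["ann_report"].splits
        t4_rows.append(
            {
                "configuration": name,
                "architecture": f"[{len(feats)}-{n_hidden}-1]",
                "training_absolute_error": rep["training"]["absolute_error"],
                "validation_absolute_error": rep["validation"]["absolute_error"],
                "testing_absolute_error": rep["testing"]["absolute_error"],
                "training_accuracy": rep["training"]["minmax_accuracy_percent"],
                "validation_accuracy": rep["validation"]["minmax_accuracy_percent"],
                "testing_accuracy": rep["testing"]["minmax_accuracy_percent"],
            }
        )
    return models, pd.DataFrame(t3_rows), pd.DataFrame(t4_rows)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage into ``out_dir``; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        layout = default_layout()
        layout.write_blocks_geojson(out / "blocks.geojson")
        cdates = census_dates(cfg.start_date, cfg.cycles_per_year, cfg.years)
        first_needed = cdates[0] - datetime.timedelta(days=7 * 6 + cfg.window_days)
        days = pd.date_range(first_needed, cdates[-1], freq="D").date.tolist()
        scenes = simulate_scenes(
            layout, days, cfg.weather, cfg.pw_variant, derive_seed(cfg.seed, "weather")
        )
        if cfg.write_scenes:
            sdir = out / "scenes"
            sdir.mkdir(exist_ok=True)
            for sc in scenes:
                write_scene(sc, sdir / f"scene_{sc.timestamp.isoformat()}.tif")

        stage = "derive-rh"
        rh_rasters = [
            derive_rh(sc, variant=cfg.pw_variant, clamp=cfg.clamp) for sc in scenes
        ]
        (out / "rh").mkdir(exist_ok=True)
        rh_rasters[0].write(out / "rh" / f"rh_{rh_rasters[0].timestamp.isoformat()}.tif")

        stage = "resample"
        fine = [resample_nearest(r, cfg.target_pixel_m) for r in rh_rasters]

        stage = "extract"
        series = build_block_series(fine, layout)
        block_tbl = pd.concat(
            [s.frame.assign(block_id=s.block_id) for s in series], ignore_index=True
        )[["date", "block_id", "rh"]]
        block_tbl.to_csv(out / "block_rh.csv", index=False)

        stage = "census"
        response = dataclasses.replace(
            cfg.response, seed=derive_seed(cfg.seed, "census")
        )
        census = generate_census(
            layout, block_tbl, response,
            cycles_per_year=cfg.cycles_per_year, years=cfg.years,
            start_date=cfg.start_date, window_days=cfg.window_days,
        )
        write_census_csv(census, out / "census.csv")

        stage = "build-dataset"
        ds = assemble_lagged(series, census, window_days=cfg.window_days)
        ds = clean_dataset(ds, cfg.cleaning_rule)
        ds.write(out / "dataset.csv")
        log.info("dataset: %d rows, %d dropped", len(ds.frame), len(ds.cleaning_log))

        stage = "correlation"
        from .regression import pearson_by_cycle

        pearson_by_cycle(ds).write(out / "table1_correlations.csv")

        stage = "fit"
        models, table3, table4 = fit_all_models(ds, cfg)
        mdir = out / "models"
        mdir.mkdir(exist_ok=True)
        reports = {}
        for name, entry in models.items():
            safe = name.replace(",", "_").lower()
            (mdir / f"regression_linear_{safe}.json").write_text(entry["linear"].to_json())
            (mdir / f"regression_polynomial_{safe}.json").write_text(
                entry["polynomial"].to_json()
            )
            (mdir / f"ann_{safe}.json").write_text(entry["ann"].network.to_json())
            entry["ann"].history.to_csv(mdir / f"ann_{safe}_history.csv", index=False)
            reports[name] = {
                "linear": json.loads(entry["linear_report"].to_json()),
                "polynomial": json.loads(entry["polynomial_report"].to_json()),
                "ann": json.loads(entry["ann_report"].to_json()),
            }

        stage = "evaluate"
        table3.to_csv(out / "table3_adjusted_r2.csv", index=False)
        table4.to_csv(out / "table4_ann_errors.csv", index=False)
        (out / "reports.json").write_text(json.dumps(reports, sort_keys=True, indent=2))

        manifest = {
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "version": __version__,
            "n_scenes": len(scenes),
            "n_census_records": len(census),
            "n_dataset_rows": int(len(ds.frame)),
            "n_dropped_rows": len(ds.cleaning_log),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=2, default=str)
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
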