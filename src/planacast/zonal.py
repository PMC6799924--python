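"""Zonal extraction and lagged-dataset assembly.

RH rasters are resampled (nearest neighbour, 1 km -> 250 m by default),
reduced to per-block means weighted by the exact pixel/polygon
intersection area, and joined to the biweekly census as six lagged
predictors: rh_Tk is the mean RH over a short window ending exactly
7*k days before the census date, k = 1..6.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

from .raster import Raster
from .synthetic import CensusRecord, EstateLayout, LAG_INDICES, _lag_window

log = logging.getLogger(__name__)

LAG_COLUMNS = tuple(f"rh_T{k}" for k in LAG_INDICES)
COUNT_COLUMN = "mean_count_per_palm"


def resample_nearest(raster: Raster, target_pixel_m: float) -> Raster:
    """Nearest-neighbour resampling to a new pixel size over the same extent.

    Every output pixel takes the value of the source pixel whose centre is
    nearest its own centre, so no new values are introduced.
    """
    if target_pixel_m <= 0:
        raise ValueError("target pixel size must be positive")
    ny, nx = raster.shape
    width_m = nx * raster.pixel_size
    height_m = ny * raster.pixel_size
    nx_out = max(1, round(width_m / target_pixel_m))
    ny_out = max(1, round(height_m / target_pixel_m))
    xc = (np.arange(nx_out) + 0.5) * target_pixel_m
    yc = (np.arange(ny_out) + 0.5) * target_pixel_m
    cols = np.clip(np.floor(xc / raster.pixel_size).astype(int), 0, nx - 1)
    rows = np.clip(np.floor(yc / raster.pixel_size).astype(int), 0, ny - 1)
    return replace(
        raster,
        data=raster.data[np.ix_(rows, cols)],
        pixel_size=target_pixel_m,
        meta={**raster.meta, "resampled_from_m": raster.pixel_size},
    )


def pixel_block_weights(
    raster: Raster, block: BaseGeometry
) -> list[tuple[int, int, float]]:
    """(row, col, intersection_area_m2) for pixels overlapping the block.

    Areas come from exact polygon intersection, not centre-in-polygon
    tests, so partially covered edge pixels contribute proportionally.
    """
    minx, miny, maxx, maxy = block.bounds
    ny, nx = raster.shape
    c0 = max(0, int(np.floor((minx - raster.origin_x) / raster.pixel_size)))
    c1 = min(nx - 1, int(np.floor((maxx - raster.origin_x) / raster.pixel_size)))
    r0 = max(0, int(np.floor((raster.origin_y - maxy) / raster.pixel_size)))
    r1 = min(ny - 1, int(np.floor((raster.origin_y - miny) / raster.pixel_size)))
    prepared = prep(block)
    weights: list[tuple[int, int, float]] = []
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            cell = raster.pixel_polygon(r, c)
            if not prepared.intersects(cell):
                continue
            area = block.intersection(cell).area
            if area > 0:
                weights.append((r, c, area))
    return weights


def area_weighted_mean(
    raster: Raster,
    block: BaseGeometry,
    min_coverage: float = 0.5,
    weights: list[tuple[int, int, float]] | None = None,
    block_name: str = "<block>",
) -> float:
    """Area-weighted mean of raster values over a block polygon.

    NaN pixels are excluded from both numerator and denominator; NaN is
    returned (with a log entry) when less than ``min_coverage`` of the
    block area has valid pixels. Raises if the block misses the raster.
    """
    if weights is None:
        weights = pixel_block_weights(raster, block)
    if not weights:
        raise ValueError(f"block {block_name} does not intersect the raster extent")
    total_area = sum(a for _, _, a in weights)
    num = den = 0.0
    for r, c, a in weights:
        v = raster.data[r, c]
        if np.isfinite(v):
            num += a * v
            den += a
    if den == 0 or den / total_area < min_coverage:
        log.warning(
            "area_weighted_mean: block %s valid coverage %.0f%% below %.0f%% -> NaN",
            block_name, 100 * den / total_area, 100 * min_coverage,
        )
        return float("nan")
    return num / den


@dataclass
class BlockRHSeries:
    """Dated area-weighted RH means for one block."""

    block_id: str
    frame: pd.DataFrame  # columns: date (datetime.date), rh
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        dates = list(self.frame["date"])
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"dates not strictly increasing for block {self.block_id}")


def build_block_series(
    rasters: list[Raster],
    layout: EstateLayout,
    min_coverage: float = 0.5,
) -> list[BlockRHSeries]:
    """One dated RH series per block from a stack of RH rasters.

    All rasters must share the layout grid's CRS and one geotransform;
    pixel/block intersection weights are computed once and reused.
    Duplicate raster dates are rejected.
    """
    if not rasters:
        raise ValueError("no rasters supplied")
    first = rasters[0]
    for r in rasters[1:]:
        if not first.same_grid(r):
            raise ValueError("rasters disagree in grid definition")
    if first.crs != layout.crs:
        raise ValueError(f"raster CRS {first.crs} != layout CRS {layout.crs}")
    dates = [r.timestamp for r in rasters]
    if any(d is None for d in dates):
        raise ValueError("every raster needs a timestamp")
    if len(set(dates)) != len(dates):
        raise ValueError("duplicate raster dates")
    order = np.argsort(dates)
    weights = {b.block_id: pixel_block_weights(first, b.polygon) for b in layout.blocks}
    out = []
    for block in layout.blocks:
        rows = []
        for i in order:
            rast = rasters[i]
            rows.append(
                {
                    "date": rast.timestamp,
                    "rh": area_weighted_mean(
                        rast, block.polygon, min_coverage,
                        weights=weights[block.block_id], block_name=block.block_id,
                    ),
                }
            )
        out.append(
            BlockRHSeries(
                block_id=block.block_id,
                frame=pd.DataFrame(rows),
                provenance=[str(rasters[i].timestamp) for i in order],
            )
        )
    return out


def block_series_from_table(table: pd.DataFrame) -> list[BlockRHSeries]:
    """Adapt a (date, block_id, rh) table to BlockRHSeries objects."""
    tbl = table.copy()
    tbl["date"] = pd.to_datetime(tbl["date"]).dt.date
    return [
        BlockRHSeries(block_id=bid, frame=grp.sort_values("date")[["date", "rh"]])
        for bid, grp in tbl.groupby("block_id")
    ]


@dataclass
class LaggedDataset:
    """Census counts paired with the six lagged RH predictors.

    ``frame`` columns: block_id, cycle_index, census_date,
    mean_count_per_palm, rh_T1..rh_T6. ``cleaning_log`` records every
    dropped row and why.
    """

    frame: pd.DataFrame
    lag_days: tuple[int, ...] = tuple(7 * k for k in LAG_INDICES)
    window_days: int = 8
    cleaning_log: list[dict] = field(default_factory=list)

    def write(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        out = self.frame.copy()
        out["census_date"] = [d.isoformat() for d in out["census_date"]]
        out.to_csv(csv_path, index=False)
        sidecar = {
            "lag_days": list(self.lag_days),
            "window_days": self.window_days,
            "cleaning_log": self.cleaning_log,
        }
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def assemble_lagged(
    series: list[BlockRHSeries],
    census: list[CensusRecord],
    window_days: int = 8,
) -> LaggedDataset:
    """Join census counts to lagged RH window means.

    rh_Tk is the mean of the RH values available in the ``window_days``
    window ending exactly 7*k days before the census date. Rows with any
    lag window empty or NaN are dropped and logged.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    if not census:
        raise ValueError("empty census")
    by_block = {
        s.block_id: s.frame.set_index("date")["rh"].sort_index() for s in series
    }
    missing = {r.block_id for r in census} - set(by_block)
    if missing:
        raise ValueError(f"no RH series for census blocks: {sorted(missing)}")
    rows, dropped = [], []
    for rec in census:
        srs = by_block[rec.block_id]
        row = {
            "block_id": rec.block_id,
            "cycle_index": rec.cycle_index,
            "census_date": rec.census_date,
            COUNT_COLUMN: rec.mean_count_per_palm,
        }
        ok = True
        for k in LAG_INDICES:
            start, end = _lag_window(rec.census_date, k, window_days)
            vals = srs.loc[start:end].dropna()
            if vals.empty:
                dropped.append(
                    {
                        "block_id": rec.block_id,
                        "census_date": str(rec.census_date),
                        "reason": f"no RH in T{k} window {start}..{end}",
                    }
                )
                ok = False
                break
            row[f"rh_T{k}"] = float(vals.mean())
        if ok:
            rows.append(row)
    frame = pd.DataFrame(
        rows,
        columns=["block_id", "cycle_index", "census_date", COUNT_COLUMN, *LAG_COLUMNS],
    )
    return LaggedDataset(frame=frame, window_days=window_days, cleaning_log=dropped)


def clean_dataset(ds: LaggedDataset, outlier_rule: str = "zscore3") -> LaggedDataset:
    """Drop missing-value rows and count-column outliers.

    Rules: ``none`` (missing values only), ``zscore3`` (|z| > 3 on the
    count), ``iqr1.5`` (outside 1.5 interquartile ranges of the count
    quartiles).
    """
    if outlier_rule not in ("none", "zscore3", "iqr1.5"):
        raise ValueError(f"unknown outlier rule {outlier_rule!r}")
    frame = ds.frame
    log_entries = list(ds.cleaning_log)
    used = [COUNT_COLUMN, *LAG_COLUMNS]
    has_na = frame[used].isna().any(axis=1)
    keep = ~has_na
    counts = frame[COUNT_COLUMN]
    if outlier_rule == "zscore3":
        sd = counts[keep].std(ddof=1)
        if sd > 0:
            z = (counts - counts[keep].mean()) / sd
            keep &= z.abs() <= 3
    elif outlier_rule == "iqr1.5":
        q1, q3 = counts[~has_na].quantile([0.25, 0.75])
        iqr = q3 - q1
        keep &= (counts >= q1 - 1.5 * iqr) & (counts <= q3 + 1.5 * iqr)
    for idx in frame.index[~keep]:
        reason = "missing value" if has_na[idx] else f"outlier ({outlier_rule})"
        log_entries.append(
            {
                "block_id": frame.at[idx, "block_id"],
                "census_date": str(frame.at[idx, "census_date"]),
                "reason": reason,
            }
        )
    return LaggedDataset(
        frame=frame[keep].reset_index(drop=True),
        lag_days=ds.lag_days,
        window_days=ds.window_days,
        cleaning_log=log_entries,
    )
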