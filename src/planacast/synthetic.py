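"""Synthetic estate, imagery and census generators.

Everything the pipeline consumes can be simulated here with known ground
truth: a 2000-ha estate of 26 management blocks in two divisions
(10 + 16), NIR scenes constructed by *inverting* the RH retrieval chain
(so the forward derivation recovers a chosen precipitable-water field
exactly), a plausible tropical block-level RH weather series, and a
biweekly larval census whose counts respond — through a configurable
nonlinear function and lag weighting — to the RH the blocks experienced
one to six weeks earlier.
"""

from __future__ import annotations

import datetime
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from . import rh as rhmod
from .raster import DEFAULT_CRS, Raster, write_geojson
from .rh import PW_VALID_MAX, Scene

log = logging.getLogger(__name__)

LAG_INDICES = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class Block:
    block_id: str
    division: str
    polygon: BaseGeometry

    @property
    def area_ha(self) -> float:
        return self.polygon.area / 1e4


@dataclass(frozen=True)
class EstateLayout:
    """Block polygons plus the raster grid definition that covers them."""

    blocks: tuple[Block, ...]
    origin_x: float
    origin_y: float
    pixel_size: float
    n_rows: int
    n_cols: int
    crs: str = DEFAULT_CRS

    @property
    def block_ids(self) -> list[str]:
        return [b.block_id for b in self.blocks]

    def empty_raster(self, fill: float = 0.0) -> Raster:
        return Raster(
            data=np.full((self.n_rows, self.n_cols), fill, dtype=float),
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            pixel_size=self.pixel_size,
            crs=self.crs,
        )

    def write_blocks_geojson(self, path) -> None:
        write_geojson(
            [
                (b.polygon, {"block_id": b.block_id, "division": b.division,
                             "area_ha": round(b.area_ha, 4)})
                for b in self.blocks
            ],
            path,
        )


def default_layout(
    n_division_a: int = 10,
    n_division_b: int = 16,
    estate_width_m: float = 5000.0,
    estate_height_m: float = 4000.0,
    pixel_size_m: float = 1000.0,
    margin_m: float = 500.0,
) -> EstateLayout:
    """A 2000-ha rectangular estate split into 26 rectangular blocks.

    Blocks are laid out row-major on a 2 x 13 grid; the first ten are
    division A, the remainder division B. The raster grid covers the
    estate with a margin so block polygons sit strictly inside it.
    """
    n_blocks = n_division_a + n_division_b
    n_rows_blk = 2
    n_cols_blk = math.ceil(n_blocks / n_rows_blk)
    bw = estate_width_m / n_cols_blk
    bh = estate_height_m / n_rows_blk
    blocks: list[Block] = []
    k = 0
    for r in range(n_rows_blk):
        for c in range(n_cols_blk):
            if k >= n_blocks:
                break
            division = "A" if k < n_division_a else "B"
            idx = k + 1 if division == "A" else k + 1 - n_division_a
            x0, y1 = c * bw, estate_height_m - r * bh
            blocks.append(
                Block(
                    block_id=f"{division}{idx:02d}",
                    division=division,
                    polygon=box(x0, y1 - bh, x0 + bw, y1),
                )
            )
            k += 1
    n_cols = math.ceil((estate_width_m + 2 * margin_m) / pixel_size_m)
    n_rows = math.ceil((estate_height_m + 2 * margin_m) / pixel_size_m)
    return EstateLayout(
        blocks=tuple(blocks),
        origin_x=-margin_m,
        origin_y=estate_height_m + margin_m,
        pixel_size=pixel_size_m,
        n_rows=n_rows,
        n_cols=n_cols,
    )


# ---------------------------------------------------------------------------
# Scene generation by inversion of the RH chain
# ---------------------------------------------------------------------------

def _invert_tobs(pw: np.ndarray, alpha: float, beta: float, variant: str) -> np.ndarray:
    """Transmittance whose forward PW retrieval returns ``pw`` exactly.

    Of the two algebraic roots, the branch giving a positive and (for the
    log form) sub-unity transmittance is taken.
    """
    root = np.sqrt(pw)
    if variant == "as_printed_grouped":
        return alpha + beta * root
    if variant == "as_printed_literal":
        return beta * (alpha + root)
    if variant == "log_form":
        return np.exp(alpha - beta * root)
    raise ValueError(f"unknown PW variant {variant!r}")


def generate_scene(
    layout: EstateLayout,
    true_pw: np.ndarray,
    true_ta_celsius: np.ndarray,
    elevation_m: np.ndarray,
    pw_variant: str = "as_printed_grouped",
    seed: int = 0,
    window_reflectance: tuple[float, float] = (0.30, 0.25),
    timestamp: datetime.date | None = None,
) -> Scene:
    """Build NIR reflectance grids that retrieve ``true_pw`` exactly.

    The two window bands (0.865 and 1.24 um) are set to configurable base
    reflectances with a seeded +/-10% spatial jitter (so scenes are not
    trivially constant); each absorption-band reflectance is then solved
    from the transmittance that the forward chain must observe. Because
    the absorption band is expressed relative to the *same* window-band
    grid, the round trip is exact regardless of the jitter.
    """
    true_pw = np.asarray(true_pw, dtype=float)
    true_ta_celsius = np.asarray(true_ta_celsius, dtype=float)
    elevation_m = np.asarray(elevation_m, dtype=float)
    if not (true_pw.shape == true_ta_celsius.shape == elevation_m.shape):
        raise ValueError("true_pw, true_ta_celsius and elevation_m must share a shape")
    if np.nanmin(true_pw) < 0 or np.nanmax(true_pw) > PW_VALID_MAX:
        raise ValueError(f"true_pw must lie within [0, {PW_VALID_MAX}] cm")
    if np.nanmin(true_ta_celsius) < -10 or np.nanmax(true_ta_celsius) > 50:
        raise ValueError("true_ta_celsius outside plausible range [-10, 50] C")

    rng = np.random.default_rng(seed)
    jitter = lambda base: base * rng.uniform(0.9, 1.1, size=true_pw.shape)  # noqa: E731
    rho_865 = jitter(window_reflectance[0])
    rho_1240 = jitter(window_reflectance[1])

    coeffs = rhmod.DEFAULT_COEFFS
    t17 = _invert_tobs(true_pw, coeffs.alpha[17], coeffs.beta[17], pw_variant)
    t18 = _invert_tobs(true_pw, coeffs.alpha[18], coeffs.beta[18], pw_variant)
    t19 = _invert_tobs(true_pw, coeffs.alpha[19], coeffs.beta[19], pw_variant)
    return Scene(
        rho_865=rho_865,
        rho_1240=rho_1240,
        rho_905=t17 * rho_865,
        rho_936=t18 * rho_865,
        rho_940=t19 * (coeffs.c1 * rho_865 + coeffs.c2 * rho_1240),
        ta_celsius=true_ta_celsius,
        elevation_m=elevation_m,
        origin_x=layout.origin_x,
        origin_y=layout.origin_y,
        pixel_size=layout.pixel_size,
        timestamp=timestamp,
    )


def true_rh(true_pw, true_ta_celsius, elevation_m, clamp: bool = True) -> np.ndarray:
    """Ground-truth RH field implied by a generated scene's inputs."""
    return rhmod.rh_scalar_chain(true_pw, true_ta_celsius, elevation_m, clamp=clamp)


# ---------------------------------------------------------------------------
# Weather fields and block-level RH series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeatherSpec:
    """Tropical-lowland weather emulation for the estate.

    Defaults target the humid Malaysian setting the pipeline was designed
    for: block-mean RH mostly inside 47-71%, Ta 24-35 C, with a weak
    annual cycle, day-to-day autocorrelated weather shared across the
    estate, and small persistent block-to-block offsets.
    """

    rh_base: float = 59.0
    rh_seasonal_amp: float = 4.0
    rh_daily_sd: float = 5.0
    rh_ar: float = 0.6
    rh_block_sd: float = 2.0
    rh_block_daily_sd: float = 1.5
    rh_lo: float = 47.0
    rh_hi: float = 71.0
    ta_base: float = 29.0
    ta_amp: float = 3.0
    ta_daily_sd: float = 1.0


def generate_block_rh(
    layout: EstateLayout,
    start_date: datetime.date,
    end_date: datetime.date,
    seed: int = 0,
    weather: WeatherSpec = WeatherSpec(),
) -> pd.DataFrame:
    """Daily block-mean RH table with columns (date, block_id, rh).

    RH is an AR(1) estate-wide weather signal plus an annual harmonic,
    a fixed block offset and independent daily block noise, clipped to
    the spec's plausible range.
    """
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start_date, end_date, freq="D")
    n_days, n_blocks = len(dates), len(layout.blocks)
    shared = np.empty(n_days)
    innov = rng.normal(0.0, weather.rh_daily_sd, n_days)
    shared[0] = innov[0]
    for t in range(1, n_days):
        shared[t] = weather.rh_ar * shared[t - 1] + math.sqrt(
            1 - weather.rh_ar**2
        ) * innov[t]
    doy = dates.dayofyear.to_numpy()
    seasonal = weather.rh_seasonal_amp * np.sin(2 * np.pi * doy / 365.25)
    offsets = rng.normal(0.0, weather.rh_block_sd, n_blocks)
    block_noise = rng.normal(0.0, weather.rh_block_daily_sd, (n_days, n_blocks))
    rhvals = (
        weather.rh_base
        + seasonal[:, None]
        + shared[:, None]
        + offsets[None, :]
        + block_noise
    )
    rhvals = np.clip(rhvals, weather.rh_lo, weather.rh_hi)
    frame = pd.DataFrame(
        {
            "date": np.repeat(dates.date, n_blocks),
            "block_id": np.tile(layout.block_ids, n_days),
            "rh": rhvals.ravel(),
        }
    )
    return frame


def pw_for_target_rh(
    rh_percent: np.ndarray,
    ta_celsius: np.ndarray,
    elevation_m: np.ndarray,
    clip: bool = False,
) -> np.ndarray:
    """Invert the chain's tail: PW that yields a requested RH.

    Solves the quadratic Q(PW) for the specific humidity implied by the
    target RH, Ta and elevation; used to build scenes whose *derived*
    RH matches a prescribed weather field.

    The Q(PW) quadratic has a positive offset (Q(0) = 0.0124 kg/kg), so
    the retrieval chain cannot produce arbitrarily dry air: at warm
    temperatures RH below roughly 50-60% is out of reach. With
    ``clip=True`` the implied specific humidity is clipped into the
    reachable band (the derived RH then saturates at the attainable
    bound); otherwise out-of-domain targets raise.
    """
    rh_percent = np.asarray(rh_percent, dtype=float)
    es_hpa = rhmod.saturation_vapour_pressure(ta_celsius) / 100.0
    e = rh_percent / 100.0 * es_hpa
    pa = rhmod.air_pressure(elevation_m)
    q = 0.622 * e / pa
    a, b = -0.0762, 1.753
    q_lo = 0.001 * 12.405
    q_hi = 0.001 * (a * PW_VALID_MAX**2 + b * PW_VALID_MAX + 12.405)
    if clip:
        q = np.clip(q, q_lo, q_hi)
    # 0.001*(-0.0762 PW^2 + 1.753 PW + 12.405) = q; with q in the
    # reachable band the (-b + sqrt)/(2a) root lies in [0, PW_VALID_MAX]
    c = 12.405 - 1000.0 * q
    disc = b**2 - 4 * a * c
    if np.nanmin(disc) < 0:
        raise ValueError("target RH unreachable for the given Ta/elevation")
    pw = (-b + np.sqrt(disc)) / (2 * a)
    pw = np.clip(pw, 0.0, PW_VALID_MAX) if clip else pw
    if np.nanmin(pw) < 0 or np.nanmax(pw) > PW_VALID_MAX:
        raise ValueError("target RH requires PW outside the valid domain")
    return pw


# ---------------------------------------------------------------------------
# Census generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseSpec:
    """How larval counts respond to lag-weighted relative humidity.

    ``lag_weights`` weight the six lagged RH means (T1..T6, weeks before
    the census) into a single exposure z; ``response_shape`` maps z to an
    expected count per palm. The quadratic default is a peaked curve —
    an ecological optimum near mid-range humidity (desiccation below,
    fungal mortality above) — peaking at ``peak_count`` when z equals
    ``optimum_rh`` and reaching zero ``width_rh`` away. Gaussian noise
    of ``noise_sd`` is added and counts are clamped to
    [count_floor, count_cap] (bagworm infestations here are zero to
    mild, at most ~32 larvae per frond).
    """

    lag_weights: tuple[float, ...] = (0.5, 0.3, 0.2, 0.0, 0.0, 0.0)
    response_shape: str = "quadratic"
    noise_sd: float = 1.0
    count_floor: float = 0.0
    count_cap: float = 32.0
    seed: int = 0
    optimum_rh: float = 59.0
    peak_count: float = 12.0
    width_rh: float = 8.0
    linear_intercept: float = 16.0
    linear_slope: float = -0.2
    saturating_midpoint: float = 59.0
    saturating_scale: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lag_weights", tuple(self.lag_weights))
        if len(self.lag_weights) != 6:
            raise ValueError("lag_weights must have six entries (T1..T6)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def response(self, z: np.ndarray) -> np.ndarray:
        """Deterministic expected count for exposure z (before noise/clamp)."""
        z = np.asarray(z, dtype=float)
        if self.response_shape == "linear":
            out = self.linear_intercept + self.linear_slope * z
        elif self.response_shape == "quadratic":
            out = self.peak_count * (1.0 - ((z - self.optimum_rh) / self.width_rh) ** 2)
        elif self.response_shape == "saturating":
            out = self.count_cap / (
                1.0 + np.exp(-(z - self.saturating_midpoint) / self.saturating_scale)
            )
        else:
            raise ValueError(f"unknown response_shape {self.response_shape!r}")
        return np.clip(out, self.count_floor, self.count_cap)


@dataclass(frozen=True)
class CensusRecord:
    block_id: str
    cycle_index: int
    census_date: datetime.date
    mean_count_per_palm: float


def _lag_window(census_date: datetime.date, k: int, window_days: int):
    """Dates of the averaging window ending exactly 7k days before census."""
    end = census_date - datetime.timedelta(days=7 * k)
    start = end - datetime.timedelta(days=window_days - 1)
    return start, end


def census_dates(
    start_date: datetime.date, cycles_per_year: int = 24, years: int = 2
) -> list[datetime.date]:
    """Biweekly census calendar: fixed 14-day spacing from the epoch."""
    n = cycles_per_year * years
    return [start_date + datetime.timedelta(days=14 * i) for i in range(n)]


def generate_census(
    layout: EstateLayout,
    rh_by_block_and_date: pd.DataFrame,
    spec: ResponseSpec = ResponseSpec(),
    cycles_per_year: int = 24,
    years: int = 2,
    start_date: datetime.date = datetime.date(2014, 3, 1),
    window_days: int = 8,
) -> list[CensusRecord]:
    """Biweekly census records driven by lagged block RH.

    For each block and cycle the six lagged RH means are combined with
    ``spec.lag_weights`` into an exposure z; the count is
    clamp(response(z) + noise). Raises if the RH table does not cover a
    required lag window for any census date.
    """
    if not {"date", "block_id", "rh"} <= set(rh_by_block_and_date.columns):
        raise ValueError("rh table needs columns date, block_id, rh")
    rng = np.random.default_rng(spec.seed)
    tbl = rh_by_block_and_date.copy()
    tbl["date"] = pd.to_datetime(tbl["date"]).dt.date
    by_block = {
        bid: grp.set_index("date")["rh"].sort_index()
        for bid, grp in tbl.groupby("block_id")
    }
    records: list[CensusRecord] = []
    for ci, cdate in enumerate(census_dates(start_date, cycles_per_year, years)):
        for block in layout.blocks:
            series = by_block.get(block.block_id)
            if series is None:
                raise ValueError(f"no RH series for block {block.block_id}")
            z = 0.0
            for k, w in zip(LAG_INDICES, spec.lag_weights):
                start, end = _lag_window(cdate, k, window_days)
                vals = series.loc[start:end].dropna()
                if vals.empty:
                    raise ValueError(
                        f"RH coverage missing for block {block.block_id}, "
                        f"census {cdate}, lag T{k} window {start}..{end}"
                    )
                z += w * float(vals.mean())
            mean = float(spec.response(z))
            noisy = mean + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0)
            count = float(np.clip(noisy, spec.count_floor, spec.count_cap))
            records.append(CensusRecord(block.block_id, ci, cdate, count))
    return records


def census_to_frame(records: list[CensusRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "block_id": [r.block_id for r in records],
            "cycle_index": [r.cycle_index for r in records],
            "census_date": [r.census_date for r in records],
            "mean_count_per_palm": [r.mean_count_per_palm for r in records],
        }
    )


def write_census_csv(records: list[CensusRecord], path) -> None:
    frame = census_to_frame(records)
    frame["census_date"] = [d.isoformat() for d in frame["census_date"]]
    frame.to_csv(path, index=False)


def generate_palm_level_census(
    block_mean: float, n_palms: int = 25, seed: int = 0
) -> np.ndarray:
    """Per-palm integer larval counts whose average tracks the block mean.

    Counts are Poisson with the block mean as intensity — the census
    protocol samples 25 palms per block and reports their average; the
    field data give no palm-level dispersion, so equidispersion is the
    neutral choice.
    """
    if block_mean < 0:
        raise ValueError("block_mean must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.poisson(block_mean, size=n_palms)


def average_palm_counts(counts: np.ndarray) -> float:
    """The census averaging convention: total over palms / number of palms."""
    counts = np.asarray(counts)
    return float(counts.sum() / counts.size)
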