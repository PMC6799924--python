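"""Relative-humidity retrieval from near-infrared channel ratios.

Atmospheric water vapour absorbs strongly at 0.905, 0.936 and 0.940 um
while the neighbouring 0.865 and 1.24 um channels are nearly transparent
("window" bands). The ratio of an absorption-band apparent reflectance to
the window-band reflectance approximates the two-way water-vapour
transmittance of the atmosphere (Tobs). From Tobs each absorption band
yields an estimate of total precipitable water PW (cm); the three are
fused with fixed weights, converted to specific humidity Q by an
empirical quadratic, combined with elevation-derived air pressure into
vapour pressure e, and divided by the temperature-driven saturation
vapour pressure es to give relative humidity RH = 100 * e / es.

The chain, with coefficients calibrated for the Malaysian region:

    Tobs17 = rho*(0.905) / rho*(0.865)
    Tobs18 = rho*(0.936) / rho*(0.865)
    Tobs19 = rho*(0.940) / (C1 * rho*(0.865) + C2 * rho*(1.24))
    PW_b   = ((alpha_b - Tobs_b) / beta_b)^2          (default variant)
    PW     = f1 PW17 + f2 PW18 + f3 PW19
    Q      = 0.001 * (-0.0762 PW^2 + 1.753 PW + 12.405)
    Pa     = 1013.3 - 0.1038 H                        [hPa]
    e      = Q * Pa / 0.622                           [hPa]
    es     = 611 * exp(17.27 Ta / (237.3 + Ta))       [Pa]
    RH     = 100 * e / (es / 100)

Unit note: the es formula is in pascals while Pa (and therefore e) is in
hectopascals; es is divided by 100 before the final ratio so that RH is a
true percentage. The PW-from-Tobs step is published ambiguously; three
algebraic variants are provided (see :func:`precipitable_water`) and the
variant used is recorded in the output metadata.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .raster import Raster

log = logging.getLogger(__name__)

ABSORPTION_BANDS = (17, 18, 19)

#: Supported algebraic forms of the PW-from-transmittance relation.
PW_VARIANTS = ("as_printed_grouped", "as_printed_literal", "log_form")

#: Upper validity bound for PW (cm): the vertex of the Q(PW) quadratic,
#: beyond which Q would decrease with increasing water vapour.
PW_VALID_MAX = 11.5


@dataclass(frozen=True)
class TransmittanceCoefficients:
    """Per-band transmittance-to-PW coefficients and fusion weights."""

    alpha: Mapping[int, float] = field(
        default_factory=lambda: MappingProxyType({17: 0.025, 18: 0.056, 19: 0.120})
    )
    beta: Mapping[int, float] = field(
        default_factory=lambda: MappingProxyType({17: 0.30, 18: 0.60, 19: 0.651})
    )
    c1: float = 0.8
    c2: float = 0.2
    pw_weights: tuple[float, float, float] = (0.36, 0.24, 0.40)

    def __post_init__(self) -> None:
        if abs(sum(self.pw_weights) - 1.0) > 1e-6:
            raise ValueError(
                f"PW fusion weights must sum to 1, got {sum(self.pw_weights)!r}"
            )
        for band in ABSORPTION_BANDS:
            if band not in self.alpha or band not in self.beta:
                raise ValueError(f"missing coefficients for band {band}")


DEFAULT_COEFFS = TransmittanceCoefficients()


@dataclass
class Scene:
    """Co-registered grids of the five NIR reflectances, Ta and elevation.

    Reflectances are apparent reflectances rho* (dimensionless),
    ``ta_celsius`` is surface air temperature in degrees C and
    ``elevation_m`` is terrain height in metres. All grids share one
    shape and geotransform.
    """

    rho_865: np.ndarray
    rho_1240: np.ndarray
    rho_905: np.ndarray
    rho_936: np.ndarray
    rho_940: np.ndarray
    ta_celsius: np.ndarray
    elevation_m: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 1000.0
    timestamp: datetime.date | None = None

    _GRIDS = (
        "rho_865",
        "rho_1240",
        "rho_905",
        "rho_936",
        "rho_940",
        "ta_celsius",
        "elevation_m",
    )

    def __post_init__(self) -> None:
        shapes = set()
        for name in self._GRIDS:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValueError(f"scene grids disagree in shape: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.rho_865.shape


def write_scene(scene: Scene, path) -> None:
    """Write a scene as a 7-band float32 TIFF with JSON georeferencing."""
    import json as _json
    from pathlib import Path as _Path

    import tifffile

    stack = np.stack([getattr(scene, g) for g in Scene._GRIDS]).astype(np.float32)
    desc = {
        "bands": list(Scene._GRIDS),
        "origin_x": scene.origin_x,
        "origin_y": scene.origin_y,
        "pixel_size": scene.pixel_size,
        "timestamp": scene.timestamp.isoformat() if scene.timestamp else None,
    }
    tifffile.imwrite(_Path(path), stack, description=_json.dumps(desc, sort_keys=True))


def read_scene(path) -> Scene:
    import json as _json
    from pathlib import Path as _Path

    import tifffile

    with tifffile.TiffFile(_Path(path)) as tf:
        stack = tf.asarray().astype(float)
        desc = _json.loads(tf.pages[0].description)
    grids = {name: stack[i] for i, name in enumerate(desc["bands"])}
    ts = desc.get("timestamp")
    return Scene(
        **grids,
        origin_x=desc["origin_x"],
        origin_y=desc["origin_y"],
        pixel_size=desc["pixel_size"],
        timestamp=datetime.date.fromisoformat(ts) if ts else None,
    )


def observed_transmittance(
    scene: Scene, coeffs: TransmittanceCoefficients = DEFAULT_COEFFS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Channel-ratio transmittances for the three absorption bands.

    Zero denominators yield NaN at the affected pixels (count logged).
    """
    den19 = coeffs.c1 * scene.rho_865 + coeffs.c2 * scene.rho_1240
    with np.errstate(divide="ignore", invalid="ignore"):
        t17 = np.where(scene.rho_865 != 0, scene.rho_905 / scene.rho_865, np.nan)
        t18 = np.where(scene.rho_865 != 0, scene.rho_936 / scene.rho_865, np.nan)
        t19 = np.where(den19 != 0, scene.rho_940 / den19, np.nan)
    n_bad = int(np.sum(scene.rho_865 == 0) + np.sum(den19 == 0))
    if n_bad:
        log.warning("observed_transmittance: %d zero-denominator pixels -> NaN", n_bad)
    return t17, t18, t19


def precipitable_water(
    tobs: np.ndarray,
    alpha: float,
    beta: float,
    variant: str = "as_printed_grouped",
) -> np.ndarray:
    """Precipitable water (cm) from one band's observed transmittance.

    Variants:

    - ``as_printed_grouped``: PW = ((alpha - Tobs) / beta)^2  (default)
    - ``as_printed_literal``: PW = (alpha - Tobs / beta)^2
    - ``log_form``:           PW = ((alpha - ln Tobs) / beta)^2
    """
    tobs = np.asarray(tobs, dtype=float)
    if variant == "as_printed_grouped":
        return ((alpha - tobs) / beta) ** 2
    if variant == "as_printed_literal":
        return (alpha - tobs / beta) ** 2
    if variant == "log_form":
        bad = tobs <= 0
        n_bad = int(np.sum(bad & np.isfinite(tobs)))
        if n_bad:
            log.warning("precipitable_water: %d non-positive Tobs under log_form", n_bad)
        with np.errstate(divide="ignore", invalid="ignore"):
            pw = ((alpha - np.log(np.where(bad, np.nan, tobs))) / beta) ** 2
        return pw
    raise ValueError(f"unknown PW variant {variant!r}; expected one of {PW_VARIANTS}")


def fuse_pw(
    pw17: np.ndarray,
    pw18: np.ndarray,
    pw19: np.ndarray,
    coeffs: TransmittanceCoefficients = DEFAULT_COEFFS,
) -> np.ndarray:
    """Weighted fusion of the three per-band PW estimates."""
    f1, f2, f3 = coeffs.pw_weights
    if abs(f1 + f2 + f3 - 1.0) > 1e-6:
        raise ValueError("PW fusion weights must sum to 1")
    return f1 * np.asarray(pw17) + f2 * np.asarray(pw18) + f3 * np.asarray(pw19)


def specific_humidity(pw: np.ndarray, pw_valid_max: float = PW_VALID_MAX) -> np.ndarray:
    """Specific humidity Q (kg/kg) from PW (cm) via the empirical quadratic.

    PW outside [0, ``pw_valid_max``] is mapped to NaN: past the
    quadratic's vertex Q would no longer increase with water vapour.
    """
    pw = np.asarray(pw, dtype=float)
    out_of_range = (pw < 0) | (pw > pw_valid_max)
    n_bad = int(np.sum(out_of_range & np.isfinite(pw)))
    if n_bad:
        log.warning("specific_humidity: %d pixels with PW outside [0, %g] -> NaN",
                    n_bad, pw_valid_max)
    pw = np.where(out_of_range, np.nan, pw)
    return 0.001 * (-0.0762 * pw**2 + 1.753 * pw + 12.405)


def air_pressure(elevation_m: np.ndarray, elevation_floor: float = 0.0) -> np.ndarray:
    """Air pressure Pa (hPa) from elevation H (m): Pa = 1013.3 - 0.1038 H."""
    h = np.maximum(np.asarray(elevation_m, dtype=float), elevation_floor)
    return 1013.3 - 0.1038 * h


def vapour_pressure(q: np.ndarray, pa: np.ndarray) -> np.ndarray:
    """Vapour pressure e = Q * Pa / 0.622, in the unit of ``pa``."""
    return np.asarray(q, dtype=float) * np.asarray(pa, dtype=float) / 0.622


def saturation_vapour_pressure(ta_celsius: np.ndarray) -> np.ndarray:
    """Saturation vapour pressure es (Pa): 611 * exp(17.27 Ta / (237.3 + Ta))."""
    ta = np.asarray(ta_celsius, dtype=float)
    denom = 237.3 + ta
    with np.errstate(divide="ignore", invalid="ignore"):
        es = 611.0 * np.exp(np.where(denom > 0, 17.27 * ta / denom, np.nan))
    return es


def relative_humidity(
    e: np.ndarray, es: np.ndarray, clamp: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """RH (%) = 100 e / es; returns (rh, raw_rh) with raw values unclamped.

    ``e`` and ``es`` must be in identical units (the full chain converts
    es to hPa before calling this).
    """
    e = np.asarray(e, dtype=float)
    es = np.asarray(es, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(es != 0, 100.0 * e / es, np.nan)
    rh = np.clip(raw, 0.0, 100.0) if clamp else raw
    return rh, raw


def rh_scalar_chain(
    pw: np.ndarray,
    ta_celsius: np.ndarray,
    elevation_m: np.ndarray,
    clamp: bool = True,
) -> np.ndarray:
    """RH from already-known PW, Ta and elevation (the tail of the chain)."""
    q = specific_humidity(pw)
    pa = air_pressure(elevation_m)
    e = vapour_pressure(q, pa)
    es_hpa = saturation_vapour_pressure(ta_celsius) / 100.0
    rh, _ = relative_humidity(e, es_hpa, clamp=clamp)
    return rh


def derive_rh(
    scene: Scene,
    coeffs: TransmittanceCoefficients = DEFAULT_COEFFS,
    variant: str = "as_printed_grouped",
    clamp: bool = True,
    keep_intermediates: bool = False,
) -> Raster:
    """Full RH retrieval on a scene; returns a georeferenced RH raster.

    The result's ``meta`` records the PW variant, the coefficients and the
    clamp setting; with ``keep_intermediates`` the per-stage grids
    (Tobs, per-band and fused PW, Q, Pa, e, es and raw RH) are attached
    under ``meta['intermediates']``.
    """
    if variant not in PW_VARIANTS:
        raise ValueError(f"unknown PW variant {variant!r}")
    stage = "observed_transmittance"
    try:
        t17, t18, t19 = observed_transmittance(scene, coeffs)
        stage = "precipitable_water"
        pw17 = precipitable_water(t17, coeffs.alpha[17], coeffs.beta[17], variant)
        pw18 = precipitable_water(t18, coeffs.alpha[18], coeffs.beta[18], variant)
        pw19 = precipitable_water(t19, coeffs.alpha[19], coeffs.beta[19], variant)
        stage = "fuse_pw"
        pw = fuse_pw(pw17, pw18, pw19, coeffs)
        stage = "specific_humidity"
        q = specific_humidity(pw)
        stage = "air_pressure"
        pa = air_pressure(scene.elevation_m)
        stage = "vapour_pressure"
        e = vapour_pressure(q, pa)
        stage = "saturation_vapour_pressure"
        es_hpa = saturation_vapour_pressure(scene.ta_celsius) / 100.0
        stage = "relative_humidity"
        rh, raw = relative_humidity(e, es_hpa, clamp=clamp)
    except Exception as exc:
        raise RuntimeError(f"RH derivation failed at stage {stage!r}: {exc}") from exc

    meta: dict = {
        "pw_variant": variant,
        "clamp": clamp,
        "coefficients": {
            "alpha": dict(coeffs.alpha),
            "beta": dict(coeffs.beta),
            "c1": coeffs.c1,
            "c2": coeffs.c2,
            "pw_weights": list(coeffs.pw_weights),
        },
    }
    if keep_intermediates:
        meta["intermediates"] = {
            "tobs_17": t17, "tobs_18": t18, "tobs_19": t19,
            "pw_17": pw17, "pw_18": pw18, "pw_19": pw19,
            "pw": pw, "q": q, "pa_hpa": pa, "e_hpa": e,
            "es_hpa": es_hpa, "rh_raw": raw,
        }
    return Raster(
        data=rh,
        origin_x=scene.origin_x,
        origin_y=scene.origin_y,
        pixel_size=scene.pixel_size,
        timestamp=scene.timestamp,
        meta=meta,
    )
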