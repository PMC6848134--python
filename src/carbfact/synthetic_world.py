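"""Seeded synthetic worlds with the structure the factory model assumes.

The generator emulates the gross structure of the real inputs - a zonal
SST gradient whose seasonal amplitude grows poleward (seasons are local
warm/cool composites, so one field pair serves both hemispheres), a
subtropical salinity maximum with a hypersaline marginal gulf, low
background phytoplankton absorption rising toward high latitudes with
upwelling stripes along western continental margins, continental shelves
shallower than 200 m around two idealized continents, and coastal
terrigenous bands (a river-mouth "high" patch, "low" fringes, a polar
"arctic" band). It makes no attempt at ocean dynamics or real coastline
geometry: passing tests show the model machinery is self-consistent on
data with the assumed structure, not that the real ocean obeys it.

Every draw is fixed by ``WorldConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .factory_model import FactoryMap, FactoryParams, default_params, predict
from .grid_io import (
    TERR_ARCTIC,
    TERR_HIGH,
    TERR_LOW,
    TERR_NONE,
    EnvStack,
    Grid,
    MaskSet,
    build_masks,
    reclassify_salinity,
)


@dataclass
class WorldConfig:
    """Knobs of the synthetic world; defaults give a plausible 1.5-degree Earth."""

    nlat: int = 120
    nlon: int = 240
    # zonal SST structure (degC)
    sst_equator: float = 28.0
    sst_pole: float = -2.0
    amp_min: float = 1.5     # seasonal amplitude at the equator
    amp_max: float = 10.0    # seasonal amplitude at the poles
    # salinity province structure (psu)
    sss_base: float = 33.5
    sss_subtropical_bump: float = 3.5
    sss_bump_lat: float = 25.0
    sss_bump_width: float = 15.0
    # productivity (absorption due to phytoplankton, m^-1)
    prod_background: float = 0.012
    prod_polar: float = 0.05
    prod_transition_lat: float = 45.0
    prod_transition_width: float = 8.0
    upwelling_prod: float = 0.08
    upwelling_cooling: float = 3.0
    upwelling_lat: tuple[float, float] = (12.0, 40.0)
    # geography (degrees)
    continents: tuple[tuple[float, float], ...] = ((-60.0, -25.0), (55.0, 95.0))
    continent_lat: tuple[float, float] = (-65.0, 75.0)
    shelf_width: float = 7.5
    shelf_depth_min: float = 15.0
    shelf_depth_max: float = 190.0
    deep_depth: float = 4000.0
    land_depth: float = -500.0
    # hypersaline marginal gulf (biochemical regime)
    gulf_lat: tuple[float, float] = (22.0, 30.0)
    gulf_lon: tuple[float, float] = (95.0, 107.0)
    gulf_depth: float = 30.0
    gulf_sss: float = 39.5
    gulf_sst_boost: float = 10.0
    # terrigenous bands
    river_lat: tuple[float, float] = (-6.0, 6.0)
    low_fringe_lat: float = 30.0   # |lat| in [low_fringe_lat, low_fringe_lat + 20]
    low_fringe_width: float = 3.0
    arctic_lat: float = 72.0
    # noise (1 sd, truncated to physical ranges)
    noise_sst: float = 0.2
    noise_sss: float = 0.1
    noise_prod: float = 0.0015
    seed: int = 0


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_env(
    config: WorldConfig | None = None,
    params_all: Mapping[str, FactoryParams] | None = None,
) -> tuple[EnvStack, MaskSet]:
    """Deterministic environmental stack plus the matching mask set."""
    cfg = config or WorldConfig()
    if cfg.nlat < 2 or cfg.nlon < 2:
        raise ValueError("degenerate grid: need at least 2x2 cells")
    rng = np.random.default_rng(cfg.seed)
    dlat, dlon = 180.0 / cfg.nlat, 360.0 / cfg.nlon
    lat = -90.0 + dlat * (0.5 + np.arange(cfg.nlat))
    lon = -180.0 + dlon * (0.5 + np.arange(cfg.nlon))
    LAT, LON = np.meshgrid(lat, lon, indexing="ij")
    alat = np.abs(LAT)

    # --- geography ---------------------------------------------------------
    in_lat = (LAT >= cfg.continent_lat[0]) & (LAT <= cfg.continent_lat[1])
    land = np.zeros(LAT.shape, dtype=bool)
    shelf_dist = np.full(LAT.shape, np.inf)  # distance (deg lon) to the nearest coast
    west_margin = np.zeros(LAT.shape, dtype=bool)
    east_inner = np.zeros(LAT.shape, dtype=bool)
    for lon_w, lon_e in cfg.continents:
        body = in_lat & (LON >= lon_w) & (LON <= lon_e)
        land |= body
        west = in_lat & (LON < lon_w) & (LON >= lon_w - cfg.shelf_width)
        east = in_lat & (LON > lon_e) & (LON <= lon_e + cfg.shelf_width)
        shelf_dist = np.where(west, np.minimum(shelf_dist, lon_w - LON), shelf_dist)
        shelf_dist = np.where(east, np.minimum(shelf_dist, LON - lon_e), shelf_dist)
        west_margin |= west
        east_inner |= east & (LON <= lon_e + cfg.low_fringe_width)
    shelf = np.isfinite(shelf_dist) & ~land
    depth = np.full(LAT.shape, cfg.deep_depth)
    ramp = np.clip(shelf_dist / cfg.shelf_width, 0.0, 1.0)
    depth[shelf] = (
        cfg.shelf_depth_min + (cfg.shelf_depth_max - cfg.shelf_depth_min) * ramp[shelf]
    )
    depth[land] = cfg.land_depth
    gulf = (
        (LAT >= cfg.gulf_lat[0]) & (LAT <= cfg.gulf_lat[1])
        & (LON >= cfg.gulf_lon[0]) & (LON <= cfg.gulf_lon[1]) & ~land
    )
    depth[gulf] = cfg.gulf_depth

    # --- SST ---------------------------------------------------------------
    mean = cfg.sst_pole + (cfg.sst_equator - cfg.sst_pole) * np.cos(np.radians(LAT)) ** 2
    amp = cfg.amp_min + (cfg.amp_max - cfg.amp_min) * np.sin(np.radians(LAT)) ** 2
    upwelling = (
        west_margin & shelf & (alat >= cfg.upwelling_lat[0]) & (alat <= cfg.upwelling_lat[1])
    )
    cooling = np.where(upwelling, cfg.upwelling_cooling, 0.0)
    sst_summer = mean + amp - cooling + rng.normal(0.0, cfg.noise_sst, LAT.shape)
    sst_winter = mean - amp - cooling + rng.normal(0.0, cfg.noise_sst, LAT.shape)
    sst_summer[gulf] += cfg.gulf_sst_boost
    sst_winter = np.minimum(sst_winter, sst_summer)  # seasons are local warm/cool
    sst_summer = np.clip(sst_summer, -2.0, 38.0)
    sst_winter = np.clip(sst_winter, -2.0, sst_summer)

    # --- SSS ---------------------------------------------------------------
    sss = cfg.sss_base + cfg.sss_subtropical_bump * np.exp(
        -(((alat - cfg.sss_bump_lat) / cfg.sss_bump_width) ** 2)
    )
    sss = sss + rng.normal(0.0, cfg.noise_sss, LAT.shape)
    sss[gulf] = cfg.gulf_sss + rng.normal(0.0, cfg.noise_sss, int(gulf.sum()))
    sss = np.clip(sss, 29.0, 42.0)
    sss_class = reclassify_salinity(sss)

    # --- productivity ------------------------------------------------------
    prod = cfg.prod_background + (cfg.prod_polar - cfg.prod_background) * _logistic(
        (alat - cfg.prod_transition_lat) / cfg.prod_transition_width
    )
    prod_summer = prod + rng.normal(0.0, cfg.noise_prod, LAT.shape)
    prod_winter = prod + rng.normal(0.0, cfg.noise_prod, LAT.shape)
    up_s = cfg.upwelling_prod + rng.normal(0.0, cfg.noise_prod, int(upwelling.sum()))
    up_w = cfg.upwelling_prod + rng.normal(0.0, cfg.noise_prod, int(upwelling.sum()))
    prod_summer[upwelling] = up_s
    prod_winter[upwelling] = up_w
    prod_summer = np.clip(prod_summer, 1e-4, None)
    prod_winter = np.clip(prod_winter, 1e-4, None)

    # --- terrigenous -------------------------------------------------------
    terr = np.full(LAT.shape, TERR_NONE, dtype=np.int16)
    low_band = (alat >= cfg.low_fringe_lat) & (alat <= cfg.low_fringe_lat + 20.0)
    terr[east_inner & low_band & shelf] = TERR_LOW
    for _, lon_e in cfg.continents[:1]:  # river mouth on the first continent's east coast
        river = (
            shelf & (LAT >= cfg.river_lat[0]) & (LAT <= cfg.river_lat[1])
            & (LON > lon_e) & (LON <= lon_e + cfg.shelf_width)
        )
        terr[river] = TERR_HIGH
    terr[alat >= cfg.arctic_lat] = TERR_ARCTIC

    def grid(v):
        return Grid(np.asarray(v, dtype=float) if v.dtype != np.int16 else v, lat, lon)

    env = EnvStack(
        sst_summer=grid(sst_summer),
        sst_winter=grid(sst_winter),
        sss_class_summer=grid(sss_class),
        sss_class_winter=grid(sss_class.copy()),
        prod_summer=grid(prod_summer),
        prod_winter=grid(prod_winter),
        bathymetry=grid(depth),
        terrigenous=Grid(terr, lat, lon),
    )
    env.validate()
    masks = build_masks(env, params_all or default_params())
    return env, masks


def generate_truth(
    env: EnvStack,
    params_all: Mapping[str, FactoryParams] | None = None,
    masks: MaskSet | None = None,
) -> FactoryMap:
    """Truth factory map: the model's own prediction under the truth parameters."""
    return predict(env, params_all or default_params(), masks)[0]


# ---------------------------------------------------------------------------
# perturbation

def perturb_map(fmap: FactoryMap, flip_fraction: float, seed: int = 0) -> FactoryMap:
    """Flip a fraction of the assigned (non-none) cells to "none", seeded."""
    if not 0.0 <= flip_fraction <= 1.0:
        raise ValueError("flip fraction must lie in [0, 1]")
    category = fmap.category.values.copy()
    assigned = np.flatnonzero(category > 0)
    k = int(round(flip_fraction * assigned.size))
    if k:
        rng = np.random.default_rng(seed)
        category[np.unravel_index(rng.choice(assigned, size=k, replace=False), category.shape)] = 0
    return FactoryMap(category=fmap.category.like(category))


def perturb_env(env: EnvStack, noise_sd: float, seed: int = 0) -> EnvStack:
    """Add truncated Gaussian noise to the continuous fields (SST as given,
    productivity at 1/100 scale to respect its units)."""
    if noise_sd == 0.0:
        return env
    rng = np.random.default_rng(seed)

    def noisy(g: Grid, sd: float, lo=None) -> Grid:
        v = g.values + rng.normal(0.0, sd, g.shape)
        if lo is not None:
            v = np.clip(v, lo, None)
        return g.like(v)

    ss = noisy(env.sst_summer, noise_sd)
    sw = noisy(env.sst_winter, noise_sd)
    sw = sw.like(np.minimum(sw.values, ss.values))
    return EnvStack(
        sst_summer=ss,
        sst_winter=sw,
        sss_class_summer=env.sss_class_summer.copy(),
        sss_class_winter=env.sss_class_winter.copy(),
        prod_summer=noisy(env.prod_summer, noise_sd / 100.0, lo=1e-4),
        prod_winter=noisy(env.prod_winter, noise_sd / 100.0, lo=1e-4),
        bathymetry=env.bathymetry.copy(),
        terrigenous=env.terrigenous.copy(),
    )


def perturb(obj, flip_fraction: float | None = None, noise_sd: float | None = None, seed: int = 0):
    """Dispatch: category flips for maps, field noise for environments."""
    if isinstance(obj, FactoryMap):
        return perturb_map(obj, flip_fraction or 0.0, seed)
    if isinstance(obj, EnvStack):
        return perturb_env(obj, noise_sd or 0.0, seed)
    raise TypeError(f"cannot perturb object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# calibration footprints

def sample_with_quantiles(lower, upper, q_lower, q_upper, n, rng) -> np.ndarray:
    """Uniform samples whose (q_lower, q_upper) quantiles equal (lower, upper)
    in expectation - the footprint emulation for calibration recovery."""
    if not (0.0 <= q_lower < q_upper <= 1.0):
        raise ValueError("quantile levels must satisfy 0 <= q_lower < q_upper <= 1")
    span = (upper - lower) / (q_upper - q_lower)
    lo = lower - q_lower * span
    return lo + span * rng.random(n)


def calibration_world(
    n: int = 2500,
    seed: int = 0,
    sst_truth: tuple[float, float, float] = (24.15, 17.65, 30.5),
    prod_truth: tuple[float, float] = (0.02, 0.10),
    factory: str = "photozoan_T",
) -> tuple[EnvStack, FactoryMap, dict]:
    """A single-factory footprint world for end-to-end calibration recovery.

    The footprint covers every cell. Warm-season SST is sampled so its
    1st/99th percentiles sit on the production threshold and the upper
    threshold; the cool season is offset so its 1st percentile sits on
    the persistence threshold. Absorption is sampled so its 5th/95th
    percentiles sit on the two productivity crossings. The returned
    ``truth`` dict holds the generating mid-points and spreads
    (f(threshold) = 1/2 convention) the chain should recover.
    """
    production, persistence, sst_upper = sst_truth
    p_lo, p_hi = prod_truth
    rng = np.random.default_rng(seed)
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    size = nrow * ncol
    lat = 0.5 + np.arange(nrow)
    lon = 0.5 + np.arange(ncol)

    sst_summer = sample_with_quantiles(production, sst_upper, 0.01, 0.99, size, rng)
    sst_winter = sst_summer - (production - persistence)
    prod = sample_with_quantiles(p_lo, p_hi, 0.05, 0.95, size, rng)

    def grid(v):
        return Grid(np.asarray(v, dtype=float).reshape(nrow, ncol), lat, lon)

    env = EnvStack(
        sst_summer=grid(sst_summer),
        sst_winter=grid(sst_winter),
        sss_class_summer=grid(np.full(size, 5.0)),
        sss_class_winter=grid(np.full(size, 5.0)),
        prod_summer=grid(prod),
        prod_winter=grid(prod.copy()),
        bathymetry=grid(np.full(size, 20.0)),
        terrigenous=Grid(np.zeros((nrow, ncol), dtype=np.int16), lat, lon),
    )
    env.validate()
    from .grid_io import FACTORY_CODES

    observed = FactoryMap(
        category=Grid(np.full((nrow, ncol), FACTORY_CODES[factory], dtype=np.int16), lat, lon)
    )
    sst_mp = ((production + persistence) / 2.0 + sst_upper) / 2.0
    prod_mp = (p_lo + p_hi) / 2.0
    truth = {
        "SST": {"form": "gaussian", "mp": sst_mp,
                "s": np.log(2.0) / (sst_upper - sst_mp) ** 2},
        "P": {"form": "near_gaussian", "mp": prod_mp, "s": 1.0 / (p_hi - prod_mp) ** 2},
    }
    return env, observed, truth
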