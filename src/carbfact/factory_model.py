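"""Weighted carbonate-factory susceptibility functions and their combination.

Each factory's susceptibility of occurrence is the weighted overlay

    F = a f(z) + b f(SST) + c f(SSS) + d f(P),        a + b + c + d = 1,

evaluated per grid cell, with the terrigenous/bathymetric constraints
realized as an eligibility mask (equivalent to subtracting a binary
inhibition term and clamping). f(z) is the indicator of the factory's
depth interval, so it contributes its full weight at every eligible cell.
A factory is present where F strictly exceeds its final threshold; the
four presence maps are combined into a single categorical map in which
competing non-background factories are resolved by the largest margin
F - threshold and the heterozoan-C background factory fills cells no
other factory claims, provided seasonal-mean productivity reaches its
floor.

Seasonal handling is per factory and parameter: the warm-season field,
the cool-season field, the seasonal mean, or - for the photo-C SST - the
product of a production function of the warm season and a persistence
function of the cool season, which preserves the seasonality signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .grid_io import FACTORIES, FACTORY_CODES, EnvStack, Grid, MaskSet, build_masks
from .membership import MembershipSpec, evaluate

logger = logging.getLogger("carbfact")

SEASONAL_RULES = ("mean_of_seasons", "warm_season", "cool_season", "product_of_two_specs")

#: non-background factories in fixed tie-break order
_COMPETING = ("biochemical", "photozoan_T", "photo_C")


@dataclass
class FactoryParams:
    """Full parameterization of one carbonate factory function.

    ``sst`` is the single SST membership, or the production function when
    ``sst_rule == "product_of_two_specs"``, in which case
    ``sst_persistence`` holds the cool-season persistence function.
    Weights follow the overlay order: ``weight_z`` (a), ``weight_sst``
    (b), ``weight_sss`` (c), ``weight_prod`` (d).
    """

    name: str
    sst: MembershipSpec
    sss: MembershipSpec
    prod: MembershipSpec
    weight_z: float
    weight_sst: float
    weight_sss: float
    weight_prod: float
    final_threshold: float
    depth_max: float
    sst_rule: str = "mean_of_seasons"
    sss_rule: str = "mean_of_seasons"
    prod_rule: str = "mean_of_seasons"
    sst_persistence: MembershipSpec | None = None
    tolerates_low_terrigenous: bool = False
    background: bool = False
    productivity_floor: float | None = None

    def __post_init__(self) -> None:
        w = self.weights
        if any(x < 0 for x in w):
            raise ValueError(f"{self.name}: weights must be non-negative, got {w}")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: weights must sum to 1, got {sum(w)!r}")
        if not (0.0 < self.final_threshold < 1.0):
            raise ValueError(f"{self.name}: final threshold must lie in (0, 1)")
        for rule in (self.sst_rule, self.sss_rule, self.prod_rule):
            if rule not in SEASONAL_RULES:
                raise ValueError(f"{self.name}: unknown seasonal rule {rule!r}")
        if (self.sst_rule == "product_of_two_specs") != (self.sst_persistence is not None):
            raise ValueError(
                f"{self.name}: the production x persistence rule requires (exactly then) "
                "an sst_persistence spec"
            )

    @property
    def weights(self) -> tuple[float, float, float, float]:
        return (self.weight_z, self.weight_sst, self.weight_sss, self.weight_prod)


@dataclass
class SusceptibilityMap:
    """Per-factory susceptibility grid in [0, 1]; NaN where ineligible."""

    factory: str
    values: Grid


@dataclass
class FactoryMap:
    """Categorical factory assignment, plus optional per-factory presence bits."""

    category: Grid
    presence: dict[str, np.ndarray] | None = field(default=None)

    def presence_layers(self) -> dict[str, np.ndarray]:
        """Binary presence per factory derived from the categorical assignment."""
        return {f: self.category.values == FACTORY_CODES[f] for f in FACTORIES}


# ---------------------------------------------------------------------------
# defaults: the published parameterization

def default_params() -> dict[str, FactoryParams]:
    """The shipped factory parameterization (membership forms, MP/S, weights,
    thresholds), with bathymetry weights set to 1 - (b + c + d)."""
    g, ng, sig, ind = "gaussian", "near_gaussian", "sigmoid_large", "independent"
    return {
        "biochemical": FactoryParams(
            name="biochemical",
            sst=MembershipSpec(sig, 30.5, 58.0),
            sst_rule="warm_season",
            sss=MembershipSpec(ng, 8.0, 3.0),
            sss_rule="cool_season",
            prod=MembershipSpec(ind),
            weight_z=0.10, weight_sst=0.45, weight_sss=0.45, weight_prod=0.0,
            final_threshold=0.6,
            depth_max=100.0,
        ),
        "photozoan_T": FactoryParams(
            name="photozoan_T",
            sst=MembershipSpec(g, 25.7, 0.03),
            sss=MembershipSpec(g, 5.0, 0.043),
            prod=MembershipSpec(g, 0.015, 565.0),
            weight_z=0.03, weight_sst=0.64, weight_sss=0.06, weight_prod=0.27,
            final_threshold=0.7,
            depth_max=100.0,
        ),
        "photo_C": FactoryParams(
            name="photo_C",
            sst=MembershipSpec(g, 25.25, 0.025),
            sst_persistence=MembershipSpec(g, 12.325, 0.0244),
            sst_rule="product_of_two_specs",
            sss=MembershipSpec(g, 7.0, 0.075),
            prod=MembershipSpec(g, 0.0203, 2450.0),
            weight_z=0.04, weight_sst=0.62, weight_sss=0.12, weight_prod=0.22,
            final_threshold=0.5,
            depth_max=200.0,
        ),
        "heterozoan_C": FactoryParams(
            name="heterozoan_C",
            sst=MembershipSpec(ind),
            sss=MembershipSpec(ind),
            prod=MembershipSpec(ng, 0.06, 625.0),
            weight_z=0.10, weight_sst=0.0, weight_sss=0.0, weight_prod=0.9,
            final_threshold=0.5,
            depth_max=200.0,
            tolerates_low_terrigenous=True,
            background=True,
            productivity_floor=0.01,
        ),
    }


# --- config (de)serialization ----------------------------------------------

def _spec_to_dict(spec: MembershipSpec) -> dict:
    d = {"form": spec.form}
    if spec.form != "independent":
        d.update(mp=float(spec.mp), s=float(spec.s))
    return d


def _spec_from_dict(d: Mapping) -> MembershipSpec:
    return MembershipSpec(d["form"], float(d.get("mp", np.nan)), float(d.get("s", np.nan)))


def params_to_dict(params_all: Mapping[str, FactoryParams]) -> dict:
    out = {}
    for name, p in params_all.items():
        block = {
            "sst": _spec_to_dict(p.sst),
            "sss": _spec_to_dict(p.sss),
            "prod": _spec_to_dict(p.prod),
            "rules": {"sst": p.sst_rule, "sss": p.sss_rule, "prod": p.prod_rule},
            "weights": {"z": p.weight_z, "sst": p.weight_sst, "sss": p.weight_sss,
                        "prod": p.weight_prod},
            "final_threshold": p.final_threshold,
            "depth_max": p.depth_max,
            "tolerates_low_terrigenous": p.tolerates_low_terrigenous,
            "background": p.background,
        }
        if p.sst_persistence is not None:
            block["sst_persistence"] = _spec_to_dict(p.sst_persistence)
        if p.productivity_floor is not None:
            block["productivity_floor"] = p.productivity_floor
        out[name] = block
    return out


def params_from_dict(cfg: Mapping) -> dict[str, FactoryParams]:
    out = {}
    for name, b in cfg.items():
        w = b["weights"]
        rules = b.get("rules", {})
        out[name] = FactoryParams(
            name=name,
            sst=_spec_from_dict(b["sst"]),
            sss=_spec_from_dict(b["sss"]),
            prod=_spec_from_dict(b["prod"]),
            sst_persistence=(
                _spec_from_dict(b["sst_persistence"]) if "sst_persistence" in b else None
            ),
            sst_rule=rules.get("sst", "mean_of_seasons"),
            sss_rule=rules.get("sss", "mean_of_seasons"),
            prod_rule=rules.get("prod", "mean_of_seasons"),
            weight_z=float(w["z"]), weight_sst=float(w["sst"]),
            weight_sss=float(w["sss"]), weight_prod=float(w["prod"]),
            final_threshold=float(b["final_threshold"]),
            depth_max=float(b["depth_max"]),
            tolerates_low_terrigenous=bool(b.get("tolerates_low_terrigenous", False)),
            background=bool(b.get("background", False)),
            productivity_floor=b.get("productivity_floor"),
        )
    return out


def save_params(params_all: Mapping[str, FactoryParams], path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(params_all), sort_keys=False))


def load_params(path) -> dict[str, FactoryParams]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    cfg = yaml.safe_load(text)
    return params_from_dict(cfg)


# ---------------------------------------------------------------------------
# model evaluation

_PARAM_PREFIX = {"SST": "sst", "SSS_class": "sss_class", "P": "prod"}


def seasonal_input(env: EnvStack, parameter: str, rule: str) -> Grid:
    """The per-cell field a membership function sees for one parameter.

    Class fields averaged across seasons stay fractional (classes 5 and 6
    average to 5.5); the product rule has no single input field and is
    handled inside :func:`susceptibility`.
    """
    if parameter not in _PARAM_PREFIX:
        raise ValueError(f"unknown parameter {parameter!r}")
    prefix = _PARAM_PREFIX[parameter]
    summer = getattr(env, f"{prefix}_summer")
    winter = getattr(env, f"{prefix}_winter")
    if rule == "mean_of_seasons":
        return summer.like((summer.values + winter.values) / 2.0)
    if rule == "warm_season":
        return summer.copy()
    if rule == "cool_season":
        return winter.copy()
    if rule == "product_of_two_specs":
        raise ValueError("the production x persistence rule is resolved inside susceptibility()")
    raise ValueError(f"unknown seasonal rule {rule!r}")


def _sst_membership(env: EnvStack, params: FactoryParams) -> np.ndarray:
    if params.sst_rule == "product_of_two_specs":
        production = evaluate(params.sst, env.sst_summer.values)
        persistence = evaluate(params.sst_persistence, env.sst_winter.values)
        return production * persistence
    return evaluate(params.sst, seasonal_input(env, "SST", params.sst_rule).values)


def susceptibility(env: EnvStack, params: FactoryParams, masks: MaskSet) -> SusceptibilityMap:
    """Weighted overlay F at every eligible cell; NaN elsewhere.

    Zero-weight terms are skipped so a missing field cannot contaminate a
    factory it does not constrain. Output is clamped to [0, 1] (the terms
    are bounded, so clamping only guards rounding).
    """
    if params.name not in masks.eligible:
        raise ValueError(f"no eligibility mask for factory {params.name!r}")
    eligible = masks.eligible[params.name]
    if eligible.shape != env.shape:
        raise ValueError("masks and environment are not co-registered")
    f = np.full(env.shape, params.weight_z, dtype=float)  # f(z) = 1 on the eligible interval
    if params.weight_sst > 0:
        f += params.weight_sst * _sst_membership(env, params)
    if params.weight_sss > 0:
        f += params.weight_sss * evaluate(
            params.sss, seasonal_input(env, "SSS_class", params.sss_rule).values
        )
    if params.weight_prod > 0:
        f += params.weight_prod * evaluate(
            params.prod, seasonal_input(env, "P", params.prod_rule).values
        )
    f = np.clip(f, 0.0, 1.0)
    f[~eligible] = np.nan
    return SusceptibilityMap(params.name, env.sst_summer.like(f))


def occurrence(susc: SusceptibilityMap, final_threshold: float) -> np.ndarray:
    """Presence where F strictly exceeds the threshold; missing cells are absent."""
    v = susc.values.values
    return np.isfinite(v) & (v > final_threshold)


def combine(
    presences: Mapping[str, np.ndarray],
    suscs: Mapping[str, SusceptibilityMap],
    params_all: Mapping[str, FactoryParams],
    env: EnvStack,
) -> FactoryMap:
    """Resolve the four presence maps into one categorical factory map.

    Competing (non-background) factories are won by the largest margin
    F - final_threshold, ties by the fixed order biochemical >
    photozoan-T > photo-C. The background heterozoan-C factory is
    assigned only where no other factory is present, its own presence bit
    is set, and seasonal-mean productivity reaches its floor.
    """
    missing = [f for f in FACTORIES if f in params_all and f not in presences]
    if missing:
        raise ValueError(f"presence map(s) missing for: {missing}")
    shape = env.shape
    competing = [f for f in _COMPETING if f in params_all]
    margins = np.full((len(competing),) + shape, -np.inf)
    for i, name in enumerate(competing):
        v = suscs[name].values.values
        margin = v - params_all[name].final_threshold
        margins[i] = np.where(presences[name] & np.isfinite(v), margin, -np.inf)
    category = np.zeros(shape, dtype=np.int16)
    if competing:
        winner = np.argmax(margins, axis=0)  # first maximum wins ties
        any_competing = np.any(np.isfinite(margins) & (margins > -np.inf), axis=0)
        for i, name in enumerate(competing):
            category[any_competing & (winner == i)] = FACTORY_CODES[name]
    background = [f for f, p in params_all.items() if p.background]
    for name in background:
        p = params_all[name]
        mean_prod = (env.prod_summer.values + env.prod_winter.values) / 2.0
        cells = (category == 0) & presences[name]
        if p.productivity_floor is not None:
            cells &= np.isfinite(mean_prod) & (mean_prod >= p.productivity_floor)
        category[cells] = FACTORY_CODES[name]
    return FactoryMap(
        category=env.sst_summer.like(category),
        presence={f: np.asarray(presences[f], dtype=bool) for f in params_all},
    )


def predict(
    env: EnvStack,
    params_all: Mapping[str, FactoryParams],
    masks: MaskSet | None = None,
) -> tuple[FactoryMap, dict[str, SusceptibilityMap]]:
    """Full deterministic pipeline: susceptibility -> occurrence -> combine."""
    if masks is None:
        masks = build_masks(env, params_all)
    backgrounds = [f for f, p in params_all.items() if p.background]
    if len(backgrounds) != 1:
        raise ValueError(f"exactly one background factory expected, got {backgrounds}")
    suscs = {name: susceptibility(env, p, masks) for name, p in params_all.items()}
    presences = {
        name: occurrence(suscs[name], params_all[name].final_threshold) for name in params_all
    }
    return combine(presences, suscs, params_all, env), suscs


# ---------------------------------------------------------------------------
# diagnostic: the SST niche structure

def temperature_domains(
    params_all: Mapping[str, FactoryParams],
    sst_summer: np.ndarray,
    sst_winter: np.ndarray,
) -> np.ndarray:
    """Winner factory over a (summer, winter) SST plane, all else optimal.

    Evaluates each competing factory's overlay with every non-SST
    membership at its optimum (value 1), applies the presence thresholds
    and the margin rule. This reproduces the exclusive temperature
    domains of the final map; note that the raw occurrence regions do
    overlap where a hot summer pairs with a mild winter, and it is the
    margin rule that keeps the combined map exclusive.
    """
    ss = np.asarray(sst_summer, dtype=float)
    sw = np.asarray(sst_winter, dtype=float)
    competing = [f for f in _COMPETING if f in params_all]
    margins = np.full((len(competing),) + ss.shape, -np.inf)
    for i, name in enumerate(competing):
        p = params_all[name]
        if p.sst_rule == "product_of_two_specs":
            fsst = evaluate(p.sst, ss) * evaluate(p.sst_persistence, sw)
        elif p.sst_rule == "warm_season":
            fsst = evaluate(p.sst, ss)
        elif p.sst_rule == "cool_season":
            fsst = evaluate(p.sst, sw)
        else:
            fsst = evaluate(p.sst, (ss + sw) / 2.0)
        f = (p.weight_z + p.weight_sss + p.weight_prod) + p.weight_sst * fsst
        margin = f - p.final_threshold
        margins[i] = np.where(margin > 0, margin, -np.inf)
    category = np.zeros(ss.shape, dtype=np.int16)
    winner = np.argmax(margins, axis=0)
    present = np.any(margins > -np.inf, axis=0)
    for i, name in enumerate(competing):
        category[present & (winner == i)] = FACTORY_CODES[name]
    return category
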