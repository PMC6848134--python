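"""Calibration chain: footprint extraction -> percentile summaries -> thresholds
-> mid-points and spreads.

The chain mirrors how the factory functions are parameterized from data:
environmental values are pooled over the cells of each observed factory
footprint per season, summarized by percentiles (whiskers at p1/p99 for
SST and salinity class, p5/p95 for phytoplankton absorption), turned into
production (warm-season) and persistence (cool-season) lower thresholds
plus an upper threshold, and finally inverted into the membership
parameters: MP is the mean of the lower and upper thresholds (two lower
thresholds are first averaged), or the sample mode when only one
threshold exists, and the spread is fixed by requiring f(threshold) = 1/2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .grid_io import FACTORY_CODES, EnvStack

logger = logging.getLogger("carbfact")

PERCENTILES = (1, 5, 25, 50, 75, 95, 99)

#: whisker percentile convention per parameter
WHISKERS = {"SST": (1, 99), "SSS_class": (1, 99), "P": (5, 95)}

_PARAM_FIELDS = {"SST": "sst", "SSS_class": "sss_class", "P": "prod"}


@dataclass
class StatsSummary:
    """Percentile table for one factory / parameter / season."""

    factory: str
    parameter: str
    season: str
    n: int
    mean: float
    p1: float
    p5: float
    p25: float
    p50: float
    p75: float
    p95: float
    p99: float

    @property
    def median(self) -> float:
        return self.p50

    def percentile(self, q: int) -> float:
        return getattr(self, f"p{q}")


@dataclass
class ThresholdPair:
    """Lower (production, persistence) and upper environmental thresholds.

    ``lower`` is a (production, persistence) pair when both seasons
    contribute, else a single value; ``source`` records which percentile
    and season produced each entry.
    """

    lower: tuple[float, float] | float | None
    upper: float | None
    source: dict[str, str]


def extract_values(env: EnvStack, observed, factory: str, parameter: str, season: str) -> np.ndarray:
    """Values of one parameter/season over the observed footprint of a factory.

    ``observed`` is a categorical factory map co-registered with ``env``;
    one value is returned per cell assigned to ``factory`` where the field
    is non-missing.
    """
    if parameter not in _PARAM_FIELDS:
        raise ValueError(f"unknown parameter {parameter!r}")
    if season not in ("summer", "winter"):
        raise ValueError(f"unknown season {season!r}")
    category = observed.category if hasattr(observed, "category") else observed
    if not category.same_lattice(env.sst_summer):
        raise ValueError("observed map and environment are not co-registered")
    code = FACTORY_CODES[factory]
    fp = category.values == code
    if not fp.any():
        logger.warning("factory %s absent from the observed map", factory)
        return np.empty(0)
    vals = getattr(env, f"{_PARAM_FIELDS[parameter]}_{season}").values[fp]
    return vals[np.isfinite(vals)].astype(float)


def summarize(samples, parameter: str, factory: str = "", season: str = "") -> StatsSummary:
    """Percentile summary (linear interpolation between order statistics)."""
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if samples.size == 0:
        raise ValueError(f"no samples to summarize ({factory}/{parameter}/{season})")
    pv = np.percentile(samples, PERCENTILES, method="linear")
    return StatsSummary(
        factory=factory,
        parameter=parameter,
        season=season,
        n=int(samples.size),
        mean=float(samples.mean()),
        **{f"p{q}": float(v) for q, v in zip(PERCENTILES, pv)},
    )


def derive_thresholds(
    summary_summer: StatsSummary, summary_winter: StatsSummary, parameter: str
) -> ThresholdPair:
    """Production/persistence lower thresholds and the upper threshold.

    The production threshold is the warm-season lower whisker, the
    persistence threshold the cool-season lower whisker; the upper
    threshold is the larger of the two seasons' upper whiskers. Whisker
    percentiles follow :data:`WHISKERS` (p1/p99 for SST and salinity
    class, p5/p95 for absorption).
    """
    for s in (summary_summer, summary_winter):
        if s.parameter != parameter:
            raise ValueError(f"summary for {s.parameter!r} passed as {parameter!r}")
    if summary_summer.factory != summary_winter.factory:
        raise ValueError("seasonal summaries describe different factories")
    q_lo, q_hi = WHISKERS[parameter]
    production = summary_summer.percentile(q_lo)
    persistence = summary_winter.percentile(q_lo)
    upper_season = "summer" if summary_summer.percentile(q_hi) >= summary_winter.percentile(q_hi) else "winter"
    upper = max(summary_summer.percentile(q_hi), summary_winter.percentile(q_hi))
    return ThresholdPair(
        lower=(production, persistence),
        upper=upper,
        source={
            "production": f"summer p{q_lo}",
            "persistence": f"winter p{q_lo}",
            "upper": f"{upper_season} p{q_hi}",
        },
    )


def compute_midpoint(lower, upper: float | None = None, mode: float | None = None) -> float:
    """Mid-point from thresholds, or from the mode when only one threshold exists.

    Two lower thresholds (production, persistence) are first averaged into
    a single minimum; with both a minimum and a maximum, MP is their mean.
    With a single threshold the distribution mode is used instead.
    """
    if lower is not None and not np.isscalar(lower):
        lo_vals = [float(v) for v in lower]
        lower = sum(lo_vals) / len(lo_vals)
    if lower is not None and upper is not None:
        return (float(lower) + float(upper)) / 2.0
    if mode is not None:
        return float(mode)
    raise ValueError("need either two thresholds or one threshold plus a mode")


def calibrate_spread(form: str, mp: float, threshold_x: float) -> float:
    """Spread such that the membership equals 1/2 at the threshold value."""
    d2 = (float(threshold_x) - float(mp)) ** 2
    if d2 == 0.0:
        raise ValueError("threshold coincides with the mid-point; spread undefined")
    if form == "gaussian":
        return math.log(2.0) / d2
    if form == "near_gaussian":
        return 1.0 / d2
    raise ValueError(f"calibrate_spread supports bell forms only, got {form!r}")


def fit_sigmoid_spread(mp: float, ref_x: float, ref_f: float) -> float:
    """Spread of the large sigmoid passing through (ref_x, ref_f).

    Closed-form inversion: S = -ln(1/f - 1) / ln(x / MP). The reference
    point must be off the mid-point with f != 1/2 (at x = MP every spread
    gives 1/2, and f = 1/2 elsewhere has no solution).
    """
    if not (ref_x > 0 and mp > 0):
        raise ValueError("sigmoid is defined for positive x and MP only")
    if not (0.0 < ref_f < 1.0):
        raise ValueError("reference susceptibility must lie strictly in (0, 1)")
    if math.isclose(ref_x, mp, rel_tol=1e-12):
        raise ValueError("reference at the mid-point does not constrain the spread")
    if math.isclose(ref_f, 0.5, abs_tol=1e-12):
        raise ValueError("f = 1/2 away from the mid-point has no sigmoid solution")
    return -math.log(1.0 / ref_f - 1.0) / math.log(ref_x / mp)
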