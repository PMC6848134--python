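"""Fuzzy membership functions normalizing environmental values to [0, 1].

Three bounded forms share a mid-point MP (location of the optimum, in the
parameter's units) and a spread S (dimensionless shape parameter):

* ``gaussian``       f(x) = exp(-S (x - MP)^2)
* ``near_gaussian``  f(x) = 1 / (1 + S (x - MP)^2)   (heavier tails)
* ``sigmoid_large``  f(x) = 1 / (1 + (x / MP)^-S)    (monotone, f(MP) = 1/2)

plus ``independent``, the constant 1 used when a parameter does not
constrain a factory. The two bell forms attain 1 at MP and cross 1/2 at
MP +/- sqrt(ln 2 / S) (gaussian) or MP +/- 1/sqrt(S) (near-gaussian); the
sigmoid is for one-sided affinities with a lower threshold only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("carbfact")

FORMS = ("gaussian", "near_gaussian", "sigmoid_large", "independent")


@dataclass(frozen=True)
class MembershipSpec:
    """One membership function: form plus mid-point and spread."""

    form: str
    mp: float = math.nan
    s: float = math.nan

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown membership form {self.form!r}; expected one of {FORMS}")
        if self.form != "independent":
            if not math.isfinite(self.mp):
                raise ValueError(f"{self.form}: mid-point must be finite")
            if not (self.s > 0):
                raise ValueError(f"{self.form}: spread must be > 0, got {self.s}")

    def half_crossings(self) -> tuple[float, float]:
        """The two x where f(x) = 1/2 (bell forms only)."""
        if self.form == "gaussian":
            w = math.sqrt(math.log(2.0) / self.s)
        elif self.form == "near_gaussian":
            w = 1.0 / math.sqrt(self.s)
        else:
            raise ValueError(f"half_crossings undefined for form {self.form!r}")
        return self.mp - w, self.mp + w


def _prepare(x):
    x = np.asarray(x, dtype=float)
    return x, x.ndim == 0


def gaussian(x, mp: float, s: float):
    """exp(-S (x-MP)^2); 1 iff x = MP, symmetric about MP. NaN passes through."""
    if not s > 0:
        raise ValueError("gaussian: spread must be > 0")
    x, scalar = _prepare(x)
    out = np.exp(-s * (x - mp) ** 2)
    return float(out) if scalar else out


def near_gaussian(x, mp: float, s: float):
    """1 / (1 + S (x-MP)^2); like the Gaussian but with heavier tails."""
    if not s > 0:
        raise ValueError("near_gaussian: spread must be > 0")
    x, scalar = _prepare(x)
    out = 1.0 / (1.0 + s * (x - mp) ** 2)
    return float(out) if scalar else out


def sigmoid_large(x, mp: float, s: float):
    """1 / (1 + (x/MP)^-S): strictly increasing, f(MP) = 1/2 exactly.

    The form is undefined for x <= 0; such values return 0 (total
    inhibition, with a logged warning) - they only arise for sub-freezing
    SST where the modelled affinity is nil anyway.
    """
    if not s > 0 or not mp > 0:
        raise ValueError("sigmoid_large: spread and mid-point must be > 0")
    x, scalar = _prepare(x)
    out = np.zeros_like(x)
    finite = np.isfinite(x)
    bad = finite & (x <= 0)
    if np.any(bad):
        logger.warning("sigmoid_large: %d value(s) <= 0 mapped to susceptibility 0", int(bad.sum()))
    ok = finite & (x > 0)
    out[ok] = 1.0 / (1.0 + (x[ok] / mp) ** (-s))
    out[~finite] = np.nan
    return float(out) if scalar else out


def evaluate(spec: MembershipSpec, x):
    """Evaluate a membership spec elementwise, preserving missing values."""
    if spec.form == "gaussian":
        return gaussian(x, spec.mp, spec.s)
    if spec.form == "near_gaussian":
        return near_gaussian(x, spec.mp, spec.s)
    if spec.form == "sigmoid_large":
        return sigmoid_large(x, spec.mp, spec.s)
    # independent: constant 1 wherever the input is defined
    x, scalar = _prepare(x)
    out = np.where(np.isfinite(x), 1.0, np.nan)
    return float(out) if scalar else out
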