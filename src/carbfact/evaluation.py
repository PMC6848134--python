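"""Agreement scoring between observed and predicted factory maps.

Both maps are expanded into four binary presence layers (from the
categorical assignment, so the metric is symmetric and a map scores 100%
against itself). Per-cell accuracy is 25% per correctly estimated layer;
global accuracy is the arithmetic mean over the evaluation domain.
Anomalies are layer mismatches, classified per factory as overestimation
(predicted, not observed) or underestimation (observed, not predicted),
with their repartition as a percentage of all mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_io import FACTORIES, TERR_ARCTIC, TERR_HIGH, EnvStack, Grid
from .factory_model import FactoryMap


@dataclass
class AccuracyReport:
    """Per-cell accuracy grid, its mean, and the anomaly bookkeeping."""

    accuracy_grid: Grid
    global_accuracy: float
    overestimation: dict[str, int]
    underestimation: dict[str, int]
    repartition: dict[str, float]

    @property
    def total_anomalies(self) -> int:
        return sum(self.overestimation.values()) + sum(self.underestimation.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "factory": f,
                "overestimation": self.overestimation[f],
                "underestimation": self.underestimation[f],
                "repartition_pct": self.repartition[f],
            }
            for f in FACTORIES
        ]
        return pd.DataFrame(rows)


def _layers(fmap: FactoryMap) -> dict[str, np.ndarray]:
    return fmap.presence_layers()


def cell_accuracy(observed: FactoryMap, predicted: FactoryMap) -> Grid:
    """Per-cell accuracy in {0, 25, 50, 75, 100}%.

    Each of the four factories counts 25% when its presence/absence
    matches between the maps; a cell where the observed and predicted
    categories are two different factories scores 50% (two layers wrong),
    a factory against "none" scores 75%.
    """
    if not observed.category.same_lattice(predicted.category):
        raise ValueError("observed and predicted maps are not co-registered")
    obs, pred = _layers(observed), _layers(predicted)
    matches = np.zeros(observed.category.shape, dtype=float)
    for f in FACTORIES:
        matches += obs[f] == pred[f]
    return observed.category.like(25.0 * matches)


def global_accuracy(accuracy_grid: Grid, evaluation_mask: np.ndarray | None = None) -> float:
    """Mean per-cell accuracy (%) over the evaluation domain."""
    acc = accuracy_grid.values
    if evaluation_mask is None:
        evaluation_mask = np.isfinite(acc)
    evaluation_mask = np.asarray(evaluation_mask, dtype=bool)
    if not evaluation_mask.any():
        raise ValueError("empty evaluation mask")
    return float(np.mean(acc[evaluation_mask]))


def evaluation_domain(env: EnvStack, depth_max: float = 200.0) -> np.ndarray:
    """Default scoring domain: shelf cells (0..depth_max m) outside the
    inhibiting high-terrigenous / arctic categories."""
    z = env.bathymetry.values
    terr = env.terrigenous.values
    return np.isfinite(z) & (z >= 0) & (z <= depth_max) & (terr != TERR_HIGH) & (terr != TERR_ARCTIC)


def anomaly_summary(
    observed: FactoryMap,
    predicted: FactoryMap,
    evaluation_mask: np.ndarray | None = None,
) -> AccuracyReport:
    """Full agreement report: accuracy grid and per-factory anomaly counts."""
    acc = cell_accuracy(observed, predicted)
    if evaluation_mask is None:
        evaluation_mask = np.ones(acc.shape, dtype=bool)
    evaluation_mask = np.asarray(evaluation_mask, dtype=bool)
    obs, pred = _layers(observed), _layers(predicted)
    over, under = {}, {}
    for f in FACTORIES:
        o, p = obs[f] & evaluation_mask, pred[f] & evaluation_mask
        over[f] = int(np.count_nonzero(p & ~o))
        under[f] = int(np.count_nonzero(o & ~p))
    total = sum(over.values()) + sum(under.values())
    repartition = {
        f: (100.0 * (over[f] + under[f]) / total) if total else 0.0 for f in FACTORIES
    }
    return AccuracyReport(
        accuracy_grid=acc,
        global_accuracy=global_accuracy(acc, evaluation_mask),
        overestimation=over,
        underestimation=under,
        repartition=repartition,
    )
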