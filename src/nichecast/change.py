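"""Standardized climatic-suitability change and protection-regime summaries.

Raw ensemble suitability scores live on species-specific [0, 1] scales, so
future-minus-current differences are computed on standard scores: every map
is centred and scaled with the mean and sample standard deviation of the
*current* prediction, and the per-cell change Δz = z_future − z_current then
counts standard deviations gained or lost. Changes are summarized per
species x scenario x range x protection regime as 5/25/50/75/95 percentiles
(the box-plot summary) and compared with paired or Welch t-tests.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    AlignmentError,
    DegenerateReferenceError,
    DegenerateTestError,
    MaskError,
    ParameterError,
)
from .sdm import SuitabilityMap
from .synthetic import OccurrenceSet, ProtectionMask

logger = logging.getLogger(__name__)

REGIME_LABELS = ("outside", "n2000", "targeted_n2000")
PERCENTILES = (5, 25, 50, 75, 95)


def standardize(map_: SuitabilityMap, ref: SuitabilityMap,
                cells: np.ndarray | None = None) -> np.ndarray:
    """Standard scores of a suitability map against a reference map.

    z = (score − mean(ref)) / sd(ref), with the sample (n−1) standard
    deviation, taken over ``cells`` (boolean grid; default all cells) of the
    reference. Future maps are standardized with the *current* map as
    reference so current/future scales align.
    """
    if map_.values.shape != ref.values.shape:
        raise AlignmentError("suitability maps are not aligned")
    refvals = ref.values if cells is None else ref.values[cells]
    mu = float(np.mean(refvals))
    sd = float(np.std(refvals, ddof=1))
    if sd <= 0 or not np.isfinite(sd):
        raise DegenerateReferenceError("reference suitability has zero spread")
    return (map_.values - mu) / sd


@dataclass
class ChangeMap:
    """Per-cell Δz = z_future − z_current on a masked cell set."""

    delta: np.ndarray  # 1-D, aligned with cells
    cells: np.ndarray  # (k, 2) row, col
    species: str
    scenario: str


def change_map(z_future: np.ndarray, z_current: np.ndarray,
               mask_cells: np.ndarray, species: str, scenario: str) -> ChangeMap:
    """Δz restricted to a cell mask (occurrence cells or a potential range).

    ``mask_cells`` is either a boolean grid or a (k, 2) index array.
    Positive values mean the future is more suitable than the present.
    """
    if z_future.shape != z_current.shape:
        raise AlignmentError("z maps are not aligned")
    mask_cells = np.asarray(mask_cells)
    if mask_cells.dtype == bool:
        mask_cells = np.argwhere(mask_cells)
    if len(mask_cells) == 0:
        raise MaskError("mask selects no cells")
    r, c = mask_cells[:, 0], mask_cells[:, 1]
    delta = z_future[r, c] - z_current[r, c]
    if not np.all(np.isfinite(delta)):
        raise ParameterError("non-finite change values under mask")
    return ChangeMap(delta=delta, cells=mask_cells, species=species, scenario=scenario)


def potential_range(native_occurrences: list[OccurrenceSet],
                    grid_shape: tuple[int, int]) -> np.ndarray:
    """Union of presence cells across native species, as a boolean grid.

    Models the long-distance-dispersal scenario: the invader is assumed able
    to reach every locality where any native species was recorded.
    """
    if not native_occurrences:
        raise ParameterError("need at least one occurrence set")
    mask = np.zeros(grid_shape, dtype=bool)
    for occ in native_occurrences:
        cells = occ.presence_cells
        mask[cells[:, 0], cells[:, 1]] = True
    return mask


def _percentile_row(values: np.ndarray) -> dict[str, float]:
    p = np.percentile(values, PERCENTILES)  # linear interpolation
    return {"p5": p[0], "q25": p[1], "median": p[2], "q75": p[3], "p95": p[4]}


def regime_summary(cm: ChangeMap, pm: ProtectionMask,
                   target_species_filter: str | None = None) -> pd.DataFrame:
    """Percentile summary of Δz per protection regime.

    Cells are partitioned into outside / n2000 / targeted_n2000, where
    "targeted" means targeted *for the filtered species* (defaults to the
    change map's species); protected cells targeted only for other species
    count as plain n2000. Empty regimes are omitted with a logged notice.
    """
    if pm.regime.shape[0] <= cm.cells[:, 0].max() or pm.regime.shape[1] <= cm.cells[:, 1].max():
        raise AlignmentError("protection mask does not cover the change map")
    species = target_species_filter or cm.species
    r, c = cm.cells[:, 0], cm.cells[:, 1]
    protected = pm.protected[r, c]
    targeted = pm.targeted_for(species)[r, c]
    groups = {
        "outside": ~protected,
        "n2000": protected & ~targeted,
        "targeted_n2000": protected & targeted,
    }
    rows = []
    for regime, sel in groups.items():
        if not np.any(sel):
            logger.info("regime %s empty for %s/%s; row omitted",
                        regime, cm.species, cm.scenario)
            continue
        row = {"species": cm.species, "scenario": cm.scenario, "regime": regime,
               "n_cells": int(sel.sum())}
        row.update(_percentile_row(cm.delta[sel]))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    """Outcome of a two-group location test."""

    grouping: str
    test: str  # 'paired_t' | 'welch_t'
    statistic: float
    df: float
    pvalue: float


def compare_groups(a: np.ndarray, b: np.ndarray, paired: bool,
                   grouping: str = "") -> ComparisonResult:
    """Paired t-test when a cell-to-cell pairing exists, else Welch's t.

    Pairing is only meaningful when the two samples are the same cells under
    two conditions (e.g. two scenarios); different cell sets (inside versus
    outside protection) use the unpaired unequal-variance test. Two-sided p.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if paired:
        if len(a) != len(b):
            raise ParameterError("paired test requires equal-length samples")
        d = a - b
        if len(d) < 2 or np.std(d, ddof=1) == 0:
            raise DegenerateTestError("paired differences have zero variance")
        res = stats.ttest_rel(a, b)
        return ComparisonResult(grouping, "paired_t", float(res.statistic),
                                float(len(d) - 1), float(res.pvalue))
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("Welch test requires n >= 2 in each group")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        raise DegenerateTestError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(grouping, "welch_t", float(res.statistic),
                            float(res.df), float(res.pvalue))
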