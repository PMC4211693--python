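"""Differential-abundance screening of DIGE spot-volume ratio tables.

The design emulates a severity-paired DIGE study: on each gel a complete-injury
(AIS A) CSF sample is co-run against an incomplete-injury (AIS C/D) sample,
one labelled Cy5 and the other Cy3, with the labelling reversed on half of the
gels to cancel dye bias. Analysis always works on the *oriented* ratio
complete/incomplete, obtained from the raw Cy5/Cy3 volume ratio and the gel's
recorded dye orientation.

A spot is called differential when three joint criteria hold: the average fold
magnitude reaches ``fold_threshold`` (default 1.5), at least ``trend_min``
gels (default 3 of 7) agree on the direction of change, and a two-sided
one-sample t-test of the log2 oriented ratios against zero gives
p < ``p_max`` (default 0.1, strict).

Fold changes use the signed convention of difference-gel software: a ratio
r >= 1 maps to +r, a ratio r < 1 maps to -1/r, so a halving is reported as
-2.0 and no value can fall strictly between -1 and 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InvalidParameterError
from .io_formats import COMPLETE_CY3, COMPLETE_CY5, DigeExperiment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the differential-abundance call."""

    fold_threshold: float = 1.5
    trend_min: int = 3
    n_gels_ref: int = 7
    p_max: float = 0.1
    min_presence: int = 2

    def __post_init__(self) -> None:
        if self.fold_threshold < 1:
            raise InvalidParameterError("fold_threshold must be >= 1")
        if not 0 < self.p_max <= 1:
            raise InvalidParameterError("p_max must be in (0, 1]")
        if self.trend_min > self.n_gels_ref:
            raise InvalidParameterError("trend_min cannot exceed n_gels_ref")
        if self.min_presence < 2:
            raise InvalidParameterError("min_presence must be >= 2")


@dataclass(frozen=True)
class FoldChangeResult:
    spot_id: str
    avg_signed_fold: float
    p_value: float
    n_gels_present: int
    trend_count: int
    is_differential: bool


@dataclass(frozen=True)
class TemporalChange:
    """Classification of one protein's fold across the two sampling periods."""

    protein: str
    early_fold: float
    late_fold: float
    classification: str  # persistent | reversed | within_threshold
    presence_note: str = ""


@dataclass
class TemporalComparison:
    changes: dict[str, TemporalChange] = field(default_factory=dict)


def orient_ratio(cy5_over_cy3: float, dye_orientation: str) -> float:
    """Convert a raw Cy5/Cy3 volume ratio to the complete/incomplete ratio.

    Returns the ratio unchanged when the complete-injury sample carried Cy5,
    its reciprocal on reverse-labelled gels.
    """
    if not cy5_over_cy3 > 0:
        raise InvalidParameterError(f"ratio must be positive, got {cy5_over_cy3}")
    if dye_orientation == COMPLETE_CY5:
        return cy5_over_cy3
    if dye_orientation == COMPLETE_CY3:
        return 1.0 / cy5_over_cy3
    raise InvalidParameterError(f"unknown dye orientation {dye_orientation!r}")


def signed_fold(ratio: float) -> float:
    """Signed fold change of a complete/incomplete ratio: r if r>=1 else -1/r."""
    if not ratio > 0:
        raise InvalidParameterError(f"ratio must be positive, got {ratio}")
    return ratio if ratio >= 1 else -1.0 / ratio


def signed_fold_to_ratio(fold: float) -> float:
    """Inverse of :func:`signed_fold`; requires |fold| >= 1."""
    if abs(fold) < 1:
        raise InvalidParameterError(f"|signed fold| must be >= 1, got {fold}")
    return fold if fold >= 1 else -1.0 / fold


def call_spot(spot_id: str, oriented_ratios: Sequence[float],
              config: ScreenConfig = ScreenConfig()) -> FoldChangeResult:
    """Differential call for one spot from its per-gel oriented ratios.

    The average fold is the signed fold of the geometric mean ratio (so up-
    and down-regulation are treated symmetrically); the p-value is a two-sided
    one-sample t-test of the log2 ratios against zero. With zero variance the
    t statistic degenerates: p is reported as 0 when the common log-ratio is
    nonzero and 1 when it is exactly zero, with a warning.
    """
    if len(oriented_ratios) < config.min_presence:
        raise InvalidParameterError(
            f"spot {spot_id}: {len(oriented_ratios)} observation(s), "
            f"need >= {config.min_presence}")
    log2r = np.log2(np.asarray(oriented_ratios, dtype=float))
    avg_fold = signed_fold(float(2.0 ** log2r.mean()))
    n_up = int((log2r > 0).sum())
    n_down = int((log2r < 0).sum())
    trend = max(n_up, n_down)
    if np.ptp(log2r) == 0.0:
        p = 0.0 if log2r[0] != 0.0 else 1.0
        logger.warning("spot %s: zero variance across gels; p reported as %g",
                       spot_id, p)
    else:
        p = float(stats.ttest_1samp(log2r, 0.0).pvalue)
    is_diff = (abs(avg_fold) >= config.fold_threshold
               and trend >= config.trend_min
               and p < config.p_max)
    return FoldChangeResult(spot_id=spot_id, avg_signed_fold=avg_fold,
                            p_value=p, n_gels_present=len(oriented_ratios),
                            trend_count=trend, is_differential=is_diff)


def screen(experiment: DigeExperiment,
           config: ScreenConfig = ScreenConfig(),
           ) -> tuple[list[FoldChangeResult], list[str]]:
    """Run the differential screen over every spot of a DIGE experiment.

    Returns per-spot results (spots observed on fewer than ``min_presence``
    gels are skipped with a logged reason) and the unique gene symbols of the
    differential spots, resolved through the experiment's spot map.
    """
    if not experiment.gels:
        raise InvalidParameterError("experiment has no gels")
    per_spot: dict[str, list[float]] = {}
    for gel in experiment.gels:
        for spot, ratio in gel.spot_ratios.items():
            per_spot.setdefault(spot, []).append(
                orient_ratio(ratio, gel.dye_orientation))
    results = []
    for spot in sorted(per_spot):
        ratios = per_spot[spot]
        if len(ratios) < config.min_presence:
            logger.info("spot %s skipped: present on %d gel(s), need >= %d",
                        spot, len(ratios), config.min_presence)
            continue
        results.append(call_spot(spot, ratios, config))
    diff_spots = [r.spot_id for r in results if r.is_differential]
    proteins = map_spots_to_proteins(diff_spots, experiment.spot_map)
    return results, proteins


def differential_spots_from_folds(folds: Mapping[str, float],
                                  config: ScreenConfig = ScreenConfig(),
                                  ) -> list[str]:
    """Spots whose average signed fold magnitude reaches the threshold.

    Bookkeeping entry point for tables that report per-spot average folds
    (trend and p criteria already applied upstream).
    """
    return sorted(s for s, f in folds.items()
                  if abs(f) >= config.fold_threshold)


def map_spots_to_proteins(spot_ids: Iterable[str],
                          spot_map: Mapping[str, Sequence[tuple[str, str]]],
                          ) -> list[str]:
    """Union of gene symbols identified in the given spots, duplicates collapsed.

    Comigrating spots contribute all their proteins; isoform spots of one
    protein collapse to a single symbol. Unknown spot ids are an error.
    """
    genes: dict[str, None] = {}
    for spot in spot_ids:
        if spot not in spot_map:
            raise InvalidParameterError(f"spot {spot!r} absent from spot map")
        for _name, gene in spot_map[spot]:
            genes.setdefault(gene)
    return sorted(genes)


def temporal_compare(early_folds: Mapping[str, float],
                     late_folds: Mapping[str, float],
                     config: ScreenConfig = ScreenConfig(),
                     late_presence: Mapping[str, tuple[int, int]] | None = None,
                     ) -> TemporalComparison:
    """Classify each shared protein's abundance trajectory across periods.

    within_threshold: the late fold magnitude is below ``fold_threshold``
    (the protein is no longer differential). reversed: both folds exceed the
    threshold with opposite signs. persistent: otherwise. ``late_presence``
    maps a protein to (gels observed, gels total) and yields a presence note
    when the spot was missing from some late gels.
    """
    shared = sorted(set(early_folds) & set(late_folds))
    if not shared:
        logger.warning("temporal comparison: no shared proteins between periods")
        return TemporalComparison()
    comparison = TemporalComparison()
    for protein in shared:
        e, l = early_folds[protein], late_folds[protein]
        if abs(l) < config.fold_threshold:
            cls = "within_threshold"
        elif abs(e) >= config.fold_threshold and math.copysign(1, e) != math.copysign(1, l):
            cls = "reversed"
        else:
            cls = "persistent"
        note = ""
        if late_presence and protein in late_presence:
            seen, total = late_presence[protein]
            if seen < total:
                note = f"spot found in {seen} of {total} late gels"
        comparison.changes[protein] = TemporalChange(
            protein=protein, early_fold=e, late_fold=l,
            classification=cls, presence_note=note)
    return comparison
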