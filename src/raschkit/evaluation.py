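"""Scale-level evaluation: targeting, threshold range and coverage, gaps,
ceiling/floor effects and threshold ordering.

Person measures here always include the extrapolated measures of extreme
persons — ceiling and floor effects are precisely about respondents at the
boundaries, so excluding them would understate both.  Persons exactly on a
boundary threshold count as in range (strict inequalities define ceiling and
floor), which makes floor + in-range + ceiling partition the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig


def classify_targeting(index: float, config: AnalysisConfig) -> str:
    """Band a targeting index: good / slight / substantial mis-targeting."""
    a = abs(index)
    if a < config.targeting_good:
        return "good"
    if a <= config.targeting_substantial:
        return "slight mis-targeting"
    return "substantial mis-targeting"


def targeting(result, config: Optional[AnalysisConfig] = None
              ) -> Tuple[float, str]:
    """Mean person measure minus mean item difficulty, with its band.

    Zero is perfect targeting; a positive index means the sample sits above
    the item difficulties (items too easy for — or findings too prevalent
    in — this sample).
    """
    cfg = config or result.config
    theta = result.theta_all.dropna().to_numpy()
    index = float(theta.mean() - result.delta.to_numpy().mean())
    return index, classify_targeting(index, cfg)


def gaps(result, min_gap: Optional[float] = None) -> pd.DataFrame:
    """Adjacent item-difficulty differences at or above ``min_gap`` logits.

    Item difficulty is the mean of the item's step locations (equal to
    delta because thresholds sum to zero within a group).  A large gap
    means no item discriminates in that region of the continuum.
    """
    if min_gap is None:
        min_gap = result.config.gap_min
    delta = result.delta.sort_values(kind="mergesort")
    order = sorted(delta.index, key=lambda i: (delta[i], i))
    rows = []
    for lo, hi in zip(order, order[1:]):
        size = float(delta[hi] - delta[lo])
        if size >= min_gap:
            rows.append({"item_low": lo, "item_high": hi, "gap": size})
    return pd.DataFrame(rows, columns=["item_low", "item_high", "gap"])


def threshold_range_coverage(result, config: Optional[AnalysisConfig] = None):
    """Threshold range, person range/percentile limits and coverage %.

    The range spans all item step locations delta_i + tau_gj; coverage is
    the percentage of persons (extrapolated extremes included) whose
    measure falls inside it, boundaries inclusive.
    """
    cfg = config or result.config
    steps = result.step_locations().to_numpy()
    steps = steps[np.isfinite(steps)]
    lo, hi = float(steps.min()), float(steps.max())
    theta = result.theta_all.dropna().to_numpy()
    inside = (theta >= lo) & (theta <= hi)
    coverage = 100.0 * inside.sum() / theta.size
    limits = (float(np.percentile(theta, 2.5)),
              float(np.percentile(theta, 97.5)))
    return {
        "threshold_range": (lo, hi),
        "person_range": (float(theta.min()), float(theta.max())),
        "person_limits_95": limits,
        "coverage_pct": float(coverage),
        "coverage_good": coverage >= cfg.coverage_good,
    }


def ceiling_floor(result, config: Optional[AnalysisConfig] = None):
    """Ceiling/floor percentages: persons strictly beyond the extreme item
    thresholds, flagged at the configured criterion (default 15 %)."""
    cfg = config or result.config
    steps = result.step_locations().to_numpy()
    steps = steps[np.isfinite(steps)]
    lo, hi = float(steps.min()), float(steps.max())
    theta = result.theta_all.dropna().to_numpy()
    ceiling = 100.0 * float((theta > hi).sum()) / theta.size
    floor = 100.0 * float((theta < lo).sum()) / theta.size
    return {
        "ceiling_pct": ceiling, "floor_pct": floor,
        "ceiling_flag": ceiling >= cfg.ceiling_floor_max,
        "floor_flag": floor >= cfg.ceiling_floor_max,
    }


def threshold_order(result) -> List[str]:
    """Items whose step thresholds are not strictly ascending.

    Disordered thresholds mean some response category is never the most
    probable anywhere on the continuum — usually a malfunctioning category
    wording.  Dichotomous items (a single threshold) are skipped.
    """
    spec = result.model.spec
    flagged = []
    for i in result.items:
        tau = np.asarray(result.taus[spec[i].scale_group])
        if tau.shape[0] < 2:
            continue
        if np.any(np.diff(tau) <= 0):
            flagged.append(i)
    return flagged


@dataclass
class ScaleEvaluation:
    targeting_index: float
    targeting_band: str
    threshold_range: Tuple[float, float]
    person_range: Tuple[float, float]
    person_limits_95: Tuple[float, float]
    coverage_pct: float
    coverage_good: bool
    gaps: pd.DataFrame = field(repr=False)
    floor_pct: float = 0.0
    ceiling_pct: float = 0.0
    floor_flag: bool = False
    ceiling_flag: bool = False
    disordered_items: List[str] = field(default_factory=list)


def evaluate_scale(result, config: Optional[AnalysisConfig] = None
                   ) -> ScaleEvaluation:
    cfg = config or result.config
    t, band = targeting(result, cfg)
    rng = threshold_range_coverage(result, cfg)
    cf = ceiling_floor(result, cfg)
    return ScaleEvaluation(
        targeting_index=t, targeting_band=band,
        threshold_range=rng["threshold_range"],
        person_range=rng["person_range"],
        person_limits_95=rng["person_limits_95"],
        coverage_pct=rng["coverage_pct"],
        coverage_good=rng["coverage_good"],
        gaps=gaps(result, cfg.gap_min),
        floor_pct=cf["floor_pct"], ceiling_pct=cf["ceiling_pct"],
        floor_flag=cf["floor_flag"], ceiling_flag=cf["ceiling_flag"],
        disordered_items=threshold_order(result),
    )
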