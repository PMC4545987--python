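"""Analysis configuration: estimation settings and every diagnostic criterion.

All psychometric decision thresholds (fit bands, targeting bands, coverage,
ceiling/floor, gap size, DIF contrast, ...) live here so that reports and
classifications never hard-code them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple

import yaml


@dataclass
class AnalysisConfig:
    # --- JMLE estimation ---
    tol: float = 0.005            # max |parameter change| (logits) to declare convergence
    max_iter: int = 200
    extreme_adjustment: float = 0.3   # pseudo-score offset for zero/perfect raw scores
    bias_correction: bool = False     # (L-1)/L shrinkage of item difficulties
    center: str = "items"             # identification: item difficulties mean 0
    divergence_limit: float = 30.0    # |parameter| beyond this aborts as divergent

    # --- item fit bands (mean squares) ---
    infit_lower: float = 0.6
    infit_upper: float = 1.4

    # --- reliability / separation ---
    reliability_good: float = 0.7
    separation_acceptable: Tuple[float, float] = (1.5, 2.0)
    separation_excellent: float = 3.0

    # --- targeting bands (logits, symmetric) ---
    targeting_good: float = 0.5
    targeting_substantial: float = 1.0

    # --- coverage / gaps / ceiling-floor ---
    coverage_good: float = 95.0       # percent of persons inside the threshold range
    gap_min: float = 1.0              # logits between adjacent item difficulties
    ceiling_floor_max: float = 15.0   # percent; at or above this is flagged

    # --- dimensionality / local independence ---
    unidim_eigen_cut: float = 3.0     # first-contrast eigenvalue (item units)
    residual_corr_threshold: float = 0.3

    # --- DIF ---
    dif_criterion: float = 0.5        # |difficulty contrast| in logits
    dif_anchor: str = "persons"       # "persons" (pooled-anchored) or "equate"
    age_split: float = 75.0           # group A: age < split, group B: age >= split
    stage_split: Tuple[int, ...] = (0, 1, 2)  # stages in group A; the rest in group B
    dif_enabled: bool = True

    # --- reporting ---
    wright_bin: float = 0.2           # logit bin width for the item-person map
    wright_persons_per_hash: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["separation_acceptable"] = list(self.separation_acceptable)
        d["stage_split"] = list(self.stage_split)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "separation_acceptable" in d:
            d["separation_acceptable"] = tuple(d["separation_acceptable"])
        if "stage_split" in d:
            d["stage_split"] = tuple(d["stage_split"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


DEFAULT_CONFIG = AnalysisConfig()
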