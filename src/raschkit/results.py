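"""Calibration results container with diagnostics and summary table."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import _pcm
from ._pcm import MISSING
from .config import AnalysisConfig


@dataclass
class RaschResults:
    """JMLE calibration of one domain: estimates, errors and diagnostics.

    Person measures ``theta`` and item difficulties ``delta`` share one
    logit metric with items centred at zero.  ``taus[g]`` holds the
    sum-to-zero step thresholds of rating-scale group ``g``; an item's
    step difficulties are ``delta[i] + taus[g]``.  Extreme persons (zero or
    perfect raw score) are excluded from estimation and carry extrapolated
    measures in ``extreme_theta``.
    """

    model: "RaschModel"
    persons: List[str]
    items: List[str]
    theta: pd.Series
    se_theta: pd.Series
    delta: pd.Series
    se_delta: pd.Series
    taus: Dict[str, np.ndarray]
    se_taus: Dict[str, np.ndarray]
    extreme_persons: List[str]
    extreme_items: List[str]
    converged: bool
    n_iter: int
    max_change: float
    trace: List[dict]
    loglik: float
    config: AnalysisConfig
    extreme_theta: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    extreme_raw: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    # ------------------------------------------------------------------
    def _kernel_arrays(self):
        """Responses, masks and model arrays over non-extreme persons/items."""
        mat = self.model.matrix
        p_idx = [mat.persons.index(p) for p in self.persons]
        i_idx = [mat.items.index(i) for i in self.items]
        X = mat.values[np.ix_(p_idx, i_idx)]
        spec = self.model.spec
        m = np.array([spec[i].n_categories for i in self.items])
        groups = [spec[i].scale_group for i in self.items]
        uniq = sorted(set(groups))
        goi = np.array([uniq.index(g) for g in groups])
        taus = {uniq.index(g): np.asarray(self.taus[g]) for g in uniq}
        return X, m, goi, taus

    def _attach_extreme_measures(self, adjustment: float) -> None:
        spec = self.model.spec
        mat = self.model.matrix
        thetas, raws = {}, {}
        for p in self.extreme_persons:
            row = mat.values[mat.persons.index(p)]
            obs_items = [i for i, v in zip(mat.items, row)
                         if v != MISSING and i in self.delta.index]
            if not obs_items:
                thetas[p] = np.nan
                raws[p] = np.nan
                continue
            raw = int(sum(row[mat.items.index(i)] for i in obs_items))
            from .model import measure_extreme
            thetas[p] = measure_extreme(raw, obs_items, self,
                                        adjustment=adjustment)
            raws[p] = raw
        self.extreme_theta = pd.Series(thetas, dtype=float)
        self.extreme_raw = pd.Series(raws, dtype=float)

    # ------------------------------------------------------------------
    @property
    def theta_all(self) -> pd.Series:
        """Measures for every person, extrapolated extremes included."""
        return pd.concat([self.theta, self.extreme_theta]).astype(float)

    def expected_and_variance(self):
        """Model expected score and variance per (person, item) cell."""
        X, m, goi, taus = self._kernel_arrays()
        p = _pcm.category_probs(self.theta.to_numpy(),
                                self.delta.to_numpy(), taus, goi, m)
        E, V = _pcm.moments(p)
        obs = X != MISSING
        Ed = pd.DataFrame(np.where(obs, E, np.nan),
                          index=self.persons, columns=self.items)
        Vd = pd.DataFrame(np.where(obs, V, np.nan),
                          index=self.persons, columns=self.items)
        return Ed, Vd

    def responses(self) -> pd.DataFrame:
        X, *_ = self._kernel_arrays()
        return pd.DataFrame(np.where(X != MISSING, X, np.nan).astype(float),
                            index=self.persons, columns=self.items)

    def step_locations(self) -> pd.DataFrame:
        """Step difficulties delta_i + tau_gj; one row per item, NaN padded."""
        spec = self.model.spec
        M = int(max(spec[i].n_categories for i in self.items))
        out = np.full((len(self.items), M - 1), np.nan)
        for r, i in enumerate(self.items):
            tau = np.asarray(self.taus[spec[i].scale_group])
            out[r, : tau.shape[0]] = self.delta.loc[i] + tau
        return pd.DataFrame(
            out, index=self.items,
            columns=[f"step_{j + 1}" for j in range(M - 1)],
        )

    # ------------------------------------------------------------------
    # diagnostics / evaluation conveniences (thin wrappers)
    # ------------------------------------------------------------------
    def standardized_residuals(self) -> pd.DataFrame:
        from .diagnostics import standardized_residuals
        return standardized_residuals(self)

    def infit_outfit(self, by: str = "item") -> pd.DataFrame:
        from .diagnostics import infit_outfit
        return infit_outfit(self, by=by)

    def reliability(self, of: str = "persons"):
        """(reliability, separation) for persons (default) or items."""
        from .diagnostics import separation_reliability
        if of == "persons":
            return separation_reliability(self.theta.to_numpy(),
                                          self.se_theta.to_numpy())
        if of == "items":
            return separation_reliability(self.delta.to_numpy(),
                                          self.se_delta.to_numpy())
        raise ValueError("of must be 'persons' or 'items'")

    def evaluate(self, config: Optional[AnalysisConfig] = None):
        from .evaluation import evaluate_scale
        return evaluate_scale(self, config or self.config)

    def wright_map(self, **kwargs) -> str:
        from .wright import wright_map
        return wright_map(self, **kwargs)

    # ------------------------------------------------------------------
    def item_table(self, config: Optional[AnalysisConfig] = None
                   ) -> pd.DataFrame:
        """Calibration table: difficulty, SE, infit, classification.

        Rows sorted by difficulty (ties broken by item id), the layout used
        for published Rasch item tables.
        """
        from .diagnostics import classify_fit
        cfg = config or self.config
        fit = self.infit_outfit(by="item")
        df = pd.DataFrame({
            "difficulty": self.delta,
            "se": self.se_delta,
            "infit": fit["infit"],
            "outfit": fit["outfit"],
        })
        df["fit_class"] = [classify_fit(v, cfg) for v in df["infit"]]
        # strict order by difficulty, ties broken by item id
        df = df.loc[sorted(df.index,
                           key=lambda i: (df.loc[i, "difficulty"], i))]
        df.index.name = "item"
        return df

    def summary(self, config: Optional[AnalysisConfig] = None) -> str:
        cfg = config or self.config
        R, G = self.reliability("persons")
        lines = []
        title = f"Rasch calibration ({self.model.domain or 'all items'})"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(
            f"persons: {len(self.persons)} calibrated, "
            f"{len(self.extreme_persons)} extreme; "
            f"items: {len(self.items)} calibrated, "
            f"{len(self.extreme_items)} extreme"
        )
        lines.append(
            f"converged: {self.converged} in {self.n_iter} iterations "
            f"(max change {self.max_change:.5f} logits)"
        )
        lines.append(f"person reliability (separation): {R:.2f} ({G:.2f})")
        lines.append("")
        tab = self.item_table(cfg)
        lines.append(f"{'item':<12}{'difficulty':>12}{'SE':>8}{'infit':>8}  class")
        for item, row in tab.iterrows():
            lines.append(
                f"{item:<12}{row['difficulty']:>12.2f}{row['se']:>8.2f}"
                f"{row['infit']:>8.2f}  {row['fit_class']}"
            )
        for g in sorted(self.taus):
            tau = np.asarray(self.taus[g])
            if tau.shape[0] > 1:
                vals = ", ".join(f"{t:.2f}" for t in tau)
                lines.append(f"thresholds[{g}]: {vals}")
        return "\n".join(lines)

    def to_csv(self, path, config: Optional[AnalysisConfig] = None) -> None:
        """Export the item calibration table (difficulty, SE, infit)."""
        self.item_table(config).to_csv(path, float_format="%.4f")
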