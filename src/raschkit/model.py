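"""Rasch measurement model for one questionnaire domain.

:class:`RaschModel` follows the familiar two-object pattern: construct the
model from a :class:`~raschkit.instrument.ResponseMatrix` plus
:class:`~raschkit.instrument.InstrumentSpec` (optionally restricted to one
domain), then call :meth:`RaschModel.fit` to obtain a
:class:`~raschkit.results.RaschResults` with person measures, item
difficulties, group step thresholds, standard errors and diagnostics.

Estimation is joint maximum likelihood (JMLE): alternating damped Newton
updates of persons, items and thresholds until the largest parameter change
falls below tolerance.  Persons and items with minimum or maximum possible
raw scores carry no information about their own parameter and are removed
from iteration; extreme persons receive finite extrapolated measures from a
pseudo-score convention (default 0.3 score points inside the boundary).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _pcm
from ._pcm import MISSING, DivergenceError
from .config import AnalysisConfig
from .instrument import InstrumentSpec, ResponseMatrix, from_dataframe
from .results import RaschResults

__all__ = ["RaschModel", "category_probabilities", "expected_score",
           "prox_initialize", "measure_extreme", "DivergenceError"]


class RaschModel:
    """Mixed rating-scale / partial-credit Rasch model for one item set.

    Parameters
    ----------
    matrix : ResponseMatrix
        Persons x items ordinal responses (0-based categories, -1 missing).
    spec : InstrumentSpec
        Item structure.  Items flagged ``excluded`` are dropped.
    domain : str, optional
        Restrict the analysis to one domain's items; each domain is
        calibrated separately on its own logit metric.
    """

    def __init__(self, matrix: ResponseMatrix, spec: InstrumentSpec,
                 domain: Optional[str] = None):
        item_ids = [i for i in spec.analyzed_items(domain) if i in matrix.items]
        if len(item_ids) < 2:
            raise ValueError(
                f"need >= 2 analyzed items (domain={domain!r}), got {len(item_ids)}"
            )
        self.spec = spec.subset(item_ids)
        self.domain = domain
        self.matrix = matrix.subset_items(item_ids)
        # keep persons with at least one observed response on these items
        keep = self.matrix.observed.any(axis=1)
        if not keep.all():
            persons = [p for p, k in zip(self.matrix.persons, keep) if k]
            self.matrix = self.matrix.subset_persons(persons)

        self.item_ids: List[str] = item_ids
        self.m = np.array([self.spec[i].n_categories for i in item_ids])
        groups = sorted({self.spec[i].scale_group for i in item_ids})
        self.group_labels: List[str] = groups
        self.group_index = {g: k for k, g in enumerate(groups)}
        self.group_of_item = np.array(
            [self.group_index[self.spec[i].scale_group] for i in item_ids]
        )
        self.category_maps: dict = {}
        self.collapsed_categories: dict = {}
        self._collapse_null_categories()

    def _collapse_null_categories(self, person_mask=None,
                                  item_mask=None) -> bool:
        """Squeeze out categories unobserved across a whole scale group.

        A response category with zero observations in every item of its
        group (among the persons that will enter estimation) has no
        estimable step threshold — it diverges — so the observed categories
        are renumbered onto a contiguous range and the effective spec's
        category counts reduced, the convention this software family calls
        squeezing null categories.  The composed original-to-effective maps
        are recorded in ``category_maps`` (also applied to subgroup data
        during DIF re-estimation) and the removed categories, in effective
        coding, in ``collapsed_categories``.  Returns True if anything
        changed.
        """
        import warnings
        from dataclasses import replace as _replace

        values = self.matrix.values
        N = values.shape[0]
        pmask = np.ones(N, dtype=bool) if person_mask is None else person_mask
        changed = False
        for g, members in self.spec.scale_groups().items():
            cols = [self.matrix.items.index(i) for i in members]
            if item_mask is not None:
                cols = [c for c in cols if item_mask[c]]
                members = [self.matrix.items[c] for c in cols]
            if not cols:
                continue
            m = self.spec[members[0]].n_categories
            if m < 3:
                continue
            block = values[np.ix_(pmask, cols)]
            counts = np.bincount(block[block != MISSING].ravel(), minlength=m)
            observed = np.nonzero(counts > 0)[0]
            if observed.size == m or observed.size < 2:
                continue
            lut = np.full(m, -1, dtype=np.int64)
            lut[observed] = np.arange(observed.size)
            # clamp codes seen only outside the estimation sample to the
            # nearest retained lower category (nearest upper at the bottom)
            filled = np.maximum.accumulate(np.where(lut >= 0, lut, -1))
            first = int(observed[0])
            filled[:first] = 0
            all_members = self.spec.scale_groups()[g]
            for i in all_members:
                c = self.matrix.items.index(i)
                obs = values[:, c] != MISSING
                values[obs, c] = filled[values[obs, c]]
                prev = self.category_maps.get(i)
                if prev is None:
                    self.category_maps[i] = filled.copy()
                else:
                    self.category_maps[i] = filled[prev]
            self.collapsed_categories.setdefault(g, []).extend(
                int(k) for k in range(m) if counts[k] == 0)
            new_items = [
                _replace(it, n_categories=int(observed.size))
                if it.scale_group == g else it
                for it in self.spec.items
            ]
            self.spec = InstrumentSpec(new_items,
                                       max_categories=self.spec.max_categories)
            self.m = np.array(
                [self.spec[i].n_categories for i in self.item_ids])
            changed = True
            warnings.warn(
                f"scale group {g!r}: unobserved categories collapsed "
                f"before estimation"
            )
        return changed

    def recode_like_model(self, values: np.ndarray, items) -> np.ndarray:
        """Apply this model's null-category collapse to external responses."""
        out = values.copy()
        for j, i in enumerate(items):
            lut = self.category_maps.get(i)
            if lut is None:
                continue
            obs = out[:, j] != MISSING
            out[obs, j] = lut[out[obs, j]]
        return out

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: InstrumentSpec,
                       domain: Optional[str] = None,
                       covariates: Optional[pd.DataFrame] = None,
                       ) -> "RaschModel":
        """Build from a persons x items DataFrame (NaN = missing)."""
        return cls(from_dataframe(df, spec, covariates=covariates), spec,
                   domain=domain)

    # ------------------------------------------------------------------
    def _find_extremes(self) -> Tuple[np.ndarray, np.ndarray]:
        """Boolean masks (persons, items) of extreme rows/columns.

        Iterates because removing an extreme item can make a person
        extreme on the remaining items, and vice versa.
        """
        X = self.matrix.values
        obs = X != MISSING
        maxima = (self.m - 1)
        keep_p = np.ones(X.shape[0], dtype=bool)
        keep_i = np.ones(X.shape[1], dtype=bool)
        while True:
            changed = False
            sub_obs = obs & keep_p[:, None] & keep_i[None, :]
            raw_i = np.where(sub_obs, X, 0).sum(axis=0)
            max_i = (sub_obs * maxima[None, :]).sum(axis=0)
            n_obs_i = sub_obs.sum(axis=0)
            ext_i = keep_i & ((n_obs_i == 0) | (raw_i == 0) | (raw_i == max_i))
            if ext_i.any():
                keep_i &= ~ext_i
                changed = True
            sub_obs = obs & keep_p[:, None] & keep_i[None, :]
            raw_p = np.where(sub_obs, X, 0).sum(axis=1)
            max_p = (sub_obs * maxima[None, :]).sum(axis=1)
            n_obs_p = sub_obs.sum(axis=1)
            ext_p = keep_p & ((n_obs_p == 0) | (raw_p == 0) | (raw_p == max_p))
            if ext_p.any():
                keep_p &= ~ext_p
                changed = True
            if not changed:
                break
        return ~keep_p, ~keep_i

    def fit(self, config: Optional[AnalysisConfig] = None, **overrides
            ) -> RaschResults:
        """Calibrate by JMLE and return a :class:`RaschResults`.

        Keyword overrides (``tol``, ``max_iter``, ``bias_correction``,
        ``extreme_adjustment``, ``divergence_limit``) take precedence over
        the supplied config.
        """
        config = config or AnalysisConfig()
        tol = overrides.get("tol", config.tol)
        max_iter = overrides.get("max_iter", config.max_iter)
        bias_correction = overrides.get("bias_correction", config.bias_correction)
        adjustment = overrides.get("extreme_adjustment", config.extreme_adjustment)
        divergence_limit = overrides.get("divergence_limit", config.divergence_limit)

        ext_p, ext_i = self._find_extremes()
        # removing extreme persons can empty a response category (and a
        # collapse can in turn create new extremes): iterate to a fixed point
        for _ in range(6):
            if not self._collapse_null_categories(~ext_p, ~ext_i):
                break
            ext_p, ext_i = self._find_extremes()
        if (~ext_i).sum() < 2 or (~ext_p).sum() < 2:
            raise ValueError("need >= 2 non-extreme items and persons")

        X = self.matrix.values[np.ix_(~ext_p, ~ext_i)]
        m = self.m[~ext_i]
        goi_items = self.group_of_item[~ext_i]
        # compact group indices over retained items
        kept_groups = sorted(set(int(g) for g in goi_items))
        remap = {g: k for k, g in enumerate(kept_groups)}
        goi = np.array([remap[int(g)] for g in goi_items])
        taus0 = {remap[g]: np.zeros(int(m[goi == remap[g]].max()) - 1)
                 for g in kept_groups}
        group_sizes = {remap[g]: int((goi == remap[g]).sum()) for g in kept_groups}

        theta0, delta0 = _pcm.prox_initialize(X, m)
        sol = _pcm.jmle(X, m, goi, group_sizes, theta0, delta0, taus0,
                        tol=tol, max_iter=max_iter,
                        divergence_limit=divergence_limit)

        delta = sol["delta"]
        if bias_correction:
            L = delta.shape[0]
            delta = delta * (L - 1) / L

        persons = list(np.array(self.matrix.persons, dtype=object)[~ext_p])
        items = list(np.array(self.item_ids, dtype=object)[~ext_i])
        taus_named = {self.group_labels[g_orig]: sol["taus"][remap[g_orig]]
                      for g_orig in kept_groups}
        se_taus_named = {self.group_labels[g_orig]: sol["se_taus"][remap[g_orig]]
                         for g_orig in kept_groups}

        res = RaschResults(
            model=self,
            persons=persons,
            items=items,
            theta=pd.Series(sol["theta"], index=persons, name="theta"),
            se_theta=pd.Series(sol["se_theta"], index=persons, name="se"),
            delta=pd.Series(delta, index=items, name="difficulty"),
            se_delta=pd.Series(sol["se_delta"], index=items, name="se"),
            taus=taus_named,
            se_taus=se_taus_named,
            extreme_persons=list(
                np.array(self.matrix.persons, dtype=object)[ext_p]),
            extreme_items=list(np.array(self.item_ids, dtype=object)[ext_i]),
            converged=sol["converged"],
            n_iter=sol["n_iter"],
            max_change=sol["max_change"],
            trace=sol["trace"],
            loglik=sol["loglik"],
            config=config,
        )
        res._attach_extreme_measures(adjustment)
        return res


# ---------------------------------------------------------------------------
# functional surface over the kernel (single item / small-scale use)
# ---------------------------------------------------------------------------

def _single_item_arrays(item, delta, steps):
    """Assemble kernel arrays for one item given its tau vector."""
    m = np.array([item.n_categories])
    tau = np.asarray(steps, dtype=float)
    if tau.shape[0] != item.n_categories - 1:
        raise ValueError("steps length must be n_categories - 1")
    taus = {0: tau}
    goi = np.array([0])
    return np.array([float(delta)]), taus, goi, m


def category_probabilities(theta: float, item, delta: float,
                           steps: Sequence[float]) -> np.ndarray:
    """P(X = k), k = 0..m-1, for one item at one person location.

    ``steps`` is the item's threshold vector tau (length m-1; a dichotomous
    item has the single threshold 0), so the step difficulty of step j is
    ``delta + steps[j-1]``.
    """
    d, taus, goi, m = _single_item_arrays(item, delta, steps)
    p = _pcm.category_probs(np.array([float(theta)]), d, taus, goi, m)
    return p[0, 0, : item.n_categories]


def expected_score(theta: float, item, delta: float,
                   steps: Sequence[float]) -> Tuple[float, float]:
    """Expected category value and its variance for one item."""
    p = category_probabilities(theta, item, delta, steps)
    k = np.arange(item.n_categories, dtype=float)
    E = float((p * k).sum())
    V = float((p * k**2).sum() - E**2)
    return E, max(V, 0.0)


def prox_initialize(matrix: ResponseMatrix, spec: InstrumentSpec
                    ) -> Tuple[pd.Series, pd.Series]:
    """PROX warm start (log-odds with variance expansion) as named series."""
    m = np.array([spec[i].n_categories for i in matrix.items])
    theta0, delta0 = _pcm.prox_initialize(matrix.values, m)
    return (pd.Series(theta0, index=matrix.persons),
            pd.Series(delta0, index=matrix.items))


def measure_extreme(raw_score: int, item_ids: Sequence[str],
                    result: RaschResults,
                    adjustment: float = 0.3) -> float:
    """Finite extrapolated measure for a zero or perfect raw score.

    The measure is the theta whose expected total score on the calibrated
    subset of ``item_ids`` equals ``adjustment`` (zero score) or
    ``max - adjustment`` (perfect score).
    """
    items = [i for i in item_ids if i in result.delta.index]
    if not items:
        raise ValueError("no calibrated items in the given item set")
    spec = result.model.spec
    max_score = int(sum(spec[i].n_categories - 1 for i in items))
    if raw_score not in (0, max_score):
        raise ValueError(
            f"raw score {raw_score} is not extreme (0 or {max_score}); "
            "use the calibrated measure instead"
        )
    delta = result.delta.loc[items].to_numpy()
    m = np.array([spec[i].n_categories for i in items])
    group_labels = [spec[i].scale_group for i in items]
    uniq = sorted(set(group_labels))
    goi = np.array([uniq.index(g) for g in group_labels])
    taus = {uniq.index(g): np.asarray(result.taus.get(g, np.zeros(1)))
            for g in uniq}
    target = adjustment if raw_score == 0 else max_score - adjustment
    return _pcm.solve_theta_for_expected(target, delta, taus, goi, m)
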