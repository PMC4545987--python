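"""Differential item functioning between person subgroups.

An item shows DIF when subgroups at the same underlying trait level have
different probabilities of endorsing it.  Following common Rasch practice,
person measures are anchored at their pooled-calibration values, item
difficulties are re-estimated separately within each subgroup (step
thresholds held at pooled values), and the difficulty contrast
``delta_A - delta_B`` is flagged when its magnitude exceeds a pure size
criterion (default 0.5 logits) — no significance testing is involved.
An alternative anchoring, two independent calibrations linked by mean-item
equating, is available via ``anchor="equate"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import _pcm
from ._pcm import MISSING
from .config import AnalysisConfig
from .instrument import InstrumentSpec, ResponseMatrix
from .model import RaschModel


def split_groups(matrix: ResponseMatrix,
                 rule: Union[str, Callable[[pd.Series], bool]],
                 config: Optional[AnalysisConfig] = None,
                 ) -> Tuple[ResponseMatrix, ResponseMatrix, Tuple[str, str]]:
    """Partition persons into two subgroup views by a covariate rule.

    Built-in rules: ``"age_75"`` (group A: age < 75, group B: age >= 75)
    and ``"severity_stage"`` (group A: GOLD stage in the configured mild
    set, default {0, 1, 2}; group B: the rest).  A custom predicate maps a
    covariate row to True (group A) / False (group B).  Persons with a
    missing covariate are excluded with a warning; an empty group raises.
    """
    cfg = config or AnalysisConfig()
    if matrix.covariates is None:
        raise ValueError("response matrix has no covariates")
    cov = matrix.covariates

    if rule == "age_75":
        if "age_years" not in cov.columns:
            raise ValueError("covariate 'age_years' required for rule age_75")
        key = pd.to_numeric(cov["age_years"], errors="coerce")
        pred = key < cfg.age_split
        names = (f"age<{cfg.age_split:g}", f"age>={cfg.age_split:g}")
    elif rule == "severity_stage":
        if "stage" not in cov.columns:
            raise ValueError("covariate 'stage' required for rule severity_stage")
        key = pd.to_numeric(cov["stage"], errors="coerce")
        mild = set(int(s) for s in cfg.stage_split)
        pred = key.map(lambda s: int(s) in mild if pd.notna(s) else np.nan)
        tag_a = "".join(str(s) for s in sorted(mild))
        observed = {int(s) for s in key.dropna().unique()}
        tag_b = "".join(str(s) for s in sorted(observed - mild)) or "other"
        names = (f"stage{tag_a}", f"stage{tag_b}")
    elif callable(rule):
        pred = cov.apply(rule, axis=1)
        key = pred
        names = ("group_A", "group_B")
    else:
        raise ValueError(f"unknown grouping rule {rule!r}")

    missing = [p for p in matrix.persons
               if p not in cov.index or pd.isna(key.loc[p])]
    if missing:
        warnings.warn(
            f"{len(missing)} persons excluded from DIF grouping "
            f"(missing covariate)"
        )
    usable = [p for p in matrix.persons if p not in set(missing)]
    a_ids = [p for p in usable if bool(pred.loc[p])]
    b_ids = [p for p in usable if not bool(pred.loc[p])]
    if not a_ids or not b_ids:
        raise ValueError(
            f"grouping {rule!r} produced an empty group "
            f"({len(a_ids)} vs {len(b_ids)})"
        )
    return matrix.subset_persons(a_ids), matrix.subset_persons(b_ids), names


@dataclass
class DIFTable:
    """Per-item group difficulties, contrasts and flags for one grouping."""
    grouping: str
    group_names: Tuple[str, str]
    table: pd.DataFrame      # delta_a, se_a, delta_b, se_b, contrast, flag, domain
    criterion: float
    anchor: str

    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flag"].eq(True)]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, float_format="%.4f")

    def plot_data(self) -> pd.DataFrame:
        """Scatter coordinates plus identity and ±criterion band lines.

        The classic DIF display plots group-A difficulty against group-B
        difficulty; items outside the band around the identity line show
        DIF at the criterion.
        """
        pts = self.table.dropna(subset=["delta_a", "delta_b"])
        lo = float(min(pts["delta_a"].min(), pts["delta_b"].min())) - 0.5
        hi = float(max(pts["delta_a"].max(), pts["delta_b"].max())) + 0.5
        rows = [
            {"kind": "point", "item": i,
             "x": float(r["delta_a"]), "y": float(r["delta_b"])}
            for i, r in pts.iterrows()
        ]
        for kind, off in (("identity", 0.0),
                          ("band_upper", self.criterion),
                          ("band_lower", -self.criterion)):
            rows.append({"kind": kind, "item": "", "x": lo, "y": lo + off})
            rows.append({"kind": kind, "item": "", "x": hi, "y": hi + off})
        return pd.DataFrame(rows, columns=["kind", "item", "x", "y"])


def _group_delta_anchored(group: ResponseMatrix, pooled, config: AnalysisConfig):
    """Re-estimate item difficulties for one subgroup, persons fixed at the
    pooled measures, thresholds fixed at pooled values.

    Anchor measures are shrunk by the (L-1)/L joint-likelihood bias factor
    (L = test length) before re-estimation: JMLE inflates the logit metric
    by roughly L/(L-1), and group difficulties estimated against inflated
    anchors inherit that inflation, which would de-calibrate a pure
    magnitude DIF criterion.  On the corrected metric the group
    difficulties are approximately unbiased.
    """
    persons = [p for p in group.persons if p in pooled.theta.index]
    if len(persons) < 2:
        raise ValueError("subgroup has < 2 non-extreme calibrated persons")
    items = list(pooled.items)
    sub = group.subset_persons(persons).subset_items(items)
    X = pooled.model.recode_like_model(sub.values, items)
    spec = pooled.model.spec
    m = np.array([spec[i].n_categories for i in items])

    # items extreme (or unobserved) within this subgroup: contrast undefined
    obs = X != MISSING
    raw = np.where(obs, X, 0).sum(axis=0)
    mx = (obs * (m - 1)[None, :]).sum(axis=0)
    usable = (obs.sum(axis=0) >= 2) & (raw > 0) & (raw < mx)

    groups = [spec[i].scale_group for i in items]
    uniq = sorted(set(groups))
    goi_all = np.array([uniq.index(g) for g in groups])
    taus = {uniq.index(g): np.asarray(pooled.taus[g]) for g in uniq}

    keep = np.nonzero(usable)[0]
    Xk = X[:, keep]
    mk = m[keep]
    goik = goi_all[keep]
    L = len(items)
    theta = pooled.theta.loc[persons].to_numpy() * (L - 1) / L
    delta0 = pooled.delta.loc[[items[i] for i in keep]].to_numpy()
    sol = _pcm.jmle(
        Xk, mk, goik, {}, theta, delta0, taus,
        tol=config.tol, max_iter=config.max_iter,
        divergence_limit=config.divergence_limit, anchor_theta=True,
    )
    delta = pd.Series(np.nan, index=items, dtype=float)
    se = pd.Series(np.nan, index=items, dtype=float)
    delta.iloc[keep] = sol["delta"]
    se.iloc[keep] = sol["se_delta"]
    return delta, se


def _group_delta_equated(group: ResponseMatrix, pooled, config: AnalysisConfig):
    """Independent subgroup calibration; item-centred metrics are already
    mean-equated, so difficulties are comparable across groups directly."""
    model = RaschModel(group, pooled.model.spec, domain=pooled.model.domain)
    res = model.fit(config)
    delta = res.delta.reindex(pooled.items)
    se = res.se_delta.reindex(pooled.items)
    return delta, se


def dif_contrast(matrix: ResponseMatrix, spec: InstrumentSpec,
                 groups: Tuple[ResponseMatrix, ResponseMatrix],
                 criterion: Optional[float] = None,
                 domain: Optional[str] = None,
                 config: Optional[AnalysisConfig] = None,
                 grouping: str = "custom",
                 group_names: Tuple[str, str] = ("A", "B"),
                 pooled=None) -> DIFTable:
    """Anchored per-group item difficulties and the DIF contrast per item.

    ``groups`` are two person-subset views of ``matrix`` (see
    :func:`split_groups`).  The pooled calibration (computed here unless
    supplied) fixes the person metric; each group's item difficulties are
    then re-estimated and differenced.  Items extreme within either group
    get a missing contrast.
    """
    cfg = config or AnalysisConfig()
    crit = cfg.dif_criterion if criterion is None else criterion
    if pooled is None:
        pooled = RaschModel(matrix, spec, domain=domain).fit(cfg)
    estimator = (_group_delta_anchored if cfg.dif_anchor == "persons"
                 else _group_delta_equated)
    da, sa = estimator(groups[0], pooled, cfg)
    db, sb = estimator(groups[1], pooled, cfg)
    contrast = da - db
    flag = contrast.abs() > crit
    flag = flag.where(contrast.notna())
    table = pd.DataFrame({
        "delta_a": da, "se_a": sa, "delta_b": db, "se_b": sb,
        "contrast": contrast, "flag": flag,
        "domain": [spec[i].domain for i in pooled.items],
    })
    table.index.name = "item"
    return DIFTable(grouping=grouping, group_names=group_names,
                    table=table, criterion=crit, anchor=cfg.dif_anchor)


def dif_summary(table: DIFTable) -> pd.DataFrame:
    """Counts of flagged items per domain, formatted ``n (pct %)``."""
    rows = []
    for domain, sub in table.table.groupby("domain", sort=True):
        testable = sub["contrast"].notna().sum()
        flagged = int(sub["flag"].eq(True).sum())
        pct = round(100.0 * flagged / testable) if testable else 0
        rows.append({
            "domain": domain, "n_flagged": flagged, "n_testable": int(testable),
            "display": f"{flagged} ({pct} %)",
        })
    return pd.DataFrame(rows).set_index("domain")
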