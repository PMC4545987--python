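"""Synthetic SGRQ-like response generation with known truth.

Emulates the structure of the St. George's Respiratory Questionnaire as
analysed per domain in Rasch studies: a Symptom domain of 6 polytomous
items in mixed 4/5-category formats, an Activity domain of 16 dichotomous
items spanning a wide difficulty range, and an Impact domain of 26 items
(3 polytomous, 23 dichotomous), with age and GOLD-stage covariates for a
COPD-like sample (default N = 240, mean age 70.4, SD 7.9).  Responses are
drawn cell by cell from the mixed rating-scale / partial-credit model at
the true parameters, so every downstream stage can be validated by
parameter recovery.  DIF is injectable as a group-specific difficulty
shift at generation time, and a correlated second latent trait can
contaminate a subset of items for dimensionality power studies.

One seed sequence with per-component substreams (covariates / traits /
responses / missingness) keeps generation reproducible and insensitive to
added analysis steps.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._pcm import MISSING
from .instrument import InstrumentSpec, ItemSpec, ResponseMatrix

DELTA_RANGE = (-7.0, 5.0)   # plausible generating-difficulty span (logits)


def sgrq_like_spec(include_excluded: bool = False) -> InstrumentSpec:
    """Bundled instrument mirroring the analysed SGRQ structure.

    6 polytomous Symptom items (four 5-category items sharing one response
    format, two 4-category items each with its own format), 16 dichotomous
    Activity items and 26 Impact items (two 5-category, one reversed
    4-category, 23 dichotomous).  The 4-vs-5 category assignment within the
    Symptom domain is illustrative.  With ``include_excluded`` the two
    Symptom items conventionally dropped from psychometric analysis are
    present but flagged ``excluded``.
    """
    items: List[ItemSpec] = []
    for i in range(1, 5):
        items.append(ItemSpec(f"S_a{i}", "Symptom", 5, "sym_freq"))
    items.append(ItemSpec("S_a5", "Symptom", 4, "sym_attack", reversed=True))
    if include_excluded:
        items.append(ItemSpec("S_a6", "Symptom", 4, "sym_dur", excluded=True))
    items.append(ItemSpec("S_a7", "Symptom", 4, "sym_days"))
    if include_excluded:
        items.append(ItemSpec("S_a8", "Symptom", 4, "sym_morn", excluded=True))
    for i in range(1, 8):
        items.append(ItemSpec(f"A_c{i}", "Activity", 2, "act_bin"))
    for i in range(1, 10):
        items.append(ItemSpec(f"A_g{i}", "Activity", 2, "act_bin"))
    items.append(ItemSpec("I_b1", "Impact", 5, "imp_b1"))
    items.append(ItemSpec("I_b2", "Impact", 5, "imp_b2"))
    items.append(ItemSpec("I_i", "Impact", 4, "imp_i", reversed=True))
    for grp, n in (("d", 6), ("e", 8), ("f", 4), ("h", 5)):
        for i in range(1, n + 1):
            items.append(ItemSpec(f"I_{grp}{i}", "Impact", 2, "imp_bin"))
    return InstrumentSpec(items)


def _default_delta(spec: InstrumentSpec) -> Dict[str, float]:
    """Evenly spaced generating difficulties per domain, spanning spreads
    typical of the three SGRQ domains (Activity much wider than the rest)."""
    spans = {"Symptom": (-1.1, 0.5), "Activity": (-6.4, 4.5),
             "Impact": (-1.9, 1.75)}
    out: Dict[str, float] = {}
    for domain, ids in spec.domains().items():
        ids = [i for i in ids if not spec[i].excluded]
        lo, hi = spans.get(domain, (-2.0, 2.0))
        for i, v in zip(ids, np.linspace(lo, hi, len(ids))):
            out[i] = float(v)
    return out


def _default_taus(spec: InstrumentSpec) -> Dict[str, List[float]]:
    """Symmetric, ordered step thresholds per rating-scale group."""
    out: Dict[str, List[float]] = {}
    for g, members in spec.scale_groups().items():
        m = spec[members[0]].n_categories
        if m == 2:
            out[g] = [0.0]
        else:
            half = (m - 2) / 2.0
            out[g] = list(np.linspace(-half, half, m - 1))
    return out


@dataclass(frozen=True)
class DIFInjection:
    """Difficulty shift for one item in one subgroup (group B of a rule)."""
    item: str
    shift: float
    rule: str = "severity_stage"   # "age_75" or "severity_stage"


@dataclass(frozen=True)
class SecondDimension:
    """A second latent trait, correlated with the first, driving a subset
    of items (multidimensional contamination)."""
    items: Tuple[str, ...]
    correlation: float


@dataclass
class GenerationConfig:
    spec: Optional[InstrumentSpec] = None    # defaults to sgrq_like_spec()
    n_persons: int = 240
    theta_mean: float = 0.0
    theta_sd: float = 1.5
    delta: Optional[Dict[str, float]] = None
    taus: Optional[Dict[str, List[float]]] = None
    dif_injections: Tuple[DIFInjection, ...] = ()
    second_dimension: Optional[SecondDimension] = None
    age_mean: float = 70.4
    age_sd: float = 7.9
    age_range: Tuple[float, float] = (46.0, 88.0)
    stage_probs: Tuple[float, ...] = (0.08125, 0.08125, 0.3583, 0.3958, 0.0834)
    severity_theta_shift: float = 0.5   # extra mean theta for stages 3-4
    missing_rate: float = 0.0


def inject_second_dimension(config: GenerationConfig,
                            items: Sequence[str],
                            correlation: float) -> GenerationConfig:
    """Return a config whose listed items respond to a second trait.

    ``correlation`` is the latent correlation with the primary trait and
    must lie in [0, 1); the subset must be non-empty and must not cover the
    whole instrument (no contrast would remain).
    """
    spec = config.spec or sgrq_like_spec()
    items = tuple(items)
    if not items:
        raise ValueError("second-dimension item subset is empty")
    unknown = [i for i in items if i not in spec]
    if unknown:
        raise ValueError(f"unknown items: {unknown}")
    if set(items) >= set(spec.analyzed_items()):
        raise ValueError("second dimension cannot cover all analyzed items")
    if not 0.0 <= correlation < 1.0:
        raise ValueError("correlation must lie in [0, 1)")
    return dataclasses.replace(
        config, spec=spec,
        second_dimension=SecondDimension(items, float(correlation)),
    )


@dataclass
class TruthRecord:
    """Generating parameters behind one synthetic dataset."""
    seed: int
    theta: Dict[str, float]
    theta2: Dict[str, float]
    delta: Dict[str, float]
    taus: Dict[str, List[float]]
    covariates: Dict[str, Dict[str, float]]
    dif_injections: List[dict]
    dimension2_items: List[str]

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "TruthRecord":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(**d)

    def delta_series(self) -> pd.Series:
        return pd.Series(self.delta, dtype=float)


def _group_b_mask(rule: str, age: np.ndarray, stage: np.ndarray) -> np.ndarray:
    if rule == "age_75":
        return age >= 75.0
    if rule == "severity_stage":
        return stage >= 3
    raise ValueError(f"unknown DIF rule {rule!r}")


def generate(config: Optional[GenerationConfig] = None, seed: int = 0,
             **overrides) -> Tuple[ResponseMatrix, TruthRecord]:
    """Draw a synthetic response matrix plus its truth record.

    Responses are sampled per cell from the category probabilities at the
    true person/item parameters.  Identical ``(config, seed)`` yield
    byte-identical output.
    """
    config = dataclasses.replace(config or GenerationConfig(), **overrides)
    spec = config.spec or sgrq_like_spec()
    if config.theta_sd < 0 or config.age_sd < 0:
        raise ValueError("distribution scale parameters must be >= 0")
    if not np.isclose(sum(config.stage_probs), 1.0):
        raise ValueError("stage_probs must sum to 1")
    if not 0.0 <= config.missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")

    item_ids = spec.analyzed_items()
    delta_map = dict(config.delta) if config.delta else _default_delta(spec)
    missing_delta = [i for i in item_ids if i not in delta_map]
    if missing_delta:
        raise ValueError(f"no generating difficulty for items: {missing_delta}")
    lo, hi = DELTA_RANGE
    bad = {i: d for i, d in delta_map.items() if not lo <= d <= hi}
    if bad:
        raise ValueError(f"generating difficulties outside [{lo}, {hi}]: {bad}")
    taus_map = dict(config.taus) if config.taus else _default_taus(spec)
    for g, members in spec.scale_groups().items():
        if any(i in item_ids for i in members):
            m = spec[members[0]].n_categories
            tau = np.asarray(taus_map[g], dtype=float)
            if tau.shape[0] != m - 1:
                raise ValueError(f"group {g!r}: need {m - 1} thresholds")

    ss = np.random.SeedSequence(seed)
    rng_cov, rng_trait, rng_resp, rng_miss = (
        np.random.default_rng(c) for c in ss.spawn(4))

    N = config.n_persons
    persons = [f"P{i + 1:04d}" for i in range(N)]
    stage = rng_cov.choice(len(config.stage_probs), size=N,
                           p=np.asarray(config.stage_probs))
    age = np.clip(rng_cov.normal(config.age_mean, config.age_sd, size=N),
                  *config.age_range)

    rho = (config.second_dimension.correlation
           if config.second_dimension else 0.0)
    z1 = rng_trait.standard_normal(N)
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng_trait.standard_normal(N)
    shift = config.theta_mean + config.severity_theta_shift * (stage >= 3)
    theta = shift + config.theta_sd * z1
    theta2 = shift + config.theta_sd * z2

    I = len(item_ids)
    m = np.array([spec[i].n_categories for i in item_ids])
    M = int(m.max())
    delta_cells = np.tile(
        np.array([delta_map[i] for i in item_ids]), (N, 1))
    for inj in config.dif_injections:
        if inj.item not in item_ids:
            raise ValueError(f"DIF injection targets unknown item {inj.item!r}")
        j = item_ids.index(inj.item)
        mask = _group_b_mask(inj.rule, age, stage)
        delta_cells[mask, j] += inj.shift

    dim2 = set(config.second_dimension.items) if config.second_dimension else set()
    theta_cells = np.tile(theta[:, None], (1, I))
    for j, i in enumerate(item_ids):
        if i in dim2:
            theta_cells[:, j] = theta2

    # cumulative thresholds per item: cumtau[i, k] = sum_{j<=k} tau_gj
    cumtau = np.zeros((I, M))
    for j, i in enumerate(item_ids):
        tau = np.asarray(taus_map[spec[i].scale_group], dtype=float)
        cumtau[j, 1: m[j]] = np.cumsum(tau)
    k = np.arange(M)
    logits = (k[None, None, :] * (theta_cells - delta_cells)[:, :, None]
              - cumtau[None, :, :])
    logits = np.where(k[None, None, :] >= m[None, :, None], -np.inf, logits)
    logits -= logits.max(axis=2, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=2, keepdims=True)

    u = rng_resp.random((N, I, 1))
    values = (u > np.cumsum(p, axis=2)[:, :, :-1]).sum(axis=2).astype(np.int64)

    if config.missing_rate > 0:
        miss = rng_miss.random((N, I)) < config.missing_rate
        values[miss] = MISSING

    cov = pd.DataFrame(
        {"age_years": np.round(age, 1), "stage": stage.astype(int)},
        index=pd.Index(persons, name="person_id"),
    )
    matrix = ResponseMatrix(
        persons=persons, items=list(item_ids), values=values,
        covariates=cov, provenance={"generator": "raschkit.simulate",
                                    "seed": int(seed)},
    )
    truth = TruthRecord(
        seed=int(seed),
        theta={p_: float(t) for p_, t in zip(persons, theta)},
        theta2={p_: float(t) for p_, t in zip(persons, theta2)},
        delta={i: float(delta_map[i]) for i in item_ids},
        taus={g: [float(x) for x in taus_map[g]]
              for g in sorted({spec[i].scale_group for i in item_ids})},
        covariates={p_: {"age_years": float(a), "stage": int(s)}
                    for p_, a, s in zip(persons, np.round(age, 1), stage)},
        dif_injections=[dataclasses.asdict(inj)
                        for inj in config.dif_injections],
        dimension2_items=sorted(dim2),
    )
    return matrix, truth


def dichotomous_bank_config(n_persons: int = 300, n_items: int = 20,
                            delta_span: Tuple[float, float] = (-3.0, 3.0),
                            theta_sd: float = 1.5) -> GenerationConfig:
    """Plain dichotomous item-bank design used for recovery studies:
    difficulties equally spaced across ``delta_span``, theta normal."""
    items = [ItemSpec(f"Q{i + 1:02d}", "Bank", 2, "bank") for i in range(n_items)]
    spec = InstrumentSpec(items)
    delta = {it.id: float(v)
             for it, v in zip(items, np.linspace(*delta_span, n_items))}
    return GenerationConfig(
        spec=spec, n_persons=n_persons, theta_sd=theta_sd, delta=delta,
        severity_theta_shift=0.0,
    )
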