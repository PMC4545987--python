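"""Instrument structure, response matrices, file I/O and classical scoring.

An instrument is an ordered set of ordinal items, each belonging to one
domain (subscale), with ``n_categories`` ordered response categories coded
0..m-1, a rating-scale group (items sharing a response format share one set
of step thresholds) and an optional reverse-scoring flag.  Responses are
held as a persons x items integer matrix with an explicit missing mask;
category coding is 0-based internally, higher codes uniformly indicating
worse status after reversal is applied at read time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

MISSING = -1
#: column names recognised as non-item metadata in a wide response CSV
RESERVED_COLUMNS = ("person_id", "age_years", "stage")


@dataclass(frozen=True)
class ItemSpec:
    """One ordinal item: identity, domain, category count and scale group."""

    id: str
    domain: str
    n_categories: int
    scale_group: str
    reversed: bool = False
    excluded: bool = False  # kept in classical domain scores, dropped from calibration

    def __post_init__(self):
        if self.n_categories < 2:
            raise ValueError(f"item {self.id!r}: n_categories must be >= 2")


@dataclass
class InstrumentSpec:
    """Ordered item collection partitioned into domains.

    Invariants enforced on construction: unique item ids; every item in
    exactly one domain (by construction of :class:`ItemSpec`); all items of
    a rating-scale group share one category count; category counts within
    ``[2, max_categories]``.
    """

    items: List[ItemSpec]
    max_categories: int = 5

    def __post_init__(self):
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids: {dupes}")
        for it in self.items:
            if it.n_categories > self.max_categories:
                raise ValueError(
                    f"item {it.id!r}: n_categories={it.n_categories} exceeds "
                    f"max_categories={self.max_categories}"
                )
        for g, members in self.scale_groups().items():
            counts = {self[i].n_categories for i in members}
            if len(counts) > 1:
                raise ValueError(
                    f"scale group {g!r} mixes category counts {sorted(counts)}"
                )

    # -- lookups -----------------------------------------------------------
    def __getitem__(self, item_id: str) -> ItemSpec:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def __contains__(self, item_id: str) -> bool:
        return any(it.id == item_id for it in self.items)

    @property
    def item_ids(self) -> List[str]:
        return [it.id for it in self.items]

    def domains(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for it in self.items:
            out.setdefault(it.domain, []).append(it.id)
        return out

    def scale_groups(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for it in self.items:
            out.setdefault(it.scale_group, []).append(it.id)
        return out

    def analyzed_items(self, domain: Optional[str] = None) -> List[str]:
        """Item ids entering the psychometric analysis (excluded flag off)."""
        return [
            it.id
            for it in self.items
            if not it.excluded and (domain is None or it.domain == domain)
        ]

    def subset(self, item_ids: Sequence[str]) -> "InstrumentSpec":
        keep = set(item_ids)
        return InstrumentSpec(
            [it for it in self.items if it.id in keep], self.max_categories
        )

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "max_categories": self.max_categories,
            "items": [
                {
                    "id": it.id,
                    "domain": it.domain,
                    "n_categories": it.n_categories,
                    "scale_group": it.scale_group,
                    "reversed": it.reversed,
                    "excluded": it.excluded,
                }
                for it in self.items
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentSpec":
        items = [
            ItemSpec(
                id=str(e["id"]),
                domain=str(e["domain"]),
                n_categories=int(e["n_categories"]),
                scale_group=str(e["scale_group"]),
                reversed=bool(e.get("reversed", False)),
                excluded=bool(e.get("excluded", False)),
            )
            for e in d["items"]
        ]
        return cls(items, max_categories=int(d.get("max_categories", 5)))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "InstrumentSpec":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ResponseMatrix:
    """Persons x items ordinal responses with missing mask and covariates.

    ``values[n, i]`` is the 0-based category of person ``n`` on item
    ``items[i]`` or :data:`MISSING`.  ``covariates`` (optional) is indexed
    by person id and may carry ``age_years`` and ``stage``.
    """

    persons: List[str]
    items: List[str]
    values: np.ndarray
    covariates: Optional[pd.DataFrame] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (len(self.persons), len(self.items)):
            raise ValueError("values shape does not match persons x items")

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def observed(self) -> np.ndarray:
        return self.values != MISSING

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values.astype(float), index=self.persons, columns=self.items
        )
        return df.where(self.values != MISSING)

    def subset_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        idx = [self.items.index(i) for i in item_ids]
        return ResponseMatrix(
            persons=list(self.persons),
            items=list(item_ids),
            values=self.values[:, idx].copy(),
            covariates=self.covariates,
            provenance=dict(self.provenance),
        )

    def subset_persons(self, person_ids: Sequence[str]) -> "ResponseMatrix":
        idx = [self.persons.index(p) for p in person_ids]
        cov = None
        if self.covariates is not None:
            cov = self.covariates.loc[list(person_ids)]
        return ResponseMatrix(
            persons=list(person_ids),
            items=list(self.items),
            values=self.values[idx, :].copy(),
            covariates=cov,
            provenance=dict(self.provenance),
        )


def _validate_cells(values: np.ndarray, persons, items, spec: InstrumentSpec) -> None:
    for j, item in enumerate(items):
        m = spec[item].n_categories
        col = values[:, j]
        bad = np.where((col != MISSING) & ((col < 0) | (col > m - 1)))[0]
        if bad.size:
            n = bad[0]
            raise ValueError(
                f"response out of range: person {persons[n]!r}, item {item!r}, "
                f"value {col[n]} (allowed 0..{m - 1})"
            )


def read_responses(path, spec: InstrumentSpec,
                   covariate_columns: Sequence[str] = RESERVED_COLUMNS[1:],
                   ) -> ResponseMatrix:
    """Read a wide response CSV (header row of item ids) into a matrix.

    A ``person_id`` column provides person identifiers (row numbers
    otherwise); columns named in ``covariate_columns`` become covariates;
    any remaining column that is not a known item id raises.  Reverse-scored
    items are recoded ``x -> (m-1) - x`` on read, so that higher codes
    uniformly indicate worse status.
    """
    df = pd.read_csv(path, dtype={"person_id": str, "stage": "object"})
    if "person_id" in df.columns:
        persons = [str(p) for p in df["person_id"]]
    else:
        persons = [str(i) for i in range(len(df))]
    if len(set(persons)) != len(persons):
        raise ValueError("duplicate person_id values")

    item_cols = [c for c in df.columns
                 if c not in ("person_id",) and c not in covariate_columns]
    unknown = [c for c in item_cols if c not in spec]
    if unknown:
        raise ValueError(f"unknown item columns: {unknown}")

    values = np.full((len(df), len(item_cols)), MISSING, dtype=np.int64)
    for j, c in enumerate(item_cols):
        col = pd.to_numeric(df[c], errors="raise")
        obs = col.notna().to_numpy()
        v = col.to_numpy(dtype=float)
        if np.any(v[obs] != np.round(v[obs])):
            raise ValueError(f"non-integer response in item column {c!r}")
        values[obs, j] = v[obs].astype(np.int64)
    _validate_cells(values, persons, item_cols, spec)

    reversed_items = []
    for j, c in enumerate(item_cols):
        it = spec[c]
        if it.reversed:
            obs = values[:, j] != MISSING
            values[obs, j] = (it.n_categories - 1) - values[obs, j]
            reversed_items.append(c)

    cov = None
    present = [c for c in covariate_columns if c in df.columns]
    if present:
        cov = df[present].copy()
        cov.index = pd.Index(persons, name="person_id")

    return ResponseMatrix(
        persons=persons, items=item_cols, values=values, covariates=cov,
        provenance={"source": str(path), "reversed_items": reversed_items},
    )


def write_responses(matrix: ResponseMatrix, spec: InstrumentSpec, path) -> None:
    """Write the matrix back to CSV in the original response orientation.

    Reversal is undone on write so that a write/read round trip through
    :func:`read_responses` reproduces the in-memory cells exactly.
    """
    out = matrix.values.copy()
    for j, c in enumerate(matrix.items):
        it = spec[c]
        if it.reversed:
            obs = out[:, j] != MISSING
            out[obs, j] = (it.n_categories - 1) - out[obs, j]
    df = pd.DataFrame(out.astype(float), columns=matrix.items)
    df = df.where(out != MISSING)
    df.insert(0, "person_id", matrix.persons)
    if matrix.covariates is not None:
        for c in matrix.covariates.columns:
            df[c] = matrix.covariates[c].to_numpy()
    # integer-looking cells, empty for missing
    df.to_csv(path, index=False, float_format="%.0f")


def from_dataframe(df: pd.DataFrame, spec: InstrumentSpec,
                   covariates: Optional[pd.DataFrame] = None,
                   already_reversed: bool = True) -> ResponseMatrix:
    """Build a ResponseMatrix from a persons x items DataFrame (NaN = missing)."""
    items = [c for c in df.columns]
    unknown = [c for c in items if c not in spec]
    if unknown:
        raise ValueError(f"unknown item columns: {unknown}")
    persons = [str(p) for p in df.index]
    values = np.full(df.shape, MISSING, dtype=np.int64)
    arr = df.to_numpy(dtype=float)
    obs = ~np.isnan(arr)
    values[obs] = arr[obs].astype(np.int64)
    _validate_cells(values, persons, items, spec)
    if not already_reversed:
        for j, c in enumerate(items):
            it = spec[c]
            if it.reversed:
                o = values[:, j] != MISSING
                values[o, j] = (it.n_categories - 1) - values[o, j]
    return ResponseMatrix(persons=persons, items=items, values=values,
                          covariates=covariates)


# ---------------------------------------------------------------------------
# classical (non-Rasch) scoring
# ---------------------------------------------------------------------------

def domain_scores(matrix: ResponseMatrix, spec: InstrumentSpec) -> pd.DataFrame:
    """Per-person percentage score per domain from unweighted item sums.

    score = 100 * (sum of observed item scores) / (sum of the maxima of the
    same observed items); higher means worse status.  A person with no
    observed responses in a domain gets NaN, never zero.
    """
    out = {}
    for domain, item_ids in spec.domains().items():
        cols = [matrix.items.index(i) for i in item_ids if i in matrix.items]
        ids = [i for i in item_ids if i in matrix.items]
        if not cols:
            continue
        vals = matrix.values[:, cols]
        obs = vals != MISSING
        maxima = np.array([spec[i].n_categories - 1 for i in ids], dtype=float)
        num = np.where(obs, vals, 0).sum(axis=1).astype(float)
        den = (obs * maxima).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = 100.0 * num / den
        score[den == 0] = np.nan
        out[domain] = score
    return pd.DataFrame(out, index=pd.Index(matrix.persons, name="person_id"))


def recode_categories(matrix: ResponseMatrix, spec: InstrumentSpec,
                      mapping: Mapping[str, Mapping[int, int]],
                      ):
    """Collapse response categories per item via old->new category maps.

    Each item's map must cover all its old categories, be weakly
    order-preserving, and map onto a contiguous range starting at 0.
    Rating-scale groups are re-derived so grouped items still share a
    category count: items whose new count diverges from their group get a
    derived group label.  Returns ``(new_matrix, new_spec)``.
    """
    new_counts: Dict[str, int] = {}
    for item_id, mp in mapping.items():
        it = spec[item_id]
        old = sorted(mp)
        if old != list(range(it.n_categories)):
            raise ValueError(
                f"item {item_id!r}: mapping must cover categories "
                f"0..{it.n_categories - 1}"
            )
        news = [mp[o] for o in old]
        if any(b < a for a, b in zip(news, news[1:])):
            raise ValueError(f"item {item_id!r}: mapping violates category order")
        target = sorted(set(news))
        if target != list(range(len(target))):
            raise ValueError(
                f"item {item_id!r}: mapped categories {target} are not a "
                f"contiguous range starting at 0"
            )
        new_counts[item_id] = len(target)

    values = matrix.values.copy()
    for item_id, mp in mapping.items():
        if item_id not in matrix.items:
            continue
        j = matrix.items.index(item_id)
        obs = values[:, j] != MISSING
        lut = np.array([mp[o] for o in range(spec[item_id].n_categories)])
        values[obs, j] = lut[values[obs, j]]

    new_items = []
    for it in spec.items:
        m = new_counts.get(it.id, it.n_categories)
        new_items.append(replace(it, n_categories=m))
    # split rating-scale groups whose members no longer share a count
    group_counts: Dict[str, set] = {}
    for it in new_items:
        group_counts.setdefault(it.scale_group, set()).add(it.n_categories)
    final_items = []
    for it in new_items:
        if len(group_counts[it.scale_group]) > 1:
            it = replace(it, scale_group=f"{it.scale_group}:{it.n_categories}cat")
        final_items.append(it)
    new_spec = InstrumentSpec(final_items, max_categories=spec.max_categories)
    new_matrix = ResponseMatrix(
        persons=list(matrix.persons), items=list(matrix.items), values=values,
        covariates=matrix.covariates,
        provenance={**matrix.provenance, "recoded_items": sorted(mapping)},
    )
    return new_matrix, new_spec
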