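"""Residual-based fit, reliability/separation, dimensionality and local
independence diagnostics for a Rasch calibration.

All statistics operate on the non-extreme persons and items of a
:class:`~raschkit.results.RaschResults`; extreme rows and columns carry no
residual information and are excluded throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig


# ---------------------------------------------------------------------------
# low-level formula layer (array in / array out, independently testable)
# ---------------------------------------------------------------------------

def residuals_from_moments(X: np.ndarray, E: np.ndarray, V: np.ndarray
                           ) -> np.ndarray:
    """Standardized residuals z = (x - E)/sqrt(V); NaN where missing or V=0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (X - E) / np.sqrt(V)
    z = np.where(V <= 0, np.nan, z)
    return z


def infit_outfit_from_moments(X: np.ndarray, E: np.ndarray, V: np.ndarray,
                              axis: int = 0) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Information-weighted (infit) and unweighted (outfit) mean squares.

    infit = sum (x-E)^2 / sum V  (sums over persons for item fit, axis=0);
    outfit = mean of z^2.  Cells with missing data (NaN in E) are skipped.
    Returns (infit, outfit, n_observed); entries with < 2 observations are NaN.
    """
    obs = np.isfinite(E) & np.isfinite(X)
    sq = np.where(obs, (X - E) ** 2, 0.0)
    v = np.where(obs, V, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        infit = sq.sum(axis=axis) / v.sum(axis=axis)
        z2 = np.where(obs & (V > 0), sq / np.where(V > 0, V, 1.0), np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            outfit = np.nanmean(z2, axis=axis)
    n = obs.sum(axis=axis)
    infit = np.where(n >= 2, infit, np.nan)
    outfit = np.where(n >= 2, outfit, np.nan)
    return infit, outfit, n


# ---------------------------------------------------------------------------
# result-level API
# ---------------------------------------------------------------------------

def standardized_residuals(result) -> pd.DataFrame:
    """Standardized residual per observed cell (NaN missing/degenerate)."""
    E, V = result.expected_and_variance()
    X = result.responses()
    z = residuals_from_moments(X.to_numpy(), E.to_numpy(), V.to_numpy())
    return pd.DataFrame(z, index=result.persons, columns=result.items)


def classify_fit(mean_square: float, config: AnalysisConfig) -> str:
    """Band a mean-square fit statistic: overfit / fit / misfit."""
    if not np.isfinite(mean_square):
        return "n/a"
    if mean_square < config.infit_lower:
        return "overfit"
    if mean_square > config.infit_upper:
        return "misfit"
    return "fit"


def infit_outfit(result, by: str = "item",
                 config: Optional[AnalysisConfig] = None) -> pd.DataFrame:
    """Per-item (or per-person) infit/outfit mean squares with fit bands.

    Infit weights each cell by its model variance, so persons located close
    to an item dominate that item's statistic; outfit is the plain mean of
    squared standardized residuals and is more sensitive to outlying
    responses from far-away persons.
    """
    cfg = config or result.config
    E, V = result.expected_and_variance()
    X = result.responses()
    axis = 0 if by == "item" else 1
    infit, outfit, n = infit_outfit_from_moments(
        X.to_numpy(), E.to_numpy(), V.to_numpy(), axis=axis)
    index = result.items if by == "item" else result.persons
    df = pd.DataFrame({"infit": infit, "outfit": outfit, "n_obs": n},
                      index=index)
    df["classification"] = [classify_fit(v, cfg) for v in df["infit"]]
    return df


def separation_reliability(measures: np.ndarray, ses: np.ndarray
                           ) -> Tuple[float, float]:
    """Rasch reliability R and separation index G = sqrt(R/(1-R)).

    Adjusted (true) variance is observed variance minus mean squared SE,
    floored at zero; R is their ratio.  A degenerate sample (zero observed
    variance) returns (0, 0).
    """
    measures = np.asarray(measures, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if measures.size < 2:
        raise ValueError("need >= 2 non-extreme measures")
    obs_var = float(np.var(measures, ddof=1))
    if obs_var <= 0:
        return 0.0, 0.0
    err_var = float(np.mean(ses**2))
    adj = max(obs_var - err_var, 0.0)
    R = adj / obs_var
    if R >= 1.0:
        R = np.nextafter(1.0, 0.0)
    G = float(np.sqrt(R / (1.0 - R)))
    return float(R), G


def separation_from_reliability(R: float) -> float:
    """Closed form G = sqrt(R/(1-R)) linking the two published indices."""
    if not 0.0 <= R < 1.0:
        raise ValueError("reliability must lie in [0, 1)")
    return float(np.sqrt(R / (1.0 - R)))


@dataclass
class ResidualPCA:
    eigenvalues: np.ndarray      # descending, item units (sum = n items kept)
    first_contrast: float
    n_items: int
    dropped_items: List[str]
    unidimensional: bool
    cut: float


def pca_residuals(z: pd.DataFrame,
                  config: Optional[AnalysisConfig] = None) -> ResidualPCA:
    """Principal components of the inter-item residual correlation matrix.

    Pairwise-complete correlations; eigenvalues are in item units (their sum
    equals the number of retained items), so the first value is directly
    comparable to the conventional unidimensionality cuts.  Items with
    constant (or all-missing) residuals are dropped with a warning.
    """
    cfg = config or AnalysisConfig()
    if z.shape[1] < 3:
        raise ValueError("need >= 3 items for residual PCA")
    sd = z.std(ddof=0)
    dropped = [c for c in z.columns if not np.isfinite(sd[c]) or sd[c] <= 1e-12]
    if dropped:
        warnings.warn(f"dropping constant-residual items from PCA: {dropped}")
        z = z.drop(columns=dropped)
    corr = z.corr(min_periods=2)
    c = corr.to_numpy()
    np.fill_diagonal(c, 1.0)
    c = np.where(np.isfinite(c), c, 0.0)
    c = (c + c.T) / 2.0
    eig = np.linalg.eigvalsh(c)[::-1]
    first = float(eig[0])
    return ResidualPCA(
        eigenvalues=eig, first_contrast=first, n_items=z.shape[1],
        dropped_items=dropped, unidimensional=first < cfg.unidim_eigen_cut,
        cut=cfg.unidim_eigen_cut,
    )


def local_independence(z: pd.DataFrame, threshold: float = 0.3) -> pd.DataFrame:
    """Item pairs whose residual correlation exceeds the threshold in
    magnitude, sorted by |r| descending — candidate local-dependence pairs."""
    corr = z.corr(min_periods=2)
    rows = []
    cols = list(z.columns)
    for a_i in range(len(cols)):
        for b_i in range(a_i + 1, len(cols)):
            r = corr.iloc[a_i, b_i]
            if np.isfinite(r) and abs(r) > threshold:
                rows.append({"item_a": cols[a_i], "item_b": cols[b_i],
                             "r": float(r)})
    df = pd.DataFrame(rows, columns=["item_a", "item_b", "r"])
    if len(df):
        df = df.reindex(df["r"].abs().sort_values(ascending=False).index)
        df = df.reset_index(drop=True)
    return df


def kr20(matrix, spec=None) -> float:
    """Kuder-Richardson formula 20 internal consistency for dichotomous items.

    ``matrix`` may be a ResponseMatrix (optionally with a spec to select the
    dichotomous items) or a persons x items 0/1 DataFrame.  Rows with any
    missing value are dropped (listwise deletion).

        KR-20 = k/(k-1) * (1 - sum p_i q_i / var(total))

    which coincides with Cronbach's alpha on 0/1 data.
    """
    if hasattr(matrix, "to_dataframe"):
        df = matrix.to_dataframe()
        if spec is not None:
            keep = [i for i in df.columns
                    if i in spec and spec[i].n_categories == 2]
            df = df[keep]
    else:
        df = pd.DataFrame(matrix)
    df = df.dropna(axis=0, how="any")
    vals = df.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("KR-20 requires >= 2 dichotomous items")
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("KR-20 requires dichotomous (0/1) responses")
    k = vals.shape[1]
    p = vals.mean(axis=0)
    pq = p * (1 - p)
    total_var = np.var(vals.sum(axis=1), ddof=0)
    if total_var <= 0:
        raise ValueError("total score variance is zero; KR-20 undefined")
    return float(k / (k - 1) * (1.0 - pq.sum() / total_var))


@dataclass
class DiagnosticsReport:
    """Bundle of the fit / reliability / dimensionality diagnostics."""
    item_fit: pd.DataFrame
    person_fit: pd.DataFrame
    person_reliability: float
    person_separation: float
    item_reliability: float
    item_separation: float
    pca: ResidualPCA
    dependent_pairs: pd.DataFrame
    kr20: Optional[float]


def diagnose(result, config: Optional[AnalysisConfig] = None
             ) -> DiagnosticsReport:
    """Run the full diagnostic battery on a calibration."""
    cfg = config or result.config
    z = standardized_residuals(result)
    R_p, G_p = result.reliability("persons")
    R_i, G_i = result.reliability("items")
    spec = result.model.spec
    dich = [i for i in result.items if spec[i].n_categories == 2]
    alpha = None
    if len(dich) >= 2:
        df = result.responses()[dich]
        try:
            alpha = kr20(df)
        except ValueError:
            alpha = None
    return DiagnosticsReport(
        item_fit=infit_outfit(result, "item", cfg),
        person_fit=infit_outfit(result, "person", cfg),
        person_reliability=R_p, person_separation=G_p,
        item_reliability=R_i, item_separation=G_i,
        pca=pca_residuals(z, cfg),
        dependent_pairs=local_independence(z, cfg.residual_corr_threshold),
        kr20=alpha,
    )
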