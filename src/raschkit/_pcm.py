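"""Numeric kernel for the mixed rating-scale / partial-credit Rasch model.

Parameterisation (Masters / Andrich): for item i with m_i ordered categories,
difficulty delta_i and group step thresholds tau_g1..tau_g(m-1) summing to 0,

    P(X = k | theta) = exp( sum_{j<=k} (theta - delta_i - tau_gj) ) / Z,

with the empty sum equal to 0 and Z the sum of the numerators over
k = 0..m_i-1.  A dichotomous item has a single threshold fixed at 0 and
reduces to the simple logistic Rasch model.

Arrays: X is persons x items int with -1 for missing; m is the per-item
category count; taus maps scale-group index -> threshold vector.  All
estimation is deterministic (no randomness anywhere in this module).
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

MISSING = -1


class DivergenceError(RuntimeError):
    """A parameter left the plausible logit range during estimation."""


def step_locations(delta: np.ndarray, taus: Dict[int, np.ndarray],
                   group_of_item: np.ndarray, m: np.ndarray) -> np.ndarray:
    """(I, max_m-1) matrix of step difficulties delta_i + tau_gj; NaN padded."""
    I = delta.shape[0]
    M = int(m.max())
    S = np.full((I, M - 1), np.nan)
    for i in range(I):
        tau = taus[int(group_of_item[i])]
        S[i, : m[i] - 1] = delta[i] + tau
    return S


def category_probs(theta: np.ndarray, delta: np.ndarray,
                   taus: Dict[int, np.ndarray], group_of_item: np.ndarray,
                   m: np.ndarray) -> np.ndarray:
    """(N, I, max_m) category probabilities; zero beyond each item's range."""
    S = step_locations(delta, taus, group_of_item, m)
    return category_probs_from_steps(theta, S, m)


def category_probs_from_steps(theta: np.ndarray, S: np.ndarray,
                              m: np.ndarray) -> np.ndarray:
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    I, Mm1 = S.shape
    M = Mm1 + 1
    k = np.arange(M)
    cumS = np.concatenate(
        [np.zeros((I, 1)), np.nancumsum(S, axis=1)], axis=1)      # (I, M)
    logits = theta[:, None, None] * k[None, None, :] - cumS[None, :, :]
    invalid = k[None, :] >= m[:, None]                             # (I, M)
    logits = np.where(invalid[None, :, :], -np.inf, logits)
    logits -= logits.max(axis=2, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=2, keepdims=True)
    return p


def moments(p: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Expected category value and variance per (person, item)."""
    M = p.shape[2]
    k = np.arange(M, dtype=float)
    E = (p * k).sum(axis=2)
    V = (p * k**2).sum(axis=2) - E**2
    return E, np.maximum(V, 0.0)


def exceed_probs(p: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Q[n, i, t] = P(X_ni >= t+1) for thresholds t = 0..max_m-2."""
    M = p.shape[2]
    # reversed cumulative sum: P(X >= k)
    ge = np.flip(np.cumsum(np.flip(p, axis=2), axis=2), axis=2)
    return ge[:, :, 1:M]


def loglik(X: np.ndarray, p: np.ndarray) -> float:
    obs = X != MISSING
    n_idx, i_idx = np.nonzero(obs)
    pr = p[n_idx, i_idx, X[n_idx, i_idx]]
    return float(np.log(np.clip(pr, 1e-300, None)).sum())


def _newton_step(grad: np.ndarray, info: np.ndarray, cap: float = 1.0) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        step = grad / info
    step[~np.isfinite(step)] = 0.0
    return np.clip(step, -cap, cap)


def jmle(X: np.ndarray, m: np.ndarray, group_of_item: np.ndarray,
         group_sizes: Dict[int, int],
         theta0: np.ndarray, delta0: np.ndarray,
         taus0: Dict[int, np.ndarray],
         tol: float = 0.005, max_iter: int = 200,
         divergence_limit: float = 30.0,
         anchor_theta: bool = False) -> dict:
    """Joint maximum likelihood for the mixed RSM/PCM model.

    Alternates damped Newton updates of person measures theta, item
    difficulties delta and group thresholds tau (diagonal information),
    re-centering delta to mean zero each sweep (tau to sum zero per group,
    compensated into delta so step locations are unchanged).  Missing cells
    contribute nothing to any sum.  With ``anchor_theta`` the person
    measures are held fixed and only delta is updated (DIF re-estimation).

    Returns estimates, standard errors (inverse root observed information),
    the iteration trace and a convergence flag.
    """
    X = np.asarray(X)
    obs = X != MISSING
    N, I = X.shape
    theta = theta0.astype(float).copy()
    delta = delta0.astype(float).copy()
    taus = {g: t.astype(float).copy() for g, t in taus0.items()}
    Xval = np.where(obs, X, 0)

    def probs():
        return category_probs(theta, delta, taus, group_of_item, m)

    trace: List[dict] = []
    converged = False
    max_change = np.inf
    for it in range(1, max_iter + 1):
        max_change = 0.0

        if not anchor_theta:
            # --- persons ---
            p = probs()
            E, V = moments(p)
            grad = ((Xval - E) * obs).sum(axis=1)
            info = (V * obs).sum(axis=1)
            step = _newton_step(grad, info)
            ll0 = loglik(X, p)
            for _ in range(6):
                theta_try = theta + step
                p_try = category_probs(theta_try, delta, taus, group_of_item, m)
                if loglik(X, p_try) >= ll0 - 1e-10:
                    break
                step *= 0.5
            else:
                step[:] = 0.0
            theta = theta + step
            max_change = max(max_change, float(np.abs(step).max(initial=0.0)))

        # --- items ---
        p = probs()
        E, V = moments(p)
        grad = ((E - Xval) * obs).sum(axis=0)   # dL/ddelta = sum(E - x); ascend
        info = (V * obs).sum(axis=0)
        step = _newton_step(grad, info)
        ll0 = loglik(X, p)
        for _ in range(6):
            delta_try = delta + step
            p_try = category_probs(theta, delta_try, taus, group_of_item, m)
            if loglik(X, p_try) >= ll0 - 1e-10:
                break
            step *= 0.5
        else:
            step[:] = 0.0
        delta = delta + step
        max_change = max(max_change, float(np.abs(step).max(initial=0.0)))

        # --- thresholds (groups with >= 3 categories) ---
        if not anchor_theta:
            p = probs()
            Q = exceed_probs(p, m)
            for g, tau in taus.items():
                if tau.shape[0] < 2:
                    continue  # dichotomous: single threshold fixed at 0
                cols = np.nonzero(group_of_item == g)[0]
                T = tau.shape[0]
                grad = np.zeros(T)
                info = np.zeros(T)
                for t in range(T):
                    ind = (Xval[:, cols] >= t + 1) & obs[:, cols]
                    q = Q[:, cols, t]
                    w = obs[:, cols]
                    grad[t] = float(((q - ind) * w).sum())
                    info[t] = float((q * (1 - q) * w).sum())
                step = _newton_step(grad, info)
                ll0 = loglik(X, p)
                for _ in range(6):
                    tau_try = tau + step
                    taus_try = dict(taus)
                    taus_try[g] = tau_try
                    p_try = category_probs(theta, delta, taus_try,
                                           group_of_item, m)
                    if loglik(X, p_try) >= ll0 - 1e-10:
                        break
                    step *= 0.5
                else:
                    step[:] = 0.0
                taus[g] = tau + step
                max_change = max(max_change, float(np.abs(step).max(initial=0.0)))
                p = probs()
                Q = exceed_probs(p, m)
            # re-centre tau to sum zero, compensating into delta
            for g, tau in taus.items():
                if tau.shape[0] < 2:
                    continue
                shift = tau.mean()
                if shift != 0.0:
                    taus[g] = tau - shift
                    delta[group_of_item == g] += shift

        # --- identification: items mean zero ---
        if not anchor_theta:
            c = delta.mean()
            delta -= c
            theta -= c  # keep person-item relation; persons free otherwise

        biggest = max(
            float(np.abs(theta).max(initial=0.0)),
            float(np.abs(delta).max(initial=0.0)),
            max((float(np.abs(t).max(initial=0.0)) for t in taus.values()),
                default=0.0),
        )
        if biggest > divergence_limit:
            raise DivergenceError(
                f"parameter magnitude {biggest:.1f} exceeds "
                f"{divergence_limit} logits"
            )

        p = probs()
        trace.append({"iteration": it, "max_change": max_change,
                      "loglik": loglik(X, p)})
        if max_change < tol:
            converged = True
            break

    # --- standard errors at the solution ---
    p = probs()
    E, V = moments(p)
    with np.errstate(divide="ignore"):
        se_theta = 1.0 / np.sqrt((V * obs).sum(axis=1))
        se_delta = 1.0 / np.sqrt((V * obs).sum(axis=0))
    Q = exceed_probs(p, m)
    se_taus: Dict[int, np.ndarray] = {}
    for g, tau in taus.items():
        cols = np.nonzero(group_of_item == g)[0]
        T = tau.shape[0]
        se = np.zeros(T)
        for t in range(T):
            q = Q[:, cols, t]
            w = obs[:, cols]
            inf = float((q * (1 - q) * w).sum())
            se[t] = 1.0 / np.sqrt(inf) if inf > 0 else np.nan
        se_taus[g] = se

    return {
        "theta": theta, "delta": delta, "taus": taus,
        "se_theta": se_theta, "se_delta": se_delta, "se_taus": se_taus,
        "converged": converged, "n_iter": len(trace),
        "max_change": max_change, "trace": trace,
        "loglik": trace[-1]["loglik"] if trace else np.nan,
    }


def prox_initialize(X: np.ndarray, m: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Normal-approximation (PROX) warm start for theta and delta.

    Uses log-odds of each person's score proportion and of each item's
    score proportion, with the classical variance-expansion factor
    sqrt(1 + sigma^2/2.9) applied using the spread of the opposite facet.
    Extreme rows/columns must already be removed.
    """
    obs = X != MISSING
    Xval = np.where(obs, X, 0)
    maxima = (m - 1).astype(float)
    r = Xval.sum(axis=1).astype(float)
    Rmax = (obs * maxima[None, :]).sum(axis=1)
    p_person = np.clip(r / Rmax, 1e-3, 1 - 1e-3)
    theta0 = np.log(p_person / (1 - p_person))

    s = Xval.sum(axis=0).astype(float)
    Smax = (obs * maxima[None, :]).sum(axis=0)
    p_item = np.clip(s / Smax, 1e-3, 1 - 1e-3)
    delta0 = -np.log(p_item / (1 - p_item))
    delta0 -= delta0.mean()

    theta0 = theta0 * np.sqrt(1.0 + np.var(delta0) / 2.9)
    delta0 = delta0 * np.sqrt(1.0 + np.var(theta0) / 2.9)
    delta0 -= delta0.mean()
    return theta0, delta0


def solve_theta_for_expected(target: float, delta: np.ndarray,
                             taus: Dict[int, np.ndarray],
                             group_of_item: np.ndarray, m: np.ndarray,
                             lo: float = -50.0, hi: float = 50.0) -> float:
    """theta whose expected total score on the given items equals target."""
    from scipy.optimize import brentq

    def f(th):
        p = category_probs(np.array([th]), delta, taus, group_of_item, m)
        E, _ = moments(p)
        return float(E.sum()) - target

    return float(brentq(f, lo, hi, xtol=1e-8))
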